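"""Patch extraction, fraction statistics, W1 distance and threshold baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from conftest import make_level_channels
from ihcscreen.patches import (
    ThresholdPair,
    classify_by_threshold,
    extract_top_patches,
    fit_gamma,
    fit_gaussian_thresholds,
    mean_channel_intensity,
    protein_fraction,
    response_map,
    select_patch_count,
    vote_patch_labels,
    wasserstein_1d,
)


class TestResponseMap:
    def test_constant_field(self):
        rm = response_map(np.full((10, 10), 0.7), size=4)
        assert rm.shape == (7, 7)
        assert np.allclose(rm, 0.7)

    def test_impulse_response_of_mean_filter(self):
        img = np.zeros((9, 9))
        img[4, 4] = 2.0
        rm = response_map(img, size=3)
        assert rm.max() == pytest.approx(2.0 / 9)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.random((8, 8))
        rm = response_map(img, size=4)
        brute = np.array(
            [[img[r : r + 4, c : c + 4].mean() for c in range(5)] for r in range(5)]
        )
        assert np.allclose(rm, brute, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            response_map(np.zeros((3, 3)), size=4)


class TestExtractTopPatches:
    def test_single_blob_k1_centered_on_maximum(self):
        img = np.zeros((40, 40))
        img[10:20, 14:24] = 1.0
        ps = extract_top_patches(img, k=1, size=10)
        assert (ps.patches[0].row0, ps.patches[0].col0) == (10, 14)
        assert ps.patches[0].fraction == pytest.approx(100.0)

    def test_constant_image_first_admissible_row_major(self):
        ps = extract_top_patches(np.ones((20, 20)), k=3, size=8)
        # all responses tie; suppression admits disjoint origins in row-major order
        assert [(p.row0, p.col0) for p in ps.patches] == [(0, 0), (0, 8), (8, 0)]

    def test_two_regions_ranked_by_intensity(self):
        img = np.zeros((30, 60))
        img[5:15, 5:15] = 0.5  # weaker region
        img[5:15, 40:50] = 1.0  # stronger region
        ps = extract_top_patches(img, k=2, size=10)
        assert (ps.patches[0].row0, ps.patches[0].col0) == (5, 40)
        assert (ps.patches[1].row0, ps.patches[1].col0) == (5, 5)

    def test_unsuppressed_mode_matches_full_sort(self, rng):
        img = rng.random((16, 16))
        rm = response_map(img, size=4)
        order = np.argsort(-rm, axis=None, kind="stable")[:5]
        expect = list(zip(*np.unravel_index(order, rm.shape)))
        ps = extract_top_patches(img, k=5, size=4, min_separation=1)
        assert [(p.row0, p.col0) for p in ps.patches] == [(int(r), int(c)) for r, c in expect]

    def test_deterministic(self, rng):
        img = rng.random((32, 32))
        a = extract_top_patches(img, k=6, size=8)
        b = extract_top_patches(img, k=6, size=8)
        assert [(p.row0, p.col0) for p in a.patches] == [(p.row0, p.col0) for p in b.patches]

    def test_k_exceeding_origins_rejected(self):
        with pytest.raises(ValueError):
            extract_top_patches(np.zeros((10, 10)), k=10, size=10)


class TestProteinFraction:
    def test_blank_and_saturated(self):
        assert protein_fraction(np.zeros((10, 10))) == 0.0
        assert protein_fraction(np.ones((10, 10))) == 100.0

    def test_constructed_thirty_percent(self):
        patch = np.zeros((10, 10))
        patch.ravel()[:30] = 1.0
        assert protein_fraction(patch, od_threshold=0.5) == pytest.approx(30.0)

    def test_location_invariance(self, rng):
        content = rng.random((6, 6))
        assert protein_fraction(content) == protein_fraction(content.copy())


class TestWasserstein:
    def test_identity(self, rng):
        x = rng.normal(size=40)
        assert wasserstein_1d(x, x) == 0.0

    def test_sorted_pairing_example(self):
        assert wasserstein_1d([0, 1], [1, 2]) == pytest.approx(1.0)

    def test_brute_force_sorted_pairing_oracle(self, rng):
        """Equal-size samples: W1 = mean |sorted(a) - sorted(b)|."""
        for n in (3, 17, 200):
            a, b = rng.normal(size=n), rng.gamma(2.0, 1.5, size=n)
            brute = np.mean(np.abs(np.sort(a) - np.sort(b)))
            assert wasserstein_1d(a, b) == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy_unequal_sizes(self, rng):
        a, b = rng.normal(size=53), rng.normal(1.0, 2.0, size=87)
        assert wasserstein_1d(a, b) == pytest.approx(
            sstats.wasserstein_distance(a, b), abs=1e-12
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        xs=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        ys=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        c=st.floats(-20, 20),
    )
    def test_symmetry_and_translation(self, xs, ys, c):
        d = wasserstein_1d(xs, ys)
        assert d == pytest.approx(wasserstein_1d(ys, xs), abs=1e-9)
        # translating both samples leaves the distance unchanged
        assert wasserstein_1d(np.add(xs, c), np.add(ys, c)) == pytest.approx(d, abs=1e-9)

    def test_shift_of_identical_shape_equals_offset(self, rng):
        x = np.sort(rng.normal(size=25))
        assert wasserstein_1d(x, x + 3.5) == pytest.approx(3.5, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestGammaFit:
    def test_parameter_recovery(self, rng):
        x = rng.gamma(2.0, 3.0, size=10000)
        fit = fit_gamma(x)
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.scale == pytest.approx(3.0, rel=0.05)
        assert fit.mean == pytest.approx(x.mean(), rel=0.01)

    def test_exponential_special_case(self, rng):
        x = rng.exponential(2.0, size=8000)
        assert fit_gamma(x).shape == pytest.approx(1.0, rel=0.07)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([3.0])
        with pytest.raises(ValueError):
            fit_gamma([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fit_gamma([0.0, 0.0])

    def test_zeros_are_imputed_not_fatal(self, rng):
        x = np.concatenate([rng.gamma(2.0, 3.0, size=500), [0.0, 0.0]])
        assert fit_gamma(x).shape > 0


class TestSelectPatchCount:
    def test_identically_rendered_levels_give_zero_distance(self):
        """Levels backed by the very same channels pool identical samples."""
        from ihcscreen.synthetic import SyntheticSpec, generate_image

        base = [
            generate_image(
                SyntheticSpec(width=96, height=96, n_nuclei=8, stained_fraction=0.4,
                              dab_od=0.7, seed=s),
                "medium",
            ).protein_od_truth
            for s in range(4)
        ]
        channels = base * 3
        labels = ["low"] * 4 + ["medium"] * 4 + ["high"] * 4
        res = select_patch_count(
            channels, labels, grid=(3, 7), repeats=2, n_per_level=4, size=32, seed=0
        )
        assert np.allclose(res.summed, 0.0)

    def test_null_sampling_variation_far_below_separated_family(self):
        """Same distribution per level: distances dwarfed by real separation."""
        from ihcscreen.synthetic import SyntheticSpec, generate_image

        null_ch, sep_ch, labels = [], [], []
        for li, lev in enumerate(("low", "medium", "high")):
            for s in range(4):
                null_ch.append(
                    generate_image(
                        SyntheticSpec(width=96, height=96, n_nuclei=8,
                                      stained_fraction=0.4, dab_od=0.7, seed=li * 10 + s),
                        lev,
                    ).protein_od_truth
                )
                sep_ch.append(
                    generate_image(
                        SyntheticSpec(width=96, height=96, n_nuclei=8, seed=li * 10 + s), lev
                    ).protein_od_truth
                )
                labels.append(lev)
        kw = dict(grid=(3, 7), repeats=2, n_per_level=4, size=32, seed=0)
        null = select_patch_count(null_ch, labels, **kw).summed.max()
        sep = select_patch_count(sep_ch, labels, **kw).summed.min()
        assert null < 0.25 * sep

    def test_singleton_grid(self):
        channels, labels = make_level_channels(width=96, per_level=2)
        res = select_patch_count(
            channels, labels, grid=(11,), repeats=1, n_per_level=2, size=24, seed=0
        )
        assert res.chosen_k == 11

    def test_missing_level_rejected(self):
        channels, labels = make_level_channels(width=64, per_level=1)
        bad = [c for c, l in zip(channels, labels) if l != "low"]
        with pytest.raises(ValueError):
            select_patch_count(bad, ["medium", "high"], grid=(3,), size=24)

    def test_additivity_on_ordered_family(self):
        """Stochastically ordered levels: d(H,L) ~ d(H,M) + d(M,L)."""
        channels, labels = make_level_channels(width=160, per_level=4)
        res = select_patch_count(
            channels, labels, grid=(5, 11, 21), repeats=2, n_per_level=4, size=24, seed=1
        )
        hm = res.d_high_medium.mean(axis=1)
        ml = res.d_medium_low.mean(axis=1)
        hl = res.d_high_low.mean(axis=1)
        assert np.all(np.abs(hl - (hm + ml)) <= 0.15 * hl)


class TestGaussianThresholds:
    def test_equal_variance_midpoint(self, rng):
        frac = {
            "low": rng.normal(40, 5, 4000),
            "medium": rng.normal(60, 5, 4000),
            "high": rng.normal(90, 5, 4000),
        }
        t = fit_gaussian_thresholds(frac)
        assert t.t_low_med == pytest.approx(50.0, abs=0.5)
        assert t.t_med_high == pytest.approx(75.0, abs=0.5)

    def test_unequal_variance_matches_grid_oracle(self, rng):
        frac = {
            "low": rng.normal(30, 4, 6000),
            "medium": rng.normal(55, 10, 6000),
            "high": rng.normal(85, 6, 6000),
        }
        t = fit_gaussian_thresholds(frac)
        # dense numeric search for the density crossing between the means
        stats_ = {k: (np.mean(v), np.std(v)) for k, v in frac.items()}
        for lo, hi, got in [
            ("low", "medium", t.t_low_med),
            ("medium", "high", t.t_med_high),
        ]:
            (m1, s1), (m2, s2) = stats_[lo], stats_[hi]
            xs = np.linspace(m1, m2, 200001)
            diff = np.abs(sstats.norm.pdf(xs, m1, s1) - sstats.norm.pdf(xs, m2, s2))
            assert got == pytest.approx(xs[np.argmin(diff)], abs=0.01)

    def test_unordered_means_rejected(self, rng):
        frac = {
            "low": rng.normal(70, 5, 100),
            "medium": rng.normal(50, 5, 100),
            "high": rng.normal(90, 5, 100),
        }
        with pytest.raises(ValueError):
            fit_gaussian_thresholds(frac)

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair(t_low_med=70, t_med_high=50)


class TestThresholdClassifier:
    @pytest.mark.parametrize(
        "value,expected",
        [(40, "low"), (52, "medium"), (67.9, "medium"), (68, "high"), (90, "high")],
    )
    def test_published_threshold_pair(self, value, expected):
        t = ThresholdPair(t_low_med=52, t_med_high=68)
        assert classify_by_threshold(value, t) == expected

    def test_majority_vote_over_patches(self):
        t = ThresholdPair(t_low_med=52, t_med_high=68)
        assert vote_patch_labels([40, 55, 57, 90], t) == "medium"
        assert vote_patch_labels([90], t) == "high"
        with pytest.raises(ValueError):
            vote_patch_labels([], t)


class TestMeanChannelIntensity:
    def test_constant_no_background(self):
        assert mean_channel_intensity(np.full((5, 5), 0.8)) == pytest.approx(0.8)

    def test_background_exclusion(self):
        ch = np.zeros((4, 4))
        ch[:2] = 0.9
        assert mean_channel_intensity(ch, od_threshold=0.15) == pytest.approx(0.9)

    def test_masked_mean_oracle(self, synthetic_medium):
        ch = synthetic_medium.protein_od_truth
        mask = ch <= 0.15
        assert mean_channel_intensity(ch) == pytest.approx(ch[~mask].mean())

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            mean_channel_intensity(np.zeros((3, 3)))
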