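"""Patch-of-interest extraction and the Wasserstein patch-count criterion.

Whole IHC images carry large unstained stromal regions, so downstream
classification works on the K most protein-stained 224x224 patches of
each image.  A box (mean) filter slid over the unmixed protein channel
scores every candidate origin; the K highest-response windows are the
patches of interest.  K itself is chosen by maximizing the summed
pairwise 1-D Wasserstein distances between the per-level distributions
of patch protein-fraction values, and the same fraction statistics yield
the Gaussian-intersection threshold baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Patch",
    "PatchSet",
    "GammaFit",
    "PatchCountSearch",
    "ThresholdPair",
    "DEFAULT_K",
    "DEFAULT_PATCH_SIZE",
    "DEFAULT_OD_THRESHOLD",
    "DEFAULT_K_GRID",
    "response_map",
    "extract_top_patches",
    "protein_fraction",
    "wasserstein_1d",
    "fit_gamma",
    "select_patch_count",
    "fit_gaussian_thresholds",
    "classify_by_threshold",
    "vote_patch_labels",
    "mean_channel_intensity",
]

DEFAULT_K = 81
DEFAULT_PATCH_SIZE = 224
#: OD floor above which a protein-channel pixel counts as stained
DEFAULT_OD_THRESHOLD = 0.15
#: candidate patch counts searched by the Wasserstein criterion
DEFAULT_K_GRID = tuple(range(11, 202, 10))


@dataclass(frozen=True)
class Patch:
    row0: int
    col0: int
    size: int = DEFAULT_PATCH_SIZE
    fraction: float = 0.0  # percent of patch area stained, in [0, 100]
    response: float = 0.0  # mean protein OD under the window


@dataclass
class PatchSet:
    """Patches of one image in greedy selection order.

    Within each suppression round responses are non-increasing; a relaxed
    overlap round (entered only when the disjoint capacity is exhausted)
    restarts from the highest remaining response, so the global sequence
    is piecewise non-increasing rather than globally sorted.
    """

    image_id: str
    patches: list[Patch]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p.fraction for p in self.patches])


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    n: int

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class PatchCountSearch:
    grid: tuple[int, ...]
    #: per-K arrays of shape (repeats,) for each level pair
    d_high_medium: np.ndarray
    d_medium_low: np.ndarray
    d_high_low: np.ndarray
    chosen_k: int = 0

    @property
    def summed(self) -> np.ndarray:
        """Repeat-averaged summed distance per grid K."""
        return (
            self.d_high_medium.mean(axis=1)
            + self.d_medium_low.mean(axis=1)
            + self.d_high_low.mean(axis=1)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.grid,
                "d_high_medium": self.d_high_medium.mean(axis=1),
                "d_medium_low": self.d_medium_low.mean(axis=1),
                "d_high_low": self.d_high_low.mean(axis=1),
                "summed": self.summed,
            }
        )

    def plot(self, ax=None):
        """Distance-vs-K curves with the chosen K marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        frame = self.to_frame()
        for col, style in [
            ("d_high_medium", "C0.-"),
            ("d_medium_low", "C1.-"),
            ("d_high_low", "C2.-"),
            ("summed", "r.-"),
        ]:
            ax.plot(frame["k"], frame[col], style, label=col.replace("_", " "))
        ax.axvline(self.chosen_k, color="k", linestyle=":", label=f"chosen K={self.chosen_k}")
        ax.set_xlabel("patches per image (K)")
        ax.set_ylabel("Wasserstein distance")
        ax.legend(fontsize=8)
        return ax


@dataclass(frozen=True)
class ThresholdPair:
    t_low_med: float
    t_med_high: float

    def __post_init__(self) -> None:
        if not self.t_low_med < self.t_med_high:
            raise ValueError("thresholds must satisfy t_low_med < t_med_high")


def _integral(arr: np.ndarray) -> np.ndarray:
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=s[1:, 1:])
    return s


def _window_sums(arr: np.ndarray, size: int) -> np.ndarray:
    s = _integral(arr)
    return (
        s[size:, size:] - s[:-size, size:] - s[size:, :-size] + s[:-size, :-size]
    )


def response_map(protein_od: np.ndarray, size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Mean protein OD under every valid size x size window origin.

    Output shape is (H-size+1, W-size+1); entry (r, c) is the window mean
    with top-left corner (r, c).
    """
    protein_od = np.asarray(protein_od, dtype=float)
    if protein_od.ndim != 2:
        raise ValueError("protein channel must be 2-D")
    h, w = protein_od.shape
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than window size {size}")
    return _window_sums(protein_od, size) / (size * size)


def protein_fraction(
    patch_od: np.ndarray, od_threshold: float = DEFAULT_OD_THRESHOLD
) -> float:
    """Percent of patch pixels whose protein OD exceeds the positivity floor."""
    patch_od = np.asarray(patch_od)
    return 100.0 * float(np.mean(patch_od > od_threshold))


def extract_top_patches(
    protein_od: np.ndarray,
    k: int = DEFAULT_K,
    size: int = DEFAULT_PATCH_SIZE,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    image_id: str = "",
    min_separation: int | None = None,
) -> PatchSet:
    """Greedy top-k window origins by descending response with suppression.

    Candidate origins are visited in descending response order (ties
    row-major, fixed by a stable sort).  An origin is accepted only if its
    Chebyshev distance to every accepted origin is at least
    ``min_separation`` (default: the patch size, i.e. no overlap).  When
    the admissible origins at the current separation are exhausted before
    k patches are found, the separation is halved and the scan repeats, so
    overlapping patches appear only once the image's disjoint capacity is
    exceeded — small k yields disjoint patches of interest, excessive k
    degrades into overlapping, redundant ones.  ``min_separation=1``
    recovers the pure unsuppressed top-k.  Deterministic throughout.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    resp = response_map(protein_od, size)
    n_valid = resp.size
    if n_valid < k:
        raise ValueError(f"only {n_valid} valid origins but k={k} requested")
    sep = size if min_separation is None else int(min_separation)
    if sep < 1:
        raise ValueError("min_separation must be >= 1")
    order = np.argsort(-resp, axis=None, kind="stable")
    all_rows, all_cols = np.unravel_index(order, resp.shape)

    taken = np.zeros(n_valid, dtype=bool)
    sel_rows: list[int] = []
    sel_cols: list[int] = []
    nr, nc = resp.shape
    while len(sel_rows) < k and sep >= 1:
        blocked = np.zeros((nr, nc), dtype=bool)
        for r, c in zip(sel_rows, sel_cols):
            blocked[max(0, r - sep + 1) : r + sep, max(0, c - sep + 1) : c + sep] = True
        for i in range(n_valid):
            if len(sel_rows) >= k:
                break
            if taken[i]:
                continue
            r, c = int(all_rows[i]), int(all_cols[i])
            if blocked[r, c]:
                continue
            taken[i] = True
            sel_rows.append(r)
            sel_cols.append(c)
            blocked[max(0, r - sep + 1) : r + sep, max(0, c - sep + 1) : c + sep] = True
        sep //= 2
    rows, cols = np.array(sel_rows, dtype=int), np.array(sel_cols, dtype=int)
    # stained-pixel counts per window via a second integral image
    frac = _window_sums((np.asarray(protein_od) > od_threshold).astype(float), size)
    frac = 100.0 * frac / (size * size)
    patches = [
        Patch(
            row0=int(r),
            col0=int(c),
            size=size,
            fraction=float(frac[r, c]),
            response=float(resp[r, c]),
        )
        for r, c in zip(rows, cols)
    ]
    return PatchSet(image_id=image_id, patches=patches)


def wasserstein_1d(samples_a, samples_b) -> float:
    """First-order Wasserstein distance between two empirical distributions.

    Computed by integrating the absolute difference of the two empirical
    CDFs over the merged support (equivalently, quantile-function
    integration).  Handles unequal sample sizes; symmetric; zero iff the
    empirical distributions coincide.
    """
    a = np.sort(np.asarray(samples_a, dtype=float).ravel())
    b = np.sort(np.asarray(samples_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    support = np.concatenate([a, b])
    support.sort(kind="mergesort")
    deltas = np.diff(support)
    cdf_a = np.searchsorted(a, support[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, support[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def fit_gamma(samples) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at 0).

    Zeros are replaced by half the smallest positive sample (blank patches
    yield fraction 0, which lies outside the gamma support).  Degenerate
    all-equal or non-positive samples are rejected.
    """
    from scipy import stats

    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples to fit a gamma distribution")
    if np.any(x < 0):
        raise ValueError("gamma samples must be non-negative")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all samples are zero; gamma fit undefined")
    x = np.where(x == 0, pos.min() / 2.0, x)
    if np.all(x == x[0]):
        raise ValueError("degenerate constant sample; gamma fit undefined")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return GammaFit(shape=float(shape), scale=float(scale), n=int(x.size))


def select_patch_count(
    channels: list[np.ndarray],
    labels: list[str],
    grid: tuple[int, ...] = DEFAULT_K_GRID,
    repeats: int = 5,
    n_per_level: int = 100,
    size: int = DEFAULT_PATCH_SIZE,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    seed: int = 0,
) -> PatchCountSearch:
    """Search the patch count K by the summed pairwise Wasserstein criterion.

    For each repeat, ``n_per_level`` images are sampled per expression
    level; for each K in the grid the first K (highest-response) patch
    protein fractions of every sampled image are pooled per level, and the
    three pairwise W1 distances between the pooled level distributions are
    recorded.  chosen_k maximizes the repeat-averaged summed distance.

    ``channels`` are unmixed protein OD maps aligned with ``labels``.
    Patches are extracted once at max(grid) per image and reused (top-K
    selection is nested in K), so the search cost is one extraction pass.
    """
    grid = tuple(grid)
    if len(grid) == 0 or any(a >= b for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be non-empty and strictly increasing")
    by_level: dict[str, list[int]] = {"high": [], "medium": [], "low": []}
    for i, lab in enumerate(labels):
        if lab not in by_level:
            raise ValueError(f"unknown level {lab!r}")
        by_level[lab].append(i)
    missing = [lev for lev, idx in by_level.items() if not idx]
    if missing:
        raise ValueError(f"levels {missing} have no images")

    kmax = grid[-1]
    fractions: dict[int, np.ndarray] = {}
    for i, ch in enumerate(channels):
        ps = extract_top_patches(ch, k=kmax, size=size, od_threshold=od_threshold)
        fractions[i] = ps.fractions

    rng = np.random.default_rng(seed)
    n_k = len(grid)
    d_hm = np.zeros((n_k, repeats))
    d_ml = np.zeros((n_k, repeats))
    d_hl = np.zeros((n_k, repeats))
    for rep in range(repeats):
        sampled: dict[str, list[int]] = {}
        for lev, idx in by_level.items():
            replace = len(idx) < n_per_level
            sampled[lev] = list(rng.choice(idx, size=n_per_level, replace=replace))
        for ki, k in enumerate(grid):
            pools = {
                lev: np.concatenate([fractions[i][:k] for i in sampled[lev]])
                for lev in by_level
            }
            d_hm[ki, rep] = wasserstein_1d(pools["high"], pools["medium"])
            d_ml[ki, rep] = wasserstein_1d(pools["medium"], pools["low"])
            d_hl[ki, rep] = wasserstein_1d(pools["high"], pools["low"])

    summed = d_hm.mean(axis=1) + d_ml.mean(axis=1) + d_hl.mean(axis=1)
    chosen = grid[int(np.argmax(summed))]
    return PatchCountSearch(
        grid=grid, d_high_medium=d_hm, d_medium_low=d_ml, d_high_low=d_hl, chosen_k=chosen
    )


def _gaussian_intersection(m1: float, s1: float, m2: float, s2: float) -> float:
    """Crossing point of two normal densities, taken between the means.

    Equal variances give the midpoint; otherwise the quadratic from
    equating log-densities is solved and the root inside (m1, m2) is
    returned (nearest root to the midpoint if neither lies inside).
    """
    if m1 >= m2:
        raise ValueError("means must be ordered m1 < m2")
    if np.isclose(s1, s2):
        return (m1 + m2) / 2.0
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + np.log(s1 / s2)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    if roots.size == 0:
        return (m1 + m2) / 2.0
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size:
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - (m1 + m2) / 2.0))])


def fit_gaussian_thresholds(fractions_by_level: dict[str, np.ndarray]) -> ThresholdPair:
    """Per-level Gaussian fits and their adjacent density intersections.

    Requires non-empty low/medium/high samples with strictly ordered means;
    the low/medium and medium/high crossing points become the two decision
    thresholds of the fraction-baseline classifier.
    """
    stats_ = {}
    for lev in ("low", "medium", "high"):
        x = np.asarray(fractions_by_level.get(lev, ()), dtype=float).ravel()
        if x.size == 0:
            raise ValueError(f"level {lev!r} has no samples")
        stats_[lev] = (float(x.mean()), float(x.std()))
    m_lo, s_lo = stats_["low"]
    m_md, s_md = stats_["medium"]
    m_hi, s_hi = stats_["high"]
    if not m_lo < m_md < m_hi:
        raise ValueError("level means must be ordered low < medium < high")
    t1 = _gaussian_intersection(m_lo, s_lo, m_md, s_md)
    t2 = _gaussian_intersection(m_md, s_md, m_hi, s_hi)
    return ThresholdPair(t_low_med=t1, t_med_high=t2)


def classify_by_threshold(value: float, thresholds: ThresholdPair) -> str:
    """Threshold a fraction (or intensity) into a level.

    Left-closed on the upper class: value >= t belongs to the class above t.
    """
    if value < thresholds.t_low_med:
        return "low"
    if value < thresholds.t_med_high:
        return "medium"
    return "high"


def vote_patch_labels(values, thresholds: ThresholdPair) -> str:
    """Image-level label as the majority vote over per-patch threshold calls.

    Ties broken by class order high > medium > low.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no patch values to vote over")
    counts = {"high": 0, "medium": 0, "low": 0}
    for v in values:
        counts[classify_by_threshold(float(v), thresholds)] += 1
    return max(("high", "medium", "low"), key=lambda lev: (counts[lev], -("high", "medium", "low").index(lev)))


def mean_channel_intensity(
    protein_od: np.ndarray,
    background_mask: np.ndarray | None = None,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
) -> float:
    """Mean protein OD over foreground (non-background) pixels.

    Background defaults to pixels at or below the stain positivity floor.
    """
    protein_od = np.asarray(protein_od, dtype=float)
    if background_mask is None:
        background_mask = protein_od <= od_threshold
    else:
        background_mask = np.asarray(background_mask, dtype=bool)
        if background_mask.shape != protein_od.shape:
            raise ValueError("mask shape must match channel shape")
    fg = ~background_mask
    if not fg.any():
        raise ValueError("empty foreground: every pixel is background")
    return float(protein_od[fg].mean())
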