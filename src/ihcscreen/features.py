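"""The 1247-dimensional handcrafted color descriptor.

Five blocks describe the color distribution of an IHC image or patch:

======================  ====  =========================================
block                   size  content
======================  ====  =========================================
color histogram         1012  10x10x10 joint RGB histogram + 12-bin hue
color moments             33  mean/var/skew/kurt of R,G,B,H,S,V + the
                              median/min/max of R,G,B
color coherence vector    54  (coherent, incoherent) pixel fractions for
                              27 quantized RGB colors
color correlogram        128  autocorrelogram over 32 HSV colors at
                              Chebyshev distances 1, 3, 5, 7
characteristic curve      20  stain-colored pixel percentage p(s_low) at
                              20 rising saturation lower bounds
======================  ====  =========================================

The characteristic curve targets the brown DAB chromogen: a pixel counts
as stain-colored when its hue lies in the brown window, its value in the
mid range, and its saturation exceeds the moving lower bound s_low; the
resulting curve is non-increasing in s_low and encodes how much of the
staining is strongly saturated.

Patch descriptors are aggregated to an image descriptor by the
component-wise mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats
from skimage import measure as _skmeasure
from skimage.color import rgb2hsv

__all__ = [
    "CharacteristicCurveConfig",
    "FeatureConfig",
    "FeatureVector",
    "BLOCK_SIZES",
    "color_histogram",
    "color_moments",
    "color_coherence_vector",
    "color_correlogram",
    "characteristic_curve",
    "extract_features",
    "feature_names",
]

#: block name -> expected length
BLOCK_SIZES = {
    "histogram": 1012,
    "moments": 33,
    "ccv": 54,
    "correlogram": 128,
    "curves": 20,
}
TOTAL_FEATURES = sum(BLOCK_SIZES.values())  # 1247


@dataclass(frozen=True)
class CharacteristicCurveConfig:
    """Stain-color gate and saturation grid of the characteristic curve.

    Hue in degrees [0, 360); the default window [20, 50) brackets the
    brown DAB hue.  Value bounds exclude near-black and near-white
    pixels.  The 20 saturation lower bounds rise 0.10..0.48 in steps of
    0.02.
    """

    h1: float = 20.0
    h2: float = 50.0
    v1: float = 0.2
    v2: float = 0.95
    s_low_grid: tuple[float, ...] = tuple(np.round(0.10 + 0.02 * np.arange(20), 10))

    def __post_init__(self) -> None:
        if not self.h1 < self.h2:
            raise ValueError("hue bounds must satisfy h1 < h2")
        if not self.v1 < self.v2:
            raise ValueError("value bounds must satisfy v1 < v2")
        g = np.asarray(self.s_low_grid)
        if g.size != 20 or np.any(np.diff(g) <= 0):
            raise ValueError("s_low_grid must be 20 strictly increasing values")


@dataclass(frozen=True)
class FeatureConfig:
    rgb_bins: int = 10  # per-axis joint RGB histogram resolution
    hue_bins: int = 12
    ccv_levels: int = 3  # quantization levels per RGB axis -> 27 colors
    ccv_tau: int = 25  # coherence area threshold in pixels
    correlogram_hsv_bins: tuple[int, int, int] = (4, 4, 2)  # -> 32 colors
    correlogram_distances: tuple[int, ...] = (1, 3, 5, 7)
    curve: CharacteristicCurveConfig = CharacteristicCurveConfig()

    def __post_init__(self) -> None:
        sizes = self.block_sizes()
        if sizes != BLOCK_SIZES:
            raise ValueError(f"configuration emits block sizes {sizes}, expected {BLOCK_SIZES}")

    def block_sizes(self) -> dict[str, int]:
        h, s, v = self.correlogram_hsv_bins
        return {
            "histogram": self.rgb_bins**3 + self.hue_bins,
            "moments": 33,
            "ccv": 2 * self.ccv_levels**3,
            "correlogram": h * s * v * len(self.correlogram_distances),
            "curves": len(self.curve.s_low_grid),
        }


@dataclass
class FeatureVector:
    """1247 ordered components with a named block layout."""

    values: np.ndarray
    block_index: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TOTAL_FEATURES,):
            raise ValueError(f"feature vector must have length {TOTAL_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite components")
        if not self.block_index:
            self.block_index = default_block_index()

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_index[name]
        return self.values[lo:hi]


def default_block_index() -> dict[str, tuple[int, int]]:
    index, start = {}, 0
    for name, size in BLOCK_SIZES.items():
        index[name] = (start, start + size)
        start += size
    return index


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Stable per-component column names for feature tables."""
    names: list[str] = []
    b = config.rgb_bins
    names += [f"hist_rgb_{r}_{g}_{bb}" for r in range(b) for g in range(b) for bb in range(b)]
    names += [f"hist_hue_{i}" for i in range(config.hue_bins)]
    for ch in ("r", "g", "b", "h", "s", "v"):
        names += [f"moment_{ch}_{m}" for m in ("mean", "var", "skew", "kurt")]
    for ch in ("r", "g", "b"):
        names += [f"moment_{ch}_{m}" for m in ("median", "min", "max")]
    for c in range(config.ccv_levels**3):
        names += [f"ccv_{c}_coherent", f"ccv_{c}_incoherent"]
    h, s, v = config.correlogram_hsv_bins
    for c in range(h * s * v):
        names += [f"corr_{c}_d{d}" for d in config.correlogram_distances]
    names += [f"curve_slow_{sl:g}" for sl in config.curve.s_low_grid]
    return names


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    if image.size == 0:
        raise ValueError("empty image")
    return image


def _hsv(image: np.ndarray) -> np.ndarray:
    """HSV with hue in [0, 360), s and v in [0, 1]; gray pixels get hue 0."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    hsv = rgb2hsv(img)
    hsv[..., 0] *= 360.0
    return hsv


def color_histogram(image: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Joint 10x10x10 RGB histogram plus a 12-bin hue histogram (1012 values).

    Each sub-histogram is normalized to sum 1.
    """
    image = _check_rgb(image)
    b = config.rgb_bins
    q = (image.astype(int) * b) // 256
    flat = (q[..., 0] * b + q[..., 1]) * b + q[..., 2]
    joint = np.bincount(flat.ravel(), minlength=b**3).astype(float)
    joint /= joint.sum()

    hue = _hsv(image)[..., 0]
    hq = np.minimum((hue * config.hue_bins / 360.0).astype(int), config.hue_bins - 1)
    hhist = np.bincount(hq.ravel(), minlength=config.hue_bins).astype(float)
    hhist /= hhist.sum()
    return np.concatenate([joint, hhist])


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    x = x.ravel().astype(float)
    mean = float(x.mean())
    var = float(x.var())  # population convention
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    return (
        mean,
        var,
        float(_sstats.skew(x, bias=True)),
        float(_sstats.kurtosis(x, bias=True)),  # excess kurtosis
    )


def color_moments(image: np.ndarray) -> np.ndarray:
    """33 moment features: 4 moments x {R,G,B,H,S,V} + median/min/max of R,G,B.

    Variance is the population variance; skewness and excess kurtosis are
    defined as 0 for constant channels.
    """
    image = _check_rgb(image)
    hsv = _hsv(image)
    channels = [image[..., i] for i in range(3)] + [hsv[..., i] for i in range(3)]
    out: list[float] = []
    for ch in channels:
        out.extend(_moments(ch))
    for i in range(3):
        ch = image[..., i].astype(float)
        out.extend([float(np.median(ch)), float(ch.min()), float(ch.max())])
    return np.array(out)


def color_coherence_vector(
    image: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """(coherent, incoherent) pixel fractions for 27 quantized colors (54 values).

    Colors are quantized to ``ccv_levels`` per RGB axis; 8-connected
    components of at least ``ccv_tau`` pixels are coherent.  The 54
    fractions sum to 1.
    """
    image = _check_rgb(image)
    lv = config.ccv_levels
    q = (image.astype(int) * lv) // 256
    color = (q[..., 0] * lv + q[..., 1]) * lv + q[..., 2]
    n = color.size
    out = np.zeros(2 * lv**3)
    for c in np.unique(color):
        mask = color == c
        labels = _skmeasure.label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        coherent_labels = np.flatnonzero(sizes >= config.ccv_tau)
        coherent = int(sizes[coherent_labels].sum())
        total = int(mask.sum())
        out[2 * c] = coherent / n
        out[2 * c + 1] = (total - coherent) / n
    return out


def _quantize_hsv(image: np.ndarray, bins: tuple[int, int, int]) -> np.ndarray:
    hsv = _hsv(image)
    hb, sb, vb = bins
    h = np.minimum((hsv[..., 0] * hb / 360.0).astype(int), hb - 1)
    s = np.minimum((hsv[..., 1] * sb).astype(int), sb - 1)
    v = np.minimum((hsv[..., 2] * vb).astype(int), vb - 1)
    return (h * sb + s) * vb + v


def color_correlogram(
    image: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Autocorrelogram over 32 HSV colors at Chebyshev distances {1,3,5,7}.

    Entry (c, d) is the probability that a pixel at Chebyshev distance
    exactly d from a color-c pixel also has color c, over in-bounds
    neighbor positions; colors absent from the image yield 0.  128 values
    in [0, 1], ordered color-major.
    """
    image = _check_rgb(image)
    dmax = max(config.correlogram_distances)
    if min(image.shape[:2]) < 2 * dmax + 1:
        raise ValueError(f"image must be at least {2 * dmax + 1} pixels on each side")
    hb, sb, vb = config.correlogram_hsv_bins
    n_colors = hb * sb * vb
    q = _quantize_hsv(image, config.correlogram_hsv_bins)
    h, w = q.shape
    n_d = len(config.correlogram_distances)
    num = np.zeros((n_colors, n_d))
    den = np.zeros((n_colors, n_d))
    for di, d in enumerate(config.correlogram_distances):
        offsets = [
            (dy, dx)
            for dy in range(-d, d + 1)
            for dx in range(-d, d + 1)
            if max(abs(dy), abs(dx)) == d
        ]
        for dy, dx in offsets:
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            a = q[y0:y1, x0:x1].ravel()
            bq = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
            den[:, di] += np.bincount(a, minlength=n_colors)
            eq = a == bq
            num[:, di] += np.bincount(a[eq], minlength=n_colors)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return out.ravel()


def characteristic_curve(
    image: np.ndarray, config: CharacteristicCurveConfig = CharacteristicCurveConfig()
) -> np.ndarray:
    """p(s_low): percent of pixels inside the stain color gate, per s_low.

    A pixel qualifies when h1 <= h < h2, v1 <= v < v2 and s > s_low; the
    20 values (percent of all image pixels) are non-increasing in s_low.
    """
    image = _check_rgb(image)
    hsv = _hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    gate = (config.h1 <= h) & (h < config.h2) & (config.v1 <= v) & (v < config.v2)
    s_gated = s[gate]
    n = h.size
    return np.array([100.0 * np.count_nonzero(s_gated > sl) / n for sl in config.s_low_grid])


def _single_vector(image: np.ndarray, config: FeatureConfig) -> np.ndarray:
    return np.concatenate(
        [
            color_histogram(image, config),
            color_moments(image),
            color_coherence_vector(image, config),
            color_correlogram(image, config),
            characteristic_curve(image, config.curve),
        ]
    )


def extract_features(
    image: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
    patch_set=None,
) -> FeatureVector:
    """Descriptor of a whole image, or the mean descriptor of its patches.

    With ``patch_set`` (a :class:`ihcscreen.patches.PatchSet`), each patch
    window is cut from ``image`` and described separately; the per-patch
    vectors are averaged component-wise.  Both modes emit length-1247
    vectors with the standard block layout.
    """
    image = _check_rgb(image)
    if patch_set is None:
        return FeatureVector(values=_single_vector(image, config))
    if not patch_set.patches:
        raise ValueError("empty patch set")
    acc = np.zeros(TOTAL_FEATURES)
    for p in patch_set.patches:
        window = image[p.row0 : p.row0 + p.size, p.col0 : p.col0 + p.size]
        acc += _single_vector(window, config)
    return FeatureVector(values=acc / len(patch_set.patches))
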