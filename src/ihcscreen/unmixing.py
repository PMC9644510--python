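"""Linear spectral unmixing of H-DAB immunohistochemistry images.

An IHC image mixes two chromogens: DAB (brown) marking the target protein
and hematoxylin (purple) counterstaining nuclei.  In optical-density (OD)
space the stains combine linearly (Beer-Lambert), so a per-pixel
least-squares solve against the stain matrix separates a protein
concentration channel from a nuclear one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "StainChannels",
    "HDAB",
    "rgb_to_od",
    "od_to_rgb",
    "unmix",
    "reconstruct",
]

#: guard added to intensities before the log transform so I=0 stays finite
OD_EPS = 1.0


@dataclass(frozen=True)
class StainMatrix:
    """Unit-norm OD absorption vectors, one per stain.

    ``vectors`` has shape (n_stains, 3); rows are normalized on
    construction.  Rows must be linearly independent and non-negative.
    """

    vectors: np.ndarray
    names: tuple[str, ...] = ("hematoxylin", "dab")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("stain vectors must be an (n_stains, 3) array")
        if np.any(v < 0):
            raise ValueError("stain vectors must have non-negative components")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        v = v / norms[:, None]
        if np.linalg.matrix_rank(v) < v.shape[0]:
            raise ValueError("stain vectors are linearly dependent (singular matrix)")
        object.__setattr__(self, "vectors", v)
        if len(self.names) != v.shape[0]:
            raise ValueError("one name per stain vector required")

    @property
    def n_stains(self) -> int:
        return self.vectors.shape[0]


#: standard published H-DAB absorption pair (Ruifrok-style reference values)
HDAB = StainMatrix(
    vectors=np.array([[0.650, 0.704, 0.286], [0.269, 0.568, 0.778]]),
    names=("hematoxylin", "dab"),
)


@dataclass
class StainChannels:
    """Per-pixel stain concentration maps (unitless OD) plus residual."""

    protein_od: np.ndarray
    dna_od: np.ndarray
    residual: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.protein_od.shape != self.dna_od.shape:
            raise ValueError("channel maps must share dimensions")
        if self.residual is None:
            self.residual = np.zeros_like(self.protein_od)


def rgb_to_od(image: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Convert an RGB raster to per-pixel optical density.

    OD = -log10((I + eps) / 255) channel-wise.  Works on uint8 or float
    inputs with values in [0, 255]; output is >= 0 (clipped at 0 for the
    eps overshoot at I=255).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    od = -np.log10((image.astype(float) + eps) / 255.0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Invert :func:`rgb_to_od`: I = 255 * 10**(-OD) - eps (float, unclipped)."""
    od = np.asarray(od, dtype=float)
    return 255.0 * np.power(10.0, -od) - eps


def unmix(
    od_image: np.ndarray,
    matrix: StainMatrix = HDAB,
    nnls: bool = False,
) -> StainChannels:
    """Least-squares decompose an OD image into per-stain concentration maps.

    Solves OD = c @ M per pixel.  By default an unconstrained solve is used
    and negative concentrations are clipped to 0; with ``nnls=True`` a true
    non-negative solve (scipy) is used instead.  The Euclidean norm of the
    per-pixel reconstruction error (pre-clip) is recorded as ``residual``.
    """
    od_image = np.asarray(od_image, dtype=float)
    if od_image.ndim != 3 or od_image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) OD image")
    h, w, _ = od_image.shape
    flat = od_image.reshape(-1, 3)
    m = matrix.vectors  # (n_stains, 3)

    if nnls:
        from scipy.optimize import nnls as _nnls

        conc = np.empty((flat.shape[0], matrix.n_stains))
        for i, pix in enumerate(flat):
            conc[i], _ = _nnls(m.T, pix)
    else:
        # pinv of the (3, n_stains) system; exact for images on the stain plane
        conc = flat @ np.linalg.pinv(m)

    resid = np.linalg.norm(flat - conc @ m, axis=1).reshape(h, w)
    conc = np.clip(conc, 0.0, None)
    channels = [conc[:, i].reshape(h, w) for i in range(matrix.n_stains)]
    # convention: protein (DAB) channel is the stain named "dab" if present,
    # otherwise the second row
    names = [n.lower() for n in matrix.names]
    dab_i = names.index("dab") if "dab" in names else 1
    dna_i = 1 - dab_i if matrix.n_stains == 2 else names.index("hematoxylin")
    return StainChannels(protein_od=channels[dab_i], dna_od=channels[dna_i], residual=resid)


def reconstruct(channels: StainChannels, matrix: StainMatrix = HDAB) -> np.ndarray:
    """Recombine concentration maps into an OD image (test oracle for unmix)."""
    if channels.protein_od.shape != channels.dna_od.shape:
        raise ValueError("channel shape mismatch")
    names = [n.lower() for n in matrix.names]
    dab_i = names.index("dab") if "dab" in names else 1
    conc = np.zeros(channels.protein_od.shape + (matrix.n_stains,))
    conc[..., dab_i] = channels.protein_od
    conc[..., 1 - dab_i] = channels.dna_od
    return conc @ matrix.vectors
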