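"""Synthetic two-stain IHC image and cohort generation.

Renders DAB + hematoxylin tissue images through the Beer-Lambert forward
model so that linear unmixing is exactly invertible, with the expression
level (high/medium/low) encoded by the stained-area fraction and DAB
optical density.  Ground-truth stain maps and masks are retained on every
image, which makes the generator usable as an oracle for every downstream
stage: unmixing, patch statistics, feature-based classification and
biomarker screening are all testable without any real microscopy data.

The rendered tissue is a union of random nuclei disks over a textured
stroma; the protein stain is painted on smooth random blobs (thresholded
low-pass noise) covering exactly the requested area fraction, emulating
the patchy specific staining of real IHC alongside unstained stroma.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .unmixing import HDAB, OD_EPS, StainMatrix

__all__ = [
    "LEVELS",
    "LEVEL_PARAMS",
    "SyntheticSpec",
    "LabeledImage",
    "CohortSpec",
    "generate_image",
    "generate_cohort",
    "write_cohort",
]

#: expression levels in descending order (also the classifier's class order)
LEVELS = ("high", "medium", "low")

#: default level -> (stained_fraction, dab_od) map; three separable but
#: overlapping classes
LEVEL_PARAMS = {
    "low": (0.15, 0.4),
    "medium": (0.40, 0.7),
    "high": (0.70, 1.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one rendered IHC-like image.

    ``stained_fraction`` / ``dab_od`` of ``None`` defer to the level map
    passed to :func:`generate_image`; explicit values override the level.
    """

    width: int = 1024
    height: int = 1024
    n_nuclei: int = 300
    nucleus_radius_range: tuple[int, int] = (4, 10)
    stained_fraction: float | None = None
    dab_od: float | None = None
    hema_od: float = 0.6
    stroma_od: float = 0.12
    stain_blob_sigma: float | None = None  # regional scale; default min(width, height) / 8
    cell_sigma: float = 4.0  # cell-cluster scale of stain fragmentation
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.stained_fraction is not None and not 0.0 <= self.stained_fraction <= 1.0:
            raise ValueError("stained_fraction must lie in [0, 1]")
        if (self.dab_od is not None and self.dab_od < 0) or self.hema_od < 0:
            raise ValueError("stain optical densities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class LabeledImage:
    """A rendered image with its annotation and generation ground truth."""

    pixels: np.ndarray  # uint8 (H, W, 3)
    label: str
    protein_id: str
    condition: str
    image_id: str
    # ground truth for oracle tests
    pixels_float: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    stain_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    protein_od_truth: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    dna_od_truth: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class CohortSpec:
    """A multi-protein two-condition cohort layout.

    ``images_per_protein`` counts images per protein per condition.
    ``effect`` shifts the cancer renderings of affected proteins:
    a float shifts stained_fraction; a (fraction_shift, od_shift) pair
    shifts both.  ``level_assignment`` optionally maps protein_id ->
    level or protein_id -> {condition: level}; by default levels cycle
    low/medium/high over proteins, identical in both conditions.
    """

    n_proteins: int = 22
    images_per_protein: int = 5
    effect: float | tuple[float, float] = 0.0
    level_assignment: dict | None = None
    image_spec: SyntheticSpec = SyntheticSpec()
    conditions: tuple[str, ...] = ("normal", "cancer")
    affected: frozenset[str] | None = None  # None = all proteins
    #: within-level rendering variability: per-image truncated-normal jitter
    #: of (stained_fraction, dab_od) around the level's parameters; real
    #: images within one annotation level vary, so nonzero jitter makes
    #: adjacent levels overlap
    level_jitter: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.images_per_protein < 1:
            raise ValueError("n_proteins and images_per_protein must be >= 1")


def _effect_tuple(effect: float | tuple[float, float]) -> tuple[float, float]:
    if isinstance(effect, tuple):
        return float(effect[0]), float(effect[1])
    return float(effect), 0.0


def generate_image(
    spec: SyntheticSpec,
    level: str,
    *,
    protein_id: str = "P0",
    condition: str = "normal",
    image_id: str | None = None,
    matrix: StainMatrix = HDAB,
) -> LabeledImage:
    """Render one labeled IHC-like image via the Beer-Lambert forward model.

    Deterministic for a fixed ``spec.seed``.  The float render satisfies
    I = bg * 10**(-OD) - 1, so the standard OD transform with eps=1 inverts
    it exactly; the uint8 view adds only quantization error.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    frac, dab = LEVEL_PARAMS[level]
    if spec.stained_fraction is not None:
        frac = spec.stained_fraction
    if spec.dab_od is not None:
        dab = spec.dab_od

    # stroma: faint textured hematoxylin background
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=6, mode="reflect")
    t_lo, t_hi = texture.min(), texture.max()
    if t_hi > t_lo:
        texture = (texture - t_lo) / (t_hi - t_lo)
    else:
        texture = np.zeros_like(texture)
    dna_od = spec.stroma_od * texture

    # nuclei: random disks of full counterstain density
    r_lo, r_hi = spec.nucleus_radius_range
    yy, xx = np.ogrid[:h, :w]
    nuc = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_nuclei):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(r_lo, r_hi + 1)
        nuc |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    dna_od = np.where(nuc, spec.hema_od, dna_od)

    # protein stain: a two-scale random field thresholded at the exact area
    # quantile.  The regional component makes stained cells cluster (some
    # tissue regions express more), the cell-scale component fragments the
    # stain into cell-sized blobs, so patches mix stained cells with
    # unstained stroma instead of saturating.
    sigma = spec.stain_blob_sigma
    if sigma is None:
        sigma = max(8.0, min(h, w) / 8.0)

    def _unit_field(s: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((h, w)), sigma=s, mode="reflect")
        sd = f.std()
        return f / sd if sd > 0 else f

    blob_field = _unit_field(sigma) + _unit_field(spec.cell_sigma)
    if frac <= 0.0:
        mask = np.zeros((h, w), dtype=bool)
    elif frac >= 1.0:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = blob_field >= np.quantile(blob_field, 1.0 - frac)
    protein_od = np.where(mask, dab, 0.0)

    names = [n.lower() for n in matrix.names]
    dab_vec = matrix.vectors[names.index("dab") if "dab" in names else 1]
    hem_vec = matrix.vectors[names.index("hematoxylin") if "hematoxylin" in names else 0]
    od = protein_od[..., None] * dab_vec + dna_od[..., None] * hem_vec

    bg = np.asarray(spec.background_rgb, dtype=float)
    pixels_float = bg * np.power(10.0, -od) - OD_EPS
    if spec.noise_sd > 0:
        pixels_float = pixels_float + rng.normal(0.0, spec.noise_sd, pixels_float.shape)
    pixels_float = np.clip(pixels_float, 0.0, 255.0)
    pixels = np.round(pixels_float).astype(np.uint8)

    return LabeledImage(
        pixels=pixels,
        label=level,
        protein_id=protein_id,
        condition=condition,
        image_id=image_id or f"{protein_id}_{condition}_{spec.seed}",
        pixels_float=pixels_float,
        stain_mask=mask,
        protein_od_truth=protein_od,
        dna_od_truth=dna_od,
    )


def _level_for(cspec: CohortSpec, pid: str, idx: int, condition: str) -> str:
    la = cspec.level_assignment
    if la is None:
        return ("low", "medium", "high")[idx % 3]
    entry = la.get(pid, ("low", "medium", "high")[idx % 3])
    if isinstance(entry, dict):
        return entry[condition]
    return entry


def generate_cohort(
    cspec: CohortSpec, *, matrix: StainMatrix = HDAB
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate a labeled cohort plus a manifest matching it row-for-row.

    Every protein gets ``images_per_protein`` images in each condition.
    Cancer renderings of affected proteins receive the expression-shift
    effect on top of their level's (fraction, OD) parameters; manifest
    labels record the *rendered* level per the default level map (the
    nearest level by stained fraction after the shift).
    """
    rng = np.random.default_rng(cspec.seed)
    frac_shift, od_shift = _effect_tuple(cspec.effect)
    images: list[LabeledImage] = []
    rows = []
    for i in range(cspec.n_proteins):
        pid = f"prot{i:03d}"
        affected = cspec.affected is None or pid in cspec.affected
        for condition in cspec.conditions:
            level = _level_for(cspec, pid, i, condition)
            base_frac, base_od = LEVEL_PARAMS[level]
            if cspec.image_spec.stained_fraction is not None:
                base_frac = cspec.image_spec.stained_fraction
            if cspec.image_spec.dab_od is not None:
                base_od = cspec.image_spec.dab_od
            if condition == "cancer" and affected:
                base_frac = float(np.clip(base_frac + frac_shift, 0.0, 1.0))
                base_od = max(0.0, base_od + od_shift)
            for j in range(cspec.images_per_protein):
                seed = int(rng.integers(0, 2**31 - 1))
                frac_j, od_j = base_frac, base_od
                jf, jo = cspec.level_jitter
                if jf > 0:
                    frac_j = float(np.clip(frac_j + rng.normal(0.0, jf), 0.01, 1.0))
                if jo > 0:
                    od_j = float(np.clip(od_j + rng.normal(0.0, jo), 0.05, None))
                spec_ij = replace(
                    cspec.image_spec,
                    stained_fraction=frac_j,
                    dab_od=od_j,
                    seed=seed,
                )
                image_id = f"{pid}_{condition}_{j:02d}"
                img = generate_image(
                    spec_ij,
                    level,
                    protein_id=pid,
                    condition=condition,
                    image_id=image_id,
                    matrix=matrix,
                )
                images.append(img)
                rows.append(
                    {
                        "image_path": "",
                        "image_id": image_id,
                        "protein_id": pid,
                        "condition": condition,
                        "label": level,
                    }
                )
    return images, pd.DataFrame(rows)


def write_cohort(
    images: list[LabeledImage], manifest: pd.DataFrame, out_dir: str
) -> pd.DataFrame:
    """Write cohort images as PNG plus a ``manifest.csv``; returns the manifest."""
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for img in images:
        path = os.path.join(out_dir, f"{img.image_id}.png")
        Image.fromarray(img.pixels).save(path)
        paths.append(path)
    manifest["image_path"] = paths
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
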