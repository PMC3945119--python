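"""Synthetic microscope fields and feature tables with known ground truth.

The generator emulates the structure of a genome-wide yeast GFP-fusion image
collection: fields of a few dozen elliptical cells, each with one stained
nucleus, a transmitted-light (DIC-like) channel showing bright/dark edge
shading, and a fluorescence channel rendered from a parameterized
localization-pattern class (nuclear, cytoplasmic, punctate, peripheral ring,
bud neck, or a mixture).  Per-strain feature tables are drawn from
strain-specific Gaussians whose means encode pattern classes, so downstream
profiling, mapping and divergence machinery can be exercised against exact
ground truth without any real images.

Intensities live on an 8-bit-like 0-255 scale but are written as 16-bit
TIFFs.  All randomness flows through a single seeded generator per call, so
a fixed seed fixes every emitted artifact byte-for-byte at the array level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import ParameterError, PlacementError
from .imaging import ImageField, apply_shift
from .segmentation import LabeledMask

__all__ = [
    "PATTERN_CLASSES",
    "SyntheticFieldSpec",
    "SyntheticStrainSet",
    "generate_field",
    "generate_feature_table",
    "write_field_bundle",
]

PATTERN_CLASSES = ("nuclear", "cytoplasmic", "punctate", "peripheral_ring", "bud_neck", "mixed")

#: default per-cell integrated GFP mass (intensity units) before noise
GFP_MASS = 20000.0
DIC_BASELINE = 128.0
DNA_NUCLEUS_LEVEL = 180.0


@dataclass
class SyntheticFieldSpec:
    """Parameters of one simulated field.

    ``channel_offset`` is the integer (dy, dx) shift applied to the DIC
    channel relative to the fluorescence channels, emulating camera
    misalignment.  ``max_overlap`` caps the fraction of a new cell's area
    allowed to overlap already-placed cells (0 = strictly disjoint).
    """

    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 10
    cell_radius_range: tuple[float, float] = (12.0, 18.0)
    nucleus_radius_fraction: float = 0.35
    pattern_class: str = "nuclear"
    channel_offset: tuple[int, int] = (0, 0)
    noise_sd: float = 1.0
    seed: int = 0
    max_overlap: float = 0.0
    gfp_mass: float = GFP_MASS
    poisson_noise: bool = False

    def __post_init__(self):
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ParameterError("image_size must be positive")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.pattern_class not in PATTERN_CLASSES:
            raise ParameterError(f"unknown pattern_class {self.pattern_class!r}")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ParameterError("nucleus_radius_fraction must be in (0,1)")


def _ellipse_mask(shape, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _place_cells(spec: SyntheticFieldSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping elliptical cells; bounded retries."""
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    cells = []
    r_lo, r_hi = spec.cell_radius_range
    for i in range(1, spec.n_cells + 1):
        for _ in range(300):
            r = rng.uniform(r_lo, r_hi)
            ecc = rng.uniform(0.8, 1.0)  # mild ellipticity
            ry, rx = r, r * ecc
            margin = r_hi + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, np.pi)
            m = _ellipse_mask((h, w), cy, cx, ry, rx, theta)
            overlap = (labels[m] > 0).sum() / max(m.sum(), 1)
            if overlap <= spec.max_overlap:
                labels[m & (labels == 0)] = i
                cells.append({"label": i, "cy": cy, "cx": cx, "ry": ry, "rx": rx, "theta": theta})
                break
        else:
            raise PlacementError(
                f"could not place cell {i}/{spec.n_cells} after 300 retries"
            )
    return labels, cells


def _render_gfp_cell(shape, cell, cell_mask, nuc_mask, pattern, rng):
    """Unnormalized spatial kernel for one cell's GFP; later scaled to mass."""
    img = np.zeros(shape, dtype=float)
    cyto = cell_mask & ~nuc_mask
    if pattern == "nuclear":
        img[nuc_mask] = 1.0
    elif pattern == "cytoplasmic":
        img[cyto] = 1.0
    elif pattern == "punctate":
        ys, xs = np.nonzero(cyto)
        n_puncta = 5
        idx = rng.choice(len(ys), size=min(n_puncta, len(ys)), replace=False)
        for j in idx:
            img[ys[j], xs[j]] = 1.0
        img = ndimage.gaussian_filter(img, 1.2)
        img[~cell_mask] = 0.0
    elif pattern == "peripheral_ring":
        inner = ndimage.binary_erosion(cell_mask, iterations=3)
        img[cell_mask & ~inner] = 1.0
    elif pattern == "bud_neck":
        ys, xs = np.nonzero(cell_mask & ~ndimage.binary_erosion(cell_mask, iterations=2))
        if len(ys):
            j = rng.integers(len(ys))
            spot = np.zeros(shape)
            spot[ys[j], xs[j]] = 1.0
            img = ndimage.gaussian_filter(spot, 2.0)
            img[~cell_mask] = 0.0
    elif pattern == "mixed":
        img[nuc_mask] = 0.5
        img[cyto] = 0.5
    return img


def generate_field(spec: SyntheticFieldSpec) -> tuple[ImageField, LabeledMask]:
    """Render one field; returns the channels and the ground-truth cell mask.

    Deterministic for a fixed ``spec.seed``.  The DIC channel is a mid-gray
    baseline plus the signed gradient of a smoothed cell-indicator function
    (a bright/dark rim per cell, independent of GFP); the DNA channel is
    bright only inside nuclei; GFP is rendered per ``spec.pattern_class``
    with total per-cell mass ``spec.gfp_mass`` before noise.  The stated
    ``channel_offset`` is applied to the DIC channel.  Nucleus labels match
    the parent cell label; the nucleus ground truth is retrievable as
    ``mask_nuclei`` in the returned LabeledMask's ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    if spec.n_cells == 0:
        blank = np.zeros((h, w))
        fieldi = ImageField(
            dic=np.full((h, w), DIC_BASELINE), dna=blank.copy(), gfp=blank.copy()
        )
        mask = LabeledMask(np.zeros((h, w), dtype=np.int32))
        mask.meta = {"nuclei": np.zeros((h, w), dtype=np.int32), "cells": []}
        return fieldi, mask

    labels, cells = _place_cells(spec, rng)
    nuc_labels = np.zeros_like(labels)
    gfp = np.zeros((h, w), dtype=float)
    dna = np.zeros((h, w), dtype=float)

    for c in cells:
        cell_mask = labels == c["label"]
        nr = spec.nucleus_radius_fraction * min(c["ry"], c["rx"])
        nuc = _ellipse_mask((h, w), c["cy"], c["cx"], nr, nr, 0.0) & cell_mask
        nuc_labels[nuc] = c["label"]
        dna[nuc] = DNA_NUCLEUS_LEVEL
        kern = _render_gfp_cell((h, w), c, cell_mask, nuc, spec.pattern_class, rng)
        total = kern.sum()
        if total > 0:
            gfp += kern * (spec.gfp_mass / total)

    dic_ind = ndimage.gaussian_filter((labels > 0).astype(float), 2.0)
    gy, gx = np.gradient(dic_ind)
    dic = DIC_BASELINE + 400.0 * (gy + gx)  # signed edge shading

    def _noisy(img):
        out = img.astype(float)
        if spec.poisson_noise:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, size=img.shape)
        return np.clip(out, 0.0, 65535.0)

    dic = _noisy(dic)
    dna = _noisy(ndimage.gaussian_filter(dna, 0.8))
    gfp = _noisy(gfp)

    if spec.channel_offset != (0, 0):
        dic = apply_shift(dic, spec.channel_offset, fill=DIC_BASELINE)

    fieldi = ImageField(dic=dic, dna=dna, gfp=gfp)
    fieldi.offsets["dic"] = tuple(spec.channel_offset)
    mask = LabeledMask(labels)
    mask.meta = {"nuclei": nuc_labels, "cells": cells}
    return fieldi, mask


def write_field_bundle(fieldi: ImageField, mask: LabeledMask, spec: SyntheticFieldSpec, outdir):
    """Write {dic,dna,gfp}.tif, truth_labels.tif and a spec.json sidecar."""
    from .imaging import write_field

    outdir = Path(outdir)
    paths = write_field(fieldi, outdir)
    tifffile.imwrite(outdir / "truth_labels.tif", mask.labels.astype(np.uint16))
    sidecar = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()}
    (outdir / "spec.json").write_text(json.dumps(sidecar, indent=1))
    paths["truth_labels"] = outdir / "truth_labels.tif"
    return paths


# ---------------------------------------------------------------------------
# feature-table generator (stand-in for image-derived features)
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStrainSet:
    """Strain roster for feature-table simulation.

    ``pattern_assignments`` maps strain id -> pattern-class name (any
    hashable class name is allowed here; strains sharing a class share a
    feature-space mean).  ``divergence_pairs`` lists (strainA, strainB,
    lambda) duplicate pairs: strain B's mean is interpolated between strain
    A's realized mean (lambda=0: identical parameters) and B's own class
    mean (lambda=1: fully distinct).  ``strain_jitter`` scales the
    strain-level perturbation around the class mean (sd = strain_jitter *
    effect_size), giving within-class strains distinct but similar
    distributions while keeping effect_size=0 a single shared distribution.
    """

    n_strains: int = 12
    cells_per_strain: int = 20
    pattern_assignments: dict = dc_field(default_factory=dict)
    divergence_pairs: list = dc_field(default_factory=list)
    strain_jitter: float = 0.25

    def strain_ids(self):
        if self.pattern_assignments:
            return list(self.pattern_assignments)
        return [f"S{i:04d}" for i in range(self.n_strains)]


def generate_feature_table(
    strain_set: SyntheticStrainSet,
    n_features: int = 50,
    effect_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell feature vectors drawn from strain-specific Gaussians.

    Each pattern class gets a mean vector ``effect_size * N(0, I)``; each
    strain's mean is its class mean plus ``strain_jitter * effect_size *
    N(0, I)`` (divergence-pair members interpolate instead, see
    :class:`SyntheticStrainSet`).  Cells are ``N(mean, I)``.  Columns:
    ``strain_id, cell_id, f_0001..f_NNNN``.
    """
    if effect_size < 0:
        raise ParameterError("effect_size must be >= 0")
    ids = strain_set.strain_ids()
    if len(ids) < 2:
        raise ParameterError("need at least two strains")
    if strain_set.cells_per_strain < 2:
        raise ParameterError("need at least two cells per strain")
    rng = np.random.default_rng(seed)

    assign = strain_set.pattern_assignments or {s: "classA" if i < len(ids) / 2 else "classB" for i, s in enumerate(ids)}
    classes = sorted(set(assign.values()))
    class_mu = {c: effect_size * rng.standard_normal(n_features) for c in classes}

    strain_mu = {}
    for s in ids:
        strain_mu[s] = class_mu[assign[s]] + (
            strain_set.strain_jitter * effect_size
        ) * rng.standard_normal(n_features)
    # divergence pairs override B's mean by lambda-interpolation
    for a, b, lam in strain_set.divergence_pairs:
        if not 0 <= lam <= 1:
            raise ParameterError("lambda must be in [0,1]")
        strain_mu[b] = (1 - lam) * strain_mu[a] + lam * class_mu[assign[b]]

    rows = []
    cols = [f"f_{j + 1:04d}" for j in range(n_features)]
    for s in ids:
        x = strain_mu[s] + rng.standard_normal((strain_set.cells_per_strain, n_features))
        for k in range(strain_set.cells_per_strain):
            rows.append((s, f"{s}_c{k:03d}", *x[k]))
    return pd.DataFrame(rows, columns=["strain_id", "cell_id", *cols])
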