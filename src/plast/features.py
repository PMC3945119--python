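"""Subcellular regions, single-cell normalization, and the 623-feature vector.

Each segmented cell is described by five binary regions — cellular, nuclear,
cytoplasmic (cellular minus nuclear), cytoplasmic boundary (the 3-px rim
removed by erosion of the cytoplasm with a disk), and inner cytoplasmic (the
rest of the cytoplasm).  The GFP raster is normalized so its total inside
the cellular region is one; every feature is computed after this step, which
makes the whole vector invariant to protein-expression level.

The feature registry is fixed and ordered: 81 morphology, 45 intensity,
20 intensity-ratio, 273 Haralick texture, 18 moment, and 186 local-structure
features, 623 in all.  Group compositions are enumerated here (counts are
the binding contract; the exact membership is this package's registry and is
frozen by a golden-name test):

* intensity      — 9 statistics x 5 regions
* intensity ratio— {total, mean} GFP over the 10 unordered region pairs
* morphology     — 15 mask descriptors x 5 regions + 6 cell-level descriptors
* Haralick       — 13 co-occurrence statistics x 21 configurations
                   (5 regions x distances {1,2,4} at 8 gray levels, plus the
                   cellular region x {1,2,4} at 16 and 32 levels)
* moments        — Hu's 7 invariants on the normalized GFP, Hu's 7 on the
                   binarized GFP, and 4 centroid-offset/spread statistics
* local structure— 6 statistics x (16 global + 15 stepwise window ratios)

Local structures are binary masks of pixels exceeding an adaptive threshold
(local window mean plus a bias constant); the global ratios compare six
image statistics between the structures and the whole cell, the stepwise
ratios between structures at consecutive window sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import graycomatrix
from skimage.measure import moments_hu, regionprops
from skimage.morphology import disk

from .errors import DegenerateCellError, ParameterError, ZeroSignalError
from .segmentation import CONN4, local_structures

__all__ = [
    "REGIONS",
    "CellRecord",
    "LocalStructureParams",
    "derive_regions",
    "normalize_cell",
    "extract_features",
    "local_structure_features",
    "feature_registry",
    "build_cell_record",
    "extract_field_features",
]

REGIONS = ("cellular", "nuclear", "cytoplasmic", "cytoplasmic_boundary", "inner_cytoplasmic")

INTENSITY_STATS = ("total", "mean", "sd", "median", "mad", "min", "max", "skew", "kurtosis")
MORPH_STATS = (
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis",
    "minor_axis",
    "equiv_diameter",
    "euler_number",
    "circularity",
    "aspect_ratio",
    "convex_area",
    "filled_area",
    "orientation",
    "area_fraction",
)
CELL_MORPH = (
    "nuc_cell_centroid_dist",
    "nuc_cell_area_ratio",
    "nuc_cell_perimeter_ratio",
    "bbox_height",
    "bbox_width",
    "bbox_aspect",
)
HARALICK_STATS = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_avg",
    "sum_var",
    "sum_entropy",
    "entropy",
    "diff_var",
    "diff_entropy",
    "imc1",
    "imc2",
)
HARALICK_CONFIGS = tuple(
    [(r, d, 8) for r in REGIONS for d in (1, 2, 4)]
    + [("cellular", d, q) for q in (16, 32) for d in (1, 2, 4)]
)
LS_STATS = ("total", "mean", "sd", "obj_count", "obj_area", "obj_mean_area")


@dataclass
class LocalStructureParams:
    """Window sizes and bias for local-structure features.

    Sixteen odd windows, 3..33 px: finer windows pick out puncta, coarser
    ones approach the whole-cell pattern (structures converge by ~33 px).
    ``bias`` is the additive constant of the adaptive threshold on the
    normalized GFP (default 0).
    """

    window_sizes: tuple = tuple(range(3, 34, 2))
    bias: float = 0.0

    def __post_init__(self):
        ws = tuple(self.window_sizes)
        if len(ws) < 2:
            raise ParameterError("need at least two window sizes for stepwise ratios")
        if any(w % 2 == 0 for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ParameterError("window sizes must be odd and strictly increasing")
        self.window_sizes = ws


@dataclass
class CellRecord:
    """One segmented cell: masks, normalized GFP, QC metrics, features."""

    cell_id: str
    strain_id: str
    regions: dict
    gfp_norm: np.ndarray
    qc: dict = dc_field(default_factory=dict)
    flags: set = dc_field(default_factory=set)
    features: pd.Series | None = None


def solidity_metric(cell_mask: np.ndarray, convention: str = "deficiency") -> float:
    """QC shape metric derived from solidity (area / convex-hull area).

    The quality rule removes cells whose stored metric exceeds 0.2.  Under
    the default ``deficiency`` convention the stored value is
    ``1 - area/convex_area``, so the rule discards cells deviating more than
    20% from their convex hull (badly segmented shapes).  ``classic`` stores
    plain solidity instead; the convention is isolated here so it can be
    swapped without touching the filter.
    """
    props = regionprops(cell_mask.astype(np.uint8))
    if not props:
        return 1.0 if convention == "deficiency" else 0.0
    s = float(props[0].solidity)
    return 1.0 - s if convention == "deficiency" else s


def derive_regions(cell_mask: np.ndarray, nucleus_mask: np.ndarray) -> dict:
    """Split a cell into the five subcellular regions.

    The nucleus is intersected with the cell; the cytoplasm is the
    difference; the cytoplasmic boundary is the rim removed by binary
    erosion of the cytoplasm with a circular structuring element of radius
    3 px; the inner cytoplasm is what remains.  A nucleus covering the whole
    cell leaves no cytoplasm and raises :class:`DegenerateCellError`; an
    empty nucleus is allowed (cytoplasm = cell) and downstream nuclear
    statistics are zero-with-flag.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus = np.asarray(nucleus_mask, dtype=bool) & cell_mask
    cyto = cell_mask & ~nucleus
    if not cyto.any():
        raise DegenerateCellError("nucleus covers the whole cell; no cytoplasm")
    eroded = ndimage.binary_erosion(cyto, structure=disk(3))
    boundary = cyto & ~eroded
    inner = cyto & ~boundary
    return {
        "cellular": cell_mask,
        "nuclear": nucleus,
        "cytoplasmic": cyto,
        "cytoplasmic_boundary": boundary,
        "inner_cytoplasmic": inner,
    }


def normalize_cell(gfp: np.ndarray, cellular: np.ndarray) -> np.ndarray:
    """Scale GFP so its sum over the cellular region is one; zero elsewhere."""
    gfp = np.asarray(gfp, dtype=float)
    cellular = np.asarray(cellular, dtype=bool)
    out = np.where(cellular, gfp, 0.0)
    total = out.sum()
    if total <= 0:
        raise ZeroSignalError("zero total GFP inside the cellular region")
    return out / total


# ---------------------------------------------------------------------------
# feature groups
# ---------------------------------------------------------------------------


def _intensity_stats(vals: np.ndarray) -> dict:
    if vals.size == 0:
        return {k: 0.0 for k in INTENSITY_STATS}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk = stats.skew(vals)
        ku = stats.kurtosis(vals)
    return {
        "total": float(vals.sum()),
        "mean": float(vals.mean()),
        "sd": float(vals.std()),
        "median": float(np.median(vals)),
        "mad": float(np.median(np.abs(vals - np.median(vals)))),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "skew": 0.0 if not np.isfinite(sk) else float(sk),
        "kurtosis": 0.0 if not np.isfinite(ku) else float(ku),
    }


def _region_props(mask: np.ndarray):
    props = regionprops(mask.astype(np.uint8))
    return props[0] if props else None


def _morphology(regions: dict) -> dict:
    out = {}
    cell_area = float(regions["cellular"].sum())
    for rname in REGIONS:
        p = _region_props(regions[rname])
        if p is None:
            for s in MORPH_STATS:
                out[f"mor_{rname}_{s}"] = 0.0
            continue
        per = float(p.perimeter)
        area = float(p.area)
        minor = float(p.axis_minor_length)
        vals = {
            "area": area,
            "perimeter": per,
            "eccentricity": float(p.eccentricity),
            "solidity": float(p.solidity),
            "extent": float(p.extent),
            "major_axis": float(p.axis_major_length),
            "minor_axis": minor,
            "equiv_diameter": float(p.equivalent_diameter_area),
            "euler_number": float(p.euler_number),
            "circularity": 4 * np.pi * area / per**2 if per > 0 else 0.0,
            "aspect_ratio": float(p.axis_major_length) / minor if minor > 0 else 0.0,
            "convex_area": float(p.area_convex),
            "filled_area": float(p.area_filled),
            "orientation": float(p.orientation),
            "area_fraction": area / cell_area if cell_area > 0 else 0.0,
        }
        for s in MORPH_STATS:
            out[f"mor_{rname}_{s}"] = vals[s]

    pc = _region_props(regions["cellular"])
    pn = _region_props(regions["nuclear"])
    if pc is None:
        cvals = dict.fromkeys(CELL_MORPH, 0.0)
    else:
        bh = float(pc.bbox[2] - pc.bbox[0])
        bw = float(pc.bbox[3] - pc.bbox[1])
        if pn is None:
            dist, aratio, pratio = 0.0, 0.0, 0.0
        else:
            dist = float(np.hypot(*(np.array(pc.centroid) - np.array(pn.centroid))))
            aratio = float(pn.area) / float(pc.area)
            pratio = float(pn.perimeter) / float(pc.perimeter) if pc.perimeter > 0 else 0.0
        cvals = {
            "nuc_cell_centroid_dist": dist,
            "nuc_cell_area_ratio": aratio,
            "nuc_cell_perimeter_ratio": pratio,
            "bbox_height": bh,
            "bbox_width": bw,
            "bbox_aspect": bh / bw if bw > 0 else 0.0,
        }
    for s in CELL_MORPH:
        out[f"mor_cell_{s}"] = cvals[s]
    return out


def _quantize(gfp: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Map in-region intensities to 1..levels; 0 outside the region."""
    out = np.zeros(gfp.shape, dtype=np.uint8)
    vals = gfp[mask]
    if vals.size == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        out[mask] = 1
    else:
        q = 1 + np.floor((gfp[mask] - lo) / (hi - lo) * (levels - 1e-9)).astype(int)
        out[mask] = np.clip(q, 1, levels)
    return out


def _haralick_13(P: np.ndarray) -> dict:
    """Thirteen Haralick statistics from a normalized co-occurrence matrix."""
    eps = 1e-12
    L = P.shape[0]
    if P.sum() <= 0:
        return dict.fromkeys(HARALICK_STATS, 0.0)
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux, muy = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mux) ** 2 * px).sum())
    sy = np.sqrt(((i - muy) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * L + 1)
    p_sum = np.array([P[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, L)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    asm = float((P**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    corr = float((((ii - mux) * (jj - muy) * P).sum()) / (sx * sy)) if sx * sy > 0 else 0.0
    var = float(((ii - mux) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_entropy = float(-(p_sum * np.log(p_sum + eps)).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    entropy = float(-(P * np.log(P + eps)).sum())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_entropy = float(-(p_diff * np.log(p_diff + eps)).sum())
    hx = float(-(px * np.log(px + eps)).sum())
    hy = float(-(py * np.log(py + eps)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * np.log(pxy + eps)).sum())
    hxy2 = float(-(pxy * np.log(pxy + eps)).sum())
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    arg = max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))
    imc2 = float(np.sqrt(arg))
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "variance": var,
        "idm": idm,
        "sum_avg": sum_avg,
        "sum_var": sum_var,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "diff_var": diff_var,
        "diff_entropy": diff_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def _haralick_features(gfp: np.ndarray, regions: dict) -> dict:
    out = {}
    angles = (0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    for rname, d, q in HARALICK_CONFIGS:
        mask = regions[rname]
        key = f"har_{rname}_d{d}_q{q}"
        if mask.sum() < 2:
            for s in HARALICK_STATS:
                out[f"{key}_{s}"] = 0.0
            continue
        img = _quantize(gfp, mask, q)
        glcm = graycomatrix(img, distances=[d], angles=list(angles), levels=q + 1, symmetric=True)
        P = glcm[1:, 1:, 0, :].sum(axis=2).astype(float)  # drop out-of-region level
        total = P.sum()
        stats13 = _haralick_13(P / total) if total > 0 else dict.fromkeys(HARALICK_STATS, 0.0)
        for s in HARALICK_STATS:
            out[f"{key}_{s}"] = stats13[s]
    return out


def _moment_features(gfp: np.ndarray, regions: dict) -> dict:
    from skimage.measure import moments, moments_central, moments_normalized

    out = {}
    cell = regions["cellular"]
    img = np.where(cell, gfp, 0.0)

    def _hu(arr):
        m = moments(arr)
        if m[0, 0] <= 0:
            return np.zeros(7)
        mc = moments_central(arr)
        with np.errstate(divide="ignore", invalid="ignore"):
            hu = moments_hu(moments_normalized(mc))
        return np.nan_to_num(hu, nan=0.0, posinf=0.0, neginf=0.0)

    vals = img[cell]
    thresh = vals.mean() if vals.size else 0.0
    binary = (img > thresh) & cell
    for k, v in enumerate(_hu(img)):
        out[f"mom_hu_intensity_{k + 1}"] = float(v)
    for k, v in enumerate(_hu(binary.astype(float))):
        out[f"mom_hu_binary_{k + 1}"] = float(v)

    p = _region_props(cell)
    if p is None or img.sum() <= 0:
        extra = dict.fromkeys(
            ("centroid_offset", "centroid_offset_norm", "radial_spread", "radial_spread_norm"), 0.0
        )
    else:
        ys, xs = np.nonzero(cell)
        wsum = img[ys, xs].sum()
        cy = (img[ys, xs] * ys).sum() / wsum
        cx = (img[ys, xs] * xs).sum() / wsum
        off = float(np.hypot(cy - p.centroid[0], cx - p.centroid[1]))
        req = float(p.equivalent_diameter_area) / 2.0
        r2 = ((ys - cy) ** 2 + (xs - cx) ** 2) * img[ys, xs]
        spread = float(np.sqrt(r2.sum() / wsum))
        extra = {
            "centroid_offset": off,
            "centroid_offset_norm": off / req if req > 0 else 0.0,
            "radial_spread": spread,
            "radial_spread_norm": spread / req if req > 0 else 0.0,
        }
    for k, v in extra.items():
        out[f"mom_{k}"] = v
    return out


def _ls_stats(gfp: np.ndarray, mask: np.ndarray) -> dict:
    """The six local-structure statistics on a binary mask."""
    vals = gfp[mask]
    if vals.size == 0:
        return dict.fromkeys(LS_STATS, 0.0)
    _, n_obj = ndimage.label(mask, structure=CONN4)
    area = float(mask.sum())
    return {
        "total": float(vals.sum()),
        "mean": float(vals.mean()),
        "sd": float(vals.std()),
        "obj_count": float(n_obj),
        "obj_area": area,
        "obj_mean_area": area / n_obj if n_obj > 0 else 0.0,
    }


def local_structure_features(
    gfp_norm: np.ndarray,
    cellular: np.ndarray,
    params: LocalStructureParams | None = None,
) -> dict:
    """96 global + 90 stepwise local-structure ratio features.

    For each window size w, the adaptive threshold (local mean + bias) run
    on the normalized GFP inside the cell yields a binary structure mask
    B_w.  The global ratios divide each of the six statistics on B_w by the
    same statistic on the whole cellular region; the stepwise ratios divide
    the statistic at window w_{i+1} by that at w_i.  Zero denominators give
    a 0 ratio (the value is flagged upstream, never NaN).
    """
    params = params or LocalStructureParams()
    cellular = np.asarray(cellular, dtype=bool)
    img = np.where(cellular, gfp_norm, 0.0)
    cell_stats = _ls_stats(img, cellular)

    per_w = {}
    for w in params.window_sizes:
        eff_w = min(w, min(img.shape) - (1 - min(img.shape) % 2))
        B = local_structures(img, eff_w, params.bias) & cellular
        per_w[w] = _ls_stats(img, B)

    out = {}
    for w in params.window_sizes:
        for s in LS_STATS:
            denom = cell_stats[s]
            out[f"ls_w{w:02d}_global_{s}"] = per_w[w][s] / denom if denom != 0 else 0.0
    for wa, wb in zip(params.window_sizes, params.window_sizes[1:]):
        for s in LS_STATS:
            denom = per_w[wa][s]
            out[f"ls_w{wa:02d}_{wb:02d}_step_{s}"] = per_w[wb][s] / denom if denom != 0 else 0.0
    return out


def feature_registry(params: LocalStructureParams | None = None) -> pd.DataFrame:
    """Ordered manifest (name, group, region, window) of all 623 features."""
    params = params or LocalStructureParams()
    names, groups = [], []

    def add(ns, g):
        names.extend(ns)
        groups.extend([g] * len(ns))

    add([f"mor_{r}_{s}" for r in REGIONS for s in MORPH_STATS], "morphology")
    add([f"mor_cell_{s}" for s in CELL_MORPH], "morphology")
    add([f"int_{r}_{s}" for r in REGIONS for s in INTENSITY_STATS], "intensity")
    add(
        [
            f"rat_{a}_{b}_{s}"
            for a, b in combinations(REGIONS, 2)
            for s in ("total", "mean")
        ],
        "intensity_ratio",
    )
    add(
        [f"har_{r}_d{d}_q{q}_{s}" for r, d, q in HARALICK_CONFIGS for s in HARALICK_STATS],
        "haralick",
    )
    add([f"mom_hu_intensity_{k}" for k in range(1, 8)], "moment")
    add([f"mom_hu_binary_{k}" for k in range(1, 8)], "moment")
    add(
        ["mom_centroid_offset", "mom_centroid_offset_norm", "mom_radial_spread", "mom_radial_spread_norm"],
        "moment",
    )
    ws = params.window_sizes
    add([f"ls_w{w:02d}_global_{s}" for w in ws for s in LS_STATS], "local_structure")
    add(
        [f"ls_w{a:02d}_{b:02d}_step_{s}" for a, b in zip(ws, ws[1:]) for s in LS_STATS],
        "local_structure",
    )
    def _region_of(name):
        for r in REGIONS:
            if f"_{r}_" in name or name.endswith(f"_{r}"):
                return r
        return ""

    def _window_of(name):
        return int(name[4:6]) if name.startswith("ls_w") else np.nan

    reg = pd.DataFrame(
        {
            "name": names,
            "group": groups,
            "region": [_region_of(n) for n in names],
            "window": [_window_of(n) for n in names],
        }
    )
    counts = reg["group"].value_counts()
    expected = {
        "morphology": 81,
        "intensity": 45,
        "intensity_ratio": 20,
        "haralick": 273,
        "moment": 18,
        "local_structure": 6 * len(ws) + 6 * (len(ws) - 1),
    }
    for g, n in expected.items():
        assert counts[g] == n, f"registry group {g}: {counts[g]} != {n}"
    if len(ws) == 16:
        assert len(reg) == 623, f"registry has {len(reg)} features, expected 623"
    return reg


def extract_features(cell: CellRecord, params: LocalStructureParams | None = None) -> pd.Series:
    """Compute the full ordered feature vector for one cell.

    A cell flagged ``zero_signal`` yields an all-zero vector with the flag
    propagated; all values are finite (empty-region statistics are 0).
    """
    params = params or LocalStructureParams()
    reg = feature_registry(params)
    if any(r not in cell.regions for r in REGIONS):
        raise DegenerateCellError("missing subcellular region")
    if "zero_signal" in cell.flags:
        vec = pd.Series(0.0, index=reg["name"])
        cell.features = vec
        return vec

    gfp = cell.gfp_norm
    values = {}
    values.update(_morphology(cell.regions))
    for rname in REGIONS:
        st = _intensity_stats(gfp[cell.regions[rname]])
        for s in INTENSITY_STATS:
            values[f"int_{rname}_{s}"] = st[s]
    for a, b in combinations(REGIONS, 2):
        for s in ("total", "mean"):
            num = values[f"int_{a}_{s}"]
            den = values[f"int_{b}_{s}"]
            values[f"rat_{a}_{b}_{s}"] = num / den if den != 0 else 0.0
    values.update(_haralick_features(gfp, cell.regions))
    values.update(_moment_features(gfp, cell.regions))
    values.update(local_structure_features(gfp, cell.regions["cellular"], params))

    vec = pd.Series([values[n] for n in reg["name"]], index=reg["name"], dtype=float)
    vec = vec.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    cell.features = vec
    return vec


# ---------------------------------------------------------------------------
# field-level driver
# ---------------------------------------------------------------------------


def build_cell_record(
    gfp: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_id: str,
    strain_id: str,
    pad: int = 34,
) -> CellRecord:
    """Crop one cell (with padding for the largest analysis window) and
    assemble its regions, normalized GFP and QC metrics."""
    ys, xs = np.nonzero(cell_mask)
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, cell_mask.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, cell_mask.shape[1])
    cm = cell_mask[y0:y1, x0:x1]
    nm = nucleus_mask[y0:y1, x0:x1]
    gf = np.asarray(gfp, dtype=float)[y0:y1, x0:x1]

    regions = derive_regions(cm, nm)
    flags = set()
    if not regions["nuclear"].any():
        flags.add("no_nucleus")
    try:
        gfp_norm = normalize_cell(gf, cm)
    except ZeroSignalError:
        flags.add("zero_signal")
        gfp_norm = np.zeros_like(gf)
    qc = {"area": int(cm.sum()), "solidity": solidity_metric(cm)}
    return CellRecord(cell_id, strain_id, regions, gfp_norm, qc=qc, flags=flags)


def extract_field_features(
    gfp: np.ndarray,
    cells: "LabeledMask",
    nuclei: "LabeledMask",
    strain_id: str,
    params: LocalStructureParams | None = None,
) -> pd.DataFrame:
    """Feature table for every labeled cell of one field.

    Columns: strain_id, cell_id, qc_area, qc_solidity, then the 623 named
    features.  Degenerate cells (no cytoplasm) are skipped.
    """
    params = params or LocalStructureParams()
    rows = []
    for lab in cells.label_ids():
        cm = cells.labels == lab
        nm = (nuclei.labels == lab) if nuclei is not None else np.zeros_like(cm)
        if not nm.any() and nuclei is not None:
            nm = (nuclei.labels > 0) & cm
        try:
            rec = build_cell_record(gfp, cm, nm, f"{strain_id}_c{int(lab):03d}", strain_id)
        except DegenerateCellError:
            continue
        vec = extract_features(rec, params)
        row = {"strain_id": strain_id, "cell_id": rec.cell_id}
        row["qc_area"] = rec.qc["area"]
        row["qc_solidity"] = rec.qc["solidity"]
        row.update(vec.to_dict())
        rows.append(row)
    reg = feature_registry(params)
    cols = ["strain_id", "cell_id", "qc_area", "qc_solidity", *reg["name"]]
    return pd.DataFrame(rows, columns=cols)
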