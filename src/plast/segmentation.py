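"""Nucleus-seeded cell segmentation and segmentation-quality metrics.

Nuclei are found in the (smoothed, background-subtracted) DNA-stain channel
with an adaptive local threshold; cell bodies are then recovered by flooding
the gradient of the flattened DIC image with a watershed seeded at the nuclei
plus one background seed.  Mother/bud fragments are re-joined by a rule on
combined area and DNA asymmetry, and segmentations are scored against
reference masks with the boundary-error and Rand-error indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import sobel
from skimage.segmentation import find_boundaries, watershed

from .errors import ParameterError, UndefinedMetricError

__all__ = [
    "LabeledMask",
    "SegmentationParams",
    "local_structures",
    "detect_nuclei",
    "segment_cells",
    "combine_cells",
    "boundary_error",
    "rand_error",
]

#: 4-connectivity everywhere (components, adjacency) -- matches the diamond
#: structuring element used for mask morphology.
CONN4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class LabeledMask:
    """Integer-labeled segmentation raster; 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ParameterError("labels must be a 2-D raster")

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])

    def compact(self) -> "LabeledMask":
        """Relabel to positive consecutive integers 1..n (order-preserving)."""
        ids = self.label_ids()
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
        lut[ids] = np.arange(1, len(ids) + 1)
        return LabeledMask(lut[self.labels])

    def regions(self, dna: np.ndarray | None = None) -> pd.DataFrame:
        """Per-label record table: area, total_dna, centroid."""
        ids = self.label_ids()
        rows = []
        for lab in ids:
            m = self.labels == lab
            ys, xs = np.nonzero(m)
            rows.append(
                {
                    "label": int(lab),
                    "area": int(m.sum()),
                    "total_dna": float(dna[m].sum()) if dna is not None else np.nan,
                    "centroid_y": float(ys.mean()),
                    "centroid_x": float(xs.mean()),
                }
            )
        return pd.DataFrame(rows, columns=["label", "area", "total_dna", "centroid_y", "centroid_x"])


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    ``nucleus_window`` (odd, px) and ``nucleus_bias`` parameterize the
    adaptive threshold used for nucleus detection; ``theta_area`` /
    ``theta_dna`` drive mother-bud re-joining; ``min_nucleus_area`` removes
    specks.  ``smooth_sigma`` belongs to the 9x9 Gaussian lowpass applied to
    DIC and DNA before segmentation.
    """

    nucleus_window: int = 35
    nucleus_bias: float = -60.0
    theta_area: float = 2000.0
    theta_dna: float = 1000.0
    min_nucleus_area: int = 20
    smooth_sigma: float = 1.5
    smooth_size: int = 9
    #: px to grow cell labels into background after the watershed; the
    #: flood line settles on the inner gradient crest, about one shading
    #: half-width inside the true edge, and this compensates for that bias
    boundary_expand: int = 2

    def __post_init__(self):
        if self.nucleus_window < 3 or self.nucleus_window % 2 == 0:
            raise ParameterError("nucleus_window must be odd and >= 3")


def smooth_lowpass(img: np.ndarray, size: int = 9, sigma: float = 1.5) -> np.ndarray:
    """Convolve with a normalized ``size``x``size`` 2-D Gaussian kernel."""
    ax = np.arange(size) - (size - 1) / 2.0
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    return ndimage.convolve(np.asarray(img, dtype=float), kernel, mode="reflect")


def local_structures(img: np.ndarray, w: int, C: float) -> np.ndarray:
    """Binary local structures by adaptive thresholding.

    For each pixel the threshold is the mean of the w x w window centred on it
    (reflected padding at borders) plus the bias constant ``C``; the output is
    1 exactly where the intensity strictly exceeds that threshold.
    """
    img = np.asarray(img, dtype=float)
    if w % 2 == 0:
        raise ParameterError("window size w must be odd")
    if w < 3 or w > min(img.shape):
        raise ParameterError(f"w={w} outside [3, min(image dims)]")
    mu = ndimage.uniform_filter(img, size=w, mode="reflect")
    return img > mu + C


def detect_nuclei(dna: np.ndarray, params: SegmentationParams | None = None) -> LabeledMask:
    """Label nuclear regions in a background-subtracted DNA-stain raster.

    The raster is smoothed with the 9x9 Gaussian lowpass, then adaptively
    thresholded.  ``params.nucleus_bias`` follows the OpenCV adaptiveThreshold
    sign convention (threshold = local mean - bias), so the default of -60
    selects pixels at least 60 intensity counts *above* their local mean —
    the behaviour needed to pick out stained nuclei on a dark background.
    Connected components (4-connectivity) smaller than
    ``params.min_nucleus_area`` are discarded as specks.
    """
    params = params or SegmentationParams()
    smoothed = smooth_lowpass(dna, params.smooth_size, params.smooth_sigma)
    binary = local_structures(smoothed, params.nucleus_window, -params.nucleus_bias)
    labels, _ = ndimage.label(binary, structure=CONN4)
    # speck filter
    counts = np.bincount(labels.ravel())
    small = np.nonzero(counts < params.min_nucleus_area)[0]
    keep = np.ones(len(counts), dtype=bool)
    keep[small] = False
    keep[0] = False
    lut = np.zeros(len(counts), dtype=np.int32)
    lut[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabeledMask(lut[labels])


def segment_cells(
    dic: np.ndarray,
    nuclei: LabeledMask,
    params: SegmentationParams | None = None,
) -> LabeledMask:
    """Watershed the DIC gradient magnitude from nuclear seeds.

    ``dic`` should already be background-flattened and aligned.  Seeds are
    the nucleus labels plus a single background seed placed on pixels far
    from any candidate foreground (an eroded complement of a dilated Otsu
    mask; the raster border as fallback).  Each nucleus keeps its label, so
    every nucleus ends up inside exactly one cell.
    """
    params = params or SegmentationParams()
    if nuclei.n_labels == 0:
        warnings.warn("no nuclei provided; returning empty mask", stacklevel=2)
        return LabeledMask(np.zeros_like(np.asarray(dic), dtype=np.int32))

    dic = smooth_lowpass(dic, params.smooth_size, params.smooth_sigma)
    grad = sobel(dic)

    from .imaging import _dic_cell_mask

    fg = _dic_cell_mask(dic, n_dilations=6, n_erosions=8)
    fg |= nuclei.labels > 0
    bg = ~fg
    if not bg.any():
        bg = np.zeros_like(fg)
        bg[0, :] = bg[-1, :] = bg[:, 0] = bg[:, -1] = True

    markers = nuclei.labels.astype(np.int32).copy()
    bg_label = int(markers.max()) + 1
    markers[bg & (markers == 0)] = bg_label
    ws = watershed(grad, markers=markers)
    ws[ws == bg_label] = 0
    if params.boundary_expand > 0:
        from skimage.segmentation import expand_labels

        ws = expand_labels(ws, distance=params.boundary_expand)
    return LabeledMask(ws.astype(np.int32)).compact()


def _adjacent_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """Unordered pairs of labels that touch under 4-connectivity."""
    pairs = set()
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def combine_cells(
    mask: LabeledMask,
    dna: np.ndarray,
    theta_area: float = 2000.0,
    theta_dna: float = 1000.0,
) -> LabeledMask:
    """Merge attached over-segmented fragments (mother-bud repair).

    Two touching regions are combined when their combined area is at most
    ``theta_area`` AND their total-DNA difference is at least ``theta_dna``
    (a bud carries little DNA relative to its mother).  Merging repeats until
    no pair qualifies, in a deterministic order: ascending combined area,
    then ascending label ids.  The label count never increases.
    """
    if theta_area <= 0:
        raise ParameterError("theta_area must be positive")
    labels = mask.labels.astype(np.int32).copy()
    dna = np.asarray(dna, dtype=float)

    while True:
        ids = np.unique(labels[labels > 0])
        if len(ids) < 2:
            break
        area = {int(i): int((labels == i).sum()) for i in ids}
        dtot = {int(i): float(dna[labels == i].sum()) for i in ids}
        candidates = []
        for a, b in _adjacent_pairs(labels):
            comb = area[a] + area[b]
            if comb <= theta_area and abs(dtot[a] - dtot[b]) >= theta_dna:
                candidates.append((comb, a, b))
        if not candidates:
            break
        _, a, b = min(candidates)
        labels[labels == b] = a
    return LabeledMask(labels).compact()


def _boundary_points(mask: LabeledMask) -> np.ndarray:
    b = find_boundaries(mask.labels, connectivity=1, mode="inner", background=0)
    return np.argwhere(b)


def boundary_error(manual: LabeledMask, auto: LabeledMask) -> float:
    """Symmetric mean nearest-neighbour distance between boundary pixel sets.

    For each boundary pixel of one mask, the Euclidean distance to the
    nearest boundary pixel of the other is found; the metric averages both
    directed means.  Smaller is better; identical masks give 0.
    """
    if manual.labels.shape != auto.labels.shape:
        raise ParameterError("masks must share one shape")
    pm = _boundary_points(manual)
    pa = _boundary_points(auto)
    if len(pm) == 0 or len(pa) == 0:
        raise UndefinedMetricError("empty boundary set")
    d_ma = cKDTree(pa).query(pm)[0]
    d_am = cKDTree(pm).query(pa)[0]
    return 0.5 * (float(d_ma.mean()) + float(d_am.mean()))


def rand_error(manual: LabeledMask, auto: LabeledMask) -> float:
    """Pairwise pixel co-assignment disagreement frequency, in [0, 1].

    Over all N-choose-2 pixel pairs, count pairs placed in the same region by
    both labelings (a) and in different regions by both (b); the error is
    1 - (a+b)/C(N,2).  Background (label 0) counts as a region of its own.
    Computed from the label-pair contingency table in O(N).
    """
    if manual.labels.shape != auto.labels.shape:
        raise ParameterError("masks must share one shape")
    x = manual.labels.ravel()
    y = auto.labels.ravel()
    n = x.size
    # contingency counts via joint encoding
    joint = pd.crosstab(x, y).to_numpy().astype(np.float64)
    nij2 = (joint * (joint - 1) / 2.0).sum()
    ai = joint.sum(axis=1)
    bj = joint.sum(axis=0)
    ai2 = (ai * (ai - 1) / 2.0).sum()
    bj2 = (bj * (bj - 1) / 2.0).sum()
    total = n * (n - 1) / 2.0
    a = nij2
    b = total - ai2 - bj2 + nij2
    return float(1.0 - (a + b) / total)
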