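"""Compartment catalog, per-protein null fits, and the localization map.

Each protein is compared (mean d_p) against every compartment of a catalog
of landmark organelles and large protein complexes.  Most compartments are
*not* specifically occupied by a given protein, so the bulk of its d_p
scores form a "non-specific" null distribution.  That null is estimated per
protein: the upper and lower fifth percentiles are trimmed, a Gaussian
kernel density is fit, the rightmost local maximum is taken as the null
mean mu_null, and the null sd sigma_null is the one-sided RMS deviation of
the scores above mu_null.  Standardizing all d_p scores by (mu, sigma)
yields z-scores whose lower tail under N(0,1) gives per-compartment
P-values; Bonferroni-corrected thresholding produces hard compartment
assignments.  Standardization is affine, so the within-protein ranking of
compartments is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateNullError, ParameterError, PlastError

__all__ = [
    "CompartmentCatalog",
    "LocalizationMap",
    "load_catalog",
    "fit_null",
    "standardize",
    "build_localization_map",
    "assign_compartments",
    "shared_compartment_ratio",
]


@dataclass
class CompartmentCatalog:
    """Compartment name -> member protein-id set, with provenance."""

    compartments: dict
    provenance: dict = dc_field(default_factory=dict)  # name -> "organelle" | "complex"

    def __post_init__(self):
        empty = [k for k, v in self.compartments.items() if not v]
        if empty:
            raise ParameterError(f"empty compartments: {empty}")

    @property
    def names(self):
        return list(self.compartments)

    def __len__(self):
        return len(self.compartments)


def load_catalog(
    organelles=None,
    complexes=None,
    min_subunits: int = 15,
    exclusions: set = frozenset(),
) -> CompartmentCatalog:
    """Load and filter a compartment catalog from TSV paths or DataFrames.

    Inputs have columns (compartment, protein_id); memberships are
    deduplicated.  Organelles are kept as-is; protein complexes are retained
    only with at least ``min_subunits`` members.  Names in ``exclusions``
    are dropped from either source.
    """
    comps, prov = {}, {}

    def _read(src, kind):
        if src is None:
            return
        df = pd.read_csv(src, sep="\t") if not isinstance(src, pd.DataFrame) else src
        missing = {"compartment", "protein_id"} - set(df.columns)
        if missing:
            raise ParameterError(f"{kind} table missing columns {missing}")
        bad = df[df[["compartment", "protein_id"]].isna().any(axis=1)]
        if len(bad):
            raise ParameterError(f"malformed {kind} rows at lines {list(bad.index + 2)}")
        for name, grp in df.groupby("compartment"):
            if name in exclusions:
                continue
            members = set(grp["protein_id"])
            if kind == "complex" and len(members) < min_subunits:
                continue
            comps[name] = comps.get(name, set()) | members
            prov[name] = kind

    _read(organelles, "organelle")
    _read(complexes, "complex")
    return CompartmentCatalog(comps, prov)


def fit_null(
    dp_scores,
    trim: float = 5.0,
    grid_size: int = 512,
    sigma_floor: float = 1e-6,
    method: str = "mixture",
    max_components: int = 3,
    delta_bic: float = 10.0,
):
    """Estimate (mu_null, sigma_null) from one protein's compartment scores.

    The null is the distribution of d_p between the protein and the
    compartments it does *not* specifically occupy — the dominant,
    rightmost bulk of the scores.  Two estimators are provided:

    ``mixture`` (default)
        Model the scores as a mixture of Gaussians and take the component
        with the largest mean as the null.  The component count (1 to
        ``max_components``) is chosen by BIC, requiring an improvement of
        ``delta_bic`` to accept extra components, so a unimodal score set
        keeps a single component and the estimator stays calibrated (its
        z-scores are honest under a pure null, which the mode-based route
        cannot guarantee at small n — see the methods note).
    ``kde_mode``
        Trim the upper/lower ``trim`` percentiles, fit a Gaussian KDE
        (Silverman bandwidth) on a ``grid_size``-point grid spanning the
        trimmed range +/- 3 bandwidths, take the rightmost strict local
        maximum of the density (plateaus resolve to their rightmost grid
        point) as mu_null, and estimate sigma_null one-sidedly as
        sqrt(mean((d - mu)^2)) over all scores d > mu_null.

    Both return ``(mu_null, sigma_null)`` with sigma floored at
    ``sigma_floor``; both keep a small low-d_p cluster (specifically
    occupied compartments) out of the null.
    """
    d = np.asarray(dp_scores, dtype=float)
    if d.size < 10:
        raise ParameterError("need at least 10 compartment scores")
    if np.allclose(d, d[0]):
        raise DegenerateNullError("degenerate score distribution (all equal)")

    if method == "mixture":
        from sklearn.mixture import GaussianMixture

        X = d.reshape(-1, 1)
        models, bics = {}, {}
        for k in range(1, max_components + 1):
            gm = GaussianMixture(k, random_state=0, n_init=2).fit(X)
            models[k], bics[k] = gm, gm.bic(X)
        best_k = 1
        for k in range(2, max_components + 1):
            if bics[k] < bics[best_k] - delta_bic:
                best_k = k
        gm = models[best_k]
        j = int(np.argmax(gm.means_.ravel()))
        mu = float(gm.means_.ravel()[j])
        sigma = float(np.sqrt(gm.covariances_.ravel()[j]))
        if not np.any(d > mu):
            raise DegenerateNullError("no scores above the fitted null mean")
        return mu, max(sigma, sigma_floor)

    if method != "kde_mode":
        raise ParameterError(f"unknown method {method!r}")

    lo, hi = np.percentile(d, [trim, 100 - trim])
    trimmed = d[(d >= lo) & (d <= hi)]
    if trimmed.size < 3 or np.allclose(trimmed, trimmed[0]):
        raise DegenerateNullError("degenerate score distribution")
    kde = stats.gaussian_kde(trimmed, bw_method="silverman")
    bw = kde.factor * trimmed.std(ddof=1)
    grid = np.linspace(trimmed.min() - 3 * bw, trimmed.max() + 3 * bw, grid_size)
    dens = kde(grid)

    # rightmost local maximum; plateaus resolve to their rightmost point
    is_max = np.zeros(grid_size, dtype=bool)
    for i in range(1, grid_size - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]:
            is_max[i] = True
    if dens[-1] > dens[-2]:
        is_max[-1] = True
    if not is_max.any():
        is_max[np.argmax(dens)] = True
    mu = float(grid[np.nonzero(is_max)[0][-1]])

    above = d[d > mu]
    if above.size == 0:
        raise DegenerateNullError("no scores above the fitted mode")
    sigma = float(np.sqrt(np.mean((above - mu) ** 2)))
    return mu, max(sigma, sigma_floor)


def standardize(dp_scores, mu_null: float, sigma_null: float):
    """z-scores and lower-tail normal P-values for one protein's d_p row."""
    if sigma_null <= 0:
        raise ParameterError("sigma_null must be positive")
    z = (np.asarray(dp_scores, dtype=float) - mu_null) / sigma_null
    p = stats.norm.cdf(z)
    return z, p


@dataclass
class LocalizationMap:
    """Standardized protein x compartment dissimilarities with assignments."""

    z: pd.DataFrame  # proteins x compartments
    p_adj: pd.DataFrame
    null_params: pd.DataFrame  # protein -> mu_null, sigma_null
    assignments: dict = dc_field(default_factory=dict)
    alpha: float = np.nan


def build_localization_map(dp_table: pd.DataFrame, trim: float = 5.0) -> LocalizationMap:
    """Standardize a protein-by-compartment d_p matrix.

    ``dp_table``: rows = proteins, columns = compartments, entries = mean
    d_p between the protein and the compartment's members.  Per-protein
    Bonferroni correction uses m = number of compartments scored for that
    protein.  Proteins with a degenerate null are skipped with a flag row.
    """
    zs, ps, nulls = {}, {}, {}
    for prot, row in dp_table.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        m = int(ok.sum())  # Bonferroni family: compartments tested for this protein
        try:
            mu, sigma = fit_null(vals[ok], trim=trim)
        except (DegenerateNullError, ParameterError):
            continue
        z = np.full_like(vals, np.nan)
        p = np.full_like(vals, np.nan)
        z[ok], p[ok] = standardize(vals[ok], mu, sigma)
        zs[prot] = z
        ps[prot] = np.minimum(1.0, m * p)
        nulls[prot] = (mu, sigma)
    zdf = pd.DataFrame(zs, index=dp_table.columns).T
    pdf = pd.DataFrame(ps, index=dp_table.columns).T
    ndf = pd.DataFrame(nulls, index=["mu_null", "sigma_null"]).T
    return LocalizationMap(z=zdf, p_adj=pdf, null_params=ndf)


def assign_compartments(locmap: LocalizationMap, alpha_adj: float = 2.5e-4) -> dict:
    """Hard assignments: compartment given to a protein iff adjusted P < alpha."""
    assignments = {}
    for prot, row in locmap.p_adj.iterrows():
        assignments[prot] = set(row.index[row < alpha_adj])
    locmap.assignments = assignments
    locmap.alpha = alpha_adj
    return assignments


def shared_compartment_ratio(a: set, b: set, convention: str = "jaccard") -> float:
    """Overlap of two assignment sets.

    Default is the Jaccard ratio \\|a&b\\|/\\|a|b\\|; ``min`` divides by the
    smaller set size instead.  Two empty sets give 0 (flagged convention).
    """
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    if convention == "jaccard":
        return len(a & b) / len(a | b)
    if convention == "min":
        m = min(len(a), len(b))
        return len(a & b) / m if m else 0.0
    raise ParameterError(f"unknown convention {convention!r}")


def dp_to_compartments(dp_mat: pd.DataFrame, catalog: CompartmentCatalog) -> pd.DataFrame:
    """Mean d_p between every profiled protein and every catalog compartment.

    Self-scores are excluded when the protein is itself a member of the
    compartment; compartments with no profiled member are skipped for that
    protein (NaN column dropped if empty for everyone).
    """
    ids = list(dp_mat.index)
    idset = set(ids)
    cols = {}
    for name, members in catalog.compartments.items():
        present = sorted(members & idset)
        if not present:
            continue
        sub = dp_mat.loc[ids, present].to_numpy(dtype=float)
        counts = np.full(len(ids), len(present), dtype=float)
        sums = sub.sum(axis=1)
        for k, pid in enumerate(ids):
            if pid in members and pid in idset:
                # self d_p (zero) excluded
                counts[k] -= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, sums / counts, np.nan)
        cols[name] = vals
    out = pd.DataFrame(cols, index=ids)
    if out.empty:
        raise PlastError("no catalog compartment has profiled members")
    return out
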