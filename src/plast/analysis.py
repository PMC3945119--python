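"""Downstream statistics on profiles, assignments and duplicate pairs.

Covers: ranked retrieval of complex subunits with precision/recall/F1, a
category-annotation baseline for the same task, paired-t comparison of
retrieval methods, two-sided permutation tests for mean/median differences,
similar/dissimilar (SL/DL) classification of duplicate pairs against an
empirical null of non-duplicate pairs, the localization-vs-function 2x2
contingency with Fisher's exact test, clustering of profiles (affinity
propagation with a preference sweep, and Ward hierarchical clustering), and
hypergeometric enrichment with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ParameterError, PlastError

__all__ = [
    "RetrievalResult",
    "DivergenceTable",
    "subunit_search",
    "annotation_baseline_search",
    "compare_methods",
    "permutation_test",
    "sample_null_pairs",
    "classify_divergence",
    "function_divergence_table",
    "cluster_profiles",
    "preference_sweep",
    "enrichment_test",
]


@dataclass
class RetrievalResult:
    """Ranked subunit-retrieval output with P/R/F1 curves."""

    query_ids: tuple
    ranking: pd.DataFrame  # rank, protein, mean_dp, is_truth
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    max_f1: float
    threshold_at_max: float


def _prf(tp: float, fp: float, fn: float):
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def subunit_search(query, dp_mat: pd.DataFrame, truth) -> RetrievalResult:
    """Rank all non-query proteins by mean d_p to the query set.

    ``truth`` is the full known subunit set used for scoring (query members
    are excluded from both ranking and truth).  Precision/recall/F1 are
    evaluated at every rank cutoff; the maximum F1 and the d_p threshold
    attaining it are reported.
    """
    query = list(query)
    missing = [q for q in query if q not in dp_mat.index]
    if missing:
        raise ParameterError(f"query ids missing from matrix: {missing}")
    others = [p for p in dp_mat.index if p not in set(query)]
    mean_dp = dp_mat.loc[others, query].mean(axis=1)
    order = mean_dp.sort_values(kind="stable")
    truth_set = set(truth) - set(query)
    is_truth = np.array([p in truth_set for p in order.index])

    tp_cum = np.cumsum(is_truth)
    ranks = np.arange(1, len(order) + 1)
    n_truth = int(is_truth.sum())
    precision = tp_cum / ranks
    recall = tp_cum / n_truth if n_truth > 0 else np.zeros_like(tp_cum, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    best = int(np.argmax(f1)) if len(f1) else 0
    ranking = pd.DataFrame(
        {"rank": ranks, "protein": order.index, "mean_dp": order.to_numpy(), "is_truth": is_truth}
    )
    return RetrievalResult(
        query_ids=tuple(query),
        ranking=ranking,
        precision=precision,
        recall=recall,
        f1=f1,
        max_f1=float(f1[best]) if len(f1) else 0.0,
        threshold_at_max=float(order.iloc[best]) if len(f1) else np.nan,
    )


def annotation_baseline_search(query, annotations: dict, truth, universe=None) -> RetrievalResult:
    """Category-annotation baseline for subunit retrieval.

    The category carried by the most query members (ties broken
    lexicographically) defines one prediction set: every other protein
    annotated with it.  P/R/F1 of that single set are reported.
    """
    query = list(query)
    counts = {}
    for q in query:
        for cat in annotations.get(q, ()):
            counts[cat] = counts.get(cat, 0) + 1
    if not counts:
        raise InsufficientDataError("no annotated query member; baseline undefined")
    top = max(sorted(counts), key=lambda c: counts[c])
    pool = universe if universe is not None else annotations.keys()
    predicted = {p for p in pool if top in annotations.get(p, ()) and p not in set(query)}
    truth_set = set(truth) - set(query)
    tp = len(predicted & truth_set)
    fp = len(predicted - truth_set)
    fn = len(truth_set - predicted)
    precision, recall, f1 = _prf(tp, fp, fn)
    ranking = pd.DataFrame(
        {
            "rank": np.arange(1, len(predicted) + 1),
            "protein": sorted(predicted),
            "mean_dp": np.nan,
            "is_truth": [p in truth_set for p in sorted(predicted)],
        }
    )
    return RetrievalResult(
        query_ids=tuple(query),
        ranking=ranking,
        precision=np.array([precision]),
        recall=np.array([recall]),
        f1=np.array([f1]),
        max_f1=f1,
        threshold_at_max=np.nan,
    )


def compare_methods(maxf1: pd.DataFrame) -> pd.DataFrame:
    """One-sided paired t-tests between methods' max-F1 columns.

    Rows are complexes, columns methods.  For each ordered pair (A, B) the
    alternative is mean(F1_A - F1_B) > 0; P-values are Bonferroni-adjusted
    over the number of ordered pairs.
    """
    if maxf1.shape[1] < 2 or maxf1.shape[0] < 2:
        raise ParameterError("need >=2 methods and >=2 complexes")
    if maxf1.isna().any().any():
        raise ParameterError("unpaired rows (NaNs) in max-F1 table")
    methods = list(maxf1.columns)
    rows = []
    pairs = [(a, b) for a in methods for b in methods if a != b]
    for a, b in pairs:
        with np.errstate(invalid="ignore"):
            t, p = stats.ttest_rel(maxf1[a], maxf1[b], alternative="greater")
        if np.isnan(t):  # identical columns: zero difference everywhere
            t, p = 0.0, 0.5
        rows.append({"method_a": a, "method_b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(1.0, out["p"] * len(pairs))
    return out


def permutation_test(
    x,
    y,
    stat: str = "mean_diff",
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided permutation P-value for a difference in means or medians.

    Labels of the pooled sample are permuted ``n_perm`` times; the P-value
    is the fraction of permutations whose absolute statistic is at least
    the observed absolute statistic.  A zero count is reported as below the
    resolution 1/n_perm (i.e. 0.0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse P-value", stacklevel=2)
    fn = np.mean if stat == "mean_diff" else np.median
    if stat not in ("mean_diff", "median_diff"):
        raise ParameterError(f"unknown stat {stat!r}")
    obs = abs(fn(x) - fn(y))
    pooled = np.concatenate([x, y])
    n = x.size
    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(pooled.size), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    perms = pooled[idx]
    if stat == "mean_diff":
        s = np.abs(perms[:, :n].mean(axis=1) - perms[:, n:].mean(axis=1))
    else:
        s = np.abs(np.median(perms[:, :n], axis=1) - np.median(perms[:, n:], axis=1))
    return float(np.sum(s >= obs - 1e-12) / n_perm)


@dataclass
class DivergenceTable:
    """SL/DL-classified duplicate pairs with shared-compartment data."""

    pairs: pd.DataFrame  # idA, idB, dp, shared_ratio, n_compartments_union, cls
    percentile: float
    threshold: float
    null_dp: np.ndarray = dc_field(default_factory=lambda: np.array([]))


def sample_null_pairs(ids, duplicates, n_pairs: int = 10000, seed: int = 0):
    """Random non-duplicate, non-self pairs (without replacement)."""
    rng = np.random.default_rng(seed)
    ids = list(ids)
    dupset = {frozenset(p[:2]) for p in duplicates}
    seen = set()
    out = []
    max_tries = 50 * n_pairs
    tries = 0
    while len(out) < n_pairs and tries < max_tries:
        tries += 1
        i, j = rng.integers(len(ids), size=2)
        if i == j:
            continue
        key = frozenset((ids[i], ids[j]))
        if key in dupset or key in seen:
            continue
        seen.add(key)
        out.append((ids[i], ids[j]))
    return out


def classify_divergence(
    duplicates,
    null_pairs,
    dp_mat: pd.DataFrame,
    percentile: float = 10.0,
    assignments: dict | None = None,
) -> DivergenceTable:
    """Label duplicate pairs similarly (SL) or dissimilarly localized (DL).

    The threshold is the stated percentile of the d_p distribution over the
    null (non-duplicate) pairs; a pair is DL iff its d_p >= threshold.
    Shared-compartment ratios and union sizes are attached when hard
    assignments are provided.  Pairs missing a profile are skipped with a
    log entry.
    """
    if len(null_pairs) < 100:
        raise ParameterError("null pair sample too small (need >= 100)")
    from .mapping import shared_compartment_ratio

    null_dp = np.array(
        [dp_mat.at[a, b] for a, b in null_pairs if a in dp_mat.index and b in dp_mat.index]
    )
    threshold = float(np.percentile(null_dp, percentile))
    rows = []
    for pair in duplicates:
        a, b = pair[:2]
        if a not in dp_mat.index or b not in dp_mat.index:
            warnings.warn(f"pair ({a},{b}) missing a profile; skipped", stacklevel=2)
            continue
        d = float(dp_mat.at[a, b])
        cls = "DL" if d >= threshold else "SL"
        if assignments is not None:
            sa, sb = assignments.get(a, set()), assignments.get(b, set())
            ratio = shared_compartment_ratio(sa, sb)
            union = len(sa | sb)
        else:
            ratio, union = np.nan, np.nan
        rows.append(
            {"idA": a, "idB": b, "dp": d, "shared_ratio": ratio, "n_compartments_union": union, "cls": cls}
        )
    pairs = pd.DataFrame(rows, columns=["idA", "idB", "dp", "shared_ratio", "n_compartments_union", "cls"])
    return DivergenceTable(pairs=pairs, percentile=percentile, threshold=threshold, null_dp=null_dp)


def annotation_match_fraction(terms_a, terms_b, denominator: str = "min") -> float:
    """Fraction of matching annotations between two term sets.

    Default denominator is the smaller set size (robust to annotation-depth
    asymmetry); ``union`` is available behind the flag.
    """
    a, b = set(terms_a), set(terms_b)
    if not a or not b:
        return 0.0
    if denominator == "min":
        return len(a & b) / min(len(a), len(b))
    if denominator == "union":
        return len(a & b) / len(a | b)
    raise ParameterError(f"unknown denominator {denominator!r}")


def function_divergence_table(
    table: DivergenceTable,
    annotations: dict,
    match_fraction: float = 0.75,
    denominator: str = "min",
):
    """2x2 SL/DL x similar/dissimilar-function counts with Fisher's P.

    A pair is functionally "similar" iff the fraction of matching
    annotations between its members is at least ``match_fraction``.  Pairs
    with an unannotated member are dropped; an empty table is an error.
    Returns (contingency DataFrame, two-sided Fisher exact P).
    """
    counts = {("SL", "similar"): 0, ("SL", "dissimilar"): 0, ("DL", "similar"): 0, ("DL", "dissimilar"): 0}
    n_used = 0
    for _, row in table.pairs.iterrows():
        ta = annotations.get(row["idA"])
        tb = annotations.get(row["idB"])
        if not ta or not tb:
            continue
        n_used += 1
        frac = annotation_match_fraction(ta, tb, denominator)
        sim = "similar" if frac >= match_fraction else "dissimilar"
        counts[(row["cls"], sim)] += 1
    if n_used == 0:
        raise PlastError("no duplicate pair has both members annotated")
    tab = pd.DataFrame(
        [[counts[("SL", "similar")], counts[("SL", "dissimilar")]],
         [counts[("DL", "similar")], counts[("DL", "dissimilar")]]],
        index=["SL", "DL"],
        columns=["similar", "dissimilar"],
    )
    _, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
    return tab, float(p)


def cluster_profiles(
    dp_mat: pd.DataFrame,
    mode: str = "affinity_propagation",
    preference: float | None = None,
    k: int | None = None,
    seed: int = 0,
):
    """Cluster proteins from their pairwise d_p matrix.

    ``affinity_propagation`` runs on similarity = -d_p with one shared
    preference value for every point (None lets the implementation use the
    median similarity) and returns (labels, exemplar ids).  ``hierarchical_ward``
    builds a Ward tree on the dissimilarities and cuts at ``k`` clusters,
    returning (labels, None).
    """
    M = dp_mat.to_numpy(dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ParameterError("dissimilarity matrix must be symmetric")
    if mode == "affinity_propagation":
        ap = AffinityPropagation(affinity="precomputed", preference=preference, random_state=seed, damping=0.7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = ap.fit_predict(-M)
        exemplars = [dp_mat.index[i] for i in ap.cluster_centers_indices_] if len(ap.cluster_centers_indices_) else []
        return labels, exemplars
    if mode == "hierarchical_ward":
        if k is None:
            raise ParameterError("hierarchical_ward needs k")
        Z = linkage(squareform(M, checks=False), method="ward")
        return fcluster(Z, t=k, criterion="maxclust"), None
    raise ParameterError(f"unknown mode {mode!r}")


def preference_sweep(dp_mat: pd.DataFrame, preferences, seed: int = 0) -> pd.DataFrame:
    """Cluster-count vs affinity-propagation preference curve."""
    rows = []
    for pref in preferences:
        labels, exemplars = cluster_profiles(dp_mat, "affinity_propagation", preference=pref, seed=seed)
        n = len(exemplars) if exemplars else len(np.unique(labels[labels >= 0]))
        rows.append({"preference": pref, "n_clusters": int(n)})
    return pd.DataFrame(rows)


def enrichment_test(cluster_members, category_members, universe) -> float:
    """One-sided hypergeometric tail P for category enrichment in a cluster."""
    universe = set(universe)
    if not universe:
        raise ParameterError("empty universe")
    cluster = set(cluster_members) & universe
    category = set(category_members) & universe
    k = len(cluster & category)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(category), len(cluster)))


def enrichment_table(clusters: dict, categories: dict, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of every (cluster, category) pair with
    Benjamini-Hochberg adjustment across categories within each cluster."""
    rows = []
    for cname, cmem in clusters.items():
        ps = [
            {"cluster": cname, "category": gname, "p": enrichment_test(cmem, gmem, universe)}
            for gname, gmem in categories.items()
        ]
        padj = multipletests([r["p"] for r in ps], method="fdr_bh")[1]
        for r, pa in zip(ps, padj):
            r["p_adj"] = float(pa)
            rows.append(r)
    return pd.DataFrame(rows)
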