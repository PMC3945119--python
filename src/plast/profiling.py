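"""Localization profiles (P-profiles) and their dissimilarity score.

A strain's profile is either the per-feature mean over its cells
(``mean`` method) or the normal vector of a linear maximum-margin
hyperplane separating the strain's cells from a fixed reference cell set
(``svm`` method).  The SVM route down-weights uninformative features: a
feature that does not help separate the strain from the reference pool gets
a near-zero hyperplane weight.  Profiles are compared with the dissimilarity
score d_p, by default the cosine dissimilarity 1 - cos(h, g), which is 0 for
identical directions and at most 2.

Features are z-scored with a scaler fit on the pooled strain + reference
cells before SVM training (linear SVMs are scale-sensitive); the scaler is
shared across strains so profiles stay comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import InsufficientDataError, ParameterError, RegistryError

__all__ = [
    "PProfile",
    "ReferenceSet",
    "DEFAULT_COST_GRID",
    "build_profile_mean",
    "build_profile_svm",
    "select_reference_set",
    "classify_profiles",
    "dp",
    "dp_group",
    "dp_matrix",
]

#: powers-of-two cost ladder for the linear-SVM grid search
DEFAULT_COST_GRID = tuple(2.0**k for k in range(-5, 6, 2))
#: liblinear termination tolerance
DEFAULT_EPSILON = 0.01


@dataclass
class PProfile:
    """A strain's localization signature."""

    strain_id: str
    method: str  # "svm" | "mean"
    weights: np.ndarray
    feature_names: tuple = ()
    norm_convention: str = "l1_sum"
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class ReferenceSet:
    """A fixed pool of reference cells the SVM separates each strain from."""

    cells: pd.DataFrame  # feature rows only
    size: int
    source_categories: tuple = ()
    selection_score: float = np.nan


def _as_matrix(cells) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        num = cells.select_dtypes(include=[np.number])
        drop = [c for c in ("qc_area", "qc_solidity") if c in num.columns]
        return num.drop(columns=drop).to_numpy(dtype=float)
    return np.asarray(cells, dtype=float)


def build_profile_mean(cells, strain_id: str = "") -> PProfile:
    """Per-feature mean over a strain's cells."""
    X = _as_matrix(cells)
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least two cells")
    return PProfile(strain_id, "mean", X.mean(axis=0))


def _normalize_weights(w: np.ndarray, convention: str) -> np.ndarray:
    if convention == "l1_sum":
        # scale by the sum of the elements, but keep the hyperplane's
        # orientation (decision function positive on the strain side): a
        # negative sum must not flip the profile to its antipode, which
        # would wreck every cosine-based comparison downstream
        s = abs(w.sum())
        if s < 1e-12:
            warnings.warn("weight sum ~0; falling back to l2 normalization", stacklevel=3)
            return w / np.linalg.norm(w)
        return w / s
    if convention == "l2":
        n = np.linalg.norm(w)
        if n == 0:
            raise ParameterError("zero weight vector")
        return w / n
    raise ParameterError(f"unknown norm convention {convention!r}")


def build_profile_svm(
    cells,
    reference: ReferenceSet | pd.DataFrame | np.ndarray,
    strain_id: str = "",
    cost_grid=DEFAULT_COST_GRID,
    epsilon: float = DEFAULT_EPSILON,
    norm_convention: str = "l1_sum",
    scaler: StandardScaler | None = None,
) -> PProfile:
    """Hyperplane-normal profile from a strain-vs-reference linear SVM.

    For each cost in ``cost_grid`` a linear two-class maximum-margin
    classifier is fit on the z-scored strain and reference cells; the cost
    with maximum training accuracy wins (ties -> smallest cost).  The
    hyperplane normal W is then normalized: under the default ``l1_sum``
    convention W is divided by the sum of its elements (an ``l2`` unit-norm
    alternative is available; the convention is recorded in the profile
    metadata, and d_p is scale-free either way).
    """
    X1 = _as_matrix(cells)
    X0 = _as_matrix(reference.cells if isinstance(reference, ReferenceSet) else reference)
    if X1.shape[0] < 2 or X0.shape[0] < 2:
        raise InsufficientDataError("both classes need at least two cells")
    X = np.vstack([X1, X0])
    y = np.concatenate([np.ones(len(X1)), np.zeros(len(X0))])
    if np.allclose(X.var(axis=0), 0):
        raise ParameterError(f"degenerate all-identical features for strain {strain_id!r}")
    if scaler is None:
        scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    best = None
    for cost in sorted(cost_grid):
        clf = LinearSVC(C=cost, tol=epsilon, dual=True, max_iter=20000, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        acc = clf.score(Xs, y)
        if best is None or acc > best[0] + 1e-12:
            best = (acc, cost, clf.coef_[0].copy())
    acc, cost, w = best
    return PProfile(
        strain_id,
        "svm",
        _normalize_weights(w, norm_convention),
        norm_convention=norm_convention,
        metadata={"cost": cost, "train_accuracy": acc},
    )


def build_profiles(
    table: pd.DataFrame,
    method: str = "svm",
    reference: ReferenceSet | None = None,
    **kwargs,
) -> list[PProfile]:
    """One profile per strain of a feature table (convenience driver)."""
    feats = [c for c in table.columns if c not in ("strain_id", "cell_id", "qc_area", "qc_solidity")]
    scaler = None
    if method == "svm":
        if reference is None:
            raise ParameterError("svm profiles need a reference cell set")
        pool = np.vstack([table[feats].to_numpy(float), _as_matrix(reference.cells)])
        scaler = StandardScaler().fit(pool)
    profiles = []
    for sid, grp in table.groupby("strain_id", sort=True):
        if method == "mean":
            prof = build_profile_mean(grp[feats], strain_id=sid)
        else:
            prof = build_profile_svm(grp[feats], reference, strain_id=sid, scaler=scaler, **kwargs)
        prof.feature_names = tuple(feats)
        profiles.append(prof)
    return profiles


def select_reference_set(
    table: pd.DataFrame,
    labels: dict,
    candidate_sizes=tuple(range(10, 91, 10)),
    n_repeats: int = 5,
    seed: int = 0,
    source_categories: tuple | None = None,
) -> ReferenceSet:
    """Pick the reference-cell count that best preserves class structure.

    For each candidate size, cells are sampled (uniformly, seeded) from the
    strains carrying the source categories; SVM profiles are built for every
    labeled strain and scored by cross-validated multi-class classification
    of single-category strains; scores are averaged over ``n_repeats``
    random samplings and the argmax size wins.
    """
    feats = [c for c in table.columns if c not in ("strain_id", "cell_id", "qc_area", "qc_solidity")]
    strain_labels = {s: l for s, l in labels.items() if s in set(table["strain_id"])}
    classes = sorted(set(strain_labels.values()))
    if len(classes) < 2:
        raise InsufficientDataError("need at least two labeled classes")
    if source_categories is None:
        source_categories = tuple(classes)
    pool = table[table["strain_id"].map(lambda s: strain_labels.get(s) in source_categories)]

    rng = np.random.default_rng(seed)
    best = None
    for size in candidate_sizes:
        accs = []
        for _ in range(n_repeats):
            idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
            ref = ReferenceSet(pool.iloc[idx][feats], size=size, source_categories=source_categories)
            profiles = build_profiles(table, method="svm", reference=ref)
            acc = classify_profiles(
                profiles,
                strain_labels,
                k_folds=min(
                    3,
                    int(np.bincount(pd.factorize(pd.Series([strain_labels[p.strain_id] for p in profiles]))[0]).min()),
                ),
                n_trials=1,
                seed=int(rng.integers(2**31 - 1)),
            )["accuracy"].mean()
            accs.append(acc)
            last_ref = ref
        score = float(np.mean(accs))
        if best is None or score > best[0]:
            best = (score, last_ref)
    ref = best[1]
    ref.selection_score = best[0]
    return ref


def classify_profiles(
    profiles: list[PProfile],
    labels: dict,
    k_folds: int = 6,
    n_trials: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold multi-class accuracy of profiles (evaluation harness).

    A Crammer-Singer multi-class linear SVM is trained on profile vectors;
    cross-validation is repeated ``n_trials`` times with different fold
    shuffles.  Returns a per-class accuracy table (plus one "__mean__" row).
    """
    labeled = [p for p in profiles if p.strain_id in labels]
    X = np.vstack([p.weights for p in labeled])
    y = np.array([labels[p.strain_id] for p in labeled])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientDataError("need at least two classes")
    too_small = classes[counts < k_folds]
    if len(too_small):
        raise InsufficientDataError(f"classes smaller than fold count: {list(too_small)}")

    per_class = {c: [] for c in classes}
    overall = []
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        pred = np.empty_like(y)
        for tr, te in skf.split(X, y):
            clf = LinearSVC(multi_class="crammer_singer", max_iter=20000, random_state=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[tr], y[tr])
            pred[te] = clf.predict(X[te])
        overall.append(float((pred == y).mean()))
        for c in classes:
            m = y == c
            per_class[c].append(float((pred[m] == y[m]).mean()))
    rows = [{"class": c, "accuracy": float(np.mean(per_class[c]))} for c in classes]
    rows.append({"class": "__mean__", "accuracy": float(np.mean(overall))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissimilarity score
# ---------------------------------------------------------------------------


def dp(h: PProfile | np.ndarray, g: PProfile | np.ndarray, metric: str = "cosine") -> float:
    """Dissimilarity between two profiles.

    Default is cosine dissimilarity, 1 - (h.g)/(|h||g|), in [0, 2] with 0
    for identical directions; Euclidean distance is available behind the
    ``metric`` flag.  Zero vectors are rejected.
    """
    hv = h.weights if isinstance(h, PProfile) else np.asarray(h, float)
    gv = g.weights if isinstance(g, PProfile) else np.asarray(g, float)
    if hv.shape != gv.shape:
        raise RegistryError("profiles have different feature registries")
    if metric == "cosine":
        nh, ng = np.linalg.norm(hv), np.linalg.norm(gv)
        if nh == 0 or ng == 0:
            raise ParameterError("zero-vector profile")
        return float(np.clip(1.0 - hv @ gv / (nh * ng), 0.0, 2.0))
    if metric == "euclidean":
        return float(np.linalg.norm(hv - gv))
    raise ParameterError(f"unknown metric {metric!r}")


def dp_group(h: PProfile, G, metric: str = "cosine") -> float:
    """Mean d_p between ``h`` and the members of group ``G``.

    If ``h`` itself is in the group (same strain id), its self-score is
    excluded; an empty group after exclusion is an error.
    """
    others = [g for g in G if not (isinstance(g, PProfile) and isinstance(h, PProfile) and g.strain_id == h.strain_id)]
    if not others:
        raise InsufficientDataError("group empty after self-exclusion")
    return float(np.mean([dp(h, g, metric=metric) for g in others]))


def dp_matrix(profiles: list[PProfile], metric: str = "cosine") -> pd.DataFrame:
    """Dense symmetric matrix of pairwise d_p values (zero diagonal)."""
    ids = [p.strain_id for p in profiles]
    W = np.vstack([p.weights for p in profiles])
    if metric == "cosine":
        norms = np.linalg.norm(W, axis=1)
        if np.any(norms == 0):
            raise ParameterError("zero-vector profile")
        sim = (W @ W.T) / np.outer(norms, norms)
        M = np.clip(1.0 - sim, 0.0, 2.0)
    else:
        from scipy.spatial.distance import cdist

        M = cdist(W, W, metric="euclidean")
    np.fill_diagonal(M, 0.0)
    M = (M + M.T) / 2.0
    return pd.DataFrame(M, index=ids, columns=ids)
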