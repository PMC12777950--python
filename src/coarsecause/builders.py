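"""Strata construction from covariates only.

All three builders partition units using the covariate table **X** alone —
never the treatment or the outcome, which is what licenses the stratified
effect estimators downstream. Their signatures enforce this: none of them
accepts ``t`` or ``y``.

Builders
--------
``cem_coarsen``
    Coarsened exact matching: recode each covariate into a small number of
    levels (equal-width bins for continuous columns, identity for
    categorical ones) and exact-match on the coarsened vector; strata are
    the occupied code combinations. Deterministic.
``kmeans_strata``
    Vector quantization of the covariate space by k-means; the cluster
    cells play the role of the coarsening codebook and the within-cluster
    sum of squares is the empirical quantization error.
``rf_proximity_strata``
    Breiman-style unsupervised random forest: discriminate the observed
    sample from a synthetic sample with independent marginals, read off
    tree-proximities, and cut a Ward dendrogram on sqrt(1 - proximity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .data import _is_numeric
from .errors import StrataError

logger = logging.getLogger("coarsecause")

__all__ = [
    "StrataAssignment",
    "CoarseningSpec",
    "cem_coarsen",
    "kmeans_strata",
    "rf_proximity_strata",
    "quantization_error",
]


@dataclass
class StrataAssignment:
    """Per-unit stratum labels in ``{1..J}`` with builder provenance.

    ``counts`` (per-stratum ``n_j, n_1j, n_0j``) is filled in lazily once a
    treatment vector is attached via :meth:`attach_treatment`.
    """

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    objective: float | None = None
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.size == 0:
            raise StrataError("empty assignment")
        uniq = np.unique(self.labels)
        if uniq[0] != 1 or uniq[-1] != len(uniq):
            # compact to consecutive 1..J keeping the order of stratum ids
            remap = {old: new for new, old in enumerate(uniq, start=1)}
            self.labels = np.array([remap[v] for v in self.labels])

    @property
    def J(self) -> int:
        return int(self.labels.max())

    @property
    def n(self) -> int:
        return len(self.labels)

    def attach_treatment(self, t: np.ndarray) -> pd.DataFrame:
        """Compute and cache per-stratum totals and per-arm counts."""
        t = np.asarray(t, dtype=int).ravel()
        if len(t) != self.n:
            raise StrataError("treatment vector length does not match assignment")
        tab = pd.DataFrame({"stratum": self.labels, "t": t})
        grouped = tab.groupby("stratum")["t"]
        self.counts = pd.DataFrame(
            {
                "n_j": grouped.size(),
                "n_1j": grouped.sum(),
                "n_0j": grouped.size() - grouped.sum(),
            }
        ).reset_index()
        return self.counts


@dataclass
class CoarseningSpec:
    """Per-covariate coarsening rules for CEM.

    ``rules`` maps each column name to either ``("bins", M)`` for an
    equal-width binning of a continuous column into ``M`` intervals over
    its observed range (last bin right-closed), or ``("categories",)`` for
    identity coarsening of a categorical column.
    """

    rules: Mapping[str, tuple]

    def __post_init__(self) -> None:
        for col, rule in self.rules.items():
            if rule[0] == "bins":
                if rule[1] < 1:
                    raise StrataError(f"bin count for {col!r} must be >= 1")
            elif rule[0] != "categories":
                raise StrataError(f"unknown coarsening rule {rule!r} for {col!r}")

    @classmethod
    def default(cls, x: pd.DataFrame, bins: int | None = None) -> "CoarseningSpec":
        """Sturges' bin count ``ceil(log2 n) + 1`` for continuous columns
        (or a uniform override), identity for categorical columns."""
        n = len(x)
        m = bins if bins is not None else int(np.ceil(np.log2(max(n, 2)))) + 1
        rules = {}
        for col in x.columns:
            rules[col] = ("bins", m) if _is_numeric(x[col]) else ("categories",)
        return cls(rules)


def _bin_codes(values: np.ndarray, m: int) -> np.ndarray:
    """Equal-width bin index in {1..m} over the observed range; the last
    bin is right-closed so the maximum lands inside it."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if m == 1 or lo == hi:
        return np.ones(len(values), dtype=int)
    edges = np.linspace(lo, hi, m + 1)
    return np.digitize(values, edges[1:-1], right=False) + 1


def cem_coarsen(x: pd.DataFrame, spec: CoarseningSpec | None = None) -> StrataAssignment:
    """Coarsen each covariate and exact-match on the coarsened vector.

    Strata are the occupied combinations of coarsened codes, so
    ``J <= prod_j M_j`` (with equality only when every codebook cell is
    occupied). Deterministic: no randomness enters.
    """
    x = pd.DataFrame(x)
    if x.shape[1] == 0 or len(x) == 0:
        raise StrataError("empty covariate table")
    if spec is None:
        spec = CoarseningSpec.default(x)
    missing = [c for c in x.columns if c not in spec.rules]
    if missing:
        raise StrataError(f"coarsening spec does not cover columns: {missing}")

    codes = {}
    for col in x.columns:
        rule = spec.rules[col]
        if rule[0] == "bins":
            codes[col] = _bin_codes(np.asarray(x[col], dtype=float), rule[1])
        else:
            levels = pd.Series(x[col]).astype(str)
            codes[col] = levels.map(
                {lv: i + 1 for i, lv in enumerate(sorted(levels.unique()))}
            ).to_numpy()
    code_frame = pd.DataFrame(codes)
    # label occupied tuples 1..J in lexicographic code order (deterministic)
    keys = pd.MultiIndex.from_frame(code_frame)
    uniq = sorted(set(keys))
    remap = {key: i + 1 for i, key in enumerate(uniq)}
    labels = np.array([remap[key] for key in keys])
    params = {"rules": {c: list(r) for c, r in spec.rules.items()}}
    return StrataAssignment(labels=labels, method="cem", params=params)


def _encode_numeric(x: pd.DataFrame, standardize: bool) -> np.ndarray:
    """Numeric design matrix for distance-based builders: one-hot encode
    categorical columns; z-score every column when ``standardize``."""
    parts = []
    for col in x.columns:
        if _is_numeric(x[col]):
            parts.append(pd.DataFrame({col: pd.to_numeric(x[col])}))
        else:
            parts.append(pd.get_dummies(pd.Series(x[col]).astype(str), prefix=col))
    mat = pd.concat(parts, axis=1).to_numpy(dtype=float)
    if standardize:
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    return mat


def kmeans_strata(
    x: pd.DataFrame,
    k: int,
    seed: int = 0,
    standardize: bool = True,
    n_init: int = 10,
) -> StrataAssignment:
    """Quantize the covariate space into ``k`` cells by k-means.

    Lloyd iteration with k-means++ seeding and ``n_init`` restarts, keeping
    the lowest within-cluster sum of squares (the empirical quantization
    error, stored as ``objective``). Empty clusters are dropped and labels
    compacted, so ``J <= k``. Requesting more clusters than there are
    distinct covariate rows yields one stratum per distinct row with a
    logged warning.
    """
    x = pd.DataFrame(x)
    n = len(x)
    if not 1 <= k <= n:
        raise StrataError(f"need 1 <= k <= n, got k={k}, n={n}")
    mat = _encode_numeric(x, standardize=standardize)
    n_distinct = len(np.unique(mat, axis=0))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.warning(
            "only %d distinct covariate rows; using k=%d instead of %d",
            n_distinct, k_eff, k,
        )
    km = KMeans(
        n_clusters=k_eff,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        random_state=int(seed) % (2**32),
    ).fit(mat)
    return StrataAssignment(
        labels=km.labels_ + 1,
        method="kmeans",
        params={"k": k, "seed": seed, "standardize": standardize, "n_init": n_init},
        objective=float(km.inertia_),
    )


def quantization_error(x, centers) -> float:
    """Mean over units of the squared Euclidean distance to the nearest
    center — the empirical two-point-norm quantization error of the
    codebook ``centers``. Zero iff every row coincides with a center."""
    mat = np.atleast_2d(np.asarray(x, dtype=float))
    if mat.shape[0] == 1 and mat.shape[1] > 1 and np.ndim(x) == 1:
        mat = mat.T
    cen = np.atleast_2d(np.asarray(centers, dtype=float))
    if np.ndim(centers) == 1 and mat.shape[1] == 1:
        cen = cen.T
    if cen.shape[0] < 1:
        raise StrataError("need at least one center")
    if cen.shape[1] != mat.shape[1]:
        raise StrataError(
            f"dimension mismatch: data is {mat.shape[1]}-d, centers are {cen.shape[1]}-d"
        )
    d2 = ((mat[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).mean())


def rf_proximity(
    x: pd.DataFrame, n_trees: int = 500, seed: int = 0, min_samples_leaf: int = 5
) -> np.ndarray:
    """Random-forest proximity matrix of the observed units.

    A synthetic second class is built by resampling each covariate column
    independently from its empirical marginal (destroying the joint
    dependence), a forest is trained to tell observed from synthetic, and
    proximity(i, i') is the fraction of trees in which units i and i' fall
    in the same terminal node. Symmetric with unit diagonal, entries in
    [0, 1].

    ``min_samples_leaf`` keeps terminal nodes from shrinking to single
    units: fully grown trees memorize the observed/synthetic distinction,
    which drives every proximity toward zero and leaves the clustering
    distance uninformative.
    """
    x = pd.DataFrame(x)
    n = len(x)
    rng = np.random.default_rng(seed)
    synth = pd.DataFrame(
        {col: rng.choice(x[col].to_numpy(), size=n, replace=True) for col in x.columns}
    )
    both = _encode_numeric(pd.concat([x, synth], ignore_index=True), standardize=False)
    labels = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=min_samples_leaf,
        random_state=int(rng.integers(2**31)),
        n_jobs=1,
    ).fit(both, labels)
    leaves = forest.apply(both[:n])
    prox = np.zeros((n, n))
    for tree in range(leaves.shape[1]):
        col = leaves[:, tree]
        prox += col[:, None] == col[None, :]
    prox /= leaves.shape[1]
    return prox


def rf_proximity_strata(
    x: pd.DataFrame,
    k: int,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> StrataAssignment:
    """Cluster units into ``k`` strata from random-forest proximities.

    Pipeline: proximity matrix (see :func:`rf_proximity`) -> distance
    ``sqrt(1 - proximity)`` -> Ward agglomeration -> cut the dendrogram at
    ``k`` clusters. One seed drives the synthetic sample and the forest.
    """
    x = pd.DataFrame(x)
    n = len(x)
    if not 1 <= k <= n:
        raise StrataError(f"need 1 <= k <= n, got k={k}, n={n}")
    if n_trees < 1:
        raise StrataError("n_trees must be >= 1")
    prox = rf_proximity(x, n_trees=n_trees, seed=seed, min_samples_leaf=min_samples_leaf)
    dist = np.sqrt(np.clip(1.0 - prox, 0.0, None))
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return StrataAssignment(
        labels=labels,
        method="rf",
        params={"k": k, "n_trees": n_trees, "seed": seed},
    )
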