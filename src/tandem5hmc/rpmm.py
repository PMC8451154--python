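"""Recursively partitioned beta-mixture clustering of bounded profiles.

Samples are profiles of beta values in (0,1) over a locus panel. At each
node a one-class model (independent beta per locus) is compared with a
two-class mixture fitted by EM: class-specific beta shape parameters per
locus, fuzzy responsibilities, loci independent given class. The split is
accepted iff BIC improves, children recurse up to ``max_depth``, and the
leaves are the clusters.

Numerical choices: data are clamped to [1e-6, 1 - 1e-6]; per-locus shape
parameters come from (weighted) method-of-moments with a variance floor of
1e-8 and shapes clipped to [1e-3, 1e6]; EM is initialised from a
deterministic two-means split (centroids seeded at the samples with the
smallest and largest mean beta, lexicographic sample-ID tie-break) so the
result is invariant to sample and locus order; EM runs at most ``max_iter``
iterations to an absolute log-likelihood tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .exceptions import ConfigurationError, DegenerateDataError, IngestError

logger = logging.getLogger(__name__)

_CLAMP = 1e-6
_VAR_FLOOR = 1e-6
_SHAPE_MIN, _SHAPE_MAX = 1e-3, 1e4


def _mom_shapes(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted method-of-moments beta shapes per locus.

    x: samples x loci; w: per-sample weights (sum > 0)."""
    wsum = w.sum()
    mu = (w[:, None] * x).sum(axis=0) / wsum
    var = (w[:, None] * (x - mu[None, :]) ** 2).sum(axis=0) / wsum
    var = np.maximum(var, _VAR_FLOOR)
    mu = np.clip(mu, _CLAMP, 1 - _CLAMP)
    # precision from mean/variance, bounded so densities stay finite
    phi = np.clip(mu * (1 - mu) / var - 1.0, 1e-2, 1e4)
    a = np.clip(mu * phi, _SHAPE_MIN, _SHAPE_MAX)
    b = np.clip((1 - mu) * phi, _SHAPE_MIN, _SHAPE_MAX)
    return a, b


def _loglik_per_sample(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return stats.beta.logpdf(x, a[None, :], b[None, :]).sum(axis=1)


def _two_means_split(x: np.ndarray, ids: list) -> np.ndarray:
    """Deterministic Lloyd 2-means on profiles, seeded at the min/max
    mean-beta samples (ties by lexicographic sample ID). Returns a boolean
    array marking the second cluster."""
    means = x.mean(axis=1)

    def extreme(selector):
        target = selector(means)
        cand = [i for i in range(len(ids)) if means[i] == target]
        return min(cand, key=lambda i: ids[i])

    lo, hi = extreme(np.min), extreme(np.max)
    if lo == hi:
        return np.zeros(len(ids), dtype=bool)
    centroids = np.stack([x[lo], x[hi]])
    assign = np.zeros(len(ids), dtype=int)
    for _ in range(50):
        d = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new = np.where(d[:, 1] < d[:, 0], 1, 0)
        if (new == assign).all():
            break
        assign = new
        for k in (0, 1):
            if (assign == k).any():
                centroids[k] = x[assign == k].mean(axis=0)
    return assign.astype(bool)


@dataclass
class _EMResult:
    weights: np.ndarray  # class priors
    shapes: list  # [(a, b)] per class
    resp: np.ndarray  # samples x 2 responsibilities
    loglik: float
    converged: bool
    n_iter: int


def _em_two_class(
    x: np.ndarray, init_second: np.ndarray, max_iter: int, tol: float
) -> _EMResult | None:
    n = x.shape[0]
    resp = np.zeros((n, 2))
    resp[:, 1] = init_second.astype(float)
    resp[:, 0] = 1.0 - resp[:, 1]
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wk = resp.sum(axis=0)
        if (wk < 1e-8).any():
            return None  # a class collapsed
        pi = wk / n
        shapes = [_mom_shapes(x, resp[:, k]) for k in (0, 1)]
        log_r = np.stack(
            [np.log(pi[k]) + _loglik_per_sample(x, *shapes[k]) for k in (0, 1)],
            axis=1,
        )
        ll = float(logsumexp(log_r, axis=1).sum())
        resp = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return _EMResult(pi, shapes, resp, ll_prev, converged, it)


@dataclass
class ClusterNode:
    node_id: str
    members: list  # sample IDs, sorted
    shapes: tuple | None = None  # own one-class (a, b) per locus
    loglik: float = np.nan
    split_accepted: bool = False
    children: list = field(default_factory=list)
    warning: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.split_accepted


@dataclass
class ClusterTree:
    root: ClusterNode
    locus_ids: list
    params: dict

    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    def assignments(self) -> pd.Series:
        """Hard leaf membership per sample (leaves partition the samples)."""
        data = {}
        for leaf in self.leaves():
            for s in leaf.members:
                data[s] = leaf.node_id
        return pd.Series(data, name="cluster").sort_index()


class RPMMClusterer:
    """Recursively partitioned beta-mixture model clusterer.

    Parameters
    ----------
    max_depth : maximum number of accepted split levels below the root.
    min_leaf : minimum hard members per child for a split to be accepted.
    max_iter, tol : EM iteration cap and absolute log-likelihood tolerance.
    """

    def __init__(self, max_depth: int = 5, min_leaf: int = 3, max_iter: int = 200, tol: float = 1e-6):
        if max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, betas: pd.DataFrame) -> ClusterTree:
        """Cluster samples (rows) over a locus panel (columns)."""
        vals = betas.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise IngestError("beta matrix contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise IngestError("beta values must lie in [0,1]")
        if betas.shape[0] < 2 * self.min_leaf:
            raise DegenerateDataError(
                f"need >= {2 * self.min_leaf} samples, got {betas.shape[0]}"
            )
        x_all = np.clip(vals, _CLAMP, 1 - _CLAMP)
        ids_all = list(betas.index)

        root = self._build("r", x_all, ids_all, depth=0)
        return ClusterTree(
            root=root,
            locus_ids=list(betas.columns),
            params={
                "max_depth": self.max_depth,
                "min_leaf": self.min_leaf,
                "max_iter": self.max_iter,
                "tol": self.tol,
            },
        )

    def _build(self, node_id: str, x: np.ndarray, ids: list, depth: int) -> ClusterNode:
        order = sorted(range(len(ids)), key=lambda i: ids[i])
        x = x[order]
        ids = [ids[i] for i in order]
        n, L = x.shape

        a1, b1 = _mom_shapes(x, np.ones(n))
        ll1 = float(_loglik_per_sample(x, a1, b1).sum())
        node = ClusterNode(node_id=node_id, members=ids, shapes=(a1, b1), loglik=ll1)

        if depth >= self.max_depth or n < 2 * self.min_leaf:
            return node

        init = _two_means_split(x, ids)
        if not init.any() or init.all():
            return node
        em = _em_two_class(x, init, self.max_iter, self.tol)
        if em is None:
            node.warning = f"EM degenerate at node {node_id}; retained unsplit"
            logger.warning(node.warning)
            return node
        if not em.converged:
            node.warning = f"EM did not converge at node {node_id}; retained unsplit"
            logger.warning(node.warning)
            return node

        # BIC: one class has 2L shape params; two classes 4L shapes + 1 mixing
        bic1 = -2 * ll1 + (2 * L) * np.log(n)
        bic2 = -2 * em.loglik + (4 * L + 1) * np.log(n)
        if bic2 >= bic1:
            return node

        hard = em.resp[:, 1] > 0.5
        if hard.sum() < self.min_leaf or (~hard).sum() < self.min_leaf:
            return node

        node.split_accepted = True
        for k, mask in enumerate((~hard, hard)):
            child = self._build(
                f"{node_id}{'LR'[k]}",
                x[mask],
                [ids[i] for i in np.flatnonzero(mask)],
                depth + 1,
            )
            node.children.append(child)
        return node


def rpmm_cluster(
    betas: pd.DataFrame, max_depth: int = 5, min_leaf: int = 3,
    max_iter: int = 200, tol: float = 1e-6,
) -> ClusterTree:
    """Functional wrapper: cluster a samples x loci beta matrix."""
    return RPMMClusterer(max_depth, min_leaf, max_iter, tol).fit(betas)
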