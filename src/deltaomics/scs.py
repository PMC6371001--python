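"""Spectral consensus strategy for network reconstruction.

The reconstruction problem over the reduced variable set is decomposed into
overlapping low-dimensional subproblems: a pairwise mutual-information
relevance graph is built, the symmetric normalized Laplacian of that weighted
graph is eigendecomposed, and each retained low-eigenvalue eigenvector defines
a (non-exclusive) subset of likely co-dependent variables.  Each subset is
reconstructed independently by several engines spanning the main method
families (shrinkage Gaussian-graphical, information-theoretic with
data-processing-inequality pruning, constraint-based skeleton search), and
edges enter the consensus when at least ``quorum`` engines report them.
Sub-graphs are merged over shared nodes; a pair evaluated in several subsets
takes its maximum vote.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator
from sklearn.covariance import LedoitWolf

from .networks import ConsensusNetwork

logger = logging.getLogger("deltaomics")

ENGINES = ("shrink_pcor", "mi_dpi", "pc_skeleton")


@dataclass
class RelevanceMatrix:
    """Symmetric pairwise mutual-information matrix (nats), zero diagonal."""

    values: np.ndarray
    variables: list
    estimator: str = "gaussian_copula"

    @property
    def shape(self):
        return self.values.shape


@dataclass
class EigenSubset:
    """Variables selected by one Laplacian eigenvector."""

    index: int
    members: list
    eigenvalue: float


# ---------------------------------------------------------------------------
# relevance matrix
# ---------------------------------------------------------------------------

def _spearman_matrix(data: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(rankdata, 0, data)
    return np.corrcoef(ranks, rowvar=False)


def mutual_information_matrix(data, variables=None,
                              estimator: str = "gaussian_copula",
                              n_bins: int | None = None) -> RelevanceMatrix:
    """Pairwise mutual information between variables (nats).

    Default is the Gaussian-copula estimator: the Spearman correlation is
    mapped to the Gaussian-copula correlation ``rho_g = 2 sin(pi rho_s / 6)``
    and ``MI = -1/2 ln(1 - rho_g^2)``, capped at ``ln(n)``.  It captures any
    monotone relationship and is far less biased than histogram plug-ins at
    small n.  ``estimator="binning"`` gives the equal-frequency plug-in
    alternative.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.any(data.std(axis=0) == 0):
        j = int(np.flatnonzero(data.std(axis=0) == 0)[0])
        name = variables[j] if variables is not None else j
        raise ValueError(f"constant column {name!r}; filter it upstream")
    cap = np.log(n)
    if estimator == "gaussian_copula":
        rho_s = np.clip(_spearman_matrix(data), -1.0, 1.0)
        rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)
        with np.errstate(divide="ignore"):
            mi = -0.5 * np.log1p(-np.clip(rho_g ** 2, 0.0, 1.0))
        mi = np.minimum(mi, cap)
    elif estimator == "binning":
        b = n_bins or max(2, int(np.floor(np.sqrt(n / 5))) + 1)
        binned = np.floor(
            rankdata(data, axis=0, method="ordinal") * b / (n + 1)).astype(int)
        mi = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                joint = np.zeros((b, b))
                np.add.at(joint, (binned[:, i], binned[:, j]), 1.0)
                joint /= n
                pi_, pj_ = joint.sum(1), joint.sum(0)
                nzm = joint > 0
                mi[i, j] = mi[j, i] = np.sum(
                    joint[nzm] * np.log(joint[nzm]
                                        / np.outer(pi_, pj_)[nzm]))
        mi = np.minimum(np.maximum(mi, 0.0), cap)
    else:
        raise ValueError(f"unknown MI estimator {estimator!r}")
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)
    if variables is None:
        variables = list(range(p))
    return RelevanceMatrix(values=mi, variables=list(variables),
                           estimator=estimator)


# ---------------------------------------------------------------------------
# spectral subsets
# ---------------------------------------------------------------------------

def _connected_components(W: np.ndarray) -> list:
    p = W.shape[0]
    seen = np.zeros(p, bool)
    comps = []
    for start in range(p):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(W[i] > 0):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def spectral_subsets(rel: RelevanceMatrix, eigvec_fraction: float = 0.14,
                     coord_threshold: float = 0.03,
                     min_subset: int = 3) -> list:
    """Overlapping variable subsets from low Laplacian eigenvectors.

    Per connected component of the MI-weighted graph: build the symmetric
    normalized Laplacian, take the ``ceil(eigvec_fraction * m)`` eigenvectors
    of smallest eigenvalue (excluding the trivial constant one), and select
    per eigenvector the variables whose |coordinate| is at least
    ``coord_threshold``.  Subsets smaller than ``min_subset`` are merged into
    the subset of their strongest-MI neighbour, and every variable is
    guaranteed to be covered by at least one subset.
    """
    if not 0 < eigvec_fraction <= 1:
        raise ValueError("eigvec_fraction must be in (0, 1]")
    if coord_threshold < 0:
        raise ValueError("coord_threshold must be >= 0")
    W = rel.values
    p = W.shape[0]
    comps = _connected_components(W)
    if len(comps) > 1:
        logger.info("relevance graph has %d connected components; "
                    "processing independently", len(comps))
    raw = []
    for comp in comps:
        m = len(comp)
        if m == 1:
            raw.append((comp, 0.0))
            continue
        sub = W[np.ix_(comp, comp)]
        d = sub.sum(axis=0)
        dinv = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
        L = np.eye(m) - dinv[:, None] * sub * dinv[None, :]
        evals, evecs = np.linalg.eigh(L)
        k = min(int(np.ceil(eigvec_fraction * m)), m - 1)
        for h in range(1, k + 1):       # skip the trivial lowest eigenvector
            coords = evecs[:, h]
            sel = {comp[i] for i in np.flatnonzero(
                np.abs(coords) >= coord_threshold)}
            # Markov-blanket closure: a subset must not omit the variable
            # most strongly dependent with a member, or the per-subset
            # engines cannot explain away indirect dependencies.
            for v in list(sel):
                sel.add(int(np.argmax(W[v])))
            raw.append((sorted(sel), float(evals[h])))

    # merge undersized subsets into the strongest-MI neighbour's subset
    subsets = [list(s) for s, _ in raw]
    eigenvalues = [ev for _, ev in raw]
    member_of = {}
    for si, s in enumerate(subsets):
        for v in s:
            member_of.setdefault(v, si)
    for si, s in enumerate(subsets):
        if 0 < len(s) < min_subset:
            for v in s:
                nb_order = np.argsort(-W[v])
                for nb in nb_order:
                    tj = member_of.get(int(nb))
                    if tj is not None and len(subsets[tj]) >= min_subset:
                        if v not in subsets[tj]:
                            subsets[tj].append(v)
                        break
            subsets[si] = []
    # coverage guarantee
    covered = {v for s in subsets for v in s}
    big = [si for si, s in enumerate(subsets) if s]
    for v in range(p):
        if v not in covered:
            nb_order = np.argsort(-W[v])
            target = None
            for nb in nb_order:
                tj = member_of.get(int(nb))
                if tj is not None and subsets[tj]:
                    target = tj
                    break
            if target is None:
                target = max(big, key=lambda si: len(subsets[si]),
                             default=None)
            if target is None:
                subsets.append([v])
                eigenvalues.append(0.0)
            else:
                subsets[target].append(v)
    out = [EigenSubset(index=si, members=sorted(s), eigenvalue=eigenvalues[si])
           for si, s in enumerate(subsets) if s]
    # deduplicate identical member sets (overlapping eigenvectors often agree)
    seen, unique = set(), []
    for s in out:
        key = tuple(s.members)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


# ---------------------------------------------------------------------------
# reconstruction engines
# ---------------------------------------------------------------------------

def _fisher_p(r: np.ndarray, dof: float) -> np.ndarray:
    r = np.clip(r, -0.999999, 0.999999)
    z = np.abs(np.arctanh(r)) * np.sqrt(max(dof, 1.0))
    return 2.0 * norm.sf(z)


def _engine_shrink_pcor(Z: np.ndarray, alpha: float) -> set:
    """Shrinkage covariance -> partial correlations -> Fisher-z tests."""
    n, m = Z.shape
    lw = LedoitWolf(assume_centered=False).fit(Z)
    cov = lw.covariance_
    eps = 1e-8 * np.trace(cov) / m
    for _ in range(12):
        try:
            prec = np.linalg.inv(cov + eps * np.eye(m) - 0.0)
            break
        except np.linalg.LinAlgError:
            eps *= 10.0
            warnings.warn("singular shrinkage covariance; increasing ridge")
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    dof = n - (m - 2) - 3
    if dof < 4:
        warnings.warn("shrink_pcor: conditioning set larger than sample; "
                      "degrees of freedom clamped")
        dof = 4
    pvals = _fisher_p(pcor, dof)
    ii, jj = np.where(np.triu(pvals < alpha, k=1))
    return {frozenset((int(i), int(j))) for i, j in zip(ii, jj)}


def dpi_prune(W: np.ndarray, tol: float = 1.0) -> np.ndarray:
    """Data-processing-inequality pruning of a weighted adjacency matrix.

    For every triangle, the strictly weakest edge is dropped when it is below
    ``tol`` times the smaller of the other two; all removals are decided on
    the input graph and applied at once.  Returns the pruned boolean
    adjacency.
    """
    A = W > 0
    remove = np.zeros_like(A)
    for k in range(W.shape[0]):
        wk = W[:, k]
        both = np.minimum.outer(wk, wk)          # min(W_ik, W_jk)
        tri = A & A[:, k][:, None] & A[:, k][None, :]
        remove |= tri & (W < tol * both) & A
    A = A & ~(remove | remove.T)
    np.fill_diagonal(A, False)
    return A


def _engine_mi_dpi(Z: np.ndarray, alpha: float, tol: float = 1.0) -> set:
    """Significant-MI graph pruned by the data-processing inequality.

    Edges start from pairs with a significant Spearman association at level
    ``alpha``; then, in every triangle, the weakest MI edge is dropped when it
    is strictly below ``tol`` times the smaller of the other two.
    """
    n, _m = Z.shape
    rel = mutual_information_matrix(Z).values
    rho_s = np.clip(_spearman_matrix(Z), -1, 1)
    pvals = _fisher_p(rho_s, n - 3)
    sig = pvals < alpha
    np.fill_diagonal(sig, False)
    A = dpi_prune(np.where(sig, rel, 0.0), tol=tol)
    ii, jj = np.where(np.triu(A, k=1))
    return {frozenset((int(i), int(j))) for i, j in zip(ii, jj)}


def _engine_pc_skeleton(Z: np.ndarray, alpha: float) -> set:
    """Constraint-based skeleton with marginal and order-1 Fisher-z tests.

    Conditioning candidates are restricted to the current neighbourhood of
    either endpoint (standard PC restriction).
    """
    n, m = Z.shape
    r = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(r, 0.0)
    A = _fisher_p(r, n - 3) < alpha
    np.fill_diagonal(A, False)
    edges = [(i, j) for i in range(m) for j in range(i + 1, m) if A[i, j]]
    for i, j in edges:
        if not A[i, j]:
            continue
        ks = np.flatnonzero(A[i] | A[j])
        ks = ks[(ks != i) & (ks != j)]
        if ks.size == 0:
            continue
        rik, rjk = r[i, ks], r[j, ks]
        denom = np.sqrt((1 - rik ** 2) * (1 - rjk ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            pcor = (r[i, j] - rik * rjk) / denom
        pcor = np.nan_to_num(pcor, nan=1.0)
        pv = _fisher_p(pcor, n - 4)
        if np.any(pv >= alpha):
            A[i, j] = A[j, i] = False
    ii, jj = np.where(np.triu(A, k=1))
    return {frozenset((int(i), int(j))) for i, j in zip(ii, jj)}


_ENGINE_FUNCS = {
    "shrink_pcor": _engine_shrink_pcor,
    "mi_dpi": _engine_mi_dpi,
    "pc_skeleton": _engine_pc_skeleton,
}


def reconstruct_subset(data, engine: str, alpha: float = 0.05) -> set:
    """Reconstruct an undirected edge set over one variable subset.

    ``data`` is the n x m sub-matrix (m >= 3); returns a set of frozenset
    column-index pairs.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 3:
        raise ValueError("subset size must be >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if engine not in _ENGINE_FUNCS:
        raise ValueError(f"unknown engine {engine!r}; expected {ENGINES}")
    Z = (data - data.mean(0)) / data.std(0, ddof=1)
    return _ENGINE_FUNCS[engine](Z, alpha)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_merge(per_subset_edges, quorum: int, data, variables,
                    node_classes=None, engines=ENGINES) -> ConsensusNetwork:
    """Merge per-subset, per-engine edge sets by consensual voting.

    ``per_subset_edges`` maps subset -> engine -> set of frozenset variable-id
    pairs.  Within a subset an edge's votes = number of engines reporting it;
    it is kept when votes >= quorum; across subsets the maximum vote wins.
    The edge sign is the sign of the Spearman correlation of the pair.
    """
    if not 1 <= quorum <= len(engines):
        raise ValueError("quorum must lie between 1 and the engine count")
    votes = {}
    for _subset, by_engine in per_subset_edges.items():
        local = {}
        for _eng, eset in by_engine.items():
            for e in eset:
                local[e] = local.get(e, 0) + 1
        for e, v in local.items():
            if v >= quorum:
                votes[e] = max(votes.get(e, 0), v)
    data = np.asarray(data, dtype=float)
    col = {v: i for i, v in enumerate(variables)}
    rho = _spearman_matrix(data) if data.size else np.zeros((0, 0))
    edges = []
    for e, v in sorted(votes.items(), key=lambda kv: tuple(sorted(kv[0]))):
        a, b = sorted(e)
        r = rho[col[a], col[b]]
        sign = 0 if r == 0 else (1 if r > 0 else -1)
        edges.append((a, b, v, sign))
    node_classes = node_classes or {}
    nodes = {v: node_classes.get(v, "") for v in variables}
    return ConsensusNetwork(nodes=nodes, edges=edges,
                            engines=tuple(engines), quorum=quorum)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SpectralConsensusNetwork(BaseEstimator):
    """Spectral-consensus network reconstruction as an estimator.

    Parameters mirror the pipeline configuration: ``eigvec_fraction`` (share
    of Laplacian eigenvectors retained), ``coord_threshold`` (eigenvector
    coordinate cut-off controlling subset size), ``quorum`` (minimum engine
    votes), ``engines``, ``alpha`` (per-engine test level), ``mi_estimator``.

    After :meth:`fit`: ``relevance_`` (mutual-information matrix),
    ``subsets_`` (eigen subsets), ``network_`` (:class:`ConsensusNetwork`)
    and ``graph_`` (networkx view).  Deterministic given the data.
    """

    def __init__(self, eigvec_fraction: float = 0.14,
                 coord_threshold: float = 0.03, quorum: int = 2,
                 engines: tuple = ENGINES, alpha: float = 0.05,
                 mi_estimator: str = "gaussian_copula"):
        self.eigvec_fraction = eigvec_fraction
        self.coord_threshold = coord_threshold
        self.quorum = quorum
        self.engines = engines
        self.alpha = alpha
        self.mi_estimator = mi_estimator

    def fit(self, X, y=None, variables=None, node_classes=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p < 5:
            raise ValueError("need a reduced variable set of >= 5 variables")
        if variables is None:
            variables = list(range(p))
        self.relevance_ = mutual_information_matrix(
            X, variables, estimator=self.mi_estimator)
        self.subsets_ = spectral_subsets(
            self.relevance_, self.eigvec_fraction, self.coord_threshold)
        per_subset = {}
        for s in self.subsets_:
            sub = X[:, s.members]
            by_engine = {}
            for eng in self.engines:
                try:
                    local = reconstruct_subset(sub, eng, self.alpha)
                except ValueError as exc:
                    logger.warning("engine %s on subset %d failed: %s",
                                   eng, s.index, exc)
                    continue
                by_engine[eng] = {
                    frozenset((variables[s.members[i]], variables[s.members[j]]))
                    for e in local for i, j in [sorted(e)]}
            per_subset[s.index] = by_engine
        self.network_ = consensus_merge(
            per_subset, self.quorum, X, list(variables),
            node_classes=node_classes, engines=tuple(self.engines))
        self.graph_ = self.network_.to_graph()
        return self


def run_scs(data, variables=None, node_classes=None, eigvec_fraction=0.14,
            coord_threshold=0.03, quorum=2, engines=ENGINES,
            alpha=0.05) -> ConsensusNetwork:
    """One-call spectral consensus reconstruction over a reduced data matrix."""
    est = SpectralConsensusNetwork(
        eigvec_fraction=eigvec_fraction, coord_threshold=coord_threshold,
        quorum=quorum, engines=engines, alpha=alpha)
    est.fit(data, variables=variables, node_classes=node_classes)
    return est.network_
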