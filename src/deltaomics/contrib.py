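"""Per-class contribution to an IS target via cross-validated linear
regression and normalized inverse MSE.

For each target (a change in an IS index) the predictor pool is the main
cluster (largest connected component) of the consensus network, minus the IS
markers themselves and minus serum features annotated as glucose; predictors
are grouped by block class; each class's 10-fold cross-validated mean squared
error is computed and the class's contribution share is its normalized
inverse MSE (the smaller the held-out error, the larger the inferred impact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger("deltaomics")


@dataclass
class ContributionReport:
    """Per-class CV MSE and normalized inverse-MSE shares for one target."""

    target: str
    class_members: dict = field(default_factory=dict)  # class -> [features]
    mse: dict = field(default_factory=dict)            # class -> mean CV MSE
    shares: dict = field(default_factory=dict)         # class -> share in [0,1]
    folds: int = 10
    seed: int = 0
    excluded: list = field(default_factory=list)

    def pie_table(self) -> list:
        """Pie-chart-ready (class, share) rows, largest first."""
        return sorted(self.shares.items(), key=lambda kv: -kv[1])


def _fold_indices(n: int, folds: int, seed: int) -> list:
    """Deterministic, as-equal-as-possible fold assignment from the seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cv_mse(X, y, folds: int = 10, seed: int = 0) -> float:
    """Mean held-out squared error of a linear fit of y on X.

    Ordinary least squares with intercept; when the predictor count reaches
    the training size the fit is ridge-stabilized with a negligible penalty
    ``lambda = 1e-6 * p``.  The fold assignment is a seeded permutation;
    identical seeds give identical results.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(y).size != 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sizes differ")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    if np.var(y) == 0:
        raise ValueError("zero-variance target")
    errors = []
    for test in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test)
        Xtr = np.column_stack([np.ones(train.size), X[train]])
        Xte = np.column_stack([np.ones(test.size), X[test]])
        if p >= train.size:
            lam = 1e-6 * p
            P = np.eye(p + 1)
            P[0, 0] = 0.0      # do not penalize the intercept
            beta = np.linalg.solve(Xtr.T @ Xtr + lam * P, Xtr.T @ y[train])
        else:
            beta, *_ = np.linalg.lstsq(Xtr, y[train], rcond=None)
        resid = y[test] - Xte @ beta
        errors.append(float(np.mean(resid ** 2)))
    return float(np.mean(errors))


def contribution_shares(class_mses: dict) -> dict:
    """share_c = (1 / MSE_c) / sum_c' (1 / MSE_c')."""
    if not class_mses:
        return {}
    if any(m <= 0 for m in class_mses.values()):
        raise ValueError("every MSE must be > 0 (degenerate perfect fit "
                         "cannot be normalized)")
    inv = {c: 1.0 / m for c, m in class_mses.items()}
    total = sum(inv.values())
    return {c: v / total for c, v in inv.items()}


def main_cluster(graph: nx.Graph) -> set:
    """Largest connected component by node count; ties by edge count."""
    comps = list(nx.connected_components(graph))
    if not comps:
        return set()
    return max(comps, key=lambda c: (len(c),
                                     graph.subgraph(c).number_of_edges()))


class ClassContribution(BaseEstimator):
    """Inverse-MSE contribution decomposition as an estimator.

    ``fit(X, y)`` takes the predictor matrix with ``feature_classes`` (one
    class label per column) and the target vector; fitted attributes are
    ``mse_per_class_`` and ``shares_`` (normalized inverse MSE, summing to 1).
    """

    def __init__(self, folds: int = 10, seed: int = 0):
        self.folds = folds
        self.seed = seed

    def fit(self, X, y, feature_classes=None):
        X = np.asarray(X, dtype=float)
        if feature_classes is None:
            feature_classes = ["all"] * X.shape[1]
        feature_classes = np.asarray(feature_classes)
        self.mse_per_class_ = {}
        for cls in dict.fromkeys(feature_classes):
            cols = np.flatnonzero(feature_classes == cls)
            self.mse_per_class_[cls] = cv_mse(
                X[:, cols], y, folds=self.folds, seed=self.seed)
        self.shares_ = contribution_shares(self.mse_per_class_)
        return self


def run_contribution(network, blocks, targets=None, folds: int = 10,
                     seed: int = 0) -> list:
    """Contribution reports for each IS target from the consensus network.

    The predictor pool is the main cluster of ``network`` minus features
    annotated as IS markers and minus serum features annotated as glucose;
    predictors are grouped by block class.  ``blocks`` supplies the delta
    values; ``targets`` defaults to the revised QUICKI and HOMA-B deltas.
    """
    targets = list(targets) if targets is not None else ["revQUICKI", "HOMA2_B"]
    frames = {b.name: b.to_frame() for b in blocks}
    feature_info = {}
    for b in blocks:
        for f in b.features:
            feature_info[f] = (b.name, b.block_class,
                               b.annotations.get(f, ""))
    g = network.to_graph() if not isinstance(network, nx.Graph) else network
    cluster = main_cluster(g)
    if len(cluster) < 3:
        raise ValueError("consensus network has no usable main cluster")
    excluded = []
    pool = []
    for f in sorted(cluster):
        blk, cls, note = feature_info.get(f, (None, None, ""))
        if blk is None:
            continue
        note_l = note.lower()
        if "is marker" in note_l or f in targets:
            excluded.append(f)
        elif cls == "serum_metab" and "glucose" in note_l:
            excluded.append(f)
        else:
            pool.append((f, blk, cls))
    reports = []
    for target in targets:
        t_blk = feature_info.get(target, (None,))[0]
        if t_blk is None:
            logger.warning("target %s not found in any block; skipped", target)
            continue
        y = frames[t_blk][target].to_numpy()
        by_class = {}
        for f, blk, cls in pool:
            by_class.setdefault(cls, []).append((f, blk))
        mses, members = {}, {}
        for cls, feats in sorted(by_class.items()):
            if not feats:
                logger.warning("class %s has no members; omitted", cls)
                continue
            Xc = np.column_stack([frames[blk][f].to_numpy()
                                  for f, blk in feats])
            mses[cls] = cv_mse(Xc, y, folds=folds, seed=seed)
            members[cls] = [f for f, _ in feats]
        reports.append(ContributionReport(
            target=target, class_members=members, mse=mses,
            shares=contribution_shares(mses), folds=folds, seed=seed,
            excluded=excluded))
    return reports
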