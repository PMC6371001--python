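"""Two-block PLS in canonical mode and thresholded association networks.

Canonical-mode PLS treats the two blocks as exchangeable: each component
maximizes the covariance between latent variates (linear combinations of each
block's centered, unit-variance-scaled columns), and both blocks are deflated
symmetrically on their own variates.  Feature-pair association coefficients
are derived from feature-variate correlations and thresholded into bipartite
networks.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .networks import BipartiteAssociationNetwork

logger = logging.getLogger("deltaomics")


def _center_scale(M: np.ndarray):
    mean = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    ok = scale > 0
    safe = np.where(ok, scale, 1.0)
    return (M - mean) / safe, mean, safe, ok


def _fix_sign(u: np.ndarray) -> float:
    """Sign convention: first nonzero element of u forced positive."""
    nz = np.flatnonzero(np.abs(u) > 1e-12)
    if nz.size and u[nz[0]] < 0:
        return -1.0
    return 1.0


class CanonicalPLS(BaseEstimator):
    """Two-block partial least squares with canonical (symmetric) deflation.

    Components are extracted by NIPALS power alternation on the residual
    matrices; after each component, X is deflated by regression on its own
    variate and Y on its own variate (no predictor/response asymmetry).

    Parameters
    ----------
    n_components : int, default=2
        Number of components H.
    tol : float, default=1e-12
        Convergence threshold on the change of the x-weight vector.
    max_iter : int, default=500
        Maximum NIPALS iterations per component.

    Attributes
    ----------
    x_weights_, y_weights_ : ndarray of shape (p, H) / (q, H)
        Unit-norm weight vectors u_h, v_h.
    x_scores_, y_scores_ : ndarray of shape (n, H)
        Latent variates (xi_h, omega_h).
    x_loadings_, y_loadings_ : ndarray
        Regression loadings of the (deflated) blocks on their variates.
    n_iter_ : list of int
        NIPALS iterations used per component.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-12,
                 max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of subjects")
        n, p = X.shape
        q = Y.shape[1]
        H = self.n_components
        if H > min(n - 1, p, q):
            raise ValueError(
                f"n_components={H} exceeds min(n-1, p, q)="
                f"{min(n - 1, p, q)}")

        Xc, self.x_mean_, self.x_scale_, self._x_ok = _center_scale(X)
        Yc, self.y_mean_, self.y_scale_, self._y_ok = _center_scale(Y)
        self._X_centered = Xc.copy()
        self._Y_centered = Yc.copy()

        Xr, Yr = Xc.copy(), Yc.copy()
        U = np.zeros((p, H))
        V = np.zeros((q, H))
        Xi = np.zeros((n, H))
        Om = np.zeros((n, H))
        Pl = np.zeros((p, H))
        Ql = np.zeros((q, H))
        self.n_iter_ = []

        for h in range(H):
            omega = Yr[:, np.argmax(Yr.var(axis=0))].copy()
            if not omega.any():
                omega = Yr[:, 0] + 1e-12
            u = np.zeros(p)
            for it in range(1, self.max_iter + 1):
                u_new = Xr.T @ omega
                u_new /= np.linalg.norm(u_new)
                xi = Xr @ u_new
                v = Yr.T @ xi
                v /= np.linalg.norm(v)
                omega = Yr @ v
                if np.linalg.norm(u_new - u) < self.tol:
                    u = u_new
                    break
                u = u_new
            else:
                it = self.max_iter
                warnings.warn(
                    f"NIPALS did not converge for component {h + 1}; "
                    "returning best iterate")
            self.n_iter_.append(it)
            sgn = _fix_sign(u)
            u, v, xi, omega = sgn * u, sgn * v, sgn * xi, sgn * omega
            # canonical (symmetric) deflation
            pl = Xr.T @ xi / (xi @ xi)
            ql = Yr.T @ omega / (omega @ omega)
            Xr = Xr - np.outer(xi, pl)
            Yr = Yr - np.outer(omega, ql)
            U[:, h], V[:, h] = u, v
            Xi[:, h], Om[:, h] = xi, omega
            Pl[:, h], Ql[:, h] = pl, ql

        self.x_weights_, self.y_weights_ = U, V
        self.x_scores_, self.y_scores_ = Xi, Om
        self.x_loadings_, self.y_loadings_ = Pl, Ql
        return self

    def transform(self, X, Y=None):
        """Project (new) data onto the x-weights (and y-weights if Y given)."""
        Xc = (np.asarray(X, float) - self.x_mean_) / self.x_scale_
        xs = Xc @ self.x_weights_
        if Y is None:
            return xs
        Yc = (np.asarray(Y, float) - self.y_mean_) / self.y_scale_
        return xs, Yc @ self.y_weights_

    def similarity_matrix(self, variates: str = "x") -> np.ndarray:
        """Association coefficients: sim(i, j) = sum_h cor(x_i, t_h) cor(y_j, t_h).

        With ``variates="x"`` the X-block variates xi_h are used for both
        sides (sign-preserving; reduces to the Pearson correlation when
        p = q = 1; bounded by 1 since the variates are orthogonal).  With
        ``variates="mean"`` the averaged variates (xi_h + omega_h)/2 are used.
        """
        if variates not in ("x", "mean"):
            raise ValueError("variates must be 'x' or 'mean'")
        T = self.x_scores_ if variates == "x" \
            else 0.5 * (self.x_scores_ + self.y_scores_)
        sim = np.zeros((self.x_weights_.shape[0], self.y_weights_.shape[0]))
        for h in range(T.shape[1]):
            t = T[:, h]
            cx = _safe_cor(self._X_centered, t)
            cy = _safe_cor(self._Y_centered, t)
            sim += np.outer(cx, cy)
        bad_x = ~self._x_ok
        bad_y = ~self._y_ok
        if bad_x.any() or bad_y.any():
            warnings.warn("zero-variance columns set to zero similarity")
            sim[bad_x, :] = 0.0
            sim[:, bad_y] = 0.0
        return np.clip(sim, -1.0, 1.0)


def _safe_cor(M: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Correlation of each (centered) column of M with the centered vector t."""
    tc = t - t.mean()
    denom = np.linalg.norm(M, axis=0) * np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (M.T @ tc) / denom
    return np.nan_to_num(c)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def fit_pls_canonical(X_block, Y_block, n_components: int = 2) -> CanonicalPLS:
    """Fit canonical-mode PLS between two delta blocks (aligned subjects)."""
    if X_block.subjects != Y_block.subjects:
        raise ValueError("blocks must share the same subjects in the same order")
    model = CanonicalPLS(n_components=n_components)
    model.fit(X_block.values, Y_block.values)
    return model


def similarity_matrix(model: CanonicalPLS, variates: str = "x") -> np.ndarray:
    return model.similarity_matrix(variates=variates)


def prevalence_filter(block, min_subjects: int = 2):
    """Keep features non-zero in at least ``min_subjects`` subjects.

    Intended for sparse metagenomic-species blocks before model fitting.
    """
    nz = (block.values != 0).sum(axis=0)
    keep = [f for f, c in zip(block.features, nz) if c >= min_subjects]
    if len(keep) < block.n_features:
        logger.info("prevalence filter on %s: %d -> %d features",
                    block.name, block.n_features, len(keep))
    return block.subset_features(keep)


def threshold_network(sim: np.ndarray, tau: float, x_features, y_features,
                      x_class: str = "", y_class: str = "",
                      pair: str = "") -> BipartiteAssociationNetwork:
    """Keep feature pairs with ``|sim| >= tau`` (boundary ties are kept)."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    ii, jj = np.where(np.abs(sim) >= tau)
    edges = [(x_features[i], y_features[j], float(sim[i, j]))
             for i, j in zip(ii, jj)]
    node_classes = {}
    for i, j in zip(ii, jj):
        node_classes[x_features[i]] = x_class
        node_classes[y_features[j]] = y_class
    return BipartiteAssociationNetwork(
        pair=pair or f"{x_class}:{y_class}", threshold=tau,
        edges=edges, node_classes=node_classes)


def run_all_pairs(blocks, config) -> list:
    """Fit PLS and threshold a network for every configured analysis pair.

    Per-pair errors are logged and the remaining pairs continue; the returned
    list contains one :class:`BipartiteAssociationNetwork` per successful pair.
    """
    by_name = {b.name: b for b in blocks}
    networks = []
    failures = []
    for a, b, tau in config.pairs:
        try:
            A, B = by_name[a], by_name[b]
            if A.block_class == "mgs":
                A = prevalence_filter(A, config.mgs_prevalence_min)
            if B.block_class == "mgs":
                B = prevalence_filter(B, config.mgs_prevalence_min)
            model = fit_pls_canonical(A, B, config.n_components)
            sim = model.similarity_matrix(variates=config.similarity_variates)
            net = threshold_network(sim, tau, A.features, B.features,
                                    A.block_class, B.block_class,
                                    pair=f"{a}:{b}")
            networks.append(net)
            logger.info("pair %s:%s tau=%.2f -> %d edges", a, b, tau,
                        net.n_edges)
        except Exception as exc:       # noqa: BLE001 - per-pair isolation
            failures.append((a, b, str(exc)))
            logger.error("pair %s:%s failed: %s", a, b, exc)
    if failures:
        logger.warning("%d of %d pairs failed: %s", len(failures),
                       len(config.pairs), failures)
    return networks
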