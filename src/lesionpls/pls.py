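"""Partial least squares regression (PLS2) with VIP scores.

The decomposition extracts latent variables (LVs) that maximize the
covariance between a predictor block X (region-level neuroimaging
features) and a response block Y (the four WAB-R subtest scores). Each
component's X-weight vector is the leading singular vector of the deflated
cross-covariance matrix X'Y; X is deflated by regression on the component
score (NIPALS in regression mode, X-deflation only — Y-deflation does not
change the extracted sequence because deflated X is orthogonal to earlier
scores, so predictions match both conventions).

Both blocks are column-centred and unit-variance scaled by default:
z-scoring is what makes VIP scores comparable across regions and across
modalities that mix physical units. Regression coefficients are computed
on the standardized scale and back-transformed to original units.

Variable importance in projection (VIP) summarizes each predictor's
contribution across components, weighted by the Y sum-of-squares each
component explains:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

so that sum_j VIP_j^2 = p (the mean squared VIP is exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "fit_plsr", "vip_scores", "y_loading_profile"]


@dataclass
class PLSModel:
    """Fitted PLS regression model.

    Weights ``W`` (p x A, unit norm), X-loadings ``P`` (p x A), Y-loadings
    ``Q`` (k x A), X-scores ``T`` (n x A); ``ssy`` holds per-component
    explained Y sum-of-squares on the standardized scale, ``cov_explained``
    per-component squared singular values of the deflated cross-covariance.
    """

    n_components: int
    W: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    y_mean: np.ndarray = field(repr=False)
    y_scale: np.ndarray = field(repr=False)
    ssy: np.ndarray = field(repr=False)
    cov_explained: np.ndarray = field(repr=False)
    ssx_total: float
    ssy_total: float
    cov_total: float
    constant_x_columns: list[int] = field(default_factory=list)

    # -- coefficients -----------------------------------------------------
    def coefficients_std(self, n_components: int | None = None) -> np.ndarray:
        """Standardized-scale regression coefficients (p x k) using the
        first ``n_components`` components."""
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        W, P, Q = self.W[:, :a], self.P[:, :a], self.Q[:, :a]
        # B = W (P'W)^{-1} Q'
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def coefficients(self, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Original-units coefficients (p x k) and intercept (k,)."""
        B_std = self.coefficients_std(n_components)
        B = B_std * (self.y_scale[None, :] / self.x_scale[:, None])
        intercept = self.y_mean - self.x_mean @ B
        return B, intercept

    def predict(self, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict responses (original units) for new subjects."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"feature count mismatch: model has {self.W.shape[0]}, input has {X_new.shape[1]}"
            )
        B, intercept = self.coefficients(n_components)
        return X_new @ B + intercept

    def explained_covariance(self) -> pd.DataFrame:
        """Per-component and cumulative explained fractions.

        Columns: fraction of X variance, of Y variance, and of X-Y
        covariance (squared-Frobenius of the cross-covariance captured by
        each component relative to the full cross-covariance).
        """
        tt = np.einsum("ij,ij->j", self.T, self.T)
        x_frac = tt * np.einsum("ij,ij->j", self.P, self.P) / self.ssx_total
        y_frac = self.ssy / self.ssy_total
        cov_frac = self.cov_explained / self.cov_total if self.cov_total > 0 else np.zeros_like(self.ssy)
        df = pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "x_variance": x_frac,
                "y_variance": y_frac,
                "covariance": np.minimum(cov_frac, 1.0),
            }
        )
        for col in ("x_variance", "y_variance", "covariance"):
            df[f"cumulative_{col}"] = df[col].cumsum().clip(upper=1.0)
        return df


def _standardize(M: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    constant = [int(j) for j in np.where(sd == 0)[0]]
    if scale:
        s = np.where(sd == 0, 1.0, sd)
    else:
        s = np.ones_like(sd)
    return (M - mean) / s, mean, s, constant


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    scale: bool = True,
) -> PLSModel:
    """Fit a PLS2 regression of Y on X.

    Parameters
    ----------
    X : (n, p) array
        Predictor block (subjects x features).
    Y : (n, k) array
        Response block; a 1-D array is treated as a single response.
    n_components : int
        Number of latent variables to extract; must satisfy
        ``1 <= n_components <= min(n - 1, p)``. Extraction stops early if
        the residual cross-covariance vanishes (rank exhausted).
    scale : bool
        Unit-variance scale both blocks (default). Constant columns are
        centred only and recorded in ``constant_x_columns``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"subject count mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    n, p = X.shape
    k = Y.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if not np.isfinite(X).all():
        bad = sorted(np.unique(np.where(~np.isfinite(X))[1]).tolist())
        raise ValueError(f"non-finite values in X columns {bad[:20]}")
    if not np.isfinite(Y).all():
        bad = sorted(np.unique(np.where(~np.isfinite(Y))[1]).tolist())
        raise ValueError(f"non-finite values in Y columns {bad}")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(f"n_components must be in [1, {a_max}] for n={n}, p={p}")

    Xs, x_mean, x_scale, const_x = _standardize(X, scale)
    Ys, y_mean, y_scale, _ = _standardize(Y, scale)
    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(Ys**2))
    cov_total = float(np.sum((Xs.T @ Ys) ** 2))

    Xd = Xs.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    cov = np.zeros(n_components)
    tol = 1e-12 * max(ssx_total, 1.0)
    a_used = 0
    for a in range(n_components):
        S = Xd.T @ Ys  # p x k cross-covariance of the deflated block
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] ** 2 <= tol:
            break
        w = U[:, 0]
        # deterministic sign: largest-magnitude entry positive
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p_a = Xd.T @ t / tt
        q_a = Ys.T @ t / tt
        Xd -= np.outer(t, p_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        ssy[a] = tt * float(q_a @ q_a)
        cov[a] = float(sv[0] ** 2)
        a_used += 1
    if a_used == 0:
        raise ValueError("no latent variable could be extracted (X or Y constant?)")
    return PLSModel(
        n_components=a_used,
        W=W[:, :a_used], P=P[:, :a_used], Q=Q[:, :a_used], T=T[:, :a_used],
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        ssy=ssy[:a_used], cov_explained=cov[:a_used],
        ssx_total=ssx_total, ssy_total=ssy_total, cov_total=cov_total,
        constant_x_columns=const_x,
    )


def vip_scores(model: PLSModel, n_components: int | None = None) -> np.ndarray:
    """Variable importance in projection over the first ``n_components`` LVs.

    Satisfies ``sum(VIP**2) == p`` exactly; raises if the components
    explain no Y sum-of-squares (constant responses).
    """
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    W = model.W[:, :a]
    ssy = model.ssy[:a]
    total = ssy.sum()
    if total <= 0:
        raise ValueError("components explain zero Y sum-of-squares; VIP undefined")
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    p = W.shape[0]
    return np.sqrt(p * (wn2 @ ssy) / total)


def y_loading_profile(model: PLSModel, n_components: int | None = None) -> np.ndarray:
    """Relative contribution of each response across retained components.

    Combines each response's Y-loading magnitudes across components,
    weighting components by the Y sum-of-squares they explain, then
    normalizes so the weights sum to 1 across responses. Used to rank
    responses by how strongly they load on the latent brain-behaviour
    decomposition.
    """
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    raw = np.abs(model.Q[:, :a]) @ model.ssy[:a]
    total = raw.sum()
    if total <= 0:
        raise ValueError("zero Y loading mass; profile undefined")
    return raw / total
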