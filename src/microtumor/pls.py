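"""Single-response NIPALS partial least squares with VIP and LOO validation.

This module implements PLS1 from first principles rather than delegating to
a library, because the downstream analyses depend on exact control of the
conventions: how X and y are scaled, how leave-one-out PRESS is computed
(with re-centering and re-scaling inside every fold, so no information leaks
from the held-out ROI), how the van der Voet sign-permutation test selects a
parsimonious component count, and how VIP scores are normalized.

Algorithm (per component a, on centered/scaled X and y):

    w_a = X'y / ||X'y||          (unit-norm weight)
    t_a = X w_a                  (score)
    p_a = X't_a / (t_a't_a)      (X loading)
    q_a = y't_a / (t_a't_a)      (y loading)
    X <- X - t_a p_a',  y <- y - q_a t_a   (deflation)

Regression coefficients on the standardized scale are
``b = W (P'W)^{-1} q``; scores are mutually orthogonal by construction.

VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ) with SS_a = q_a^2 t_a't_a,
so the mean of VIP^2 over predictors is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._base import BaseEstimator

_EPS = 1e-12


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return X, None


class NipalsPLS(BaseEstimator):
    """PLS1 regression estimator (NIPALS), scikit-learn style.

    Parameters
    ----------
    n_components : int
        Number of PLS components A; must satisfy 1 <= A <= min(n-1, p).
    scale : bool
        Center and unit-variance scale X columns and y before fitting
        (sample sd, ddof=1). Predictions are always returned on the
        original y scale.

    Fitted attributes
    -----------------
    x_weights_ (p, A), x_loadings_ (p, A), x_scores_ (n, A),
    y_loadings_ (A,), coef_ (p,) on the standardized scale,
    coef_original_ (p,) and intercept_ on the original scale,
    vip_ (p,), r2x_cum_ (A,), r2y_cum_ (A,),
    x_mean_, x_scale_, y_mean_, y_scale_, feature_names_in_.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "NipalsPLS":
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = Xm.shape
        if len(y) != n:
            raise ValueError(f"X has {n} rows but y has {len(y)}")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        A = int(self.n_components)
        if not 1 <= A <= min(n - 1, p):
            raise ValueError(
                f"n_components={A} outside valid range [1, {min(n - 1, p)}]"
            )
        if not (np.isfinite(Xm).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")

        constant = np.ptp(Xm, axis=0) == 0
        if constant.any():
            bad = np.where(constant)[0].tolist()
            bad_names = [names[i] for i in bad] if names else bad
            raise ValueError(f"zero-variance X column(s): {bad_names}")
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")
        x_mean = Xm.mean(axis=0)
        y_mean = y.mean()
        if self.scale:
            x_scale = Xm.std(axis=0, ddof=1)
            y_scale = y.std(ddof=1)
        else:
            x_scale = np.ones(p)
            y_scale = 1.0

        Xs = (Xm - x_mean) / x_scale
        ys = (y - y_mean) / y_scale
        ssx_total = float(np.sum(Xs**2))
        ssy_total = float(np.sum(ys**2))

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        q = np.zeros(A)
        r2x = np.zeros(A)
        r2y = np.zeros(A)

        Xd, yd = Xs.copy(), ys.copy()
        for a in range(A):
            cov = Xd.T @ yd
            cov_norm = float(np.linalg.norm(cov))
            if cov_norm < _EPS:
                raise ValueError(
                    f"no covariance remaining at component {a + 1}"
                )
            w = cov / cov_norm
            t = Xd @ w
            tt = float(t @ t)
            if tt < _EPS:
                raise ValueError(f"degenerate score at component {a + 1}")
            pl = (Xd.T @ t) / tt
            ql = float(yd @ t) / tt
            Xd = Xd - np.outer(t, pl)
            yd = yd - ql * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, ql
            r2x[a] = 1.0 - float(np.sum(Xd**2)) / ssx_total if ssx_total > 0 else 0.0
            r2y[a] = 1.0 - float(np.sum(yd**2)) / ssy_total

        PtW = P.T @ W
        try:
            b = W @ np.linalg.solve(PtW, q)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular P'W matrix: {exc}") from exc

        self.feature_names_in_ = names
        self.n_features_in_ = p
        self.x_weights_, self.x_loadings_, self.x_scores_ = W, P, T
        self.y_loadings_ = q
        self.coef_ = b
        self.x_mean_, self.x_scale_ = x_mean, x_scale
        self.y_mean_, self.y_scale_ = y_mean, float(y_scale)
        self.coef_original_ = b * self.y_scale_ / x_scale
        self.intercept_ = float(y_mean - self.coef_original_ @ x_mean)
        self.r2x_cum_, self.r2y_cum_ = r2x, r2y
        self.vip_ = self._compute_vip(W, T, q, p)
        return self

    @staticmethod
    def _compute_vip(W: np.ndarray, T: np.ndarray, q: np.ndarray, p: int) -> np.ndarray:
        ss = q**2 * np.einsum("ia,ia->a", T, T)  # SS_a = q_a^2 * t_a' t_a
        total = float(ss.sum())
        if total <= 0:
            return np.ones(p)
        return np.sqrt(p * (W**2 @ ss) / total)

    def _align(self, X) -> np.ndarray:
        Xm, names = _as_matrix(X)
        if names is not None and self.feature_names_in_ is not None:
            missing = [c for c in self.feature_names_in_ if c not in names]
            if missing:
                raise ValueError(f"columns missing from input: {missing}")
            order = [names.index(c) for c in self.feature_names_in_]
            Xm = Xm[:, order]
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xm.shape[1]}"
            )
        return Xm

    def predict(self, X) -> np.ndarray:
        """Predict y on its original scale; DataFrame columns align by name."""
        self._check_is_fitted("coef_")
        Xm = self._align(X)
        return Xm @ self.coef_original_ + self.intercept_

    def fitted_values(self) -> np.ndarray:
        """In-sample predictions, equal to T q mapped back to the y scale."""
        self._check_is_fitted("coef_")
        return self.x_scores_ @ self.y_loadings_ * self.y_scale_ + self.y_mean_

    def score(self, X, y) -> float:
        """Coefficient of determination R^2 of the prediction."""
        y = np.asarray(y, dtype=float).ravel()
        resid = y - self.predict(X)
        return 1.0 - float(resid @ resid) / float(np.sum((y - y.mean()) ** 2))


def fit_pls1(X, y, n_components: int, scale: bool = True) -> NipalsPLS:
    """Functional wrapper: fit a :class:`NipalsPLS` and return it."""
    return NipalsPLS(n_components=n_components, scale=scale).fit(X, y)


def vip(model: NipalsPLS) -> np.ndarray:
    """Variable-importance-in-projection scores of a fitted model."""
    model._check_is_fitted("vip_")
    return model.vip_


@dataclass
class CvResult:
    """Leave-one-out cross-validation curves for candidate component counts.

    ``press[a-1]`` and ``q2[a-1]`` refer to A = a components; ``sq_errors``
    holds the per-sample squared LOO prediction errors (n x A_max), which the
    van der Voet component-selection test consumes.
    """

    press: np.ndarray
    q2: np.ndarray
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray
    sq_errors: np.ndarray
    a_max: int
    n: int


def _fit_largest(X: np.ndarray, y: np.ndarray, a_max: int, scale: bool) -> NipalsPLS:
    """Fit with up to ``a_max`` components, backing off when the deflated
    covariance is exhausted (e.g. noiseless low-rank data)."""
    a = min(a_max, len(y) - 1, X.shape[1])
    while a >= 1:
        try:
            return NipalsPLS(n_components=a, scale=scale).fit(X, y)
        except ValueError as exc:
            msg = str(exc)
            if "no covariance remaining" in msg or "degenerate score" in msg:
                a -= 1
                continue
            raise
    raise ValueError("no covariance remaining at component 1")


def _loo_predictions(X: np.ndarray, y: np.ndarray, a_max: int, scale: bool) -> np.ndarray:
    """LOO predicted values, (n, a_max), refit + re-standardized per fold."""
    n = len(y)
    preds = np.full((n, a_max), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        keep = Xtr.std(axis=0, ddof=1) > 0 if scale else np.ones(X.shape[1], bool)
        if not keep.all():
            warnings.warn(
                f"fold {i}: dropping zero-variance column(s) {np.where(~keep)[0].tolist()}"
            )
        Xtr = Xtr[:, keep]
        model = _fit_largest(Xtr, ytr, a_max, scale)
        a_fold = model.n_components
        # cumulative predictions after each component
        x_new = (X[i, keep] - model.x_mean_) / model.x_scale_
        W, P, q = model.x_weights_, model.x_loadings_, model.y_loadings_
        y_hat_std = 0.0
        x_res = x_new.copy()
        for a in range(a_fold):
            t = float(x_res @ W[:, a])
            y_hat_std += q[a] * t
            x_res = x_res - t * P[:, a]
            preds[i, a] = y_hat_std * model.y_scale_ + model.y_mean_
        if a_fold < a_max:  # rank exhausted in this fold: carry last prediction
            preds[i, a_fold:] = preds[i, a_fold - 1]
    return preds


def cross_validate(X, y, a_max: int, scale: bool = True) -> CvResult:
    """Leave-one-out PRESS/Q² plus full-fit R²X/R²Y for A = 1..a_max.

    Each fold refits the model without sample i, re-centering and re-scaling
    X and y inside the fold; PRESS(A) sums squared prediction errors on the
    original y scale, and Q²(A) = 1 − PRESS(A)/Σ(yᵢ−ȳ)² with the full-sample
    corrected sum of squares in the denominator.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n < 4:
        raise ValueError(f"cross-validation needs at least 4 samples, got {n}")
    if not 1 <= a_max <= min(n - 2, p):
        raise ValueError(f"a_max={a_max} outside valid range [1, {min(n - 2, p)}]")
    preds = _loo_predictions(Xm, y, a_max, scale)
    sq_errors = (y[:, None] - preds) ** 2
    press = sq_errors.sum(axis=0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    full = _fit_largest(Xm, y, a_max, scale)
    # pad the cumulative curves if the full fit exhausted covariance early
    r2x_cum = np.concatenate([full.r2x_cum_, np.full(a_max - full.n_components, full.r2x_cum_[-1])])
    r2y_cum = np.concatenate([full.r2y_cum_, np.full(a_max - full.n_components, full.r2y_cum_[-1])])
    return CvResult(
        press=press,
        q2=q2,
        r2x_cum=r2x_cum,
        r2y_cum=r2y_cum,
        sq_errors=sq_errors,
        a_max=a_max,
        n=n,
    )


@dataclass
class ComponentSelection:
    """Outcome of the van der Voet parsimonious component choice."""

    a_star: int
    a_min_press: int
    p_values: dict[int, float] = field(default_factory=dict)
    alpha: float = 0.10


def select_components(
    cv: CvResult, alpha: float = 0.10, n_perm: int = 2000, seed: int = 0
) -> ComponentSelection:
    """Smallest A whose LOO squared errors are not significantly worse
    than the minimum-PRESS model (van der Voet T², Monte-Carlo sign flips).

    For each A below the PRESS-minimizing count the statistic is the sum of
    per-sample differences d_i = e²(i,A) − e²(i,A_min); its null is built by
    randomly flipping the signs of the d_i. The selected A* is the smallest
    A with p ≥ alpha, else A_min itself.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    a_min = int(np.argmin(cv.press)) + 1
    rng = np.random.default_rng(seed)
    p_values: dict[int, float] = {}
    a_star = a_min
    for a in range(1, a_min):
        d = cv.sq_errors[:, a - 1] - cv.sq_errors[:, a_min - 1]
        t_obs = float(d.sum())
        signs = rng.choice((-1.0, 1.0), size=(n_perm, len(d)))
        t_null = signs @ d
        p = (1.0 + float(np.sum(t_null >= t_obs))) / (n_perm + 1.0)
        p_values[a] = p
        if p >= alpha and a_star == a_min:
            a_star = a
    return ComponentSelection(a_star=a_star, a_min_press=a_min, p_values=p_values, alpha=alpha)
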