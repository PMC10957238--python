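"""Scikit-learn-style estimators: fractional ridge and shrinkage LDA.

Fractional ridge regression reparameterizes the ridge penalty by the
*fraction* γ ∈ (0, 1] of the unregularized solution's L2 norm that the
regularized coefficients should retain: for each requested fraction the
matching penalty α(γ) is found on the SVD of the design, where the whole
regularization path is cheap. This gives a hyperparameter grid that is
uniformly meaningful across time samples and data scales, unlike raw α.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["FractionalRidge", "ShrinkageLDA", "fractional_ridge_fit", "lda_auc"]

_SV_TOL = 1e-10


def _frac_ridge_coords(
    s: np.ndarray, c: np.ndarray, fracs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the fractional-ridge problem on an SVD.

    Parameters
    ----------
    s : (..., k) singular values of the (centered) design.
    c : (..., k) coordinates Uᵀy of the (centered) target.
    fracs : (F,) requested norm fractions in (0, 1].

    Returns
    -------
    coords : (..., k, F) ridge coordinates in the right-singular basis.
    alphas : (..., F) matched penalties (0 where frac == 1).

    The penalty for each fraction is located by bisection in log-penalty
    space; the norm-vs-penalty map is strictly decreasing so the solution
    is unique.
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    fracs = np.asarray(fracs, dtype=float)
    if np.any(fracs <= 0) or np.any(fracs > 1):
        raise ValueError("fractions must lie in (0, 1]")
    active = s > _SV_TOL * np.max(s, axis=-1, keepdims=True)
    if not active.any():
        raise ValueError("design matrix has rank 0")
    s_safe = np.where(active, s, 1.0)

    def norm2(alpha):
        # alpha broadcast: (..., 1, F); coords (..., k, F)
        coords = np.where(
            active[..., None], (c * s)[..., None] / (s_safe[..., None] ** 2 + alpha), 0.0
        )
        return np.sqrt(np.sum(coords**2, axis=-2)), coords

    ols_norm, _ = norm2(np.zeros((1,)))
    ols_norm = ols_norm[..., 0]  # (...,)

    smax2 = np.max(s, axis=-1) ** 2  # (...,)
    lo = np.full(s.shape[:-1] + fracs.shape, np.log(1e-12)) + np.log(smax2)[..., None]
    hi = np.full_like(lo, np.log(1e12)) + np.log(smax2)[..., None]
    target = fracs * ols_norm[..., None]  # (..., F)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val, _ = norm2(np.exp(mid)[..., None, :])
        too_big = val > target
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    alphas = np.exp(0.5 * (lo + hi))
    alphas = np.where(fracs == 1.0, 0.0, alphas)
    _, coords = norm2(alphas[..., None, :])
    return coords, alphas


def batched_fractional_ridge(
    x: np.ndarray, y: np.ndarray, fracs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractional ridge for a stack of problems sharing one target.

    ``x``: (B, n, p) designs; ``y``: (n,) or (B, n). Designs and targets
    are centered internally. Returns ``(coef, x_mean, y_mean)`` with
    ``coef`` of shape (B, p, F); predictions are
    ``(Xnew - x_mean) @ coef + y_mean``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = x.mean(axis=1, keepdims=True)
    xc = x - x_mean
    if y.ndim == 1:
        y = np.broadcast_to(y, (x.shape[0], len(y)))
    y_mean = y.mean(axis=1)
    yc = y - y_mean[:, None]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    c = np.einsum("bnk,bn->bk", u, yc)
    coords, _ = _frac_ridge_coords(s, c, fracs)
    coef = np.einsum("bkp,bkf->bpf", vt, coords)
    return coef, x_mean[:, 0, :], y_mean


class FractionalRidge(BaseEstimator, RegressorMixin):
    """Ridge regression parameterized by coefficient-norm fractions.

    Parameters
    ----------
    fracs : array-like of float in (0, 1], default 20 values linear in
        [0.001, 0.99].
        Requested ratios ‖β(α)‖₂ / ‖β_OLS‖₂. ``fracs=1.0`` reproduces the
        minimum-norm least-squares solution.

    Attributes
    ----------
    coef_ : ndarray, (n_features, n_fracs)
    alpha_ : ndarray, (n_fracs,) matched ridge penalties.
    intercept_ : ndarray, (n_fracs,)
    """

    def __init__(self, fracs=None):
        self.fracs = fracs

    def _frac_array(self) -> np.ndarray:
        if self.fracs is None:
            return np.linspace(0.001, 0.99, 20)
        return np.atleast_1d(np.asarray(self.fracs, dtype=float))

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        fracs = self._frac_array()
        if np.any(fracs <= 0) or np.any(fracs > 1):
            raise ValueError("fractions must lie in (0, 1]")
        coef, x_mean, y_mean = batched_fractional_ridge(X[None], y, fracs)
        self.coef_ = coef[0]
        self.intercept_ = y_mean[0] - x_mean[0] @ self.coef_
        u, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        c = u.T @ (y - y.mean())
        _, alphas = _frac_ridge_coords(s, c, fracs)
        self.alpha_ = alphas
        self.fracs_ = fracs
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        pred = X @ self.coef_ + self.intercept_
        if pred.shape[1] == 1:
            return pred[:, 0]
        return pred


def fractional_ridge_fit(X, y, fractions) -> np.ndarray:
    """Coefficients (n_features, n_fracs) for each requested norm fraction."""
    est = FractionalRidge(fracs=fractions).fit(np.asarray(X), np.asarray(y))
    return est.coef_


class ShrinkageLDA(LinearDiscriminantAnalysis):
    """Fisher linear discriminant with Ledoit–Wolf-shrunk pooled covariance.

    Thin preset over scikit-learn's LDA (``solver='lsqr'``,
    ``shrinkage='auto'``), the regularization needed when features
    (channels × samples) rival or exceed the trial count.
    """

    def __init__(self):
        super().__init__(solver="lsqr", shrinkage="auto")


def lda_auc(train_X, train_y, test_X, test_y) -> float:
    """Fit a shrinkage-regularized Fisher LDA on the training set and return
    the ROC AUC of its discriminant scores on the test set."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if not (np.isfinite(train_X).all() and np.isfinite(test_X).all()):
        raise ValueError("non-finite values in features")
    if len(np.unique(train_y)) != 2:
        raise ValueError("training labels must contain exactly two classes")
    clf = ShrinkageLDA().fit(train_X, train_y)
    scores = clf.decision_function(test_X)
    return float(roc_auc_score(test_y, scores))
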