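"""PLS1 calibration: NIPALS fit, leave-one-out PRESS, F-test factor choice.

The calibration curve maps a normalized averaged beat (L-vector) to a
reference blood pressure in mmHg.  PLS regression is used instead of PCR
because the reference readings from the cuff monitor themselves carry error,
which PLS accommodates in the objective variable.

The model is single-response NIPALS on mean-centered data with no variance
scaling (beats are already on a common [0, 1] scale).  Per factor:

    w = X'y / ||X'y||          (weight)
    t = X w                    (score)
    p = X't / t't              (x-loading)
    q = y't / t't              (y-loading)
    X <- X - t p',  y <- y - t q

and the regression vector is ``b = W (P'W)^{-1} q`` so that
``yhat = y_mean + (x - x_mean) b``.

The factor count is chosen by leave-one-out PRESS with a sequential F-test:
starting from the mean-only model (k = 0), a factor is added while the
PRESS ratio PRESS(k)/PRESS(k+1) exceeds the upper critical value of the F
distribution with (n, n) degrees of freedom at level alpha; otherwise the
smaller model is kept.  At least one factor is always returned (a zero-factor
calibration curve is not a curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DimensionMismatchError, DomainError, RankDeficiencyError

__all__ = [
    "BeatMatrix",
    "PLSModel",
    "EvaluationReport",
    "fit_pls",
    "predict",
    "loo_press",
    "press_curve",
    "select_factors",
    "evaluate",
]

_RANK_TOL = 1e-12


@dataclass
class BeatMatrix:
    """Normalized beats (rows) paired with reference pressures in mmHg."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise DomainError("X must be n x L with y of length n")
        if self.X.shape[0] < 4:
            raise DomainError("need at least 4 paired beats")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise DomainError("missing or non-finite values in beat matrix")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.size != self.y.size:
                raise DomainError("subject_ids length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class PLSModel:
    """Fitted calibration curve (centering + factor structure)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (k, L)
    x_loadings: np.ndarray   # (k, L)
    y_loadings: np.ndarray   # (k,)
    n_factors: int
    regression_vector: np.ndarray = field(default=None)  # (L,), mmHg per unit

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise DomainError("a calibration curve needs at least 1 factor")
        if self.regression_vector is None:
            W = self.weights.T
            P = self.x_loadings.T
            self.regression_vector = W @ np.linalg.solve(P.T @ W, self.y_loadings)

    @property
    def L(self) -> int:
        return self.x_mean.size


@dataclass
class EvaluationReport:
    """Validation-set figures of merit.

    ``sep`` is the standard error of prediction (the root sum of squared
    prediction errors over n - 1), the "measurement accuracy" in mmHg;
    ``r`` the Pearson correlation of predicted vs reference (None when the
    reference has no variance); ``bias`` the mean prediction error.
    """

    sep: float
    r: float | None
    bias: float
    n: int

    def __post_init__(self) -> None:
        if self.sep < 0:
            raise DomainError("sep must be >= 0")
        if self.r is not None and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise DomainError("r must lie in [-1, 1]")


def fit_pls(X, y, k: int) -> PLSModel:
    """Fit a k-factor PLS1 model by NIPALS on mean-centered data.

    Raises :class:`RankDeficiencyError` when k exceeds the rank of the
    centered X (the deflated covariance vanishes) and
    :class:`DomainError` for zero-variance y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, L = X.shape
    if not 1 <= k <= n - 1:
        raise DomainError(f"k must satisfy 1 <= k <= n-1 = {n - 1}")
    if np.ptp(y) == 0:
        raise DomainError("y has zero variance; nothing to calibrate")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_scale = float(np.abs(Xc).max()) or 1.0
    y_scale = float(np.abs(yc).max()) or 1.0

    W = np.empty((k, L))
    P = np.empty((k, L))
    Q = np.empty(k)
    for a in range(k):
        cov = Xc.T @ yc
        norm = np.linalg.norm(cov)
        if norm <= _RANK_TOL * x_scale * y_scale * n:
            raise RankDeficiencyError(
                f"requested {k} factors but the centered data supports only {a}"
            )
        w = cov / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * x_scale) ** 2 * n:
            raise RankDeficiencyError(
                f"requested {k} factors but the centered data supports only {a}"
            )
        p = (Xc.T @ t) / tt
        q = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        W[a], P[a], Q[a] = w, p, q
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=Q, n_factors=k,
    )


def predict(model: PLSModel, beats) -> np.ndarray:
    """Blood pressure (mmHg) for each beat row: ``y_mean + (x - x_mean) b``."""
    Xv = np.atleast_2d(np.asarray(beats, dtype=float))
    if Xv.shape[1] != model.L:
        raise DimensionMismatchError(
            f"beats have length {Xv.shape[1]}, model expects {model.L}"
        )
    return model.y_mean + (Xv - model.x_mean) @ model.regression_vector


def press_curve(X, y, k_max: int) -> np.ndarray:
    """Leave-one-out PRESS for factor counts 0..k_max (inclusive).

    PRESS(0) uses the mean-only model.  For a fold where the training data
    supports fewer than k factors, the largest supported model is carried
    forward (its prediction cannot improve further).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise DomainError("leave-one-out needs n >= 3")
    k_max = min(k_max, n - 2)
    press = np.zeros(k_max + 1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        xi = X[i]
        yhat = float(yt.mean())
        press[0] += (yhat - y[i]) ** 2
        # incremental NIPALS: record the held-out prediction after each factor
        x_mean = Xt.mean(axis=0)
        Xc = Xt - x_mean
        yc = yt - yt.mean()
        xic = xi - x_mean
        x_scale = float(np.abs(Xc).max()) or 1.0
        y_scale = float(np.abs(yc).max()) or 1.0
        for a in range(1, k_max + 1):
            cov = Xc.T @ yc
            norm = np.linalg.norm(cov)
            if norm <= _RANK_TOL * x_scale * y_scale * n:
                press[a:] += (yhat - y[i]) ** 2
                break
            w = cov / norm
            t = Xc @ w
            tt = float(t @ t)
            if tt <= (_RANK_TOL * x_scale) ** 2 * n:
                press[a:] += (yhat - y[i]) ** 2
                break
            p = (Xc.T @ t) / tt
            q = float(yc @ t) / tt
            ti = float(xic @ w)
            yhat += q * ti
            xic = xic - ti * p
            Xc = Xc - np.outer(t, p)
            yc = yc - q * t
            press[a] += (yhat - y[i]) ** 2
    return press


def loo_press(X, y, k: int) -> float:
    """Leave-one-out PRESS (mmHg^2) at a single factor count k (k=0: mean model)."""
    if k < 0:
        raise DomainError("k must be >= 0")
    return float(press_curve(X, y, k)[k])


def select_factors(X, y, k_max: int, alpha: float = 0.05) -> int:
    """Sequential F-test choice of the PLS factor count.

    From k = 0 upward, the factor k+1 is added while
    ``PRESS(k) / PRESS(k+1)`` exceeds the upper alpha critical value of
    F(n, n); the first non-significant step stops the procedure.  Returns at
    least 1.
    """
    if k_max < 1:
        raise DomainError("k_max must be >= 1")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = y.size
    press = press_curve(X, y, k_max)
    f_crit = stats.f.ppf(1.0 - alpha, n, n)
    k = 0
    while k < press.size - 1:
        num, den = press[k], press[k + 1]
        if den == 0.0:
            if num == 0.0:
                break
            k += 1
            continue
        if num / den > f_crit:
            k += 1
        else:
            break
    return max(k, 1)


def evaluate(model: PLSModel, X_val, y_val) -> EvaluationReport:
    """Standard error of prediction, correlation and bias on a validation set."""
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size == 0:
        raise DomainError("validation set is empty")
    yhat = predict(model, X_val)
    err = yhat - y_val
    n = y_val.size
    sep = float(np.sqrt(np.sum(err**2) / max(n - 1, 1)))
    bias = float(err.mean())
    if np.ptp(y_val) == 0 or np.ptp(yhat) == 0:
        r = None
    else:
        r = float(np.corrcoef(yhat, y_val)[0, 1])
    return EvaluationReport(sep=sep, r=r, bias=bias, n=n)
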