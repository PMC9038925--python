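"""Saturation analysis of cumulative unique peak discovery.

Random subsampling of samples yields a curve of cumulative distinct
peaks versus sample number; the exponential saturation model

    P(x) = a + b * exp(c*x + d)

is fitted to predict the total number of accessible regions (the
asymptote ``a``) and the number of samples needed to approach it.
Only the product ``B = b * exp(d)`` is identifiable, so the model is
fitted in the (a, B, c) parameterisation; ``d`` is reported as 0 by
default and the fit is invariant to the (b, d) split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SaturationCurve",
    "SaturationModel",
    "build_saturation_curve",
    "fit_saturation_model",
    "saturation_sample_size",
]


@dataclass
class SaturationCurve:
    """Mean cumulative unique-peak count versus number of samples."""

    x: np.ndarray  # 1..N
    mean: np.ndarray
    sd: np.ndarray
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean) < -1e-9):
            raise ValueError("saturation curve must be non-decreasing")


def build_saturation_curve(presence, n_draws: int, seed: int | None = None) -> SaturationCurve:
    """Average cumulative distinct-peak count over random sample orderings.

    For each draw, samples are visited in a uniform random permutation and
    the number of distinct peaks present in the first x samples is
    recorded; the curve is the mean over draws.
    """
    mat = np.asarray(presence, dtype=bool)
    if mat.size == 0:
        raise ValueError("empty presence matrix")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    n_peaks, n_samples = mat.shape
    rng = np.random.default_rng(seed)
    curves = np.empty((n_draws, n_samples), dtype=np.int64)
    for d in range(n_draws):
        perm = rng.permutation(n_samples)
        seen = np.maximum.accumulate(mat[:, perm], axis=1)
        curves[d] = seen.sum(axis=0)
    return SaturationCurve(
        x=np.arange(1, n_samples + 1),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=0),
        n_draws=n_draws,
        seed=seed,
    )


class SaturationModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of P(x) = a + B*exp(c*x) with self-starting values.

    Parameters
    ----------
    d : float
        Fixed offset of the overparameterised form b*exp(c*x + d); only
        b*exp(d) enters the model, so ``d`` merely splits the reported
        amplitude (``b_ = B * exp(-d)``).  Default 0.
    tol : float
        Relative SSE-change convergence tolerance.
    max_iter : int
        Iteration cap for the optimiser.

    Attributes
    ----------
    asymptote_ : float        fitted ``a`` (predicted total peak count)
    amplitude_ : float        fitted ``B = b * exp(d)`` (negative when saturating)
    rate_ : float             fitted ``c`` (negative when saturating)
    b_, d_ : float            the reported (b, d) split of the amplitude
    sse_ : float              residual sum of squares
    converged_ : bool
    saturating_ : bool        True iff ``c < 0``
    degenerate_ : bool        True for an (almost) constant input curve
    """

    def __init__(self, d: float = 0.0, tol: float = 1e-10, max_iter: int = 10_000):
        self.d = d
        self.tol = tol
        self.max_iter = max_iter

    # -- model ------------------------------------------------------------
    @staticmethod
    def _eval(params, x):
        a, B, c = params
        return a + B * np.exp(c * x)

    def _self_start(self, x, y):
        a0 = float(np.max(y)) * (1.0 + 1e-6) + 1e-9
        resid = np.clip(a0 - y, 1e-12, None)
        # log-linearised: log(a0 - P) = log(-B) + c*x
        slope, intercept = np.polyfit(x, np.log(resid), 1)
        c0 = min(slope, -1e-6)
        B0 = -math.exp(intercept)
        return np.array([a0, B0, c0])

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 4:
            raise ValueError("need >= 4 curve points to fit 3 parameters")

        scale = max(float(np.ptp(y)), 1.0)
        self.degenerate_ = np.ptp(y) <= 1e-9 * max(abs(float(y[0])), 1.0)
        if self.degenerate_:
            self.asymptote_, self.amplitude_, self.rate_ = float(y.mean()), 0.0, 0.0
            self.sse_ = float(np.sum((y - y.mean()) ** 2))
            self.converged_ = True
            self.saturating_ = False
        else:
            p0 = self._self_start(x, y)
            res = least_squares(
                lambda p: self._eval(p, x) - y,
                p0,
                method="lm",
                ftol=self.tol,
                xtol=self.tol,
                gtol=self.tol,
                max_nfev=self.max_iter,
            )
            self.asymptote_, self.amplitude_, self.rate_ = (float(v) for v in res.x)
            self.sse_ = float(2.0 * res.cost)
            self.converged_ = bool(res.success)
            self.saturating_ = self.rate_ < 0
        self.d_ = float(self.d)
        self.b_ = self.amplitude_ * math.exp(-self.d_)
        self.scale_ = scale
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self._eval((self.asymptote_, self.amplitude_, self.rate_), x)

    def sample_size_at(self, fraction: float = 0.99) -> int:
        """Smallest integer n with P(n) >= fraction * asymptote.

        Closed form: n = ceil((ln(a*(1-f)) - ln(-B)) / c).
        """
        return saturation_sample_size(self, fraction)


def fit_saturation_model(curve: SaturationCurve, d: float = 0.0) -> SaturationModel:
    """Fit the saturation model to a draw-averaged curve."""
    return SaturationModel(d=d).fit(curve.x, curve.mean)


def saturation_sample_size(fit: SaturationModel, fraction: float = 0.99) -> int:
    """Invert the fitted model for the sample number reaching saturation.

    The criterion is P(n) >= fraction * a; the asymptote itself is never
    attained, so ``fraction`` must be < 1.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1); the asymptote is never attained")
    a, B, c = fit.asymptote_, fit.amplitude_, fit.rate_
    if c >= 0 or B >= 0:
        raise ValueError("saturation point undefined for a non-saturating fit (c >= 0)")
    if a <= 0:
        raise ValueError("non-positive asymptote")
    t = (math.log(a * (1.0 - fraction)) - math.log(-B)) / c
    n = max(1, math.ceil(t - 1e-9))
    # guard the float inversion with the defining inequality
    while fit.predict(np.array([n]))[0] < fraction * a - 1e-9 * a:
        n += 1
    while n > 1 and fit.predict(np.array([n - 1]))[0] >= fraction * a - 1e-9 * a:
        n -= 1
    return int(n)
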