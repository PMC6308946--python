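"""Logistic smoothing of step-interval danger scores.

The scoring function of each meteorological danger index is the two-parameter
logistic curve

.. math::

    Y'(x) = \\frac{K}{1 + e^{\\alpha + \\beta x}},

with the saturation score :math:`K` fixed by the standard (not estimated).
:class:`StepLogisticModel` fits :math:`(\\alpha, \\beta)` to a
:class:`~firegrade.samples.StepSampleSet` and returns a
:class:`StepLogisticResults` carrying the estimates, their standard errors
and the coefficient of determination on the score scale.

Two estimation routes are provided:

``"irls"`` (default)
    Binomial-family logistic regression of the score fraction ``y/K`` on
    ``x``, solved by iteratively reweighted least squares.  Scores of exactly
    0 and K are valid observations on this route (their likelihood
    contribution is finite), which matters because every sample set pins both
    endpoints.  This is the route that reproduces the published fitted
    curves.

``"nls"``
    Unweighted Gaussian nonlinear least squares on the score scale
    (Levenberg–Marquardt via :func:`scipy.optimize.curve_fit`), started from
    a clipped-logit linear regression.

Both routes are equivariant under affine reparameterisation of ``x``: if
``x -> a + b*x`` maps one sample set onto another, the fitted curves map
likewise (``beta`` scales by ``1/b``) and R² is unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FittingError, ValidationError
from .samples import StepSampleSet, builtin_sample_sets

__all__ = [
    "StepLogisticModel",
    "StepLogisticResults",
    "fit_logistic",
    "r_squared",
    "refit_builtin",
    "export_fits_json",
]

_MAX_IRLS_ITER = 100
_IRLS_TOL = 1e-12


def _logistic(x: np.ndarray, alpha: float, beta: float, k: float) -> np.ndarray:
    """K / (1 + exp(alpha + beta*x)), computed without overflow."""
    eta = alpha + beta * np.asarray(x, dtype=float)
    # sigmoid(-eta) via the numerically stable branch split
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = np.exp(-eta[pos]) / (1.0 + np.exp(-eta[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(eta[~pos]))
    return k * out


def _clipped_logit_start(x: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Starting values from a linear regression on the clipped logit.

    Endpoint scores (p = 0 or 1) have an undefined logit, so p is clipped
    into [0.01, 0.99] first.
    """
    pc = np.clip(p, 0.01, 0.99)
    z = np.log(1.0 / pc - 1.0)  # = alpha + beta*x under the model
    beta0, alpha0 = np.polyfit(x, z, 1)
    return float(alpha0), float(beta0)


class StepLogisticModel:
    """Logistic scoring-curve model for one step-interval sample set.

    Parameters
    ----------
    samples : StepSampleSet
        The (x, score) pairs and the fixed saturation score K.

    Examples
    --------
    >>> from firegrade import builtin_sample_sets, StepLogisticModel
    >>> res = StepLogisticModel(builtin_sample_sets()["A"]).fit()
    >>> round(res.alpha, 4), round(res.beta, 4)
    (3.6421, -0.2428)
    """

    def __init__(self, samples: StepSampleSet):
        if len(samples) < 3:
            raise ValidationError("need at least 3 sample pairs to fit")
        self.samples = samples
        self.x = np.asarray(samples.x, dtype=float)
        self.y = np.asarray(samples.y, dtype=float)
        self.k = float(samples.k)
        if np.ptp(self.y) == 0:
            raise DegenerateDataError("all scores are equal; nothing to fit")

    @classmethod
    def from_pairs(cls, pairs, k: float, index_id: str = "A") -> "StepLogisticModel":
        return cls(StepSampleSet(index_id, tuple(pairs), float(k)))

    # -- estimation ---------------------------------------------------------

    def fit(self, method: Literal["irls", "nls"] = "irls") -> "StepLogisticResults":
        """Estimate (alpha, beta) with K held fixed.

        Parameters
        ----------
        method : {"irls", "nls"}
            ``"irls"`` — binomial-family logistic regression of y/K (default);
            ``"nls"`` — unweighted least squares on the score scale.
        """
        if method == "irls":
            alpha, beta, cov, niter = self._fit_irls()
        elif method == "nls":
            alpha, beta, cov, niter = self._fit_nls()
        else:
            raise ValidationError(f"unknown method {method!r}")
        return StepLogisticResults(self, alpha, beta, cov, method, niter)

    def _fit_irls(self):
        x, p = self.x, self.y / self.k
        X = np.column_stack([np.ones_like(x), x])
        # GLM convention logit(mu) = b0 + b1*x; our exponent is the negative
        a0, b0 = _clipped_logit_start(x, p)
        b = np.array([-a0, -b0])
        dev_old = np.inf
        for it in range(1, _MAX_IRLS_ITER + 1):
            eta = X @ b
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            w = mu * (1.0 - mu)
            z = eta + (p - mu) / w
            WX = X * w[:, None]
            try:
                b_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise FittingError("singular weighted design matrix") from exc
            # binomial deviance of the fractional responses
            with np.errstate(divide="ignore", invalid="ignore"):
                dev = 2.0 * np.sum(
                    np.where(p > 0, p * np.log(p / mu), 0.0)
                    + np.where(p < 1, (1 - p) * np.log((1 - p) / (1 - mu)), 0.0)
                )
            if not np.all(np.isfinite(b_new)):
                raise FittingError("IRLS diverged to non-finite coefficients")
            step = np.max(np.abs(b_new - b))
            b = b_new
            if step < _IRLS_TOL or abs(dev_old - dev) < _IRLS_TOL:
                break
            dev_old = dev
        else:
            raise FittingError(f"IRLS did not converge in {_MAX_IRLS_ITER} iterations")
        # Fisher information with quasi-binomial (Pearson) dispersion
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        n, k = len(x), 2
        pearson = float(np.sum((p - mu) ** 2 / w))
        scale = pearson / max(n - k, 1)
        cov = scale * np.linalg.inv(X.T @ (X * w[:, None]))
        # back to the exponent convention alpha + beta*x
        return -float(b[0]), -float(b[1]), cov, it

    def _fit_nls(self):
        x, y, k = self.x, self.y, self.k
        a0, b0 = _clipped_logit_start(x, y / k)
        try:
            popt, pcov = curve_fit(
                lambda xx, a, b: _logistic(xx, a, b, k),
                x, y, p0=[a0, b0], maxfev=10000,
            )
        except RuntimeError as exc:
            raise FittingError(str(exc)) from exc
        return float(popt[0]), float(popt[1]), pcov, None


@dataclass
class StepLogisticResults:
    """Fit results for one index's logistic scoring curve.

    Attributes
    ----------
    alpha, beta : float
        Exponent coefficients of ``K / (1 + e^{alpha + beta x})``.
    cov_params : ndarray
        2x2 covariance of (alpha, beta).
    method : str
        Estimation route used.
    """

    model: StepLogisticModel
    alpha: float
    beta: float
    cov_params: np.ndarray
    method: str
    n_iter: int | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def k(self) -> float:
        return self.model.k

    @property
    def nobs(self) -> int:
        return len(self.model.x)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.x)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def r_squared(self) -> float:
        """1 − SSres/SStot on the score scale."""
        y = self.model.y
        sstot = float(np.sum((y - y.mean()) ** 2))
        if sstot == 0:
            raise DegenerateDataError("zero total sum of squares")
        return 1.0 - float(np.sum(self.resid ** 2)) / sstot

    @property
    def midpoint(self) -> float:
        """x at which the curve crosses K/2 (= −alpha/beta)."""
        return -self.alpha / self.beta

    def predict(self, x) -> np.ndarray:
        """Evaluate the fitted curve; output lies strictly inside (0, K)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValidationError("predict requires finite inputs")
        return _logistic(x, self.alpha, self.beta, self.k)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        s = self
        lines = [
            "Step-interval logistic fit",
            "=" * 46,
            f"Index:            {s.model.samples.index_id}",
            f"Method:           {s.method}",
            f"No. observations: {s.nobs}",
            f"K (fixed):        {s.k:g}",
            f"R-squared:        {s.r_squared:.4f}",
            "-" * 46,
            f"{'':8s}{'coef':>10s}{'std err':>12s}",
            f"{'alpha':8s}{s.alpha:10.4f}{s.bse[0]:12.4f}",
            f"{'beta':8s}{s.beta:10.4f}{s.bse[1]:12.4f}",
            "-" * 46,
            f"Midpoint (K/2 crossing): {s.midpoint:.4f} {s.model.samples.x_units}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "index_id": self.model.samples.index_id,
            "alpha": self.alpha,
            "beta": self.beta,
            "k": self.k,
            "r_squared": self.r_squared,
            "method": self.method,
        }


def fit_logistic(samples: StepSampleSet, method: str = "irls") -> StepLogisticResults:
    """Fit the logistic scoring curve to one sample set (convenience)."""
    return StepLogisticModel(samples).fit(method=method)


def r_squared(fit: StepLogisticResults, samples: StepSampleSet) -> float:
    """Coefficient of determination of a fit evaluated on a sample set.

    ``fit`` need not have been estimated on ``samples``, but the saturation
    scores must agree.
    """
    if fit.k != samples.k:
        raise ValidationError("fit.k must equal samples.k")
    y = np.asarray(samples.y, dtype=float)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise DegenerateDataError("zero total sum of squares")
    yhat = _logistic(np.asarray(samples.x, dtype=float), fit.alpha, fit.beta, fit.k)
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def refit_builtin(method: str = "irls") -> dict[str, StepLogisticResults]:
    """Fit all four built-in sample sets; keys are index ids A–D."""
    return {sid: fit_logistic(s, method=method) for sid, s in builtin_sample_sets().items()}


def export_fits_json(fits: Mapping[str, StepLogisticResults], path: str | Path) -> None:
    """Write fitted parameters and R² per index to a JSON file."""
    data = {sid: res.to_dict() for sid, res in fits.items()}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
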