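"""Empirically estimated stochastic signatures.

Instead of imposing a theoretical normal distribution on waveform-derived
parameters (latencies, MMS amplitudes, prominences, widths), the adequate
continuous family is estimated by maximum likelihood from the empirical
samples themselves.  Candidates are the two-parameter Gamma, lognormal,
normal and Weibull families and the exponential; the winner is the maximal
log-likelihood.  The Gamma fit — shape ``a`` and scale ``b`` with 95%
confidence intervals — is the signature plotted on the Gamma parameter
plane, where lower scale reads as lower dispersion and higher shape as a
more symmetric distribution.  Gamma moments follow in closed form:

    mean = a * b,   variance = a * b**2,   skewness = 2 / sqrt(a).

A minimum of 100 samples is required for a signature (high-confidence
estimation); toy examples can override with ``allow_small``.

Signatures from many contexts (e.g. one per child) often align on a line in
the log-log plane; :class:`LogLogLine` fits that line by ordinary least
squares and reports per-point residual magnitudes ("delta" values) as a
goodness-of-fit feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import polygamma
from sklearn.base import BaseEstimator

MIN_SAMPLES = 100

FAMILY_ORDER = ("gamma", "lognormal", "normal", "weibull", "exponential")

_POSITIVE_SUPPORT = {"gamma", "lognormal", "weibull", "exponential"}


class FitError(ValueError):
    """Distribution fitting failed (degenerate or invalid samples)."""


@dataclass(frozen=True)
class FamilyFit:
    """MLE fit of one candidate family: parameters and log-likelihood."""

    family: str
    params: dict
    loglik: float
    n: int


@dataclass(frozen=True)
class GammaSignature:
    """MLE Gamma (shape, scale) with 95% CIs, moments, and context labels."""

    shape: float
    scale: float
    ci95_shape: tuple
    ci95_scale: tuple
    n: int
    mean: float
    variance: float
    skewness: float
    loglik: float
    context: dict = field(default_factory=dict)


def _validate_samples(samples, family: str, allow_small: bool) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise FitError("need at least 2 samples")
    if not allow_small and x.size < MIN_SAMPLES:
        raise FitError(
            f"n={x.size} below the {MIN_SAMPLES}-peak minimum required for a "
            "high-confidence signature (pass allow_small=True to override)"
        )
    if not np.all(np.isfinite(x)):
        raise FitError("samples must be finite")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate constant samples")
    if family in _POSITIVE_SUPPORT and np.any(x <= 0):
        raise FitError(f"{family} requires strictly positive samples")
    return x


def fit_family(samples, family: str, allow_small: bool = False) -> FamilyFit:
    """MLE fit of one candidate family (location fixed at 0 where the family
    has positive support, since latencies and MMS are positive by
    construction)."""
    if family not in FAMILY_ORDER:
        raise ValueError(f"family must be one of {FAMILY_ORDER}")
    x = _validate_samples(samples, family, allow_small)
    if family == "gamma":
        a, _, b = stats.gamma.fit(x, floc=0)
        params, frozen = {"shape": a, "scale": b}, stats.gamma(a, scale=b)
    elif family == "lognormal":
        s, _, scale = stats.lognorm.fit(x, floc=0)
        params, frozen = {"sigma": s, "scale": scale}, stats.lognorm(s, scale=scale)
    elif family == "normal":
        loc, scale = stats.norm.fit(x)
        params, frozen = {"loc": loc, "scale": scale}, stats.norm(loc, scale)
    elif family == "weibull":
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        params, frozen = {"shape": c, "scale": scale}, stats.weibull_min(c, scale=scale)
    else:  # exponential: MLE scale is the sample mean
        _, scale = stats.expon.fit(x, floc=0)
        params, frozen = {"scale": scale}, stats.expon(scale=scale)
    loglik = float(frozen.logpdf(x).sum())
    if not np.isfinite(loglik):
        raise FitError(f"{family} log-likelihood not finite")
    return FamilyFit(family=family, params=params, loglik=loglik, n=x.size)


class FamilySelector(BaseEstimator):
    """Pick the candidate family with maximal log-likelihood.

    Comparison is by raw log-likelihood (not AIC/BIC); the exponential's
    one-parameter disadvantage is accepted.  Ties break deterministically by
    the fixed candidate order gamma, lognormal, normal, weibull,
    exponential.

    Fitted attributes: ``best_``, ``fits_`` (per-family FamilyFit),
    ``failures_`` (family -> error message).
    """

    def __init__(self, allow_small: bool = False):
        self.allow_small = allow_small

    def fit(self, X, y=None):
        fits, failures = {}, {}
        for family in FAMILY_ORDER:
            try:
                fits[family] = fit_family(X, family, allow_small=self.allow_small)
            except FitError as exc:
                failures[family] = str(exc)
        if not fits:
            raise FitError(f"all candidate fits failed: {failures}")
        best = None
        for family in FAMILY_ORDER:
            f = fits.get(family)
            if f is not None and (best is None or f.loglik > best.loglik):
                best = f
        self.fits_ = fits
        self.failures_ = failures
        self.best_ = best
        return self


def select_best_family(samples, allow_small: bool = False) -> FamilyFit:
    """The winning FamilyFit among the five candidates."""
    return FamilySelector(allow_small=allow_small).fit(samples).best_


def _gamma_fisher_cov(a: float, b: float, n: int) -> np.ndarray:
    """Asymptotic covariance of the Gamma MLE (inverse Fisher information)."""
    info = np.array([[polygamma(1, a), 1.0 / b], [1.0 / b, a / b**2]])
    return np.linalg.inv(info) / n


class GammaSignatureEstimator(BaseEstimator):
    """MLE Gamma signature of a positive sample, sklearn-style.

    ``fit(X)`` takes a 1-D array of positive values and exposes::

        shape_, scale_        MLE point estimates
        ci95_shape_, ci95_scale_   95% CIs (asymptotic normal on the log
                                   parameters, delta method)
        mean_, variance_, skewness_   closed-form Gamma moments
        n_, loglik_

    Parameters
    ----------
    allow_small : bool
        Override the 100-sample minimum (toy data only).
    """

    def __init__(self, allow_small: bool = False):
        self.allow_small = allow_small

    def fit(self, X, y=None):
        fit = fit_family(X, "gamma", allow_small=self.allow_small)
        a, b = fit.params["shape"], fit.params["scale"]
        cov = _gamma_fisher_cov(a, b, fit.n)
        z = stats.norm.ppf(0.975)
        sd_log_a = np.sqrt(cov[0, 0]) / a
        sd_log_b = np.sqrt(cov[1, 1]) / b
        self.shape_ = float(a)
        self.scale_ = float(b)
        self.ci95_shape_ = (float(a * np.exp(-z * sd_log_a)),
                            float(a * np.exp(z * sd_log_a)))
        self.ci95_scale_ = (float(b * np.exp(-z * sd_log_b)),
                            float(b * np.exp(z * sd_log_b)))
        self.mean_ = float(a * b)
        self.variance_ = float(a * b**2)
        self.skewness_ = float(2.0 / np.sqrt(a))
        self.n_ = fit.n
        self.loglik_ = fit.loglik
        return self

    def signature(self, context=None) -> GammaSignature:
        return GammaSignature(
            shape=self.shape_,
            scale=self.scale_,
            ci95_shape=self.ci95_shape_,
            ci95_scale=self.ci95_scale_,
            n=self.n_,
            mean=self.mean_,
            variance=self.variance_,
            skewness=self.skewness_,
            loglik=self.loglik_,
            context=dict(context or {}),
        )


def gamma_signature(samples, context=None, allow_small: bool = False) -> GammaSignature:
    """MLE Gamma signature with 95% CIs and moments for one context cell."""
    est = GammaSignatureEstimator(allow_small=allow_small).fit(samples)
    return est.signature(context=context)


def _points_from(signatures) -> np.ndarray:
    pts = []
    for s in signatures:
        if isinstance(s, GammaSignature):
            pts.append((s.shape, s.scale))
        else:
            pts.append((float(s[0]), float(s[1])))
    return np.asarray(pts, dtype=float)


class LogLogLine(BaseEstimator):
    """OLS line through (log10 shape, log10 scale) signature points.

    Fitted attributes: ``slope_``, ``intercept_``, ``deltas_`` (per-point
    absolute vertical residuals, the goodness-of-linear-fit feature).
    """

    def fit(self, X, y=None):
        pts = _points_from(X)
        if len(pts) < 2:
            raise FitError("need at least 2 signature points")
        if np.all(np.all(pts == pts[0], axis=1)):
            raise FitError("all signature points are identical")
        lx = np.log10(pts[:, 0])
        ly = np.log10(pts[:, 1])
        if np.ptp(lx) == 0.0:
            raise FitError("log-shape values are all identical; line is vertical")
        slope, intercept = np.polyfit(lx, ly, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.deltas_ = np.abs(ly - (slope * lx + intercept))
        return self

    def predict(self, shapes) -> np.ndarray:
        """Predicted log10 scale at the given shape values."""
        return self.slope_ * np.log10(np.asarray(shapes, dtype=float)) + self.intercept_


@dataclass(frozen=True)
class LogLogFit:
    slope: float
    intercept: float
    deltas: np.ndarray


def loglog_line_fit(signatures) -> LogLogFit:
    """Slope/intercept/deltas of the log-log Gamma-plane line."""
    est = LogLogLine().fit(signatures)
    return LogLogFit(slope=est.slope_, intercept=est.intercept_, deltas=est.deltas_)


__all__ = [
    "FamilyFit",
    "FamilySelector",
    "FitError",
    "GammaSignature",
    "GammaSignatureEstimator",
    "LogLogFit",
    "LogLogLine",
    "FAMILY_ORDER",
    "MIN_SAMPLES",
    "fit_family",
    "select_best_family",
    "gamma_signature",
    "loglog_line_fit",
]
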