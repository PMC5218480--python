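"""Median-effect and four-parameter-logistic dose-response models.

The median-effect equation of the mass-action law,

    fa / fu = (D / Dm)^m,

relates the fraction of cells affected ``fa`` (and its complement
``fu = 1 - fa``) to the dose ``D`` through two parameters: the
median-effect dose ``Dm`` (the dose producing a half-maximal effect,
i.e. the IC50 under this model) and the slope ``m`` describing the
sigmoidicity of the curve.  Taking log10 of both sides linearises the
model::

    log10(fa/fu) = m * log10(D) - m * log10(Dm)

so ``m`` and ``Dm`` are obtained by ordinary least squares on the
"median-effect plot".  These single-agent fits are the substrate for
combination-index synergy scoring (see :mod:`synergykit.synergy`).

A four-parameter logistic (4PL) fit is provided as the conventional
alternative IC50 estimate for monotherapy viability curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseError",
    "InvalidControlError",
    "DegenerateDesignError",
    "FitFailureError",
    "FractionAffected",
    "MedianEffectFit",
    "LogisticFit",
    "normalize_to_fraction_affected",
    "fit_median_effect",
    "predict_effect",
    "dose_for_effect",
    "fit_logistic_ic50",
]

DEFAULT_CLIP_EPSILON = 0.005


class DoseResponseError(ValueError):
    """Base class for dose-response modelling errors."""


class InvalidControlError(DoseResponseError):
    """The vehicle-control signal is non-positive."""


class DegenerateDesignError(DoseResponseError):
    """The dose design cannot identify the model (e.g. a single dose)."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge; carries diagnostics in ``args``."""


@dataclass(frozen=True)
class FractionAffected:
    """Fraction affected / unaffected derived from a raw viability signal.

    ``fa`` is clipped into ``[epsilon, 1 - epsilon]`` because the
    median-effect plot is undefined at 0 and 1; ``clipped`` marks which
    entries were moved.
    """

    fa: np.ndarray
    fu: np.ndarray
    clipped: np.ndarray

    @property
    def n_clipped(self) -> int:
        return int(np.count_nonzero(self.clipped))


@dataclass(frozen=True)
class MedianEffectFit:
    """Parameters of a median-effect fit for one drug in one sample.

    ``m`` is the median-effect slope, ``dm`` the median-effect dose in
    the same concentration units as the input doses (here uM), ``r``
    the linear correlation coefficient of the median-effect plot, and
    ``n_points`` the number of (averaged) points entering the
    regression.  ``flagged_non_monotone`` is set when the fitted slope
    is non-positive: such fits are returned (screening data contain
    non-responders) but must not be used for dose interpolation.
    """

    m: float
    dm: float
    r: float
    n_points: int
    flagged_non_monotone: bool = False

    @property
    def is_usable(self) -> bool:
        return not self.flagged_non_monotone and np.isfinite(self.dm) and self.dm > 0


@dataclass(frozen=True)
class LogisticFit:
    """Four-parameter logistic fit: response = bottom + (top-bottom)/(1+(D/ic50)^hill)."""

    ic50: float
    hill: float
    top: float
    bottom: float


def normalize_to_fraction_affected(
    raw_signal,
    vehicle_mean: float,
    epsilon: float = DEFAULT_CLIP_EPSILON,
) -> FractionAffected:
    """Convert a raw viability signal to fraction affected.

    ``fa = 1 - raw/vehicle_mean`` clipped into ``[epsilon, 1-epsilon]``.
    Accepts a scalar or an array of raw signals.  Values outside the
    open unit interval (no effect, or growth stimulation above the
    vehicle control) are clipped and logged.
    """
    if not np.isfinite(vehicle_mean) or vehicle_mean <= 0:
        raise InvalidControlError(f"vehicle mean must be positive, got {vehicle_mean!r}")
    if not 0 < epsilon <= 0.05:
        raise ValueError(f"epsilon must be in (0, 0.05], got {epsilon!r}")
    raw = np.atleast_1d(np.asarray(raw_signal, dtype=float))
    fa = 1.0 - raw / vehicle_mean
    clipped = (fa < epsilon) | (fa > 1.0 - epsilon)
    if clipped.any():
        logger.info("clipped %d/%d fraction-affected values to [%g, %g]",
                    int(clipped.sum()), fa.size, epsilon, 1.0 - epsilon)
    fa = np.clip(fa, epsilon, 1.0 - epsilon)
    return FractionAffected(fa=fa, fu=1.0 - fa, clipped=clipped)


def _average_replicates(doses: np.ndarray, fa: np.ndarray):
    """Average fa over identical doses (replicate wells share a dose grid)."""
    uniq, inv = np.unique(doses, return_inverse=True)
    mean_fa = np.zeros_like(uniq)
    counts = np.bincount(inv, minlength=uniq.size)
    np.add.at(mean_fa, inv, fa)
    return uniq, mean_fa / counts


def fit_median_effect(
    doses: Sequence[float],
    fa: Sequence[float],
    *,
    average_replicates: bool = True,
) -> MedianEffectFit:
    """Fit the median-effect model by OLS on the median-effect plot.

    Parameters
    ----------
    doses, fa
        Paired doses (strictly positive) and fractions affected (open
        unit interval).  Replicates at identical doses are averaged
        before the regression unless ``average_replicates=False``.

    Returns
    -------
    MedianEffectFit
        With ``m`` the slope and ``dm = 10**(-intercept/m)``.  A
        non-positive slope is flagged, not raised.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if d.shape != f.shape:
        raise ValueError("doses and fa must have the same shape")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("fraction affected must lie in the open interval (0, 1); "
                         "clip raw signals with normalize_to_fraction_affected first")
    if average_replicates:
        d, f = _average_replicates(d, f)
    if np.unique(d).size < 2:
        raise DegenerateDesignError("median-effect fit needs >= 2 distinct doses")

    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    res = stats.linregress(x, y)
    m = float(res.slope)
    flagged = m <= 0
    if flagged:
        logger.warning("median-effect fit has non-positive slope m=%.4g; "
                       "flagging as non-monotone", m)
        dm = float("nan")
    else:
        dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(m=m, dm=dm, r=float(res.rvalue), n_points=int(d.size),
                           flagged_non_monotone=flagged)


def predict_effect(fit: MedianEffectFit, dose) -> np.ndarray | float:
    """Fraction affected at ``dose``: fa = 1 / (1 + (Dm/D)^m).

    Strictly increasing in dose for ``m > 0``; ``predict_effect(fit, Dm) == 0.5``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be strictly positive")
    if not fit.is_usable:
        raise ValueError("fit is flagged non-monotone; effect prediction undefined")
    out = 1.0 / (1.0 + (fit.dm / d) ** fit.m)
    return float(out) if np.isscalar(dose) else out


def dose_for_effect(fit: MedianEffectFit, fa) -> np.ndarray | float:
    """Dose producing effect level ``fa``: Dx = Dm * (fa/(1-fa))^(1/m).

    The exact inverse of :func:`predict_effect`; ``dose_for_effect(fit, 0.5) == Dm``.
    """
    f = np.asarray(fa, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("fa must lie in the open interval (0, 1)")
    if not fit.is_usable:
        raise ValueError("fit is flagged non-monotone; dose interpolation undefined")
    out = fit.dm * (f / (1.0 - f)) ** (1.0 / fit.m)
    return float(out) if np.isscalar(fa) else out


def _four_pl(d, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def fit_logistic_ic50(doses: Sequence[float], responses: Sequence[float]) -> LogisticFit:
    """Fit a four-parameter logistic to a (decreasing) viability curve.

    Nonlinear least squares of ``bottom + (top-bottom)/(1+(D/ic50)^hill)``
    with ``hill > 0`` (response falls with dose).  Raises
    :class:`FitFailureError` on non-convergence or degenerate input
    (e.g. a constant response).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size < 4:
        raise DegenerateDesignError("4PL fit needs >= 4 points")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if np.ptp(y) < 1e-9:
        raise FitFailureError("constant response: 4PL parameters unidentifiable")

    top0, bottom0 = float(np.max(y)), float(np.min(y))
    mid = 0.5 * (top0 + bottom0)
    # initial ic50: dose whose response is closest to the midpoint
    ic50_0 = float(d[np.argmin(np.abs(y - mid))])
    p0 = [top0, bottom0, ic50_0, 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, d, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 50.0]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover - rare
        raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, ic50, hill = (float(v) for v in popt)
    if bottom > top:
        raise FitFailureError(
            f"4PL fit implies response increasing with dose (top={top:.4g} < "
            f"bottom={bottom:.4g}); not a viability inhibition curve")
    return LogisticFit(ic50=ic50, hill=hill, top=top, bottom=bottom)
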