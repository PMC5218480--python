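"""Tumor time-to-endpoint (TTE) derivation and survival comparison.

Xenograft efficacy studies track subcutaneous tumor volume
(``width^2 x length / 2``, mm^3) twice weekly and euthanise each animal
when its tumor reaches an endpoint volume (2000 mm^3 by default).  The
study endpoint for survival analysis is not the (coarse) day of the
triggering measurement but a fractional **time to endpoint** obtained
by regressing log10(volume) on study day over a short window around the
endpoint crossing: the first observation exceeding the endpoint volume
and up to the three observations immediately preceding it.  The TTE is
the day at which the fitted line crosses log10(endpoint volume).  When
the regression extrapolates outside the bracketing observations (or is
degenerate), log-linear interpolation between the bracketing
observations is used instead.

Animals that die of treatment-related causes are events at their death
day; non-treatment-related deaths are excluded; animals below endpoint
at study end are censored at the last study day (day 34 by default).

Kaplan-Meier estimation and the log-rank (Mantel-Cox) test are
delegated to :mod:`lifelines`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FATE_KINDS",
    "AnimalFate",
    "TumorVolumeSeries",
    "TTEOutcome",
    "KaplanMeierSummary",
    "LogRankResult",
    "compute_tte",
    "km_curve_and_median",
    "logrank_test",
    "tte_table",
]

DEFAULT_ENDPOINT_MM3 = 2000.0
DEFAULT_LAST_DAY = 34.0

FATE_KINDS = ("reached_endpoint", "treatment_death", "nontreatment_death",
              "survived_to_end")


@dataclass(frozen=True)
class AnimalFate:
    """Outcome annotation for one animal; ``day`` required for deaths."""

    kind: str
    day: Optional[float] = None

    def __post_init__(self):
        if self.kind not in FATE_KINDS:
            raise ValueError(f"unknown fate kind {self.kind!r}; expected one of {FATE_KINDS}")
        if self.kind.endswith("death") and self.day is None:
            raise ValueError(f"fate {self.kind!r} requires a death day")


@dataclass(frozen=True)
class TumorVolumeSeries:
    """One animal's tumor-volume trajectory.

    ``days`` strictly increasing, ``volumes`` positive (mm^3).  ``fate``
    may be omitted, in which case it is inferred from the data: endpoint
    reached if any observation attains the endpoint volume, otherwise
    survived to study end.
    """

    animal_id: str
    group: str
    days: np.ndarray
    volumes: np.ndarray
    fate: Optional[AnimalFate] = None

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)
        if days.size != vols.size or days.size == 0:
            raise ValueError("days and volumes must be equal-length and non-empty")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(vols <= 0):
            raise ValueError("volumes must be positive")


@dataclass(frozen=True)
class TTEOutcome:
    """Derived time-to-endpoint for one animal.

    ``event`` is True when the endpoint (or a treatment-related death)
    was reached; censored animals carry ``event=False`` with
    ``tte = last_day``.  Excluded animals (non-treatment deaths) carry
    no usable ``tte``.
    """

    animal_id: str
    group: str
    tte: float
    event: bool
    excluded: bool
    method: str  # regression | interpolation | assigned_death_day | assigned_last_day | excluded


@dataclass(frozen=True)
class KaplanMeierSummary:
    times: np.ndarray
    survival: np.ndarray
    median_km: float          # first time S(t) <= 0.5; inf if never reached
    median_plain: float       # plain median of the TTE values
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median_km)


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    groups: tuple


def _interpolate_crossing(days, log_vols, log_endpoint, lo, hi) -> float:
    """Linear interpolation of log10(volume) in time between indices lo < hi."""
    d0, d1 = days[lo], days[hi]
    y0, y1 = log_vols[lo], log_vols[hi]
    if y1 == y0:
        return float(d1)
    return float(d0 + (log_endpoint - y0) / (y1 - y0) * (d1 - d0))


def compute_tte(
    series: TumorVolumeSeries,
    endpoint_volume: float = DEFAULT_ENDPOINT_MM3,
    last_day: float = DEFAULT_LAST_DAY,
) -> TTEOutcome:
    """Derive the time to endpoint for one animal.

    For an animal that attains the endpoint volume, log10(volume) is
    regressed on day over the window consisting of the first
    observation strictly exceeding the endpoint (or the equality point
    if none exceeds) plus up to three immediately preceding
    observations; ``tte = (log10(endpoint) - intercept) / slope``.  The
    regression estimate is accepted only when it falls within the
    bracketing observation days; otherwise (or when the window is
    degenerate or has non-positive slope) a log-linear interpolation
    between the bracketing observations is used.
    """
    fate = series.fate
    if fate is not None and fate.kind == "nontreatment_death":
        logger.info("animal %s excluded (non-treatment-related death on day %s)",
                    series.animal_id, fate.day)
        return TTEOutcome(series.animal_id, series.group, tte=math.nan,
                          event=False, excluded=True, method="excluded")
    if fate is not None and fate.kind == "treatment_death":
        return TTEOutcome(series.animal_id, series.group, tte=float(fate.day),
                          event=True, excluded=False, method="assigned_death_day")

    days, vols = series.days, series.volumes
    attained = np.flatnonzero(vols >= endpoint_volume)
    if fate is not None and fate.kind == "survived_to_end":
        return TTEOutcome(series.animal_id, series.group, tte=float(last_day),
                          event=False, excluded=False, method="assigned_last_day")
    if attained.size == 0:
        if fate is not None and fate.kind == "reached_endpoint":
            raise ValueError(f"animal {series.animal_id} annotated reached_endpoint "
                             f"but no observation attains {endpoint_volume} mm^3")
        return TTEOutcome(series.animal_id, series.group, tte=float(last_day),
                          event=False, excluded=False, method="assigned_last_day")

    idx_att = int(attained[0])
    exceeding = np.flatnonzero(vols > endpoint_volume)
    idx_anchor = int(exceeding[0]) if exceeding.size else idx_att

    log_vols = np.log10(vols)
    log_e = math.log10(endpoint_volume)

    if idx_att == 0:
        # endpoint already attained at the first observation: no bracketing
        # window exists, so the attainment day itself is the best estimate.
        return TTEOutcome(series.animal_id, series.group, tte=float(days[0]),
                          event=True, excluded=False, method="interpolation")

    lo_bracket, hi_bracket = idx_att - 1, idx_att
    win = slice(max(0, idx_anchor - 3), idx_anchor + 1)
    wdays, wlogv = days[win], log_vols[win]

    tte = None
    method = "regression"
    if np.unique(wdays).size >= 2:
        res = stats.linregress(wdays, wlogv)
        if res.slope > 0:
            cand = (log_e - res.intercept) / res.slope
            if days[lo_bracket] <= cand <= days[hi_bracket]:
                tte = float(cand)
            else:
                logger.info("animal %s: regression TTE %.3f outside bracketing days "
                            "[%g, %g]; interpolating", series.animal_id, cand,
                            days[lo_bracket], days[hi_bracket])
        else:
            logger.info("animal %s: non-positive slope in regression window; "
                        "interpolating", series.animal_id)
    if tte is None:
        tte = _interpolate_crossing(days, log_vols, log_e, lo_bracket, hi_bracket)
        method = "interpolation"
    return TTEOutcome(series.animal_id, series.group, tte=tte,
                      event=True, excluded=False, method=method)


def _usable(outcomes: Iterable[TTEOutcome]):
    out = [o for o in outcomes if not o.excluded]
    if not out:
        raise ValueError("no non-excluded outcomes")
    return out


def km_curve_and_median(outcomes: Sequence[TTEOutcome]) -> KaplanMeierSummary:
    """Kaplan-Meier curve and median survival for one group.

    The KM median follows the convention "smallest time with survival
    <= 0.5" (``inf`` when the curve never drops that far); the plain
    median of the TTE values is reported alongside, since published
    group medians may follow either convention.
    """
    usable = _usable(outcomes)
    times = np.array([o.tte for o in usable])
    events = np.array([o.event for o in usable], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KaplanMeierSummary(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median_km=float(kmf.median_survival_time_),
        median_plain=float(np.median(times)),
        n=len(usable),
        n_events=int(events.sum()),
    )


def logrank_test(
    group_a: Sequence[TTEOutcome],
    group_b: Sequence[TTEOutcome],
) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test on TTE outcomes.

    Chi-square statistic with 1 df; requires at least one event overall.
    """
    a = _usable(group_a)
    b = _usable(group_b)
    n_events = sum(o.event for o in a) + sum(o.event for o in b)
    if n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(
        np.array([o.tte for o in a]), np.array([o.tte for o in b]),
        event_observed_A=np.array([o.event for o in a], dtype=bool),
        event_observed_B=np.array([o.event for o in b], dtype=bool),
    )
    groups = (a[0].group or "A", b[0].group or "B")
    return LogRankResult(chi_square=float(res.test_statistic),
                         p_value=float(res.p_value), groups=groups)


def tte_table(outcomes: Iterable[TTEOutcome]) -> pd.DataFrame:
    """Per-animal TTE table (one row per animal, including exclusions)."""
    return pd.DataFrame(
        [{"animal_id": o.animal_id, "group": o.group, "tte": o.tte,
          "event": o.event, "excluded": o.excluded, "method": o.method}
         for o in outcomes]
    )
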