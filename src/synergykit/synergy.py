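"""Chou-Talalay combination-index synergy scoring.

The combination index (CI) quantifies departure from Loewe additivity
for a dosed drug pair producing an observed effect level ``fa``::

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where ``Dxj(fa)`` is the dose of drug *j* that alone produces effect
``fa`` (from that drug's median-effect fit).  CI < 1 indicates
synergism, CI = 1 additivity, CI > 1 antagonism.

Two experimental designs are supported:

* **constant-ratio** series (cell lines): the two drugs are co-dosed at
  a fixed dose ratio (typically IC50:IC50) across a dilution series.
  CIs are reported both per measured point (at its observed fa) and at
  standard effect levels (ED50/75/90) via a median-effect fit to the
  combination series itself.
* **checkerboard** grids (patient samples): arbitrary fixed dose pairs;
  each point gets a CI at its observed fa and the sample is summarised
  by the median CI, with cohort-level counting of samples whose median
  CI falls below 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dose_response import MedianEffectFit, dose_for_effect, fit_median_effect

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationMeasurement",
    "CIResult",
    "SampleSynergySummary",
    "ConstantRatioProfile",
    "CohortSynergy",
    "MixedRatioError",
    "combination_index_at_point",
    "constant_ratio_ci_profile",
    "checkerboard_ci",
    "cohort_synergy_fraction",
    "classify_ci",
]

DEFAULT_FA_LEVELS = (0.5, 0.75, 0.9)


class MixedRatioError(ValueError):
    """A constant-ratio analysis was requested on points with mixed dose ratios."""


@dataclass(frozen=True)
class CombinationMeasurement:
    """One dosed combination point with its observed fraction affected."""

    dose_1: float
    dose_2: float
    fa_observed: float

    def __post_init__(self):
        if self.dose_1 < 0 or self.dose_2 < 0 or (self.dose_1 == 0 and self.dose_2 == 0):
            raise ValueError("doses must be non-negative and not both zero")
        if not 0 < self.fa_observed < 1:
            raise ValueError("fa_observed must lie in (0, 1); clip first")


@dataclass(frozen=True)
class CIResult:
    """Combination index at one effect level for one dose pair."""

    ci: float
    fa_at: float
    dose_1: float
    dose_2: float
    dx_1: float
    dx_2: float
    evaluable: bool = True
    reason: str = ""


@dataclass(frozen=True)
class SampleSynergySummary:
    """Per-sample checkerboard summary: the median of the per-point CIs."""

    sample_id: str
    ci_values: tuple
    median_ci: float
    n_valid: int
    evaluable: bool


@dataclass(frozen=True)
class ConstantRatioProfile:
    """CI profile of a constant-ratio combination series."""

    level_results: tuple          # CIs at requested fa levels (via the combo fit)
    point_results: tuple          # CIs at each point's observed fa
    combination_fit: MedianEffectFit
    dose_1_fraction: float        # d1 / (d1 + d2), constant across the series
    mean_ci_levels: float
    mean_ci_points: float


@dataclass(frozen=True)
class CohortSynergy:
    n_samples: int
    n_synergistic: int

    @property
    def fraction(self) -> float:
        return self.n_synergistic / self.n_samples


def classify_ci(ci: float, band: float = 0.0) -> str:
    """Classify a CI as synergistic / additive / antagonistic.

    Strict thresholds by default (CI < 1 synergism, CI > 1 antagonism);
    ``band`` widens the additive zone to ``1 +/- band``.
    """
    if ci < 1.0 - band:
        return "synergistic"
    if ci > 1.0 + band:
        return "antagonistic"
    return "additive"


def combination_index_at_point(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    point: CombinationMeasurement,
) -> CIResult:
    """CI at the point's observed effect level.

    ``dxj = Dxj(fa_observed)`` from each monotherapy fit; a drug dosed
    at zero contributes nothing to the index (monotherapy limit).
    Points whose monotherapy fit is flagged non-monotone are returned
    marked unevaluable rather than raising.
    """
    for j, fit in ((1, fit_1), (2, fit_2)):
        dose = point.dose_1 if j == 1 else point.dose_2
        if dose > 0 and not fit.is_usable:
            return CIResult(ci=math.nan, fa_at=point.fa_observed,
                            dose_1=point.dose_1, dose_2=point.dose_2,
                            dx_1=math.nan, dx_2=math.nan, evaluable=False,
                            reason=f"monotherapy fit for drug {j} flagged non-monotone")
    dx_1 = dose_for_effect(fit_1, point.fa_observed) if fit_1.is_usable else math.nan
    dx_2 = dose_for_effect(fit_2, point.fa_observed) if fit_2.is_usable else math.nan
    ci = 0.0
    if point.dose_1 > 0:
        ci += point.dose_1 / dx_1
    if point.dose_2 > 0:
        ci += point.dose_2 / dx_2
    return CIResult(ci=float(ci), fa_at=point.fa_observed,
                    dose_1=point.dose_1, dose_2=point.dose_2,
                    dx_1=float(dx_1), dx_2=float(dx_2))


def _dose_1_fraction(points: Sequence[CombinationMeasurement]) -> float:
    """Check the series is constant-ratio and return d1/(d1+d2).

    The ratio is expressed as the drug-1 dose fraction of the total so
    that pure-monotherapy series (one dose identically zero) are valid
    constant-ratio designs.
    """
    fracs = np.array([p.dose_1 / (p.dose_1 + p.dose_2) for p in points])
    if np.ptp(fracs) > 0.01:
        raise MixedRatioError(
            f"combination points do not share a dose ratio (drug-1 fractions span "
            f"{fracs.min():.4f}..{fracs.max():.4f})")
    return float(fracs.mean())


def constant_ratio_ci_profile(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    combo_points: Sequence[CombinationMeasurement],
    fa_levels: Iterable[float] = DEFAULT_FA_LEVELS,
) -> ConstantRatioProfile:
    """CI profile for a constant-ratio combination series.

    The combination series (total dose vs fa) is itself fitted with the
    median-effect model; at each requested ``fa`` level the total
    combination dose achieving it is split by the design ratio and the
    CI computed.  Per-point CIs at observed fa are returned alongside.
    """
    if len(combo_points) < 2:
        raise ValueError("constant-ratio profile needs >= 2 combination points")
    f1 = _dose_1_fraction(combo_points)
    f2 = 1.0 - f1

    total = np.array([p.dose_1 + p.dose_2 for p in combo_points])
    fa_obs = np.array([p.fa_observed for p in combo_points])
    combo_fit = fit_median_effect(total, fa_obs)

    point_results = tuple(combination_index_at_point(fit_1, fit_2, p)
                          for p in combo_points)

    level_results = []
    for fa in fa_levels:
        d_total = dose_for_effect(combo_fit, fa)
        level_results.append(combination_index_at_point(
            fit_1, fit_2,
            CombinationMeasurement(dose_1=f1 * d_total, dose_2=f2 * d_total,
                                   fa_observed=fa)))
    level_results = tuple(level_results)

    def _mean(results):
        vals = [r.ci for r in results if r.evaluable]
        return float(np.mean(vals)) if vals else math.nan

    return ConstantRatioProfile(
        level_results=level_results, point_results=point_results,
        combination_fit=combo_fit, dose_1_fraction=f1,
        mean_ci_levels=_mean(level_results), mean_ci_points=_mean(point_results))


def checkerboard_ci(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    points: Sequence[CombinationMeasurement],
    sample_id: str = "",
) -> SampleSynergySummary:
    """Per-point CIs for a fixed-dose grid, summarised by their median.

    Unevaluable points (flagged monotherapy fits) are excluded from the
    median and logged; the summary is marked unevaluable only when no
    valid CI remains.
    """
    if not points:
        raise ValueError("checkerboard needs >= 1 combination point")
    results = tuple(combination_index_at_point(fit_1, fit_2, p) for p in points)
    valid = [r.ci for r in results if r.evaluable]
    n_dropped = len(results) - len(valid)
    if n_dropped:
        logger.info("sample %s: %d/%d combination points unevaluable, excluded "
                    "from median CI", sample_id, n_dropped, len(results))
    if not valid:
        return SampleSynergySummary(sample_id=sample_id, ci_values=results,
                                    median_ci=math.nan, n_valid=0, evaluable=False)
    return SampleSynergySummary(sample_id=sample_id, ci_values=results,
                                median_ci=float(np.median(valid)),
                                n_valid=len(valid), evaluable=True)


def cohort_synergy_fraction(summaries: Iterable[SampleSynergySummary]) -> CohortSynergy:
    """Count of samples with median CI strictly below 1 across a cohort."""
    evaluable = [s for s in summaries if s.evaluable]
    if not evaluable:
        raise ValueError("no evaluable samples in cohort")
    n_syn = sum(1 for s in evaluable if s.median_ci < 1.0)
    return CohortSynergy(n_samples=len(evaluable), n_synergistic=n_syn)
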