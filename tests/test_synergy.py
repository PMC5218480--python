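"""Combination-index scoring: Loewe oracle, invariances, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergykit import (CombinationMeasurement, MedianEffectFit,
                        MixedRatioError, SimulationConfig, checkerboard_ci,
                        classify_ci, cohort_synergy_fraction,
                        combination_index_at_point, constant_ratio_ci_profile,
                        dose_for_effect, simulate_combination)
from synergykit.synergy import SampleSynergySummary
from conftest import exact_fit


def loewe_point(fit_1, fit_2, fa, ci, frac_1=0.5):
    """Construct the dose pair at drug-1 dose-fraction ``frac_1`` whose
    Loewe sum d1/Dx1 + d2/Dx2 equals ``ci`` at effect ``fa``."""
    dx1, dx2 = dose_for_effect(fit_1, fa), dose_for_effect(fit_2, fa)
    total = ci / (frac_1 / dx1 + (1 - frac_1) / dx2)
    return CombinationMeasurement(frac_1 * total, (1 - frac_1) * total, fa)


class TestCombinationIndexAtPoint:
    def test_additive_point_worked_example(self):
        f1, f2 = exact_fit(1.0, 1.0), exact_fit(1.0, 2.0)
        res = combination_index_at_point(f1, f2,
                                         CombinationMeasurement(0.5, 1.0, 0.5))
        assert (res.dx_1, res.dx_2) == pytest.approx((1.0, 2.0))
        assert res.ci == pytest.approx(1.0)

    def test_synergistic_point_worked_example(self):
        f1, f2 = exact_fit(1.0, 1.0), exact_fit(1.0, 2.0)
        res = combination_index_at_point(
            f1, f2, CombinationMeasurement(0.5, 1.0, 2.0 / 3.0))
        assert (res.dx_1, res.dx_2) == pytest.approx((2.0, 4.0))
        assert res.ci == pytest.approx(0.5)

    def test_monotherapy_limit(self):
        f1, f2 = exact_fit(1.0, 1.0), exact_fit(1.0, 2.0)
        res = combination_index_at_point(f1, f2,
                                         CombinationMeasurement(2.0, 0.0, 0.5))
        assert res.ci == pytest.approx(2.0 / 1.0)

    def test_flagged_fit_gives_unevaluable(self):
        bad = MedianEffectFit(m=-0.5, dm=float("nan"), r=0.1, n_points=5,
                              flagged_non_monotone=True)
        res = combination_index_at_point(bad, exact_fit(1, 1),
                                         CombinationMeasurement(1.0, 1.0, 0.5))
        assert not res.evaluable

    @given(m1=st.floats(0.5, 3.5), m2=st.floats(0.5, 3.5),
           dm1=st.floats(0.1, 50.0), dm2=st.floats(0.1, 50.0),
           fa=st.floats(0.05, 0.95), ci=st.floats(0.2, 3.0),
           frac=st.floats(0.05, 0.95))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_loewe_construction_recovered_exactly(self, m1, m2, dm1, dm2,
                                                  fa, ci, frac):
        """Any dose pair built to have Loewe sum c at effect fa scores CI = c."""
        f1, f2 = exact_fit(m1, dm1), exact_fit(m2, dm2)
        res = combination_index_at_point(f1, f2, loewe_point(f1, f2, fa, ci, frac))
        assert res.ci == pytest.approx(ci, rel=1e-9)

    def test_scale_invariance_in_drug_units(self):
        """Rescaling one drug's doses (data and fit together) leaves CI fixed."""
        f1, f2 = exact_fit(1.3, 2.0), exact_fit(0.9, 5.0)
        pt = loewe_point(f1, f2, 0.7, 0.8)
        k = 1000.0  # e.g. uM -> nM for drug 1
        f1_scaled = exact_fit(1.3, 2.0 * k)
        pt_scaled = CombinationMeasurement(pt.dose_1 * k, pt.dose_2, pt.fa_observed)
        a = combination_index_at_point(f1, f2, pt)
        b = combination_index_at_point(f1_scaled, f2, pt_scaled)
        assert a.ci == pytest.approx(b.ci, rel=1e-12)

    def test_symmetry_under_drug_relabeling(self):
        f1, f2 = exact_fit(1.3, 2.0), exact_fit(0.9, 5.0)
        pt = CombinationMeasurement(1.0, 2.5, 0.6)
        swapped = CombinationMeasurement(2.5, 1.0, 0.6)
        assert combination_index_at_point(f1, f2, pt).ci == pytest.approx(
            combination_index_at_point(f2, f1, swapped).ci)

    def test_ci_decreasing_in_observed_effect(self):
        f1, f2 = exact_fit(1.5, 1.0), exact_fit(2.0, 3.0)
        fas = np.linspace(0.1, 0.9, 17)
        cis = [combination_index_at_point(
            f1, f2, CombinationMeasurement(1.0, 1.0, fa)).ci for fa in fas]
        assert np.all(np.diff(cis) < 0)


class TestConstantRatioProfile:
    def test_additive_series_equal_slopes_exact_at_all_levels(self):
        """With equal slopes the additive mixture is itself median-effect,
        so the fitted profile recovers CI = 1 at every level to 1e-6."""
        f1, f2 = exact_fit(1.7, 1.2), exact_fit(1.7, 3.0)
        cfg = SimulationConfig(seed=0, response_cv=0.0, n_replicates=1)
        tab, _ = simulate_combination(cfg, f1, f2, true_ci=1.0)
        pts = [CombinationMeasurement(r.dose_1_uM, r.dose_2_uM, 1 - r.response)
               for r in tab.itertuples()]
        prof = constant_ratio_ci_profile(f1, f2, pts)
        for res in prof.level_results + prof.point_results:
            assert res.ci == pytest.approx(1.0, abs=1e-6)

    def test_noisy_synergy_recovered(self):
        """True CI = 0.5 recovered within 0.02 on average over 100 seeds."""
        f1, f2 = exact_fit(1.5, 1.0), exact_fit(1.5, 2.0)
        means = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, response_cv=0.05, n_replicates=3)
            tab, _ = simulate_combination(cfg, f1, f2, true_ci=0.5)
            mean_resp = tab.groupby(["dose_1_uM", "dose_2_uM"])["response"].mean()
            pts = [CombinationMeasurement(d1, d2, float(np.clip(1 - r, 0.005, 0.995)))
                   for (d1, d2), r in mean_resp.items()]
            means.append(constant_ratio_ci_profile(f1, f2, pts).mean_ci_points)
        assert np.mean(means) == pytest.approx(0.5, abs=0.02)

    def test_self_combination_is_additive(self):
        """A 'combination' that is drug 1 alone profiles at CI = 1."""
        f1, f2 = exact_fit(1.4, 2.0), exact_fit(1.0, 5.0)
        doses = 2.0 * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        pts = [CombinationMeasurement(d, 0.0, float(1 / (1 + (2.0 / d) ** 1.4)))
               for d in doses]
        prof = constant_ratio_ci_profile(f1, f2, pts)
        for res in prof.level_results:
            assert res.ci == pytest.approx(1.0, abs=1e-9)

    def test_mixed_ratios_rejected(self):
        f1, f2 = exact_fit(1, 1), exact_fit(1, 1)
        pts = [CombinationMeasurement(1.0, 1.0, 0.5),
               CombinationMeasurement(1.0, 3.0, 0.7)]
        with pytest.raises(MixedRatioError):
            constant_ratio_ci_profile(f1, f2, pts)


class TestCheckerboard:
    def test_median_of_eight(self):
        f1, f2 = exact_fit(1.0, 1.0), exact_fit(1.0, 1.0)
        targets = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        # build each point to carry exactly the target CI at fa = 0.5
        pts = [loewe_point(f1, f2, 0.5, c) for c in targets]
        summary = checkerboard_ci(f1, f2, pts, sample_id="s")
        assert summary.median_ci == pytest.approx(0.55)
        assert summary.n_valid == 8

    def test_all_additive_grid(self, rng):
        f1, f2 = exact_fit(1.6, 0.9), exact_fit(1.1, 2.2)
        pts = [loewe_point(f1, f2, fa, 1.0, frac)
               for fa, frac in zip(rng.uniform(0.1, 0.9, 8),
                                   rng.uniform(0.2, 0.8, 8))]
        summary = checkerboard_ci(f1, f2, pts)
        assert summary.median_ci == pytest.approx(1.0, abs=1e-9)

    def test_median_skips_unevaluable_points(self):
        good = exact_fit(1.0, 1.0)
        bad = MedianEffectFit(m=-1.0, dm=float("nan"), r=0.0, n_points=3,
                              flagged_non_monotone=True)
        pts_mono = [CombinationMeasurement(d, 0.0, 0.5) for d in (0.5, 1.0, 2.0)]
        pts_combo = [CombinationMeasurement(1.0, 1.0, 0.5)] * 5
        summary = checkerboard_ci(good, bad, pts_mono + pts_combo)
        assert summary.n_valid == 3
        assert summary.median_ci == pytest.approx(1.0)  # monotherapy d/Dx at fa=0.5


class TestCohort:
    @staticmethod
    def _summary(sid, median):
        return SampleSynergySummary(sample_id=sid, ci_values=(), median_ci=median,
                                    n_valid=8, evaluable=True)

    def test_printed_cohort_split(self):
        """22 of 30 samples below CI 1 gives the 73.3% synergy fraction."""
        medians = [0.5] * 22 + [1.2] * 8
        cohort = cohort_synergy_fraction(
            [self._summary(f"s{i}", m) for i, m in enumerate(medians)])
        assert (cohort.n_synergistic, cohort.n_samples) == (22, 30)
        assert cohort.fraction * 100 == pytest.approx(73.3, abs=0.05)

    def test_boundary_is_strict(self):
        cohort = cohort_synergy_fraction(
            [self._summary(f"s{i}", 1.0) for i in range(5)])
        assert cohort.fraction == 0.0

    def test_all_synergistic(self):
        cohort = cohort_synergy_fraction(
            [self._summary(f"s{i}", 0.8) for i in range(5)])
        assert cohort.fraction == 1.0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_synergy_fraction([])

    def test_classification_bands(self):
        assert classify_ci(0.9) == "synergistic"
        assert classify_ci(1.1) == "antagonistic"
        assert classify_ci(1.0) == "additive"
        assert classify_ci(1.05, band=0.1) == "additive"
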