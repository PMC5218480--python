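"""End-to-end analysis runners tying the stages together.

Each ``run_*`` function accepts either in-memory objects or file paths
(the formats of :mod:`synergykit.io`), applies the corresponding
analysis with the thresholds of a :class:`~synergykit.io.PipelineConfig`,
and returns a report dataclass of tidy DataFrames.  Passing ``outdir``
writes every table as CSV.  All outputs are deterministic given the
inputs and the config seed; every excluded or clipped record is logged
by the underlying stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as skio
from .dose_response import (MedianEffectFit, fit_median_effect,
                            normalize_to_fraction_affected)
from .expression import (CONDITIONS, ExpressionMatrix, GeneSet,
                         classify_combination_categories, collapse_to_symbols,
                         fold_changes, gsea_permutation_test,
                         rank_by_class_difference, threshold_gene_lists,
                         venn_counts, zscore_rows)
from .io import PipelineConfig
from .survival import (compute_tte, km_curve_and_median, logrank_test,
                       tte_table)
from .synergy import (CombinationMeasurement, SampleSynergySummary,
                      checkerboard_ci, classify_ci, cohort_synergy_fraction)
from .synthetic import (SimulationConfig, simulate_expression_experiment,
                        simulate_patient_cohort, simulate_tumor_growth_study)

logger = logging.getLogger(__name__)

__all__ = ["SynergyReport", "SurvivalReport", "ExpressionReport",
           "run_synergy", "run_survival", "run_expression", "run_simulate"]


def _maybe_write(df: pd.DataFrame, outdir, name: str) -> None:
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / name, index=False)


# ---------------------------------------------------------------------------
# synergy


@dataclass
class SynergyReport:
    per_point: pd.DataFrame     # one row per combination point with its CI
    per_sample: pd.DataFrame    # sample_id, median_ci, n_valid, classification
    cohort: "object"            # CohortSynergy
    fits: dict                  # sample_id -> (fit drug_1, fit drug_2)


def _fit_monotherapy(sub: pd.DataFrame, dose_col: str, epsilon: float) -> MedianEffectFit:
    mono = sub[(sub[dose_col] > 0)
               & (sub["dose_1_uM" if dose_col == "dose_2_uM" else "dose_2_uM"] == 0)]
    if mono.empty:
        raise ValueError(f"no monotherapy rows for {dose_col}")
    # average replicate responses per dose before fa conversion and fitting
    mean_resp = mono.groupby(dose_col)["response"].mean()
    fa = normalize_to_fraction_affected(mean_resp.to_numpy(), 1.0,
                                        epsilon=epsilon).fa
    return fit_median_effect(mean_resp.index.to_numpy(), fa,
                             average_replicates=False)


def run_synergy(
    combination_table: Union[pd.DataFrame, str, Path],
    config: Optional[PipelineConfig] = None,
    outdir=None,
) -> SynergyReport:
    """Checkerboard CI analysis of a (multi-sample) combination table.

    The table holds, per sample, monotherapy rows for each drug (partner
    dose 0) and combination rows.  Responses are viable fractions
    relative to vehicle; replicates are averaged per dose (pair) before
    fa conversion.  Produces per-point CIs, per-sample median CIs and
    the cohort fraction of samples with median CI < 1.
    """
    config = config or PipelineConfig()
    if not isinstance(combination_table, pd.DataFrame):
        combination_table = skio.read_combination_csv(combination_table)
    point_rows, sample_rows, fits = [], [], {}
    summaries = []
    for sid, sub in combination_table.groupby("sample_id", sort=True):
        fit_1 = _fit_monotherapy(sub, "dose_1_uM", config.clip_epsilon)
        fit_2 = _fit_monotherapy(sub, "dose_2_uM", config.clip_epsilon)
        fits[sid] = (fit_1, fit_2)
        combo = sub[(sub["dose_1_uM"] > 0) & (sub["dose_2_uM"] > 0)]
        if combo.empty:
            logger.warning("sample %s has no combination points; skipped", sid)
            continue
        mean_resp = (combo.groupby(["dose_1_uM", "dose_2_uM"])["response"]
                     .mean().reset_index())
        points = []
        for row in mean_resp.itertuples(index=False):
            fa = float(normalize_to_fraction_affected(
                row.response, 1.0, epsilon=config.clip_epsilon).fa[0])
            points.append(CombinationMeasurement(row.dose_1_uM, row.dose_2_uM, fa))
        summary = checkerboard_ci(fit_1, fit_2, points, sample_id=str(sid))
        summaries.append(summary)
        for r in summary.ci_values:
            point_rows.append({"sample_id": sid, "dose_1_uM": r.dose_1,
                               "dose_2_uM": r.dose_2, "fa": r.fa_at, "ci": r.ci,
                               "evaluable": r.evaluable, "reason": r.reason})
        sample_rows.append({"sample_id": sid, "median_ci": summary.median_ci,
                            "n_valid": summary.n_valid,
                            "classification": classify_ci(summary.median_ci)
                            if summary.evaluable else "unevaluable"})
    cohort = cohort_synergy_fraction(summaries)
    per_point = pd.DataFrame(point_rows)
    per_sample = pd.DataFrame(sample_rows)
    _maybe_write(per_point, outdir, "synergy_per_point.csv")
    _maybe_write(per_sample, outdir, "synergy_per_sample.csv")
    if outdir is not None:
        pd.DataFrame([{"n_samples": cohort.n_samples,
                       "n_synergistic": cohort.n_synergistic,
                       "fraction": cohort.fraction}]).to_csv(
            Path(outdir) / "synergy_cohort.csv", index=False)
    return SynergyReport(per_point=per_point, per_sample=per_sample,
                         cohort=cohort, fits=fits)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalReport:
    tte: pd.DataFrame          # per-animal TTE table
    medians: pd.DataFrame      # group, n, events, median_km, median_plain
    logrank: pd.DataFrame      # pairwise chi-square and p
    km: dict                   # group -> KaplanMeierSummary


def run_survival(
    volumes: Union[pd.DataFrame, str, Path],
    fates: Union[pd.DataFrame, str, Path, None] = None,
    config: Optional[PipelineConfig] = None,
    outdir=None,
) -> SurvivalReport:
    """Volume trajectories -> per-animal TTE -> KM medians and log-rank tests."""
    config = config or PipelineConfig()
    if not isinstance(volumes, pd.DataFrame):
        volumes = skio.read_tumor_volumes_csv(volumes)
    if fates is not None and not isinstance(fates, pd.DataFrame):
        fates = skio.read_animal_fates_csv(fates)
    series = skio.volume_series_from_tables(volumes, fates)
    outcomes = [compute_tte(s, endpoint_volume=config.endpoint_volume_mm3,
                            last_day=config.last_day) for s in series]
    table = tte_table(outcomes)

    by_group = {}
    for o in outcomes:
        by_group.setdefault(o.group, []).append(o)
    km, median_rows = {}, []
    for group in sorted(by_group):
        usable = [o for o in by_group[group] if not o.excluded]
        if not usable:
            logger.warning("group %s has no usable animals", group)
            continue
        summ = km_curve_and_median(usable)
        km[group] = summ
        median_rows.append({"group": group, "n": summ.n, "events": summ.n_events,
                            "median_km": summ.median_km,
                            "median_plain": summ.median_plain})
    groups = sorted(km)
    lr_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            res = logrank_test(by_group[ga], by_group[gb])
            lr_rows.append({"group_a": ga, "group_b": gb,
                            "chi_square": res.chi_square, "p_value": res.p_value})
    medians = pd.DataFrame(median_rows)
    logrank = pd.DataFrame(lr_rows)
    _maybe_write(table, outdir, "tte_per_animal.csv")
    _maybe_write(medians, outdir, "survival_medians.csv")
    _maybe_write(logrank, outdir, "survival_logrank.csv")
    return SurvivalReport(tte=table, medians=medians, logrank=logrank, km=km)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionReport:
    fold_changes: pd.DataFrame
    gene_lists: dict
    venn: dict
    categories: pd.Series
    category_counts: pd.Series
    zscored: pd.DataFrame       # z-scored rows of category-classified genes
    enrichment: pd.DataFrame


def run_expression(
    matrix: Union[ExpressionMatrix, str, Path],
    conditions: Optional[Mapping[str, str]] = None,
    chip=None,
    gene_sets: Union[Sequence[GeneSet], str, Path, None] = None,
    config: Optional[PipelineConfig] = None,
    rank_contrast: tuple = ("combination", "drug_a"),
    outdir=None,
) -> ExpressionReport:
    """Full expression stage: collapse, contrasts, lists, categories, GSEA.

    ``matrix`` may be an :class:`ExpressionMatrix` or a GCT path (then
    ``conditions``/``chip`` are required).  Gene lists and categories
    are computed after symbol collapsing when a qualifier map is
    present.  GSEA ranks genes by difference of class means between the
    two conditions of ``rank_contrast``.
    """
    config = config or PipelineConfig()
    if not isinstance(matrix, ExpressionMatrix):
        matrix = skio.load_expression_matrix(matrix, conditions, chip)
    if matrix.qualifier_to_symbol is not None:
        matrix = collapse_to_symbols(matrix)
    logger.info("expression matrix: %d genes x %d samples",
                *matrix.values.shape)

    fc = fold_changes(matrix)
    lists = threshold_gene_lists(fc, threshold=config.fold_threshold)
    venn = venn_counts(lists["fc_a"]["up"] | lists["fc_a"]["down"],
                       lists["fc_b"]["up"] | lists["fc_b"]["down"],
                       lists["fc_ab"]["up"] | lists["fc_ab"]["down"])
    categories = classify_combination_categories(fc, config.category_filters)
    cat_counts = (categories[categories != "none"]
                  .value_counts().sort_index())
    classified = categories.index[categories != "none"]
    zscored, _ = zscore_rows(matrix.values.loc[classified])

    enrichment = pd.DataFrame()
    if gene_sets is not None:
        if not isinstance(gene_sets, (list, tuple)):
            gene_sets = skio.read_gmt(gene_sets)
        ranked = rank_by_class_difference(
            matrix.values,
            matrix.samples_for(rank_contrast[0]),
            matrix.samples_for(rank_contrast[1]))
        results = gsea_permutation_test(ranked, list(gene_sets),
                                        n_perm=config.n_perm, seed=config.seed,
                                        weight_exponent=config.gsea_weight_exponent)
        enrichment = pd.DataFrame(
            [{"name": r.name, "es": r.es, "nes": r.nes,
              "p_nominal": r.p_nominal, "fdr": r.fdr, "size": r.size}
             for r in results])

    _maybe_write(fc.reset_index(), outdir, "fold_changes.csv")
    _maybe_write(pd.DataFrame([venn]), outdir, "venn_counts.csv")
    _maybe_write(categories.reset_index(), outdir, "categories.csv")
    if not enrichment.empty:
        _maybe_write(enrichment, outdir, "enrichment.csv")
    return ExpressionReport(fold_changes=fc, gene_lists=lists, venn=venn,
                            categories=categories, category_counts=cat_counts,
                            zscored=zscored, enrichment=enrichment)


# ---------------------------------------------------------------------------
# simulation fixture writer


def run_simulate(sim_config: Optional[SimulationConfig] = None, outdir=".") -> dict:
    """Generate a complete synthetic study and write it in the input formats.

    Writes the patient-cohort combination table, the tumor-volume and
    fate tables, a qualifier-level GCT expression matrix with its chip
    map and conditions, a small GMT of planted and random gene sets,
    and the matching ground-truth tables.  Returns the path mapping.
    """
    sim_config = sim_config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cohort, cohort_truth = simulate_patient_cohort(sim_config)
    cohort.to_csv(outdir / "cohort_combinations.csv", index=False)
    cohort_truth.to_csv(outdir / "cohort_truth.csv", index=False)
    paths["cohort"] = outdir / "cohort_combinations.csv"

    volumes, fates, growth_truth = simulate_tumor_growth_study(sim_config)
    volumes.to_csv(outdir / "tumor_volumes.csv", index=False)
    fates.to_csv(outdir / "animal_fates.csv", index=False)
    growth_truth.to_csv(outdir / "tumor_truth.csv", index=False)
    paths["volumes"] = outdir / "tumor_volumes.csv"
    paths["fates"] = outdir / "animal_fates.csv"

    matrix, expr_truth = simulate_expression_experiment(sim_config)
    skio.write_gct(matrix.values, outdir / "expression.gct")
    skio.write_chip_map(matrix.qualifier_to_symbol, outdir / "expression.chip")
    pd.DataFrame({"sample_id": list(matrix.sample_conditions),
                  "condition": list(matrix.sample_conditions.values())}).to_csv(
        outdir / "sample_conditions.csv", index=False)
    expr_truth.to_csv(outdir / "expression_truth.csv")
    paths["gct"] = outdir / "expression.gct"
    paths["chip"] = outdir / "expression.chip"
    paths["conditions"] = outdir / "sample_conditions.csv"

    # gene sets: the planted category-G genes plus random decoys
    rng = sim_config.rng(7)
    g_genes = expr_truth.index[expr_truth["category"] == "G"]
    universe = list(expr_truth.index)
    sets = [GeneSet(name="PLANTED_CATEGORY_G", genes=frozenset(g_genes),
                    description="genes planted as combination-amplified up")]
    for i in range(5):
        decoy = rng.choice(universe, size=max(10, len(g_genes) // 2), replace=False)
        sets.append(GeneSet(name=f"RANDOM_SET_{i + 1}", genes=frozenset(decoy),
                            description="random decoy set"))
    skio.write_gmt(sets, outdir / "gene_sets.gmt")
    paths["gmt"] = outdir / "gene_sets.gmt"
    return paths
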