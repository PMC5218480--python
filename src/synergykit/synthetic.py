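"""Synthetic data generators with known ground truth.

Every pipeline stage has a generator here that emulates the matching
experimental design and emits its ground truth alongside the data, so
recovery can be tested without any external download:

* monotherapy viability curves from the median-effect model with
  multiplicative (CV-parameterised) Gaussian noise on the response;
* combination designs (constant-ratio series and fixed-dose
  checkerboards) constructed to have a *known true combination index*,
  by solving the Loewe relation ``d1/Dx1(fa) + d2/Dx2(fa) = CI`` for
  the dose pair (constant ratio) or the effect level (checkerboard);
* a patient cohort mixing synergistic and non-synergistic samples;
* exponential xenograft tumor growth with lognormal measurement noise,
  per-group growth rates and endpoint-triggered truncation;
* log2 expression matrices with genes planted into the eight
  combination-response categories, or into a full three-contrast
  membership structure with specified up/down list sizes.

Default design sizes mirror the emulated study (11 doses in
quadruplicate over 0.1-100 uM, 3x3 checkerboards minus one cell, 30
patient samples of which 22 synergistic, 10 animals per group with a
2000 mm^3 endpoint and a day-34 cap, ~20,000 genes with 3 arrays per
condition); all are configurable downward for fast tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import MedianEffectFit, dose_for_effect
from .expression import CATEGORIES, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_dose_response",
    "simulate_combination",
    "simulate_patient_cohort",
    "simulate_tumor_growth_study",
    "benchmark_tte_study",
    "simulate_expression_experiment",
    "simulate_contrast_benchmark",
    "DEFAULT_GROWTH_RATES",
    "DEFAULT_CATEGORY_COUNTS",
    "DEFAULT_CONTRAST_COUNTS",
]

# Group growth rates g (1/day) for V(t) = V0 * exp(g t), V0 = 125 mm^3:
# calibrated so the analytic 2000 mm^3 crossing ln(16)/g sits at the
# emulated study's group median survivals of 14 / 17 / 17.6 / 33.7 days.
_LN16 = math.log(2000.0 / 125.0)
DEFAULT_GROWTH_RATES: Mapping[str, float] = {
    "vehicle": _LN16 / 14.0,
    "drug_a": _LN16 / 17.0,
    "drug_b": _LN16 / 17.6,
    "combination": _LN16 / 33.7,
}

# Planted gene counts per combination-response category.  G = 199 genes
# (both agents up, combination higher than either) matches the emulated
# study's count of combination-amplified up-regulated genes; the other
# categories are package defaults.
DEFAULT_CATEGORY_COUNTS: Mapping[str, int] = {
    "A": 150, "B": 140, "C": 60, "D": 55, "E": 120, "F": 110, "G": 199, "H": 90,
}

# (a_up, a_down, b_up, b_down, ab_up, ab_down, combination_exclusive)
DEFAULT_CONTRAST_COUNTS = (62, 12, 386, 72, 581, 539, 752)

_COMBO_SCHEMA = ["sample_id", "drug_1", "dose_1_uM", "drug_2", "dose_2_uM",
                 "response", "replicate"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all generators; the seed fully determines outputs."""

    seed: int = 0
    # noise levels
    response_cv: float = 0.05          # multiplicative CV on viability responses
    volume_sigma_log10: float = 0.05   # SD of log10 tumor-volume measurement noise
    expression_sigma_log2: float = 0.1  # per-sample additive log2 expression noise
    # design sizes
    n_doses: int = 11
    dose_min_uM: float = 0.1
    dose_max_uM: float = 100.0
    n_replicates: int = 4
    n_animals_per_group: int = 10
    n_genes: int = 20000
    samples_per_condition: int = 3

    def __post_init__(self):
        for name in ("response_cv", "volume_sigma_log10", "expression_sigma_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic generator per (seed, stream)."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# dose-response and combinations


def _noisy_response(fa: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """response = (1 - fa) * (1 + eps), eps ~ N(0, cv); kept positive."""
    resp = (1.0 - fa) * (1.0 + rng.normal(0.0, cv, size=fa.shape))
    return np.maximum(resp, 1e-6)


def simulate_dose_response(
    config: SimulationConfig,
    m: float = 1.5,
    dm: float = 1.0,
    drug: str = "drug_a",
    sample_id: str = "S01",
) -> pd.DataFrame:
    """Monotherapy viability table from a true median-effect curve.

    Columns: sample_id, drug, dose_uM, response, replicate.  The true
    fraction affected is ``1/(1 + (Dm/D)^m)``; the recorded response is
    the surviving fraction with multiplicative Gaussian noise.
    """
    if m <= 0 or dm <= 0:
        raise ValueError("true m and Dm must be positive")
    rng = config.rng(1)
    doses = np.geomspace(config.dose_min_uM, config.dose_max_uM, config.n_doses)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        resp = _noisy_response(fa, config.response_cv, rng)
        for d, r in zip(doses, resp):
            rows.append((sample_id, drug, d, r, rep))
    return pd.DataFrame(rows, columns=["sample_id", "drug", "dose_uM",
                                       "response", "replicate"])


def _fa_grid(n: int) -> np.ndarray:
    """Effect levels symmetric in log-odds, spanning fa ~ 0.09 .. 0.91."""
    odds = np.logspace(-1.0, 1.0, n)
    return odds / (1.0 + odds)


def _checkerboard_pairs(doses_1: Sequence[float], doses_2: Sequence[float]):
    """Full grid minus the (lowest, lowest) cell -> 8 of 9 pairs by default."""
    pairs = [(d1, d2) for d1 in doses_1 for d2 in doses_2]
    pairs.remove((min(doses_1), min(doses_2)))
    return pairs


def simulate_combination(
    config: SimulationConfig,
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    true_ci: float = 1.0,
    design: str = "constant_ratio",
    dose_1_fraction: Optional[float] = None,
    checkerboard_doses_1: Sequence[float] = (0.9, 1.8, 2.8),
    checkerboard_doses_2: Sequence[float] = (0.5, 1.0, 1.5),
    n_points: int = 7,
    sample_id: str = "S01",
    drug_1: str = "drug_a",
    drug_2: str = "drug_b",
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Combination table with a known true combination index.

    ``constant_ratio``: at each of ``n_points`` target effect levels the
    dose pair (at the design ratio, IC50:IC50 by default) is scaled so
    that ``d1/Dx1(fa) + d2/Dx2(fa) = true_ci`` and the response set to
    ``1 - fa`` (plus noise).  ``checkerboard``: for each fixed dose pair
    the effect level solving the same relation is found numerically.

    Returns ``(table, truth)`` where ``truth`` records the per-point
    true fraction affected and the planted CI.
    """
    if true_ci <= 0:
        raise ValueError("true_ci must be positive")
    if rng is None:
        rng = config.rng(2)
    rows, truth_rows = [], []
    if design == "constant_ratio":
        f1 = (fit_1.dm / (fit_1.dm + fit_2.dm)
              if dose_1_fraction is None else dose_1_fraction)
        f2 = 1.0 - f1
        for fa in _fa_grid(n_points):
            dx1 = dose_for_effect(fit_1, fa)
            dx2 = dose_for_effect(fit_2, fa)
            d_total = true_ci / (f1 / dx1 + f2 / dx2)
            d1, d2 = f1 * d_total, f2 * d_total
            truth_rows.append((sample_id, d1, d2, fa, true_ci))
            for rep in range(1, config.n_replicates + 1):
                resp = float(_noisy_response(np.array([fa]), config.response_cv, rng)[0])
                rows.append((sample_id, drug_1, d1, drug_2, d2, resp, rep))
    elif design == "checkerboard":
        for d1, d2 in _checkerboard_pairs(checkerboard_doses_1, checkerboard_doses_2):
            def _loewe_gap(fa, d1=d1, d2=d2):
                return (d1 / dose_for_effect(fit_1, fa)
                        + d2 / dose_for_effect(fit_2, fa) - true_ci)
            fa = optimize.brentq(_loewe_gap, 1e-9, 1.0 - 1e-9)
            truth_rows.append((sample_id, d1, d2, fa, true_ci))
            for rep in range(1, config.n_replicates + 1):
                resp = float(_noisy_response(np.array([fa]), config.response_cv, rng)[0])
                rows.append((sample_id, drug_1, d1, drug_2, d2, resp, rep))
    else:
        raise ValueError(f"unknown design {design!r}")
    table = pd.DataFrame(rows, columns=_COMBO_SCHEMA)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "dose_1_uM", "dose_2_uM",
                                              "true_fa", "true_ci"])
    return table, truth


def simulate_patient_cohort(
    config: SimulationConfig,
    n_samples: int = 30,
    n_synergistic: int = 22,
    ci_range_synergistic: tuple = (0.35, 0.85),
    ci_range_non: tuple = (1.05, 1.6),
    n_mono_doses: int = 8,
) -> tuple:
    """Per-sample monotherapy + checkerboard tables for a patient cohort.

    Each sample gets its own true median-effect parameters per drug, an
    8-point monotherapy dilution series per drug, and an 8-point
    checkerboard whose points share one true CI drawn from the
    synergistic or non-synergistic range.  Exactly ``n_synergistic`` of
    the ``n_samples`` samples are synergistic (assignment shuffled).

    Returns ``(long table in the combination CSV schema, truth table)``.
    Monotherapy rows carry the partner dose as 0.
    """
    rng = config.rng(3)
    synergistic = np.zeros(n_samples, dtype=bool)
    synergistic[:n_synergistic] = True
    rng.shuffle(synergistic)

    tables, truth_rows = [], []
    for i in range(n_samples):
        sid = f"P{i + 1:03d}"
        m1, m2 = rng.uniform(0.8, 2.5, size=2)
        dm1 = float(np.exp(rng.normal(np.log(1.8), 0.3)))   # drug-1 IC50 ~ 1.8 uM
        dm2 = float(np.exp(rng.normal(np.log(1.0), 0.3)))   # drug-2 IC50 ~ 1.0 uM
        fit_1 = MedianEffectFit(m=m1, dm=dm1, r=1.0, n_points=0)
        fit_2 = MedianEffectFit(m=m2, dm=dm2, r=1.0, n_points=0)
        lo, hi = ci_range_synergistic if synergistic[i] else ci_range_non
        true_ci = float(rng.uniform(lo, hi))

        rows = []
        for drug, fit, col in ((1, fit_1, "dose_1_uM"), (2, fit_2, "dose_2_uM")):
            doses = np.geomspace(fit.dm / 20.0, fit.dm * 20.0, n_mono_doses)
            fa = 1.0 / (1.0 + (fit.dm / doses) ** fit.m)
            for rep in range(1, config.n_replicates + 1):
                resp = _noisy_response(fa, config.response_cv, rng)
                for d, r in zip(doses, resp):
                    rows.append((sid, "drug_a", d if drug == 1 else 0.0,
                                 "drug_b", d if drug == 2 else 0.0, r, rep))
        mono = pd.DataFrame(rows, columns=_COMBO_SCHEMA)
        grid_1 = tuple(dm1 * np.array([0.5, 1.0, 1.5]))
        grid_2 = tuple(dm2 * np.array([0.5, 1.0, 1.5]))
        combo, _ = simulate_combination(
            config, fit_1, fit_2, true_ci=true_ci, design="checkerboard",
            checkerboard_doses_1=grid_1, checkerboard_doses_2=grid_2,
            sample_id=sid, rng=rng)
        tables.extend([mono, combo])
        truth_rows.append((sid, m1, dm1, m2, dm2, true_ci, bool(synergistic[i])))
    table = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "m_1", "dm_1", "m_2",
                                              "dm_2", "true_ci", "synergistic"])
    return table, truth


# ---------------------------------------------------------------------------
# tumor growth


DEFAULT_SCHEDULE = (0.0, 3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 28.0, 31.0, 34.0)


def simulate_tumor_growth_study(
    config: SimulationConfig,
    group_growth_rates: Optional[Mapping[str, float]] = None,
    v0_mean: float = 125.0,
    v0_sigma_log: float = 0.1,
    growth_rate_cv: float = 0.12,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    endpoint_volume: float = 2000.0,
    last_day: float = 34.0,
    nontreatment_deaths: Optional[Mapping[str, float]] = None,
) -> tuple:
    """Exponential tumor growth with lognormal measurement noise.

    Each animal grows as ``V(t) = V0 * exp(g t)`` with its own rate
    ``g`` (lognormal around the group rate) and start volume ``V0``;
    measurements follow the twice-weekly ``schedule`` with lognormal
    noise (SD ``volume_sigma_log10`` on log10) and stop after the first
    observation at or above the endpoint volume.  Optionally plants
    non-treatment deaths (animal id -> death day), which truncate the
    series and annotate the fate table.

    Returns ``(volumes, fates, truth)``; ``truth`` holds each animal's
    analytic noise-free endpoint-crossing time.
    """
    rates = dict(DEFAULT_GROWTH_RATES if group_growth_rates is None
                 else group_growth_rates)
    deaths = dict(nontreatment_deaths or {})
    rng = config.rng(4)
    vol_rows, fate_rows, truth_rows = [], [], []
    for group, g_group in rates.items():
        for j in range(config.n_animals_per_group):
            aid = f"{group}_{j + 1:02d}"
            g = g_group * math.exp(rng.normal(0.0, growth_rate_cv))
            v0 = v0_mean * math.exp(rng.normal(0.0, v0_sigma_log))
            crossing = math.log(endpoint_volume / v0) / g
            truth_rows.append((aid, group, crossing))
            death_day = deaths.get(aid)
            reached = False
            for day in schedule:
                if death_day is not None and day > death_day:
                    break
                v_true = v0 * math.exp(g * day)
                v_obs = v_true * 10.0 ** rng.normal(0.0, config.volume_sigma_log10)
                vol_rows.append((aid, group, day, v_obs))
                if v_obs >= endpoint_volume:
                    reached = True
                    break
            if death_day is not None:
                fate_rows.append((aid, "nontreatment_death", death_day))
            elif reached:
                fate_rows.append((aid, "reached_endpoint", None))
            else:
                fate_rows.append((aid, "survived_to_end", None))
    volumes = pd.DataFrame(vol_rows, columns=["animal_id", "group", "day",
                                              "volume_mm3"])
    fates = pd.DataFrame(fate_rows, columns=["animal_id", "fate", "day"])
    truth = pd.DataFrame(truth_rows, columns=["animal_id", "group",
                                              "true_crossing_day"])
    return volumes, fates, truth


def benchmark_tte_study(
    tte_by_group: Mapping[str, Sequence[float]],
    v0: float = 125.0,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    endpoint_volume: float = 2000.0,
    last_day: float = 34.0,
) -> tuple:
    """Synthetic stand-in for a per-animal TTE benchmark table.

    The deposited per-animal endpoint table of the emulated study is not
    redistributable, so this builds a noise-free surrogate: for each
    requested TTE value an exponential trajectory is constructed whose
    analytic endpoint crossing equals that value exactly (growth rate
    ``ln(endpoint/V0) / tte``), sampled on the measurement schedule and
    truncated after the first observation past the endpoint.  A value
    ``>= last_day`` denotes a survivor (its trajectory stays below the
    endpoint through the last day).  Running the TTE derivation on the
    output must reproduce the requested values and group medians.

    Returns ``(volumes, fates)`` tables in the standard schema.
    """
    vol_rows, fate_rows = [], []
    for group, ttes in tte_by_group.items():
        for j, tte in enumerate(ttes):
            aid = f"{group}_{j + 1:02d}"
            target = float(tte) if tte < last_day else last_day + 3.0
            g = math.log(endpoint_volume / v0) / target
            reached = False
            for day in schedule:
                v = v0 * math.exp(g * day)
                vol_rows.append((aid, group, day, v))
                if v >= endpoint_volume:
                    reached = True
                    break
            fate_rows.append((aid, "reached_endpoint" if reached else
                              "survived_to_end", None))
    volumes = pd.DataFrame(vol_rows, columns=["animal_id", "group", "day",
                                              "volume_mm3"])
    fates = pd.DataFrame(fate_rows, columns=["animal_id", "fate", "day"])
    return volumes, fates


# ---------------------------------------------------------------------------
# expression


# log2 effect sizes: "changed" conditions move +/- 1.6 (3.0-fold), and the
# combination adds a further 0.8 (1.74x beyond the single agent, comfortably
# past the 1.25x amplification filter).
_EFFECT_CHANGED = 1.6
_EFFECT_EXTRA = 0.8

_CATEGORY_EFFECTS = {
    #       (drug_a, drug_b, combination) log2 shifts vs vehicle
    "A": (0.0, 0.0, +_EFFECT_CHANGED),
    "B": (0.0, 0.0, -_EFFECT_CHANGED),
    "C": (+_EFFECT_CHANGED, 0.0, +_EFFECT_CHANGED + _EFFECT_EXTRA),
    "D": (-_EFFECT_CHANGED, 0.0, -_EFFECT_CHANGED - _EFFECT_EXTRA),
    "E": (0.0, +_EFFECT_CHANGED, +_EFFECT_CHANGED + _EFFECT_EXTRA),
    "F": (0.0, -_EFFECT_CHANGED, -_EFFECT_CHANGED - _EFFECT_EXTRA),
    "G": (+_EFFECT_CHANGED, +_EFFECT_CHANGED, +_EFFECT_CHANGED + _EFFECT_EXTRA),
    "H": (-_EFFECT_CHANGED, -_EFFECT_CHANGED, -_EFFECT_CHANGED - _EFFECT_EXTRA),
}

_CONDITION_ORDER = ("vehicle", "drug_a", "drug_b", "combination")
_SAMPLE_PREFIX = {"vehicle": "VEH", "drug_a": "TRTA", "drug_b": "TRTB",
                  "combination": "CMB"}


def _sample_layout(samples_per_condition: int):
    samples, conditions = [], {}
    for cond in _CONDITION_ORDER:
        for r in range(1, samples_per_condition + 1):
            name = f"{_SAMPLE_PREFIX[cond]}_{r}"
            samples.append(name)
            conditions[name] = cond
    return samples, conditions


def _build_matrix(config, effects: np.ndarray, gene_names, rng,
                  baseline_mean=7.0, baseline_sd=1.5,
                  multi_qualifier_fraction=0.3, unmapped_fraction=0.02):
    """Assemble a qualifier-level matrix from per-gene condition effects.

    ``effects``: (n_genes, 4) log2 shifts in condition order
    vehicle/drug_a/drug_b/combination (vehicle column zero).  Genes get
    1-3 qualifiers; secondary qualifiers sit lower in baseline signal
    so max-signal collapsing recovers the primary row.  A few unmapped
    control-style qualifiers are appended.
    """
    n_genes = len(gene_names)
    samples, conditions = _sample_layout(config.samples_per_condition)
    cond_idx = np.array([_CONDITION_ORDER.index(conditions[s]) for s in samples])

    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    extra = rng.random(n_genes) < multi_qualifier_fraction
    n_extra_per_gene = np.where(extra, rng.integers(1, 3, size=n_genes), 0)

    q_names, q_gene_idx, q_offset = [], [], []
    for i, gene in enumerate(gene_names):
        q_names.append(f"{gene}_q1_at")
        q_gene_idx.append(i)
        q_offset.append(0.0)
        for k in range(n_extra_per_gene[i]):
            q_names.append(f"{gene}_q{k + 2}_at")
            q_gene_idx.append(i)
            q_offset.append(-float(rng.uniform(0.5, 2.5)))
    q_gene_idx = np.array(q_gene_idx)
    q_offset = np.array(q_offset)

    mean_mat = (baselines[q_gene_idx, None] + q_offset[:, None]
                + effects[q_gene_idx][:, cond_idx])
    noise = rng.normal(0.0, config.expression_sigma_log2, size=mean_mat.shape)
    values = pd.DataFrame(mean_mat + noise, index=pd.Index(q_names, name="qualifier"),
                          columns=samples)
    mapping = {q: gene_names[g] for q, g in zip(q_names, q_gene_idx)}

    n_unmapped = int(round(unmapped_fraction * n_genes))
    if n_unmapped:
        ctrl = pd.DataFrame(
            rng.normal(baseline_mean, baseline_sd, size=(n_unmapped, 1))
            + rng.normal(0.0, config.expression_sigma_log2,
                         size=(n_unmapped, len(samples))),
            index=pd.Index([f"AFFX-CTRL-{i + 1:04d}" for i in range(n_unmapped)],
                           name="qualifier"),
            columns=samples)
        values = pd.concat([values, ctrl])
    return ExpressionMatrix(values=values, sample_conditions=conditions,
                            qualifier_to_symbol=mapping)


def simulate_expression_experiment(
    config: SimulationConfig,
    category_counts: Optional[Mapping[str, int]] = None,
    **matrix_kwargs,
) -> tuple:
    """Log2 expression matrix with genes planted into categories A-H.

    Planted genes receive the log2 shifts of their category (see
    ``_CATEGORY_EFFECTS``); the remaining genes are unaffected
    background.  Returns ``(qualifier-level ExpressionMatrix, truth)``
    where ``truth`` maps each gene to its planted category and shifts.
    """
    if category_counts is None:
        counts = dict(DEFAULT_CATEGORY_COUNTS)
        total = sum(counts.values())
        if config.n_genes < 2 * total:
            # scaled-down designs keep the category proportions (>= 1 each)
            f = config.n_genes / (2.0 * total)
            counts = {c: max(1, int(round(k * f))) for c, k in counts.items()}
    else:
        counts = dict(category_counts)
    n_planted = sum(counts.values())
    if n_planted > config.n_genes:
        raise ValueError("more planted genes than n_genes")
    rng = config.rng(5)
    gene_names = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)

    effects = np.zeros((config.n_genes, 4))
    labels = np.full(config.n_genes, "none", dtype=object)
    pos = 0
    for cat in CATEGORIES:
        k = counts.get(cat, 0)
        idx = order[pos:pos + k]
        pos += k
        ea, eb, eab = _CATEGORY_EFFECTS[cat]
        effects[idx, 1], effects[idx, 2], effects[idx, 3] = ea, eb, eab
        labels[idx] = cat

    matrix = _build_matrix(config, effects, gene_names, rng, **matrix_kwargs)
    truth = pd.DataFrame({"gene": gene_names, "category": labels,
                          "effect_a": effects[:, 1], "effect_b": effects[:, 2],
                          "effect_ab": effects[:, 3]}).set_index("gene")
    return matrix, truth


def _solve_contrast_membership(counts) -> dict:
    """Distribute genes over a three-contrast membership structure.

    Finds per-direction counts for: genes on the drug-A lists (all also
    on the combination list, same direction), genes on the drug-B lists
    split between shared-with-combination and B-only, and
    combination-exclusive genes, such that all seven printed totals are
    reproduced.  Raises if the totals are infeasible.
    """
    a_up, a_dn, b_up, b_dn, ab_up, ab_dn, excl = counts
    shared = ab_up + ab_dn - excl
    b_in = shared - (a_up + a_dn)
    if not 0 <= b_in <= b_up + b_dn:
        raise ValueError("infeasible contrast counts: cannot allocate shared genes")
    # split the shared-with-combination B genes by direction: proportional
    # proposal clipped into the feasibility box
    lo = max(0, b_in - min(b_dn, ab_dn - a_dn))
    hi = min(b_up, ab_up - a_up)
    if lo > hi:
        raise ValueError("infeasible contrast counts: direction split impossible")
    b_in_up = int(np.clip(round(b_in * b_up / max(b_up + b_dn, 1)), lo, hi))
    b_in_dn = b_in - b_in_up
    return {
        "a_up": a_up, "a_dn": a_dn,
        "b_in_up": b_in_up, "b_in_dn": b_in_dn,
        "b_out_up": b_up - b_in_up, "b_out_dn": b_dn - b_in_dn,
        "excl_up": ab_up - a_up - b_in_up, "excl_dn": ab_dn - a_dn - b_in_dn,
    }


def simulate_contrast_benchmark(
    config: SimulationConfig,
    counts: Sequence[int] = DEFAULT_CONTRAST_COUNTS,
    **matrix_kwargs,
) -> tuple:
    """Expression matrix planted to reproduce specified >= 2-fold list sizes.

    ``counts = (a_up, a_down, b_up, b_down, ab_up, ab_down,
    combination_exclusive)``; defaults mirror the emulated study's
    62/12, 386/72 and 581/539 contrast lists with 752 genes exclusive
    to the combination.  Membership is arranged so the fold-change ->
    threshold -> Venn path recovers every count exactly (at the default
    low noise).  Returns ``(ExpressionMatrix, truth membership table)``.
    """
    alloc = _solve_contrast_membership(tuple(counts))
    groups = [
        ("a_up", (+1, 0, +1)), ("a_dn", (-1, 0, -1)),
        ("b_in_up", (0, +1, +1)), ("b_in_dn", (0, -1, -1)),
        ("b_out_up", (0, +1, 0)), ("b_out_dn", (0, -1, 0)),
        ("excl_up", (0, 0, +1)), ("excl_dn", (0, 0, -1)),
    ]
    n_planted = sum(alloc.values())
    if n_planted > config.n_genes:
        raise ValueError("more planted genes than n_genes")
    rng = config.rng(6)
    gene_names = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)

    effects = np.zeros((config.n_genes, 4))
    member = np.full(config.n_genes, "background", dtype=object)
    pos = 0
    for name, signs in groups:
        k = alloc[name]
        idx = order[pos:pos + k]
        pos += k
        for col, s in zip((1, 2, 3), signs):
            effects[idx, col] = s * _EFFECT_CHANGED
        member[idx] = name
    matrix = _build_matrix(config, effects, gene_names, rng, **matrix_kwargs)
    truth = pd.DataFrame({"gene": gene_names, "membership": member,
                          "effect_a": effects[:, 1], "effect_b": effects[:, 2],
                          "effect_ab": effects[:, 3]}).set_index("gene")
    return matrix, truth
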