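"""Combinatorial expression-response analysis and gene-set enrichment.

Operates on RMA-style log2 expression matrices (probe-set "qualifiers"
x samples) from a four-arm design: vehicle, single agent A, single
agent B, and the A+B combination.  Stages mirror a standard microarray
combination analysis:

* collapse qualifiers to gene symbols by maximum mean signal;
* per-gene linear fold changes of each treatment arm vs vehicle
  (difference of log2 means, i.e. geometric-mean ratios);
* inclusive >= 2-fold up/down gene lists per contrast and the 7-region
  Venn decomposition of the three lists;
* the eight mutually exclusive combination-response categories A-H
  (combination-only changes, single-agent changes amplified by the
  combination, and both-agent changes amplified by the combination);
* row z-scoring for heatmap display;
* gene-set enrichment: genes ranked by difference of class means feed
  a weighted Kolmogorov-Smirnov running-sum enrichment score, with
  gene-set permutations providing normalized scores, nominal p-values
  and FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "ExpressionMatrix",
    "CategoryFilterConfig",
    "GeneSet",
    "EnrichmentScore",
    "EnrichmentResult",
    "collapse_to_symbols",
    "fold_changes",
    "threshold_gene_lists",
    "venn_counts",
    "classify_combination_categories",
    "zscore_rows",
    "rank_by_class_difference",
    "enrichment_score",
    "gsea_permutation_test",
]

CONDITIONS = ("vehicle", "drug_a", "drug_b", "combination")
CATEGORIES = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix with sample conditions and a symbol map.

    ``values``: DataFrame of log2 intensities, rows = qualifiers (or
    gene symbols after collapsing), columns = sample names.
    ``sample_conditions`` maps each sample to one of
    ``vehicle / drug_a / drug_b / combination``.
    ``qualifier_to_symbol`` maps qualifiers to gene symbols (may be
    many-to-one; unmapped qualifiers are dropped at collapse time);
    ``None`` once the matrix is keyed by symbol.
    """

    values: pd.DataFrame
    sample_conditions: Mapping[str, str]
    qualifier_to_symbol: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unknown = set(self.sample_conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown sample conditions {sorted(unknown)}; "
                             f"expected {CONDITIONS}")
        missing = [s for s in self.values.columns if s not in self.sample_conditions]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")

    def samples_for(self, condition: str) -> list:
        return [s for s in self.values.columns
                if self.sample_conditions[s] == condition]


@dataclass(frozen=True)
class CategoryFilterConfig:
    """Fold-change filters for the A-H combination-response categories.

    ``t_change``: minimum linear fold change (or its reciprocal) for a
    condition to count as changed (inclusive; default 2.0).
    ``unaffected_band``: a condition is unaffected when its fold change
    lies within [1/band, band] (default 1.5).  Genes between the band
    and the change threshold for a relevant single agent are left
    unclassified (conservative).
    ``t_extra``: the combination must change the gene at least this
    factor beyond the (largest) changed single agent, same direction
    (default 1.25).
    """

    t_change: float = 2.0
    unaffected_band: float = 1.5
    t_extra: float = 1.25

    def __post_init__(self):
        if self.t_change <= 1 or self.unaffected_band < 1 or self.t_extra < 1:
            raise ValueError("filters require t_change > 1, unaffected_band >= 1, "
                             "t_extra >= 1")
        if self.t_change <= self.unaffected_band:
            logger.warning("t_change (%.3g) <= unaffected band (%.3g): the 'changed' "
                           "and 'unaffected' zones touch; classification still "
                           "well-defined but unusual", self.t_change, self.unaffected_band)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    description: str = ""

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentScore:
    """Running-sum enrichment score with its full profile."""

    es: float
    running: np.ndarray
    hit_mask: np.ndarray
    peak_index: int


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_nominal: float
    fdr: float
    size: int
    n_perm: int


# ---------------------------------------------------------------------------
# matrix-level stages


def collapse_to_symbols(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse qualifiers to gene symbols by maximum mean signal.

    For each symbol the qualifier with the highest mean log2 intensity
    across all samples is kept; qualifiers without a symbol mapping are
    dropped (count logged).
    """
    if not matrix.qualifier_to_symbol:
        raise ValueError("qualifier_to_symbol mapping is empty")
    mapping = matrix.qualifier_to_symbol
    mapped = [q for q in matrix.values.index if q in mapping]
    n_unmapped = len(matrix.values.index) - len(mapped)
    if n_unmapped:
        logger.info("dropping %d unmapped qualifiers at symbol collapse", n_unmapped)
    sub = matrix.values.loc[mapped]
    symbols = pd.Index([mapping[q] for q in mapped], name="symbol")
    mean_signal = sub.mean(axis=1).to_numpy()
    # stable winner per symbol: highest mean signal
    order = np.lexsort((-mean_signal, symbols.to_numpy()))
    sorted_syms = symbols.to_numpy()[order]
    keep_pos = order[np.unique(sorted_syms, return_index=True)[1]]
    collapsed = sub.iloc[np.sort(keep_pos)].copy()
    collapsed.index = pd.Index([mapping[q] for q in collapsed.index], name="symbol")
    return ExpressionMatrix(values=collapsed,
                            sample_conditions=dict(matrix.sample_conditions),
                            qualifier_to_symbol=None)


def _condition_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    means = {}
    for cond in CONDITIONS:
        samples = matrix.samples_for(cond)
        if not samples:
            raise ValueError(f"no samples for condition {cond!r}")
        means[cond] = matrix.values[samples].mean(axis=1)
    return pd.DataFrame(means)


def fold_changes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene linear fold change of each treatment arm vs vehicle.

    ``fc = 2 ** (mean log2 treatment - mean log2 vehicle)``; returns a
    DataFrame with columns ``fc_a``, ``fc_b``, ``fc_ab`` indexed like
    the matrix rows.
    """
    means = _condition_means(matrix)
    return pd.DataFrame({
        "fc_a": 2.0 ** (means["drug_a"] - means["vehicle"]),
        "fc_b": 2.0 ** (means["drug_b"] - means["vehicle"]),
        "fc_ab": 2.0 ** (means["combination"] - means["vehicle"]),
    })


def threshold_gene_lists(fc: pd.DataFrame, threshold: float = 2.0) -> dict:
    """Inclusive >= threshold-fold up/down gene lists per contrast.

    Returns ``{column: {"up": set, "down": set}}`` with
    ``up = {fc >= threshold}`` and ``down = {fc <= 1/threshold}``.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    out = {}
    for col in fc.columns:
        vals = fc[col]
        out[col] = {
            "up": set(fc.index[vals >= threshold]),
            "down": set(fc.index[vals <= 1.0 / threshold]),
        }
    return out


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict:
    """Counts of the 7 disjoint regions of a three-set Venn diagram.

    Keys: ``a_only``, ``b_only``, ``c_only``, ``ab_only``, ``ac_only``,
    ``bc_only``, ``abc``, plus ``union``; region counts sum to the
    union size.  ``c_only`` is "exclusive to the third set".
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
        "union": len(a | b | c),
    }


def classify_combination_categories(
    fc: pd.DataFrame,
    filters: CategoryFilterConfig = CategoryFilterConfig(),
) -> pd.Series:
    """Assign each gene one of the A-H combination-response categories.

    With U = unaffected (within the band), up/down = changed by at
    least ``t_change``, and "more" meaning the combination exceeds the
    single-agent change by ``t_extra`` in the same direction:

    ========  ========  ========  =====================================
    drug A    drug B    combo     category
    ========  ========  ========  =====================================
    U         U         up        A
    U         U         down      B
    up        U         more up   C
    down      U         more down D
    U         up        more up   E
    U         down      more down F
    up        up        more up than either   G
    down      down      more down than either H
    ========  ========  ========  =====================================

    Genes matching no row (including those falling between the
    unaffected band and the change threshold) get ``"none"``.  The
    categories are mutually exclusive by construction.
    """
    t, band, extra = filters.t_change, filters.unaffected_band, filters.t_extra
    fa, fb, fab = (fc["fc_a"].to_numpy(), fc["fc_b"].to_numpy(),
                   fc["fc_ab"].to_numpy())

    a_up, a_dn = fa >= t, fa <= 1.0 / t
    a_un = (fa <= band) & (fa >= 1.0 / band)
    b_up, b_dn = fb >= t, fb <= 1.0 / t
    b_un = (fb <= band) & (fb >= 1.0 / band)
    ab_up, ab_dn = fab >= t, fab <= 1.0 / t

    cat = np.full(len(fc), "none", dtype=object)
    cat[a_un & b_un & ab_up] = "A"
    cat[a_un & b_un & ab_dn] = "B"
    cat[a_up & b_un & (fab >= extra * fa)] = "C"
    cat[a_dn & b_un & (fab <= fa / extra)] = "D"
    cat[a_un & b_up & (fab >= extra * fb)] = "E"
    cat[a_un & b_dn & (fab <= fb / extra)] = "F"
    cat[a_up & b_up & (fab >= extra * np.maximum(fa, fb))] = "G"
    cat[a_dn & b_dn & (fab <= np.minimum(fa, fb) / extra)] = "H"
    return pd.Series(cat, index=fc.index, name="category")


def zscore_rows(values: pd.DataFrame) -> tuple:
    """Normalize each row to mean 0, variance 1 (population convention).

    Constant rows are set to all zeros and flagged.  Returns
    ``(normalized DataFrame, boolean Series of constant-row flags)``.
    """
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("%d constant rows set to zero at z-scoring",
                       int(constant.sum()))
    sd[constant, :] = 1.0
    z = (arr - mean) / sd
    z[constant, :] = 0.0
    return (pd.DataFrame(z, index=values.index, columns=values.columns),
            pd.Series(constant, index=values.index, name="constant_row"))


# ---------------------------------------------------------------------------
# gene-set enrichment


def rank_by_class_difference(
    values: pd.DataFrame,
    class_a: Sequence[str],
    class_b: Sequence[str],
) -> pd.Series:
    """Rank genes by the difference of class means on log2 data.

    ``score = mean(class_a) - mean(class_b)`` per gene; the returned
    Series is sorted by descending score, ties broken by lexicographic
    symbol order (stable, documented).
    """
    if not len(class_a) or not len(class_b):
        raise ValueError("each class needs >= 1 sample")
    score = values[list(class_a)].mean(axis=1) - values[list(class_b)].mean(axis=1)
    df = pd.DataFrame({"_score": score.to_numpy(), "_sym": score.index.to_numpy()})
    df = df.sort_values(["_score", "_sym"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["_score"].to_numpy(), index=pd.Index(df["_sym"]),
                     name="score")


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Signed-maximum running-sum deviation from sorted 0-based hit positions.

    Evaluates the running sum only at its candidate extrema (just before
    and just after each hit, and the terminal 0), which is equivalent to
    the full walk but O(set size).
    """
    k = positions.size
    w = weights[positions]
    tot = w.sum()
    if tot > 0:
        inc = np.cumsum(w) / tot
    else:  # all-zero scores in the set: unweighted increments
        inc = np.arange(1, k + 1) / k
    dec = (positions - np.arange(k)) / (n - k)
    after = inc - dec
    before = np.concatenate(([0.0], inc[:-1])) - dec
    max_dev = max(after.max(initial=0.0), 0.0)
    min_dev = min(before.min(initial=0.0), 0.0)
    return float(max_dev if max_dev >= -min_dev else min_dev)


def enrichment_score(
    ranked: pd.Series,
    gene_set: GeneSet | Iterable[str],
    weight_exponent: float = 1.0,
) -> EnrichmentScore:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Walking down the ranked list, set members ("hits") increment the
    running sum by ``|score|^p / sum_hits |score|^p`` and non-members
    decrement it by ``1/(N - N_hits)``; the ES is the running sum's
    signed maximum deviation from zero.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hit = ranked.index.isin(genes)
    n, k = hit.size, int(hit.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if k == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    tot = w[hit].sum()
    steps = np.where(hit, (w / tot) if tot > 0 else (1.0 / k), -1.0 / (n - k))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return EnrichmentScore(es=float(running[peak]), running=running,
                           hit_mask=hit, peak_index=peak)


def _normalize(es_values: np.ndarray, mean_pos: float, mean_neg: float) -> np.ndarray:
    """NES: divide each ES by the mean |null ES| of its sign."""
    out = np.empty_like(es_values, dtype=float)
    pos = es_values >= 0
    out[pos] = es_values[pos] / mean_pos if mean_pos > 0 else np.nan
    out[~pos] = es_values[~pos] / mean_neg if mean_neg > 0 else np.nan
    return out


def gsea_permutation_test(
    ranked: pd.Series,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    weight_exponent: float = 1.0,
) -> list:
    """Gene-set-permutation GSEA: NES, nominal p and FDR per set.

    For each set, ``n_perm`` random gene sets of equal size drawn from
    the ranked universe provide the null ES distribution.  The NES
    divides the ES by the mean |null ES| of matching sign; the nominal
    p-value is the fraction of same-sign null ES at least as extreme
    (with the +1 pseudocount); the FDR follows the standard GSEA
    ratio-of-tail-fractions procedure over the set collection, pooling
    normalized null scores across sets.  Fully reproducible given
    ``seed``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value/FDR resolution limited to %.3g",
                       n_perm, 1.0 / n_perm)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent

    obs_es, null_es, sizes = [], [], []
    for gs in sets:
        score = enrichment_score(ranked, gs, weight_exponent)
        k = int(score.hit_mask.sum())
        nulls = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(n, size=k, replace=False))
            nulls[i] = _es_from_positions(pos, weights, n)
        obs_es.append(score.es)
        null_es.append(nulls)
        sizes.append(k)
    obs_es = np.array(obs_es)

    obs_nes = np.empty_like(obs_es)
    null_nes_pool = []
    p_nominal = np.empty_like(obs_es)
    for j, nulls in enumerate(null_es):
        pos_nulls = nulls[nulls >= 0]
        neg_nulls = -nulls[nulls < 0]
        mean_pos = pos_nulls.mean() if pos_nulls.size else 0.0
        mean_neg = neg_nulls.mean() if neg_nulls.size else 0.0
        obs_nes[j] = _normalize(obs_es[j:j + 1], mean_pos, mean_neg)[0]
        null_nes_pool.append(_normalize(nulls, mean_pos, mean_neg))
        same_sign = pos_nulls if obs_es[j] >= 0 else neg_nulls
        n_extreme = int((same_sign >= abs(obs_es[j])).sum())
        p_nominal[j] = (n_extreme + 1) / (same_sign.size + 1)
    null_nes_pool = np.concatenate(null_nes_pool)
    null_nes_pool = null_nes_pool[np.isfinite(null_nes_pool)]

    results = []
    for j, gs in enumerate(sets):
        nes = obs_nes[j]
        if not math.isfinite(nes):
            fdr = math.nan
        elif nes >= 0:
            denom_null = max(int((null_nes_pool >= 0).sum()), 1)
            pct_null = (null_nes_pool >= nes).sum() / denom_null
            pct_obs = (obs_nes[np.isfinite(obs_nes)] >= nes).sum() / max(
                int((obs_nes >= 0).sum()), 1)
            fdr = min(1.0, float(pct_null / pct_obs)) if pct_obs > 0 else math.nan
        else:
            denom_null = max(int((null_nes_pool < 0).sum()), 1)
            pct_null = (null_nes_pool <= nes).sum() / denom_null
            pct_obs = (obs_nes[np.isfinite(obs_nes)] <= nes).sum() / max(
                int((obs_nes < 0).sum()), 1)
            fdr = min(1.0, float(pct_null / pct_obs)) if pct_obs > 0 else math.nan
        results.append(EnrichmentResult(
            name=gs.name, es=float(obs_es[j]), nes=float(nes),
            p_nominal=float(p_nominal[j]), fdr=fdr, size=sizes[j], n_perm=n_perm))
    return results
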