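"""Readers, writers and configuration for the pipeline's text formats.

Tables are plain CSV (comma-separated, header row, UTF-8, '.' decimal):

* dose-response (long): sample_id, drug, dose_uM, response, replicate
* combination (long):   sample_id, drug_1, dose_1_uM, drug_2, dose_2_uM,
  response, replicate (monotherapy rows carry one dose as 0)
* tumor volumes (long): animal_id, group, day, volume_mm3
* animal fates:         animal_id, fate, day
* sample conditions:    sample_id, condition

Expression matrices use GCT 1.2; gene sets use GMT; qualifier-to-symbol
maps are two-column TSV with header ``qualifier<TAB>symbol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .expression import CategoryFilterConfig, ExpressionMatrix, GeneSet
from .survival import AnimalFate, TumorVolumeSeries

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_dose_response_csv",
    "read_combination_csv",
    "read_tumor_volumes_csv",
    "read_animal_fates_csv",
    "volume_series_from_tables",
    "read_sample_conditions_csv",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_chip_map",
    "write_chip_map",
    "load_expression_matrix",
]

DOSE_RESPONSE_COLUMNS = ("sample_id", "drug", "dose_uM", "response", "replicate")
COMBINATION_COLUMNS = ("sample_id", "drug_1", "dose_1_uM", "drug_2", "dose_2_uM",
                       "response", "replicate")
VOLUME_COLUMNS = ("animal_id", "group", "day", "volume_mm3")
FATE_COLUMNS = ("animal_id", "fate", "day")


class ParseError(ValueError):
    """Malformed input file; the message names the file (and line if known)."""


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_dose_response_csv(path) -> pd.DataFrame:
    df = _read_csv(path, DOSE_RESPONSE_COLUMNS)
    bad = df.index[df["dose_uM"] <= 0]
    if len(bad):
        raise ParseError(f"{path}: non-positive dose_uM on data line(s) "
                         f"{[int(i) + 2 for i in bad[:5]]}")
    return df


def read_combination_csv(path) -> pd.DataFrame:
    df = _read_csv(path, COMBINATION_COLUMNS)
    bad = df.index[(df["dose_1_uM"] < 0) | (df["dose_2_uM"] < 0)
                   | ((df["dose_1_uM"] == 0) & (df["dose_2_uM"] == 0))]
    if len(bad):
        raise ParseError(f"{path}: invalid dose pair on data line(s) "
                         f"{[int(i) + 2 for i in bad[:5]]}")
    return df


def read_tumor_volumes_csv(path) -> pd.DataFrame:
    df = _read_csv(path, VOLUME_COLUMNS)
    bad = df.index[df["volume_mm3"] <= 0]
    if len(bad):
        raise ParseError(f"{path}: non-positive volume on data line(s) "
                         f"{[int(i) + 2 for i in bad[:5]]}")
    return df


def read_animal_fates_csv(path) -> pd.DataFrame:
    return _read_csv(path, FATE_COLUMNS)


def volume_series_from_tables(
    volumes: pd.DataFrame,
    fates: Optional[pd.DataFrame] = None,
) -> list:
    """Assemble :class:`TumorVolumeSeries` per animal from long tables."""
    fate_map = {}
    if fates is not None:
        for row in fates.itertuples(index=False):
            day = None if pd.isna(row.day) else float(row.day)
            fate_map[row.animal_id] = AnimalFate(kind=row.fate, day=day)
    series = []
    for aid, sub in volumes.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        series.append(TumorVolumeSeries(
            animal_id=str(aid), group=str(sub["group"].iloc[0]),
            days=sub["day"].to_numpy(dtype=float),
            volumes=sub["volume_mm3"].to_numpy(dtype=float),
            fate=fate_map.get(aid)))
    return series


def read_sample_conditions_csv(path) -> dict:
    df = _read_csv(path, ("sample_id", "condition"))
    return dict(zip(df["sample_id"].astype(str), df["condition"].astype(str)))


# ---------------------------------------------------------------------------
# GCT / GMT / chip map


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix; returns rows x samples with the Description
    column stored in ``df.attrs['description']``."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ParseError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ParseError(f"{path}: malformed GCT dimension line 2")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.shape[0] != n_rows or df.shape[1] - 1 != n_cols:
        raise ParseError(f"{path}: matrix is {df.shape[0]}x{df.shape[1] - 1} but "
                         f"header declares {n_rows}x{n_cols}")
    desc = df.iloc[:, 0]
    out = df.iloc[:, 1:].astype(float)
    out.attrs["description"] = desc
    return out


def write_gct(values: pd.DataFrame, path,
              descriptions: Optional[pd.Series] = None) -> None:
    path = Path(path)
    desc = (descriptions if descriptions is not None
            else pd.Series("na", index=values.index))
    body = values.copy()
    body.insert(0, "Description", desc)
    body.index.name = "Name"
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        body.to_csv(fh, sep="\t")


def read_gmt(path) -> list:
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT lines need name, "
                                 f"description and >= 1 gene")
            sets.append(GeneSet(name=parts[0], description=parts[1],
                                genes=frozenset(g for g in parts[2:] if g)))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description or 'na'}\t{genes}\n")


def read_chip_map(path) -> dict:
    df = _read_csv_tsv(path, ("qualifier", "symbol"))
    return dict(zip(df["qualifier"].astype(str), df["symbol"].astype(str)))


def _read_csv_tsv(path, required):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def write_chip_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame({"qualifier": list(mapping.keys()),
                  "symbol": list(mapping.values())}).to_csv(
        path, sep="\t", index=False)


def load_expression_matrix(gct_path, conditions, chip_path=None) -> ExpressionMatrix:
    """Load a GCT matrix plus sample conditions (mapping or CSV path) and an
    optional qualifier-to-symbol map."""
    values = read_gct(gct_path)
    if not isinstance(conditions, Mapping):
        conditions = read_sample_conditions_csv(conditions)
    mapping = read_chip_map(chip_path) if chip_path is not None else None
    return ExpressionMatrix(values=values, sample_conditions=dict(conditions),
                            qualifier_to_symbol=mapping)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable thresholds of the three analyses, with study defaults.

    Defaults follow the emulated study design where it states one: a
    2000 mm^3 endpoint volume, day-34 study end, inclusive 2-fold gene
    lists; clip epsilon, fa levels, category filters and permutation
    count are documented package defaults.
    """

    seed: int = 0
    clip_epsilon: float = 0.005
    fa_levels: tuple = (0.5, 0.75, 0.9)
    endpoint_volume_mm3: float = 2000.0
    last_day: float = 34.0
    fold_threshold: float = 2.0
    category_filters: CategoryFilterConfig = field(default_factory=CategoryFilterConfig)
    n_perm: int = 1000
    gsea_weight_exponent: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        if "category_filters" in raw:
            raw["category_filters"] = CategoryFilterConfig(**raw["category_filters"])
        if "fa_levels" in raw:
            raw["fa_levels"] = tuple(raw["fa_levels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["fa_levels"] = list(self.fa_levels)
        cf = data.pop("category_filters")
        data["category_filters"] = {"t_change": cf.t_change,
                                    "unaffected_band": cf.unaffected_band,
                                    "t_extra": cf.t_extra}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
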