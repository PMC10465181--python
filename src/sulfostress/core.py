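"""Domain vocabulary and schema-validated table I/O.

The study design is three growth conditions for *Saccharolobus islandicus*
REY15A — an optimal control (pH 3.4, 76 °C), acid stress (pH 2.4, 76 °C) and
cold stress (pH 3.4, 66 °C) — sampled at two batch-growth phases (mid-log,
early stationary) in biological triplicate: 18 samples.  Each stress is
contrasted against the optimal condition at the same phase, giving four
stress-vs-optimal contrasts.

All on-disk tables are TSV with a mandatory header; ``NA`` is the only
missing-value token.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Phase",
    "SampleMeta",
    "Contrast",
    "full_design",
    "all_contrasts",
    "design_frame",
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "OD_SERIES_SCHEMA",
    "GDGT_PEAKS_SCHEMA",
    "DE_RESULTS_SCHEMA",
    "PROTEIN_QUANTS_SCHEMA",
    "DESIGN_SCHEMA",
]

NA_TOKEN = "NA"


class Condition(enum.Enum):
    """Growth condition: (pH, temperature in °C)."""

    OPTIMAL = ("optimal", 3.4, 76.0)
    ACID = ("acid", 2.4, 76.0)
    COLD = ("cold", 3.4, 66.0)

    def __init__(self, label: str, pH: float, temperature: float):
        self.label = label
        self.pH = pH
        self.temperature = temperature

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        for member in cls:
            if member.label == label:
                return member
        raise ValueError(f"unknown condition {label!r}")

    @property
    def is_stress(self) -> bool:
        return self is not Condition.OPTIMAL


class Phase(enum.Enum):
    """Harvest phase of the batch growth curve."""

    MID_LOG = ("mid_log", "ML")
    EARLY_STATIONARY = ("early_stationary", "ES")

    def __init__(self, label: str, short: str):
        self.label = label
        self.short = short

    @classmethod
    def from_label(cls, label: str) -> "Phase":
        for member in cls:
            if label in (member.label, member.short):
                return member
        raise ValueError(f"unknown phase {label!r}")


@dataclass(frozen=True)
class SampleMeta:
    """One biological sample: condition x phase x replicate."""

    condition: Condition
    phase: Phase
    replicate: int

    def __post_init__(self):
        if not 1 <= self.replicate <= 3:
            raise ValueError("replicate must be 1..3")

    @property
    def sample_id(self) -> str:
        return f"{self.condition.label}_{self.phase.short}_r{self.replicate}"


@dataclass(frozen=True)
class Contrast:
    """A stress-vs-optimal comparison at a single growth phase."""

    stress: Condition
    phase: Phase

    def __post_init__(self):
        if not self.stress.is_stress:
            raise ValueError("contrast stress condition must be acid or cold")

    baseline: Condition = Condition.OPTIMAL

    @property
    def name(self) -> str:
        return f"{self.stress.label}_vs_optimal_{self.phase.short}"


def full_design() -> list[SampleMeta]:
    """Enumerate the 18 samples: 3 conditions x 2 phases x 3 replicates."""
    return [
        SampleMeta(cond, phase, rep)
        for cond in Condition
        for phase in Phase
        for rep in (1, 2, 3)
    ]


def all_contrasts() -> list[Contrast]:
    """The four stress-vs-optimal contrasts."""
    return [
        Contrast(stress, phase)
        for stress in (Condition.ACID, Condition.COLD)
        for phase in Phase
    ]


def design_frame(samples: Iterable[SampleMeta] | None = None) -> pd.DataFrame:
    """Design as a DataFrame (sample_id, condition, phase, replicate)."""
    samples = list(samples) if samples is not None else full_design()
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition.label for s in samples],
            "phase": [s.phase.label for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# Schema-validated TSV I/O


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column specification for a TSV table kind.

    ``columns`` maps required column names to dtypes ("str", "int", "float").
    Unknown columns are preserved untouched; ``extra_dtype`` optionally coerces
    them (used for wide tables such as counts or GDGT peaks whose data columns
    are sample- or analyte-named).
    """

    name: str
    columns: dict[str, str]
    extra_dtype: str | None = None

    def required(self) -> list[str]:
        return list(self.columns)


_CASTS = {
    "str": lambda s: s.astype("string").astype(object),
    "int": lambda s: s.astype("int64"),
    "float": lambda s: s.astype("float64"),
}


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV table against ``schema``.

    Raises :class:`SchemaError` naming the missing column, or pointing at the
    offending row/column coordinate for an unparseable cell.  Row and column
    order are preserved; unknown columns pass through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False
    )
    for col in schema.required():
        if col not in df.columns:
            raise SchemaError(
                f"{schema.name} table {path.name!r} is missing required "
                f"column {col!r}"
            )
    out = {}
    for col in df.columns:
        dtype = schema.columns.get(col, schema.extra_dtype)
        if dtype is None or dtype == "str":
            out[col] = df[col].astype(object).where(df[col].notna(), np.nan)
            continue
        try:
            out[col] = _CASTS[dtype](df[col].astype("float64" if dtype == "float" else "string"))
        except (ValueError, TypeError):
            # locate the first bad cell for a coordinate-bearing message
            for i, raw in enumerate(df[col]):
                if pd.isna(raw):
                    continue
                try:
                    float(raw) if dtype == "float" else int(raw)
                except (ValueError, TypeError):
                    raise SchemaError(
                        f"{schema.name} table {path.name!r}: cannot parse "
                        f"cell at row {i + 1}, column {col!r}: {raw!r}"
                    ) from None
            raise
    return pd.DataFrame(out, columns=list(df.columns))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV: UTF-8, tab-delimited, ``NA`` for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, encoding="utf-8")


OD_SERIES_SCHEMA = TableSchema(
    "od_series", {"sample_id": "str", "time_h": "float", "od600": "float"}
)
DESIGN_SCHEMA = TableSchema(
    "design",
    {"sample_id": "str", "condition": "str", "phase": "str", "replicate": "int"},
)
GDGT_PEAKS_SCHEMA = TableSchema(
    "gdgt_peaks", {"sample_id": "str"}, extra_dtype="float"
)
COUNTS_SCHEMA = TableSchema("counts", {"gene_id": "str"}, extra_dtype="int")
DE_RESULTS_SCHEMA = TableSchema(
    "de_results",
    {
        "gene_id": "str",
        "contrast": "str",
        "log2fc": "float",
        "pvalue": "float",
        "padj": "float",
    },
)
PROTEIN_QUANTS_SCHEMA = TableSchema(
    "protein_quants",
    {
        "protein_id": "str",
        "sample_id": "str",
        "log2_ratio": "float",
        "within_se": "float",
        "n_spectra": "int",
    },
)
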