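"""GDGT lipid profiling: compositions, ring indices, condition comparisons.

GDGTs (glycerol dibiphytanyl glycerol tetraethers) carry 0-8 cyclopentane
rings; the Ring Index

    RI = sum_n n * [GDGT-n] / sum_n [GDGT-n]

is the abundance-weighted mean ring number of a profile — higher RI means a
more tightly packed, less permeable membrane.  Late-eluting chromatographic
isomers (GDGT-n') are summed into their major components before anything
else is computed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import SchemaError

__all__ = [
    "merge_isomers",
    "relative_abundance",
    "ring_index",
    "ring_index_frame",
    "summarize_condition",
    "compare_lipids",
    "two_sample_t",
]

_GDGT_RANGE = range(9)


def _gdgt_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("GDGT-") and not c.endswith("'")]


def _isomer_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("GDGT-") and c.endswith("'")]


def merge_isomers(peaks: pd.DataFrame) -> pd.DataFrame:
    """Sum isomer peak areas (GDGT-n') into their major components.

    Total area per sample is conserved exactly; isomer columns are dropped.
    An isomer column with no major counterpart raises :class:`SchemaError`.
    """
    out = peaks.copy()
    for iso in _isomer_cols(peaks):
        major = iso[:-1]
        if major not in out.columns:
            raise SchemaError(f"isomer column {iso!r} has no major column {major!r}")
        out[major] = out[major] + out[iso]
        out = out.drop(columns=[iso])
    return out


def relative_abundance(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize peak areas to relative abundances (rows on the simplex).

    Requires isomers to be merged already; an all-zero sample raises,
    naming the sample.
    """
    if _isomer_cols(peaks):
        raise ValueError("merge isomers before computing relative abundances")
    cols = _gdgt_cols(peaks)
    out = peaks.copy()
    totals = out[cols].sum(axis=1)
    for i, total in enumerate(totals):
        if total <= 0:
            sid = out["sample_id"].iloc[i] if "sample_id" in out else f"row {i}"
            raise ValueError(f"sample {sid}: total GDGT area is zero")
    out[cols] = out[cols].div(totals, axis=0)
    return out


def ring_index(composition) -> float:
    """RI of a single profile given as a mapping or sequence over GDGT-0..8."""
    if isinstance(composition, dict):
        f = np.array([composition.get(f"GDGT-{n}", 0.0) for n in _GDGT_RANGE],
                     dtype=float)
    else:
        f = np.asarray(composition, dtype=float)
        if f.size < 9:
            f = np.pad(f, (0, 9 - f.size))
    total = f.sum()
    if total <= 0:
        raise ValueError("composition has no mass")
    return float(np.dot(np.arange(f.size), f) / total)


def ring_index_frame(comp: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RI from a composition table (sample_id + GDGT-n columns)."""
    cols = _gdgt_cols(comp)
    rings = np.array([int(c.split("-")[1]) for c in cols], dtype=float)
    mat = comp[cols].to_numpy(dtype=float)
    ri = mat @ rings / mat.sum(axis=1)
    return pd.DataFrame({"sample_id": comp["sample_id"], "ring_index": ri})


def summarize_condition(ri: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean RI +/- SE per condition x phase (SE = sd/sqrt(n))."""
    merged = ri.merge(design[["sample_id", "condition", "phase"]], on="sample_id")
    rows = []
    for (cond, phase), grp in merged.groupby(["condition", "phase"], sort=False):
        vals = grp["ring_index"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"no samples for {cond}/{phase}")
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append(
            {
                "condition": cond,
                "phase": phase,
                "mean_ri": float(vals.mean()),
                "se_ri": float(se),
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows)


def two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool = True) -> tuple[float, float]:
    """Two-sample t-test returning (t, p), safe on zero-variance groups.

    Equal-mean zero-variance groups give p = 1; different means with zero
    variance give p = 0 (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero-variance groups with different means; p set to 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_lipids(
    comp: pd.DataFrame,
    design: pd.DataFrame,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    welch: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """t-tests on RI and each GDGT relative abundance between two groups.

    Groups are (condition, phase) pairs; Welch's t is the default, the
    pooled-variance test is available with ``welch=False``.  Flags at
    p < ``alpha``.
    """
    merged = comp.merge(design[["sample_id", "condition", "phase"]], on="sample_id")
    ri = ring_index_frame(comp).merge(
        design[["sample_id", "condition", "phase"]], on="sample_id"
    )

    def _select(df, key):
        cond, phase = key
        return df[(df["condition"] == cond) & (df["phase"] == phase)]

    rows = []
    t, p = two_sample_t(
        _select(ri, group_a)["ring_index"].to_numpy(),
        _select(ri, group_b)["ring_index"].to_numpy(),
        welch=welch,
    )
    rows.append({"metric": "ring_index", "t": t, "p": p, "significant": p < alpha})
    for col in _gdgt_cols(comp):
        t, p = two_sample_t(
            _select(merged, group_a)[col].to_numpy(),
            _select(merged, group_b)[col].to_numpy(),
            welch=welch,
        )
        rows.append({"metric": col, "t": t, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)
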