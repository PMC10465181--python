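"""Transcript-level analysis: replicate QC, a stand-in DE test, DEG calling
and cross-stress Venn partitioning.

The DE engine here is an explicitly labelled *stand-in* (Welch's t on
log2 counts-per-million with Benjamini-Hochberg adjustment) so that
synthetic count matrices flow end-to-end; it does not re-implement a
negative-binomial DE framework.  Real-data users supply an externally
produced DE result table instead.

Sign convention (kept throughout): **negative log2FC = increased
expression under stress**; log2FC is computed as mean(optimal) -
mean(stress) on the log2 scale.  A DEG requires |log2FC| >= 1 and
BH-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Contrast, all_contrasts
from .proteins import bh_adjust

__all__ = [
    "replicate_qc",
    "normalize_counts",
    "de_test_standin",
    "call_degs",
    "venn_partition",
    "VennPartition",
    "DifferentialExpressionModel",
    "DEResults",
]


def _count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" in counts.columns:
        return counts.set_index("gene_id")
    return counts


def replicate_qc(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation QC of libraries on raw counts.

    Per library: r_in is the best correlation to another library of the
    same condition x phase replicate group, r_out the best to any library
    outside it.  A library passes when r_in > 0.9; otherwise it is retained
    with a warning unless some outside library correlates better by more
    than 0.05 (r_out > r_in + 0.05), in which case it is excluded.
    """
    mat = _count_matrix(counts)
    design = design.set_index("sample_id")
    libs = [c for c in mat.columns if c in design.index]
    arr = mat[libs].to_numpy(dtype=float)
    sds = arr.std(axis=0)
    for j, lib in enumerate(libs):
        if sds[j] == 0:
            raise ValueError(f"library {lib}: constant counts, correlation undefined")
    corr = np.corrcoef(arr.T)
    groups = {lib: (design.loc[lib, "condition"], design.loc[lib, "phase"])
              for lib in libs}
    rows = []
    for j, lib in enumerate(libs):
        same = [k for k, other in enumerate(libs)
                if k != j and groups[other] == groups[lib]]
        other = [k for k, o in enumerate(libs) if k != j and groups[o] != groups[lib]]
        if not same:
            raise ValueError(f"library {lib}: no replicate partners in design")
        r_in = float(corr[j, same].max())
        r_out = float(corr[j, other].max()) if other else float("nan")
        if r_in > 0.9:
            status = "pass"
        elif other and r_out > r_in + 0.05:
            status = "excluded"
        else:
            status = "retained_with_warning"
        rows.append({"sample_id": lib, "r_in": r_in, "r_out": r_out,
                     "status": status})
    return pd.DataFrame(rows)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 pseudocount."""
    mat = _count_matrix(counts)
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total library: {zero.index[0]}")
    cpm = mat / totals * 1e6
    return np.log2(cpm + 0.5)


def de_test_standin(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: Contrast,
    count_floor: float = 5.0,
) -> pd.DataFrame:
    """Stand-in DE test: Welch's t on log2 CPM, BH-adjusted.

    Genes whose mean raw count across the contrast's samples falls below
    ``count_floor`` get pvalue = padj = NA (mirroring independent
    filtering) and can never become DEGs.  log2FC = mean(optimal) -
    mean(stress): negative means higher in stress.
    """
    mat = _count_matrix(counts)
    norm = normalize_counts(counts)

    def group(cond: str, phase: str) -> list[str]:
        d = design
        ids = d[(d["condition"] == cond) & (d["phase"] == phase)]["sample_id"]
        return [s for s in ids if s in mat.columns]

    stress_ids = group(contrast.stress.label, contrast.phase.label)
    opt_ids = group(contrast.baseline.label, contrast.phase.label)
    if len(stress_ids) < 2 or len(opt_ids) < 2:
        raise ValueError(f"contrast {contrast.name}: need >= 2 replicates per side")

    a = norm[opt_ids].to_numpy()       # baseline
    b = norm[stress_ids].to_numpy()    # stress
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate zero-variance genes: p = 1 when means agree, else 0
    degenerate = np.isnan(p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(degenerate & (lfc != 0), 0.0, p)

    raw_mean = mat[opt_ids + stress_ids].to_numpy().mean(axis=1)
    low = raw_mean < count_floor
    p = np.where(low, np.nan, p)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": mat.index,
            "contrast": contrast.name,
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
        }
    )


def call_degs(de: pd.DataFrame, lfc_min: float = 1.0,
              padj_max: float = 0.05) -> pd.DataFrame:
    """Directional DEG calls: |log2FC| >= 1 and padj < 0.05.

    Direction follows the stress-negative convention: log2FC <= -lfc_min
    is up_in_stress, log2FC >= +lfc_min is down_in_stress.  NA-padj rows
    are skipped.
    """
    ok = de.dropna(subset=["padj", "log2fc"])
    lfc = ok["log2fc"]
    hits = ok[(ok["padj"] < padj_max) & (lfc.abs() >= lfc_min)].copy()
    hits["direction"] = np.where(
        hits["log2fc"] <= -lfc_min, "up_in_stress", "down_in_stress"
    )
    return hits[["gene_id", "contrast", "direction"]].reset_index(drop=True)


@dataclass
class VennPartition:
    """Per-phase split of directional DEG responses across the two stresses."""

    phase: str
    counts: pd.DataFrame  # direction, n_unique_acid, n_unique_cold, n_common
    total_acid: int
    total_cold: int

    def conserved(self) -> bool:
        c = self.counts
        return (
            int((c["n_unique_acid"] + c["n_common"]).sum()) == self.total_acid
            and int((c["n_unique_cold"] + c["n_common"]).sum()) == self.total_cold
        )


def venn_partition(degs_acid: pd.DataFrame, degs_cold: pd.DataFrame,
                   phase: str) -> VennPartition:
    """Partition (gene, direction) DEG responses into stress-unique/common.

    Both inputs must come from contrasts at the same growth phase; keys are
    (gene_id, direction) so a gene moving in opposite directions under the
    two stresses is never counted as common.
    """
    for name, degs in (("acid", degs_acid), ("cold", degs_cold)):
        if len(degs) and not degs["contrast"].str.endswith(f"_{phase}").all():
            raise ValueError(f"{name} DEG calls are not all from phase {phase}")
    set_a = set(zip(degs_acid["gene_id"], degs_acid["direction"]))
    set_c = set(zip(degs_cold["gene_id"], degs_cold["direction"]))
    rows = []
    for direction in ("up_in_stress", "down_in_stress"):
        a = {g for g, d in set_a if d == direction}
        c = {g for g, d in set_c if d == direction}
        rows.append(
            {
                "direction": direction,
                "n_unique_acid": len(a - c),
                "n_unique_cold": len(c - a),
                "n_common": len(a & c),
            }
        )
    part = VennPartition(
        phase=phase,
        counts=pd.DataFrame(rows),
        total_acid=len(set_a),
        total_cold=len(set_c),
    )
    assert part.conserved(), "venn partition failed conservation"
    return part


@dataclass
class DEResults:
    """DE tables, DEG calls and QC for the fitted contrasts."""

    de_table: pd.DataFrame
    deg_calls: pd.DataFrame
    qc: pd.DataFrame
    lfc_min: float
    padj_max: float

    def degs_for(self, stress: str, phase_short: str) -> pd.DataFrame:
        name = f"{stress}_vs_optimal_{phase_short}"
        return self.deg_calls[self.deg_calls["contrast"] == name]

    def venn(self, phase_short: str) -> VennPartition:
        return venn_partition(
            self.degs_for("acid", phase_short),
            self.degs_for("cold", phase_short),
            phase_short,
        )

    def summary(self) -> str:
        counts = self.deg_calls.groupby(["contrast", "direction"]).size()
        lines = [
            "Transcript differential expression (stand-in test)",
            "=" * 62,
            f"thresholds: padj < {self.padj_max}, |log2FC| >= {self.lfc_min} "
            "(negative log2FC = up in stress)",
            counts.to_string() if len(counts) else "no DEGs called",
        ]
        return "\n".join(lines)


class DifferentialExpressionModel:
    """Stand-in DE model over a raw count matrix and the study design."""

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame):
        mat = _count_matrix(counts)
        if (mat.to_numpy() < 0).any():
            raise ValueError("count matrix has negative entries")
        self.counts = counts
        self.design = design

    def fit(
        self,
        contrasts: list[Contrast] | None = None,
        lfc_min: float = 1.0,
        padj_max: float = 0.05,
        count_floor: float = 5.0,
        run_qc: bool = True,
    ) -> DEResults:
        contrasts = contrasts if contrasts is not None else all_contrasts()
        qc = (replicate_qc(self.counts, self.design) if run_qc
              else pd.DataFrame(columns=["sample_id", "r_in", "r_out", "status"]))
        tables = [
            de_test_standin(self.counts, self.design, con, count_floor=count_floor)
            for con in contrasts
        ]
        de_table = pd.concat(tables, ignore_index=True)
        deg_calls = call_degs(de_table, lfc_min=lfc_min, padj_max=padj_max)
        return DEResults(
            de_table=de_table,
            deg_calls=deg_calls,
            qc=qc,
            lfc_min=lfc_min,
            padj_max=padj_max,
        )
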