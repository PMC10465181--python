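"""Transcript-protein concordance and the end-to-end pipeline.

The proteomic and transcriptomic tables use *inverted* sign conventions:
protein log2FC is positive when abundance rises under stress, while
transcript log2FC is negative when expression rises under stress.  This
module reconciles the two: each significant protein change is matched by
locus tag to a DEG call at the same stress and growth phase and classified
as ``consistent`` (both up or both down in stress), ``opposite``, or
``no_transcript_change``.

A curated reference table of 27 published significant protein changes with
matched transcript directions ships with the package
(``data/table1_protein_changes.tsv``) and anchors the bookkeeping: 18
distinct acid-stress proteins, of which 6 pairs are consistent and 9
opposite across all stresses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    Phase,
    all_contrasts,
    design_frame,
    read_table,
    write_table,
    OD_SERIES_SCHEMA,
    GDGT_PEAKS_SCHEMA,
    COUNTS_SCHEMA,
    PROTEIN_QUANTS_SCHEMA,
    TableSchema,
)

__all__ = [
    "concordance_classify",
    "concordance_counts",
    "load_reference_protein_changes",
    "reference_concordance",
    "run_pipeline",
    "write_report",
]


def load_reference_protein_changes() -> pd.DataFrame:
    """The packaged 27-row table of significant protein changes.

    Columns: locus_tag, stress, phase, protein_log2fc, annotation,
    transcript_direction (up/down/none, in-stress orientation).
    """
    with resources.as_file(
        resources.files("sulfostress.data") / "table1_protein_changes.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t")
    df["protein_log2fc"] = df["protein_log2fc"].astype(float)
    return df


def concordance_classify(protein_diffs: pd.DataFrame,
                         deg_calls: pd.DataFrame) -> pd.DataFrame:
    """Classify each significant protein change against the DEG calls.

    ``protein_diffs`` needs protein_id (locus tag), contrast and log2fc
    (positive = increased in stress); ``deg_calls`` needs gene_id, contrast
    and direction (up_in_stress / down_in_stress).  Matching is on exact
    (locus tag, contrast).  Duplicate keys in either input raise.
    """
    for name, df, keys in (
        ("protein_diffs", protein_diffs, ["protein_id", "contrast"]),
        ("deg_calls", deg_calls, ["gene_id", "contrast"]),
    ):
        if df.duplicated(keys).any():
            dup = df[df.duplicated(keys, keep=False)].iloc[0]
            raise ValueError(f"duplicate key in {name}: {tuple(dup[k] for k in keys)}")
    deg_map = {
        (g, c): d
        for g, c, d in zip(deg_calls["gene_id"], deg_calls["contrast"],
                           deg_calls["direction"])
    }
    rows = []
    for _, row in protein_diffs.iterrows():
        prot_dir = "increased" if row["log2fc"] > 0 else "decreased"
        deg_dir = deg_map.get((row["protein_id"], row["contrast"]))
        if deg_dir is None:
            tx_dir, cls = "none", "no_transcript_change"
        else:
            tx_dir = "up" if deg_dir == "up_in_stress" else "down"
            if (prot_dir, tx_dir) in (("increased", "up"), ("decreased", "down")):
                cls = "consistent"
            else:
                cls = "opposite"
        rows.append(
            {
                "locus_tag": row["protein_id"],
                "contrast": row["contrast"],
                "protein_log2fc": row["log2fc"],
                "protein_direction": prot_dir,
                "transcript_direction": tx_dir,
                "class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_tag", "contrast", "protein_log2fc",
                 "protein_direction", "transcript_direction", "class"],
    )


def concordance_counts(records: pd.DataFrame) -> dict:
    """Tallies of concordance classes, overall and per stress."""
    def tally(df: pd.DataFrame) -> dict:
        return {
            "n_consistent": int((df["class"] == "consistent").sum()),
            "n_opposite": int((df["class"] == "opposite").sum()),
            "n_no_change": int((df["class"] == "no_transcript_change").sum()),
            "n_total": int(len(df)),
        }

    out = {"overall": tally(records), "per_stress": {}}
    for stress in ("acid", "cold"):
        if len(records):
            sub = records[records["contrast"].str.startswith(stress + "_")]
        else:
            sub = records
        out["per_stress"][stress] = tally(sub)
    total = out["overall"]
    assert (
        total["n_consistent"] + total["n_opposite"] + total["n_no_change"]
        == total["n_total"]
    ), "concordance tallies failed conservation"
    return out


def reference_concordance() -> tuple[pd.DataFrame, dict]:
    """Concordance bookkeeping of the packaged reference protein table."""
    ref = load_reference_protein_changes()
    phase_short = {p.label: p.short for p in Phase}
    contrast = [
        f"{s}_vs_optimal_{phase_short[p]}" for s, p in zip(ref["stress"], ref["phase"])
    ]
    prot = pd.DataFrame(
        {
            "protein_id": ref["locus_tag"],
            "contrast": contrast,
            "log2fc": ref["protein_log2fc"],
        }
    )
    degs = pd.DataFrame(
        {
            "gene_id": ref["locus_tag"],
            "contrast": contrast,
            "direction": ref["transcript_direction"].map(
                {"up": "up_in_stress", "down": "down_in_stress", "none": None}
            ),
        }
    ).dropna(subset=["direction"])
    records = concordance_classify(prot, degs)
    return records, concordance_counts(records)


# ---------------------------------------------------------------------------
# Pipeline driver


class StageFailure(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


_INPUT_SCHEMAS: dict[str, TableSchema] = {
    "od_series.tsv": OD_SERIES_SCHEMA,
    "gdgt_peaks.tsv": GDGT_PEAKS_SCHEMA,
    "counts.tsv": COUNTS_SCHEMA,
    "protein_quants.tsv": PROTEIN_QUANTS_SCHEMA,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    in_dir: str | Path | None,
    out_dir: str | Path,
    simulate: bool = False,
    seed: int = 0,
    config=None,
    n_predicted_proteins: int = 2644,
) -> dict:
    """Run simulate? -> growth -> lipids -> degs -> protein-diff -> concordance.

    Either ``in_dir`` holds od_series.tsv, gdgt_peaks.tsv, counts.tsv,
    protein_quants.tsv and design.tsv, or ``simulate=True`` generates them
    under ``out_dir/inputs``.  Writes every stage table plus report.json /
    report.md and returns the report dict.
    """
    from .simulate import GeneratorConfig, simulate_all
    from .growth import GrowthCurveModel
    from .lipids import merge_isomers, relative_abundance, ring_index_frame, summarize_condition
    from .transcripts import DifferentialExpressionModel
    from .proteins import ProteinDiffModel, proteome_coverage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if simulate:
        cfg = config if config is not None else GeneratorConfig(seed=seed)
        in_dir = out_dir / "inputs"
        simulate_all(cfg, in_dir)
    elif in_dir is None:
        raise StageFailure("preflight", "no input directory and --simulate not given")
    in_dir = Path(in_dir)

    missing = [f for f in [*_INPUT_SCHEMAS, "design.tsv"] if not (in_dir / f).exists()]
    if missing:
        raise StageFailure("preflight", f"missing input tables: {missing}")

    tables = {
        name: read_table(in_dir / name, schema)
        for name, schema in _INPUT_SCHEMAS.items()
    }
    design = read_table(in_dir / "design.tsv",
                        TableSchema("design", {"sample_id": "str",
                                               "condition": "str",
                                               "phase": "str"}))
    report: dict = {
        "software": {"name": "sulfostress", "version": __version__},
        "seed": seed,
        "inputs": {f.name: _digest(f) for f in sorted(in_dir.glob("*.tsv"))},
        "thresholds": {
            "deg": {"lfc_min": 1.0, "padj_max": 0.05},
            "protein": {"lfc_min": 1.0, "padj_max": 0.1},
        },
        "stages": {},
    }

    # growth
    try:
        growth = GrowthCurveModel(tables["od_series.tsv"]).fit()
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageFailure("growth", str(exc)) from exc
    write_table(growth.summary_frame, out_dir / "growth_summary.tsv")
    report["stages"]["growth"] = {
        "n_conditions": len(growth.summary_frame),
        "anova_p": growth.anova_p,
        "td_h": dict(zip(growth.summary_frame["condition"],
                         growth.summary_frame["td_h"])),
    }

    # lipids
    try:
        merged = merge_isomers(tables["gdgt_peaks.tsv"])
        comp = relative_abundance(merged)
        ri = ring_index_frame(comp)
        ri_summary = summarize_condition(ri, design)
    except Exception as exc:
        raise StageFailure("lipids", str(exc)) from exc
    write_table(comp, out_dir / "compositions.tsv")
    write_table(ri, out_dir / "ring_index.tsv")
    write_table(ri_summary, out_dir / "ri_summary.tsv")
    report["stages"]["lipids"] = {
        "n_samples": len(ri),
        "mean_ri": {
            f"{r.condition}_{r.phase}": r.mean_ri for r in ri_summary.itertuples()
        },
    }

    # transcripts
    try:
        de = DifferentialExpressionModel(tables["counts.tsv"], design).fit()
    except Exception as exc:
        raise StageFailure("degs", str(exc)) from exc
    write_table(de.qc, out_dir / "qc.tsv")
    write_table(de.de_table, out_dir / "de_results.tsv")
    write_table(de.deg_calls, out_dir / "deg_calls.tsv")
    venns = {p.short: de.venn(p.short) for p in Phase}
    venn_rows = []
    for short, part in venns.items():
        for row in part.counts.itertuples():
            venn_rows.append(
                {
                    "phase": short,
                    "direction": row.direction,
                    "n_unique_acid": row.n_unique_acid,
                    "n_unique_cold": row.n_unique_cold,
                    "n_common": row.n_common,
                }
            )
    write_table(pd.DataFrame(venn_rows), out_dir / "venn.tsv")
    report["stages"]["degs"] = {
        "n_genes": tables["counts.tsv"].shape[0],
        "n_deg_calls": len(de.deg_calls),
        "venn": venn_rows,
    }

    # proteins
    try:
        prot = ProteinDiffModel(tables["protein_quants.tsv"], design).fit()
    except Exception as exc:
        raise StageFailure("protein-diff", str(exc)) from exc
    write_table(prot.frame, out_dir / "protein_diff.tsv")
    n_detected = tables["protein_quants.tsv"]["protein_id"].nunique()
    cov_raw, cov_round = proteome_coverage(n_detected, n_predicted_proteins)
    report["stages"]["protein_diff"] = {
        "n_proteins": n_detected,
        "n_significant": int(prot.frame["significant"].sum()),
        "coverage_percent": cov_raw,
        "coverage_percent_rounded": cov_round,
    }

    # concordance
    try:
        sig = prot.significant[["protein_id", "contrast", "log2fc"]]
        records = concordance_classify(sig, de.deg_calls)
        tallies = concordance_counts(records)
    except Exception as exc:
        raise StageFailure("concordance", str(exc)) from exc
    write_table(records, out_dir / "concordance.tsv")
    report["concordance"] = tallies
    report["proteome_coverage"] = {
        "n_detected": n_detected,
        "n_predicted": n_predicted_proteins,
        "percent": cov_raw,
        "rendered": f"{cov_round}%",
    }
    write_report(report, out_dir)
    return report


def write_report(state: dict, out_dir: str | Path) -> None:
    """Write report.json (machine) and report.md (human summary).

    Content is a pure function of the pipeline state; a regenerated report
    is byte-identical.  Timestamps, if a caller adds them, belong in the
    separate ``timestamp`` field so content hashing stays stable.
    """
    out_dir = Path(out_dir)
    content = {k: v for k, v in state.items() if k != "timestamp"}
    (out_dir / "report.json").write_text(
        json.dumps(state, indent=1, sort_keys=True, default=str) + "\n"
    )
    lines = ["# Pipeline report", ""]
    if "software" in content:
        lines.append(f"- software: {content['software']['name']} "
                     f"{content['software']['version']} (seed {content.get('seed')})")
    if "thresholds" in content:
        lines.append(f"- thresholds: {json.dumps(content['thresholds'])}")
    if "proteome_coverage" in content:
        cov = content["proteome_coverage"]
        lines.append(
            f"- proteome coverage: {cov['n_detected']} of {cov['n_predicted']} "
            f"predicted proteins ({cov['rendered']})"
        )
    if "concordance" in content:
        ov = content["concordance"]["overall"]
        lines.append(
            f"- concordance: {ov['n_consistent']} consistent, "
            f"{ov['n_opposite']} opposite, {ov['n_no_change']} without a "
            f"transcript change, of {ov['n_total']} significant protein changes"
        )
    for stage, info in content.get("stages", {}).items():
        lines.append(f"- stage {stage}: "
                     + ", ".join(f"{k}={v}" for k, v in info.items()
                                 if not isinstance(v, (dict, list))))
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
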