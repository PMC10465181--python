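"""Differential protein abundance via a layered-uncertainty Z procedure.

Input is one log2 ratio per protein x sample against a common internal
standard, together with the within-sample standard error across the
quantified spectra.  For each condition x phase group a protein gets

    m   = mean log2 ratio across biological replicates
    u   = combine(sd_between, mean within-sample SE)

where ``combine`` is the quadrature root-square sum sqrt(a^2 + b^2) by
default (a plain additive a + b reading is available).  The test statistic
for a stress-vs-optimal contrast is

    Z = (m_stress - m_optimal) / (u_stress + u_optimal)

— note the *plain sum* of the two total uncertainties in the denominator,
which makes the procedure deliberately conservative relative to a textbook
two-sample z-test.  Z maps to a two-sided standard-normal p-value,
Benjamini-Hochberg adjustment is applied per contrast, and a protein is
called significant when padj < 0.1 and |log2FC| >= 1.  Positive log2FC
means increased abundance under stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Contrast, all_contrasts

__all__ = [
    "condition_summary",
    "z_score",
    "p_from_z",
    "bh_adjust",
    "classify_significant",
    "proteome_coverage",
    "ProteinDiffModel",
    "ProteinDiffResults",
]


def _combine(sd_between: np.ndarray, se_within: np.ndarray, how: str) -> np.ndarray:
    if how == "quadrature":
        return np.sqrt(sd_between**2 + se_within**2)
    if how == "additive":
        return sd_between + se_within
    raise ValueError("combine must be 'quadrature' or 'additive'")


def condition_summary(
    quants: pd.DataFrame,
    sample_ids: list[str],
    combine: str = "quadrature",
) -> pd.DataFrame:
    """Per-protein abundance summary over one condition x phase group.

    Returns protein_id, m, sd_between, se_within_avg, u, n_reps.  Proteins
    quantified in fewer than two of the group's replicates keep their mean
    but get u = NaN, which excludes them from testing downstream.
    """
    sub = quants[quants["sample_id"].isin(sample_ids)]
    grouped = sub.groupby("protein_id", sort=False)
    out = grouped.agg(
        m=("log2_ratio", "mean"),
        sd_between=("log2_ratio", lambda v: v.std(ddof=1)),
        se_within_avg=("within_se", "mean"),
        n_reps=("log2_ratio", "size"),
    ).reset_index()
    u = _combine(out["sd_between"].to_numpy(), out["se_within_avg"].to_numpy(),
                 combine)
    u = np.where(out["n_reps"].to_numpy() >= 2, u, np.nan)
    out["u"] = u
    return out


def z_score(m_stress: float, u_stress: float, m_opt: float, u_opt: float) -> float:
    """Z = (m_stress - m_opt) / (u_stress + u_opt).

    A zero denominator gives Z = 0 (with a warning) when the numerator is
    also zero, else a signed infinity (downstream p = 0).
    """
    num = m_stress - m_opt
    den = u_stress + u_opt
    if den == 0.0:
        if num == 0.0:
            warnings.warn("zero uncertainty and zero difference; Z set to 0")
            return 0.0
        return float(np.sign(num) * np.inf)
    return float(num / den)


def p_from_z(z, two_sided: bool = True):
    """Standard-normal p-value; two-sided p = 2*(1 - Phi(|Z|)) by default."""
    z = np.asarray(z, dtype=float)
    p = stats.norm.sf(np.abs(z))
    out = 2.0 * p if two_sided else p
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the
    input order.  NaNs pass through and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    back = np.empty(m)
    back[order] = adj
    out[mask] = back
    return out


def classify_significant(results: pd.DataFrame, padj_max: float = 0.1,
                         lfc_min: float = 1.0) -> pd.DataFrame:
    """Flag rows with padj < padj_max and |log2FC| >= lfc_min."""
    out = results.copy()
    padj = out["padj"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["significant"] = (padj < padj_max) & (np.abs(lfc) >= lfc_min)
    out.loc[out["padj"].isna() | out["log2fc"].isna(), "significant"] = False
    return out


def proteome_coverage(n_detected: int, n_predicted: int) -> tuple[float, int]:
    """Percent of the predicted proteome detected: raw and integer-rounded."""
    if n_predicted <= 0 or not 0 <= n_detected <= n_predicted:
        raise ValueError("need 0 <= n_detected <= n_predicted, n_predicted > 0")
    raw = 100.0 * n_detected / n_predicted
    return raw, int(round(raw))


@dataclass
class ProteinDiffResults:
    """Per-protein per-contrast Z statistics with significance calls."""

    frame: pd.DataFrame          # protein_id, contrast, log2fc, z, p, padj, significant
    summaries: dict              # (condition, phase) -> condition_summary frame
    padj_max: float
    lfc_min: float
    combine: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def n_significant(self, stress: str | None = None) -> int:
        """Distinct significant proteins, optionally for one stress."""
        sig = self.significant
        if stress is not None:
            sig = sig[sig["contrast"].str.startswith(stress + "_")]
        return sig["protein_id"].nunique()

    def summary(self) -> str:
        counts = (
            self.frame.groupby("contrast")["significant"].sum().rename("n_significant")
        )
        lines = [
            "Protein differential abundance (layered-uncertainty Z)",
            "=" * 62,
            f"thresholds: padj < {self.padj_max}, |log2FC| >= {self.lfc_min}; "
            f"uncertainty combine: {self.combine}",
            counts.to_string(),
            f"distinct significant proteins: {self.frame[self.frame.significant]['protein_id'].nunique()}",
        ]
        return "\n".join(lines)


class ProteinDiffModel:
    """Stress-vs-optimal protein abundance model for the 18-sample design.

    Parameters
    ----------
    quants : tidy table with protein_id, sample_id, log2_ratio, within_se
    design : sample_id, condition, phase (the study design)
    """

    def __init__(self, quants: pd.DataFrame, design: pd.DataFrame):
        required = {"protein_id", "sample_id", "log2_ratio", "within_se"}
        missing = required - set(quants.columns)
        if missing:
            raise ValueError(f"quants missing columns {sorted(missing)}")
        if quants.duplicated(["protein_id", "sample_id"]).any():
            raise ValueError("duplicate protein x sample rows in quants")
        self.quants = quants
        self.design = design

    def _group_samples(self, condition: str, phase: str) -> list[str]:
        d = self.design
        return d[(d["condition"] == condition) & (d["phase"] == phase)][
            "sample_id"
        ].tolist()

    def fit(
        self,
        contrasts: list[Contrast] | None = None,
        padj_max: float = 0.1,
        lfc_min: float = 1.0,
        combine: str = "quadrature",
        two_sided: bool = True,
    ) -> ProteinDiffResults:
        contrasts = contrasts if contrasts is not None else all_contrasts()
        summaries: dict = {}

        def summary_for(condition: str, phase: str) -> pd.DataFrame:
            key = (condition, phase)
            if key not in summaries:
                summaries[key] = condition_summary(
                    self.quants, self._group_samples(condition, phase), combine
                ).set_index("protein_id")
            return summaries[key]

        frames = []
        for con in contrasts:
            s_stress = summary_for(con.stress.label, con.phase.label)
            s_opt = summary_for(con.baseline.label, con.phase.label)
            idx = s_stress.index.union(s_opt.index, sort=False)
            ss = s_stress.reindex(idx)
            so = s_opt.reindex(idx)
            lfc = ss["m"].to_numpy() - so["m"].to_numpy()
            den = ss["u"].to_numpy() + so["u"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(den > 0, lfc / den,
                             np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
            z = np.where(np.isnan(den), np.nan, z)
            p = np.where(np.isnan(z), np.nan, p_from_z(z, two_sided=two_sided))
            padj = bh_adjust(p)
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": idx,
                        "contrast": con.name,
                        "log2fc": lfc,
                        "z": z,
                        "p": p,
                        "padj": padj,
                    }
                )
            )
        frame = classify_significant(
            pd.concat(frames, ignore_index=True), padj_max=padj_max, lfc_min=lfc_min
        )
        return ProteinDiffResults(
            frame=frame,
            summaries={k: v.reset_index() for k, v in summaries.items()},
            padj_max=padj_max,
            lfc_min=lfc_min,
            combine=combine,
        )
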