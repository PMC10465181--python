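"""Growth-curve kinetics: doubling times, maximum densities, condition tests.

Two estimators are available for the specific growth rate mu:

``logistic``
    Nonlinear least-squares fit of the logistic batch-growth model
    OD(t) = K*OD0*exp(mu t) / (K + OD0*(exp(mu t) - 1)); the default, exact
    on noiseless logistic data and robust at realistic OD noise.
``window``
    Ordinary least squares on ln(OD) vs t over the contiguous run of at
    least ``min_points`` in-bounds observations that maximizes r^2 (ties
    broken toward the earlier window).  This mirrors the common practice of
    log-linear fitting over a hand-chosen exponential window; it slightly
    underestimates mu on saturating curves because OD is never far below K.

Doubling time is Td = ln 2 / mu.  The "+/-" reported everywhere is the
standard error sd/sqrt(n) across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "EstimationError",
    "fit_exponential_window",
    "fit_logistic",
    "doubling_time",
    "max_density_summary",
    "compare_max_density",
    "GrowthCurveModel",
    "GrowthResults",
]

LN2 = float(np.log(2.0))


class EstimationError(RuntimeError):
    pass


def doubling_time(mu: float) -> float:
    """Td = ln(2)/mu (hours); requires mu > 0."""
    if mu <= 0:
        raise ValueError(f"doubling time undefined for mu = {mu}")
    return LN2 / mu


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of y ~ t; r^2 = 1 for a zero-variance response."""
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    if syy == 0.0:
        return slope, 1.0
    return slope, (sxy * sxy) / (sxx * syy)


def fit_exponential_window(
    time: np.ndarray,
    od: np.ndarray,
    min_points: int = 4,
    od_bounds: tuple[float, float] | None = None,
    sample_id: str = "",
) -> tuple[float, tuple[float, float], float]:
    """Log-linear growth-rate fit over the best exponential window.

    Returns (mu, (t_start, t_end), r^2).  ``od_bounds`` defaults to
    (0.04, half the observed maximum OD).  Raises
    :class:`EstimationError` naming the sample when fewer than
    ``min_points`` observations fall inside the bounds.
    """
    time = np.asarray(time, dtype=float)
    od = np.asarray(od, dtype=float)
    if od_bounds is None:
        od_bounds = (0.04, float(od.max()) / 2.0)
    low, high = od_bounds
    mask = (od >= low) & (od <= high)
    if mask.sum() < min_points:
        raise EstimationError(
            f"sample {sample_id or '<unnamed>'}: only {int(mask.sum())} points "
            f"with OD in [{low}, {high}]; need {min_points}"
        )
    t_in, od_in = time[mask], od[mask]
    ln_od = np.log(od_in)
    n = t_in.size
    best = None  # (r2, start, end, mu)
    for start in range(n - min_points + 1):
        for end in range(start + min_points, n + 1):
            slope, r2 = _ols_slope(t_in[start:end], ln_od[start:end])
            if best is None or r2 > best[0] + 1e-15:
                best = (r2, start, end, slope)
    r2, start, end, mu = best
    return mu, (float(t_in[start]), float(t_in[end - 1])), r2


def _logistic(t, mu, K, od0):
    e = np.exp(np.clip(mu * t, None, 700.0))
    return K * od0 * e / (K + od0 * (e - 1.0))


def fit_logistic(time: np.ndarray, od: np.ndarray,
                 sample_id: str = "") -> tuple[float, float, float]:
    """Fit the logistic model by least squares; returns (mu, K, od0)."""
    time = np.asarray(time, dtype=float)
    od = np.asarray(od, dtype=float)
    if time.size < 4:
        raise EstimationError(
            f"sample {sample_id or '<unnamed>'}: need >= 4 points for a fit"
        )
    K0 = float(od.max())
    od0_0 = float(max(od[0], 1e-4))
    mu0 = 0.1
    try:
        popt, _ = optimize.curve_fit(
            _logistic, time, od, p0=[mu0, K0, od0_0],
            bounds=([1e-6, 1e-6, 1e-8], [10.0, 100.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise EstimationError(
            f"sample {sample_id or '<unnamed>'}: logistic fit failed: {exc}"
        ) from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


def max_density_summary(replicate_series: list[np.ndarray]) -> tuple[float, float]:
    """Mean and SE (sd/sqrt(n)) of per-replicate maximum OD.

    A single replicate yields SE = NaN (reported as NA on disk).
    """
    if not replicate_series:
        raise ValueError("no replicate series given")
    maxima = np.array([np.asarray(s, dtype=float).max() for s in replicate_series])
    if maxima.size == 1:
        return float(maxima[0]), float("nan")
    return float(maxima.mean()), float(maxima.std(ddof=1) / np.sqrt(maxima.size))


def compare_max_density(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus Tukey HSD on per-condition replicate maxima.

    Returns {"anova_F", "anova_p", "tukey": DataFrame}.  Degenerate inputs
    (zero variance everywhere) report p = 1 for equal means and p = 0 for
    different means rather than NaN.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    within_var = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    means = [a.mean() for a in arrays]
    if within_var < 1e-300:
        # degenerate: no within-group spread
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = means[j] - means[i]
                p = 1.0 if diff == 0.0 else 0.0
                pairs.append((names[i], names[j], diff, p, p < 0.05))
        all_equal = all(m == means[0] for m in means)
        return {
            "anova_F": 0.0 if all_equal else float("inf"),
            "anova_p": 1.0 if all_equal else 0.0,
            "tukey": pd.DataFrame(
                pairs, columns=["group1", "group2", "meandiff", "p_adj", "reject"]
            ),
        }
    F, p = stats.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey.columns = ["group1", "group2", "meandiff", "p_adj", "reject"]
    return {"anova_F": float(F), "anova_p": float(p), "tukey": tukey}


@dataclass
class GrowthResults:
    """Per-condition growth estimates plus the condition comparison."""

    summary_frame: pd.DataFrame      # condition, mu, td_h, td_se_h, max_od, max_od_se, n
    per_replicate: pd.DataFrame      # sample_id, condition, mu, td_h, max_od
    anova_p: float
    tukey: pd.DataFrame
    method: str

    def summary(self) -> str:
        lines = [
            "Growth kinetics summary",
            "=" * 62,
            f"method: {self.method}   Td = ln2/mu; +/- is SE across replicates",
            self.summary_frame.to_string(index=False, float_format="%.4g"),
            f"ANOVA on max densities: p = {self.anova_p:.4g}",
            "Tukey HSD:",
            self.tukey.to_string(index=False),
        ]
        return "\n".join(lines)


class GrowthCurveModel:
    """Doubling times and maximum densities from replicate OD600 trajectories.

    ``od_series`` needs columns sample_id, condition, time_h, od600 (one
    trajectory per sample_id).  ``fit`` estimates mu per trajectory,
    summarizes per condition and runs the ANOVA + Tukey comparison of
    maximum densities.
    """

    def __init__(self, od_series: pd.DataFrame):
        required = {"sample_id", "condition", "time_h", "od600"}
        missing = required - set(od_series.columns)
        if missing:
            raise ValueError(f"od_series missing columns {sorted(missing)}")
        self.od_series = od_series

    def fit(self, method: str = "logistic", min_points: int = 4,
            od_bounds: tuple[float, float] | None = None) -> GrowthResults:
        if method not in ("logistic", "window"):
            raise ValueError("method must be 'logistic' or 'window'")
        rep_rows = []
        for sid, grp in self.od_series.groupby("sample_id", sort=False):
            t = grp["time_h"].to_numpy()
            od = grp["od600"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"sample {sid}: times must be strictly increasing")
            if method == "logistic":
                mu, _, _ = fit_logistic(t, od, sample_id=sid)
            else:
                mu, _, _ = fit_exponential_window(
                    t, od, min_points=min_points, od_bounds=od_bounds,
                    sample_id=sid,
                )
            rep_rows.append(
                {
                    "sample_id": sid,
                    "condition": grp["condition"].iloc[0],
                    "mu": mu,
                    "td_h": doubling_time(mu) if mu > 0 else np.nan,
                    "max_od": float(od.max()),
                }
            )
        per_rep = pd.DataFrame(rep_rows)
        cond_rows = []
        for cond, grp in per_rep.groupby("condition", sort=False):
            n = len(grp)
            td = grp["td_h"].to_numpy()
            mx = grp["max_od"].to_numpy()
            cond_rows.append(
                {
                    "condition": cond,
                    "mu": float(grp["mu"].mean()),
                    "td_h": float(td.mean()),
                    "td_se_h": float(td.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "max_od": float(mx.mean()),
                    "max_od_se": float(mx.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
        summary = pd.DataFrame(cond_rows)
        groups = {
            cond: grp["max_od"].to_numpy()
            for cond, grp in per_rep.groupby("condition", sort=False)
        }
        if len(groups) >= 2 and all(a.size >= 2 for a in groups.values()):
            comp = compare_max_density(groups)
            anova_p, tukey = comp["anova_p"], comp["tukey"]
        else:
            anova_p = float("nan")
            tukey = pd.DataFrame(
                columns=["group1", "group2", "meandiff", "p_adj", "reject"]
            )
        return GrowthResults(
            summary_frame=summary,
            per_replicate=per_rep,
            anova_p=anova_p,
            tukey=tukey,
            method=method,
        )
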