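"""Seeded multi-omics data generator emulating the three-condition stress design.

Produces every pipeline input — OD600 growth curves, GDGT peak-area tables,
RNA-seq-like count matrices and isotope-ratio protein quantifications — with
the statistical structure the downstream analysis assumes, plus a
ground-truth manifest for parameter-recovery tests.

Defaults encode the study conditions: logistic growth with doubling times
6.8 / 9.8 / 14.0 h and carrying capacities 1.48 / 0.75 / 1.69 OD units for
optimal, acid and cold cultures started at OD600 = 0.02; GDGT compositions
whose ring indices hit 3.65 / 1.59 / 2.83 (mid-log) and 3.93 / 2.08 / 3.67
(early stationary); negative-binomial counts with a planted differential
set; and two-layer protein noise (between-replicate SD plus within-sample
spectral SE).

Every generator is a pure function of (config, seed): the global seed fans
out to per-stage streams as ``seed + stage_index`` (OD = 1, GDGT = 2,
counts = 3, proteins = 4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Condition,
    Phase,
    SampleMeta,
    Contrast,
    full_design,
    all_contrasts,
    design_frame,
    write_table,
)

__all__ = [
    "GeneratorConfig",
    "TruthManifest",
    "gen_design",
    "gen_od_curves",
    "gen_gdgt_peaks",
    "gen_counts",
    "gen_protein_quants",
    "make_truth",
    "simulate_all",
    "GDGT_COLUMNS",
]

GDGT_COLUMNS = [f"GDGT-{n}" for n in range(9)]
ISOMER_MAJORS = ("GDGT-3", "GDGT-4", "GDGT-5")

#: printed doubling times (h) and maximum densities per condition
_TD_HOURS = {Condition.OPTIMAL: 6.8, Condition.ACID: 9.8, Condition.COLD: 14.0}
_MAX_OD = {Condition.OPTIMAL: 1.48, Condition.ACID: 0.75, Condition.COLD: 1.69}
_OD0 = 0.02

#: target ring indices per condition x phase
RI_TARGETS = {
    (Condition.OPTIMAL, Phase.MID_LOG): 3.65,
    (Condition.ACID, Phase.MID_LOG): 1.59,
    (Condition.COLD, Phase.MID_LOG): 2.83,
    (Condition.OPTIMAL, Phase.EARLY_STATIONARY): 3.93,
    (Condition.ACID, Phase.EARLY_STATIONARY): 2.08,
    (Condition.COLD, Phase.EARLY_STATIONARY): 3.67,
}

# Qualitative composition templates (GDGT-0..8): acid profiles are enriched in
# rings 0-2 with GDGT-4 strongly reduced; cold profiles are depleted in all
# rings >= 5; optimal mass sits in rings 3-6; GDGT-7 stays below 1% where
# present and GDGT-8 is absent.  Each template is blended toward GDGT-0 or
# GDGT-6 to hit the target RI exactly.
_TEMPLATES = {
    (Condition.OPTIMAL, Phase.MID_LOG): [0.06, 0.07, 0.09, 0.13, 0.27, 0.21, 0.16, 0.006, 0.0],
    (Condition.OPTIMAL, Phase.EARLY_STATIONARY): [0.05, 0.06, 0.08, 0.11, 0.26, 0.23, 0.20, 0.006, 0.0],
    (Condition.ACID, Phase.MID_LOG): [0.30, 0.24, 0.20, 0.11, 0.02, 0.05, 0.07, 0.005, 0.0],
    (Condition.ACID, Phase.EARLY_STATIONARY): [0.26, 0.21, 0.18, 0.13, 0.04, 0.07, 0.10, 0.005, 0.0],
    (Condition.COLD, Phase.MID_LOG): [0.10, 0.13, 0.17, 0.22, 0.28, 0.06, 0.04, 0.0, 0.0],
    (Condition.COLD, Phase.EARLY_STATIONARY): [0.06, 0.08, 0.11, 0.17, 0.35, 0.13, 0.10, 0.0, 0.0],
}


def _ri_of(comp: np.ndarray) -> float:
    return float(np.dot(np.arange(9), comp) / comp.sum())


def _composition_for_target(template, target: float) -> np.ndarray:
    """Blend a simplex template toward GDGT-0 (to lower RI) or GDGT-6 (to
    raise it) so the resulting composition has exactly the target RI."""
    f = np.asarray(template, dtype=float)
    f = f / f.sum()
    r0 = _ri_of(f)
    if abs(r0 - target) < 1e-15:
        return f
    if target < r0:
        lam = 1.0 - target / r0
        anchor = np.eye(9)[0]
    else:
        lam = (target - r0) / (6.0 - r0)
        anchor = np.eye(9)[6]
    out = (1.0 - lam) * f + lam * anchor
    return out / out.sum()


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic study.

    Counts and proportions mirror the real design scale: 2,644 predicted
    genes, 1,107 quantified proteins.  Noise defaults put each analysis in
    the regime its estimator is meant for (see docs/methods.md).
    """

    n_genes: int = 2644
    n_proteins: int = 1107
    frac_de: float = 0.1
    effect_size_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.05
    base_mean_log: float = 3.5    # log-scale mean of gene baseline counts
    base_mean_sigma: float = 1.5  # log-scale SD of gene baseline counts
    dirichlet_concentration: float = 500.0
    od_noise_sd: float = 0.02
    od_interval_h: float = 2.0
    od_horizon_h: float = 168.0
    total_peak_area: float = 1e6
    frac_protein_shift: float = 0.1
    protein_shift_magnitude: float = 2.0
    protein_shift_mode: str = "single_contrast"  # or "all_contrasts"
    spectral_sd: float = 0.5
    between_rep_sd: float = 0.25
    n_spectra_rate: float = 5.0
    lib_size_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_proteins <= 0:
            raise ValueError("counts must be positive")
        for frac in (self.frac_de, self.frac_protein_shift):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.spectral_sd < 0 or self.between_rep_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be >= 0")


@dataclass
class TruthManifest:
    """Ground truth behind one synthetic dataset.

    growth: per-condition (mu 1/h, K OD units, od0); gdgt: per
    condition x phase true composition (9-simplex) and RI; transcript: per
    contrast true log2FC (stress-negative sign convention) and DE flags;
    protein: per-contrast planted shifts (positive = up in stress) plus the
    noise SDs used.
    """

    seed: int
    growth: dict = field(default_factory=dict)
    gdgt: dict = field(default_factory=dict)
    transcript: dict = field(default_factory=dict)
    protein: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def gen_design() -> tuple[list[SampleMeta], list[Contrast]]:
    """The full 18-sample design and its four contrasts (deterministic)."""
    return full_design(), all_contrasts()


def make_truth(config: GeneratorConfig) -> TruthManifest:
    """Draw the ground truth for one dataset (stage stream = seed)."""
    rng = np.random.default_rng(config.seed)
    truth = TruthManifest(seed=config.seed)

    truth.growth = {
        cond.label: {
            "mu": float(np.log(2) / _TD_HOURS[cond]),
            "td_h": _TD_HOURS[cond],
            "K": _MAX_OD[cond],
            "od0": _OD0,
        }
        for cond in Condition
    }

    truth.gdgt = {}
    for (cond, phase), target in RI_TARGETS.items():
        comp = _composition_for_target(_TEMPLATES[(cond, phase)], target)
        truth.gdgt[f"{cond.label}_{phase.short}"] = {
            "composition": comp.tolist(),
            "ri": target,
        }

    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]
    lo, hi = config.effect_size_range
    truth.transcript = {"genes": genes, "contrasts": {}}
    n_de = int(round(config.frac_de * config.n_genes))
    for phase in Phase:
        # per phase: 40% acid-unique, 20% cold-unique, 40% common responses
        idx = rng.choice(config.n_genes, size=n_de, replace=False)
        n_acid_u = int(0.4 * n_de)
        n_cold_u = int(0.2 * n_de)
        acid_u, cold_u = idx[:n_acid_u], idx[n_acid_u:n_acid_u + n_cold_u]
        common = idx[n_acid_u + n_cold_u:]
        for stress in (Condition.ACID, Condition.COLD):
            lfc = np.zeros(config.n_genes)
            members = np.concatenate(
                [acid_u if stress is Condition.ACID else cold_u, common]
            )
            mags = rng.uniform(lo, hi, size=members.size)
            signs = rng.choice([-1.0, 1.0], size=members.size)
            lfc[members] = mags * signs
            # common genes must share sign and magnitude across stresses
            if stress is Condition.COLD and common.size:
                acid_lfc = truth.transcript["contrasts"][
                    Contrast(Condition.ACID, phase).name
                ]["true_log2fc"]
                lfc[common] = np.asarray(acid_lfc)[common]
            truth.transcript["contrasts"][Contrast(stress, phase).name] = {
                "true_log2fc": lfc.tolist(),
                "is_de": (np.abs(lfc) >= 1.0).tolist(),
            }

    proteins = [f"SiRe_{i:04d}" for i in range(config.n_proteins)]
    baseline = rng.normal(0.0, 0.5, size=config.n_proteins)
    n_shift = int(round(config.frac_protein_shift * config.n_proteins))
    shifted = rng.choice(config.n_proteins, size=n_shift, replace=False)
    contrasts = all_contrasts()
    shifts: dict[str, dict[str, float]] = {c.name: {} for c in contrasts}
    if config.protein_shift_mode not in ("single_contrast", "all_contrasts"):
        raise ValueError("protein_shift_mode must be single_contrast or all_contrasts")
    which = rng.integers(0, len(contrasts), size=n_shift)
    signs = rng.choice([-1.0, 1.0], size=n_shift)
    for j, prot_idx in enumerate(shifted):
        value = float(signs[j] * config.protein_shift_magnitude)
        if config.protein_shift_mode == "all_contrasts":
            for con in contrasts:
                shifts[con.name][proteins[prot_idx]] = value
        else:
            shifts[contrasts[which[j]].name][proteins[prot_idx]] = value
    truth.protein = {
        "proteins": proteins,
        "baseline_log2": baseline.tolist(),
        "shifts": shifts,
        "between_rep_sd": config.between_rep_sd,
        "spectral_sd": config.spectral_sd,
    }
    return truth


def _logistic(t, mu, K, od0):
    e = np.exp(mu * t)
    return K * od0 * e / (K + od0 * (e - 1.0))


def gen_od_curves(config: GeneratorConfig, truth: TruthManifest) -> pd.DataFrame:
    """Logistic OD600 trajectories, one per condition x replicate culture.

    Additive Gaussian noise (sd = od_noise_sd) truncated at zero.
    """
    rng = np.random.default_rng(config.seed + 1)
    t = np.arange(0.0, config.od_horizon_h + 1e-9, config.od_interval_h)
    rows = []
    for cond in Condition:
        g = truth.growth[cond.label]
        if g["mu"] <= 0 or g["K"] <= 0 or g["od0"] <= 0:
            raise ValueError("growth parameters must be positive")
        clean = _logistic(t, g["mu"], g["K"], g["od0"])
        for rep in (1, 2, 3):
            od = clean + rng.normal(0.0, config.od_noise_sd, size=t.size)
            od = np.clip(od, 0.0, None)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": f"{cond.label}_r{rep}",
                        "condition": cond.label,
                        "replicate": rep,
                        "time_h": t,
                        "od600": od,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def gen_gdgt_peaks(config: GeneratorConfig, truth: TruthManifest) -> pd.DataFrame:
    """Per-sample GDGT peak areas: Dirichlet draws around the true composition.

    A fraction of GDGT-3/4/5 mass is split off into late-eluting isomer
    columns (GDGT-n'): isomer shares are drawn U[0, 0.10] for acid samples
    and U[0, 0.02] otherwise.  Total area is conserved by the split.
    """
    rng = np.random.default_rng(config.seed + 2)
    conc = config.dirichlet_concentration
    records = []
    for sample in full_design():
        key = f"{sample.condition.label}_{sample.phase.short}"
        comp = np.asarray(truth.gdgt[key]["composition"])
        alpha = conc * comp
        draw = np.zeros(9)
        pos = alpha > 0
        draw[pos] = rng.dirichlet(alpha[pos])
        areas = config.total_peak_area * draw
        rec = {"sample_id": sample.sample_id}
        rec.update(dict(zip(GDGT_COLUMNS, areas)))
        iso_hi = 0.10 if sample.condition is Condition.ACID else 0.02
        for major in ISOMER_MAJORS:
            share = rng.uniform(0.0, iso_hi)
            iso = rec[major] * share
            rec[major] -= iso
            rec[major + "'"] = iso
        records.append(rec)
    return pd.DataFrame.from_records(records)


def gen_counts(config: GeneratorConfig, truth: TruthManifest) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x 18 samples).

    Gene baseline means are log-normal; library sizes jitter by
    ``lib_size_jitter``; for a DE gene in a contrast the stress-condition
    mean is scaled by 2**(-true log2FC), so a negative true log2FC yields
    higher counts under stress (the transcript sign convention).

    ``dispersion`` interpolates from NB overdispersion through Poisson
    (values below 1e-12) down to the fully degenerate limit at exactly 0,
    where counts equal their rounded expectations.
    """
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(config.seed + 3)
    genes = truth.transcript["genes"]
    n = len(genes)
    base_mean = rng.lognormal(mean=config.base_mean_log,
                              sigma=config.base_mean_sigma, size=n)
    samples = full_design()
    lib = rng.uniform(1 - config.lib_size_jitter, 1 + config.lib_size_jitter,
                      size=len(samples))
    data = {}
    for j, sample in enumerate(samples):
        mean = base_mean * lib[j]
        if sample.condition.is_stress:
            cname = Contrast(sample.condition, sample.phase).name
            lfc = np.asarray(truth.transcript["contrasts"][cname]["true_log2fc"])
            mean = mean * np.power(2.0, -lfc)
        if config.dispersion == 0.0:
            # fully degenerate limit: expectation counts, no sampling noise
            counts = np.round(mean).astype(np.int64)
        elif config.dispersion < 1e-12:
            counts = rng.poisson(mean)
        else:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mean * config.dispersion)
            counts = rng.poisson(lam)
        data[sample.sample_id] = counts
    out = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return out.reset_index()


def gen_protein_quants(config: GeneratorConfig, truth: TruthManifest) -> pd.DataFrame:
    """Protein log2 ratios vs a common internal standard, per protein x sample.

    Each cell: n_spectra ~ 1 + Poisson(rate); spectrum-level log2 ratios are
    Normal(true abundance + replicate effect, spectral_sd); the reported
    value is their mean and the reported SE is the sample SD / sqrt(n)
    (zero when a single spectrum leaves the SD undefined).
    """
    rng = np.random.default_rng(config.seed + 4)
    proteins = truth.protein["proteins"]
    index_of = {pid: i for i, pid in enumerate(proteins)}
    baseline = np.asarray(truth.protein["baseline_log2"])
    shifts = truth.protein["shifts"]
    n_prot = len(proteins)
    frames = []
    for sample in full_design():
        cell_shift = np.zeros(n_prot)
        if sample.condition.is_stress:
            cname = Contrast(sample.condition, sample.phase).name
            for pid, s in shifts[cname].items():
                cell_shift[index_of[pid]] = s
        true_mean = baseline + cell_shift
        rep_eff = rng.normal(0.0, config.between_rep_sd, size=n_prot)
        n_spec = 1 + rng.poisson(config.n_spectra_rate, size=n_prot)
        total = int(n_spec.sum())
        centers = np.repeat(true_mean + rep_eff, n_spec)
        draws = centers + config.spectral_sd * rng.standard_normal(total)
        starts = np.concatenate(([0], np.cumsum(n_spec)[:-1]))
        means = np.add.reduceat(draws, starts) / n_spec
        dev = draws - np.repeat(means, n_spec)
        ss = np.add.reduceat(dev * dev, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = ss / (n_spec - 1)
        var = np.where(n_spec > 1, var, 0.0)
        se = np.sqrt(var) / np.sqrt(n_spec)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": proteins,
                    "sample_id": sample.sample_id,
                    "log2_ratio": means,
                    "within_se": se,
                    "n_spectra": n_spec,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_all(config: GeneratorConfig, out_dir: str | Path | None = None):
    """Generate every pipeline input; optionally write them to ``out_dir``.

    Returns (truth, tables) where tables maps name -> DataFrame for
    design, od_series, gdgt_peaks, counts and protein_quants.
    """
    truth = make_truth(config)
    tables = {
        "design": design_frame(),
        "od_series": gen_od_curves(config, truth),
        "gdgt_peaks": gen_gdgt_peaks(config, truth),
        "counts": gen_counts(config, truth),
        "protein_quants": gen_protein_quants(config, truth),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            write_table(df, out / f"{name}.tsv")
        truth.to_json(out / "truth.json")
    return truth, tables
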