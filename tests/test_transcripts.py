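"""Replicate QC, stand-in DE test, DEG calling and Venn partitioning."""

import numpy as np
import pandas as pd
import pytest

from sulfostress.core import Condition, Contrast, Phase, design_frame
from sulfostress.simulate import GeneratorConfig, make_truth, gen_counts
from sulfostress.transcripts import (
    DifferentialExpressionModel,
    call_degs,
    de_test_standin,
    normalize_counts,
    replicate_qc,
    venn_partition,
)

ACID_ML = Contrast(Condition.ACID, Phase.MID_LOG)


def tiny_counts(n_genes=40, groups=(("optimal", "mid_log"), ("acid", "mid_log")),
                shift_gene=None, shift_factor=1.0, seed=0, base=1000):
    """Small deterministic count table over two triplicate groups."""
    rng = np.random.default_rng(seed)
    design = design_frame()
    cols = {}
    for cond, phase in groups:
        ids = design[(design.condition == cond) & (design.phase == phase)].sample_id
        for sid in ids:
            mean = np.full(n_genes, float(base))
            if shift_gene is not None and cond != "optimal":
                mean[shift_gene] *= shift_factor
            cols[sid] = rng.poisson(mean)
    out = pd.DataFrame(cols)
    out.insert(0, "gene_id", [f"g{i}" for i in range(n_genes)])
    return out, design


class TestReplicateQC:
    def test_identical_libraries_pass(self):
        counts, design = tiny_counts(seed=1)
        # perfectly correlated libraries within each group
        base = counts.iloc[:, 1].to_numpy()
        for c in counts.columns[1:]:
            counts[c] = base + np.arange(len(base))  # identical across libraries
        qc = replicate_qc(counts, design)
        assert (qc["status"] == "pass").all()
        assert np.allclose(qc["r_in"], 1.0)

    def test_weakly_correlated_library_retained(self, rng):
        counts, design = tiny_counts(n_genes=200, seed=2)
        # corrupt one library so r_in drops but no outside library does better
        noisy = counts.columns[1]
        counts[noisy] = rng.permutation(counts[noisy].to_numpy())
        qc = replicate_qc(counts, design).set_index("sample_id")
        row = qc.loc[noisy]
        if row["r_in"] <= 0.9 and not row["r_out"] > row["r_in"] + 0.05:
            assert row["status"] == "retained_with_warning"

    def test_exclusion_rule(self):
        # craft: library correlates 0.5 within group, ~1.0 with outside group
        rng = np.random.default_rng(3)
        design = design_frame()
        n = 300
        a = rng.poisson(500.0, n).astype(float)
        b = rng.poisson(500.0, n).astype(float)
        cols = {"gene_id": [f"g{i}" for i in range(n)]}
        for sid in ("optimal_ML_r1", "optimal_ML_r2"):
            cols[sid] = a + rng.normal(0, 5, n)
        cols["optimal_ML_r3"] = b + rng.normal(0, 5, n)  # the stray library
        for sid in ("acid_ML_r1", "acid_ML_r2", "acid_ML_r3"):
            cols[sid] = b + rng.normal(0, 5, n)
        qc = replicate_qc(pd.DataFrame(cols), design).set_index("sample_id")
        assert qc.loc["optimal_ML_r3", "status"] == "excluded"

    def test_constant_library_rejected(self):
        counts, design = tiny_counts(seed=4)
        counts[counts.columns[1]] = 7
        with pytest.raises(ValueError, match=str(counts.columns[1])):
            replicate_qc(counts, design)


class TestNormalize:
    def test_cpm_arithmetic(self):
        counts = pd.DataFrame({"gene_id": ["g0", "g1"],
                               "s1": [1000, 999000]})
        norm = normalize_counts(counts)
        assert norm.loc["g0", "s1"] == pytest.approx(np.log2(1000.5))

    def test_depth_invariance_up_to_pseudocount(self):
        counts = pd.DataFrame({"gene_id": ["g0", "g1"], "s1": [100, 900],
                               "s2": [200, 1800]})
        norm = normalize_counts(counts)
        assert np.allclose(norm["s1"], norm["s2"], atol=1e-9)

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"gene_id": ["g0"], "s1": [0]})
        with pytest.raises(ValueError, match="s1"):
            normalize_counts(counts)


class TestDeStandin:
    def test_identical_groups_null(self):
        counts, design = tiny_counts(seed=5)
        de = de_test_standin(counts, design, ACID_ML)
        assert np.nanmedian(de["pvalue"]) > 0.2
        assert de["log2fc"].abs().max() < 0.5

    def test_true_effect_recovered_with_sign_convention(self):
        # gene 0 up in stress by 4x -> estimated log2FC ~ -2
        counts, design = tiny_counts(shift_gene=0, shift_factor=4.0, seed=6)
        de = de_test_standin(counts, design, ACID_ML)
        assert de["log2fc"].iloc[0] == pytest.approx(-2.0, abs=0.3)
        assert de["padj"].iloc[0] < 0.05

    def test_low_count_genes_filtered_to_na(self):
        counts, design = tiny_counts(seed=7)
        counts.iloc[0, 1:] = 1  # mean raw count below the floor of 5
        de = de_test_standin(counts, design, ACID_ML)
        assert np.isnan(de["padj"].iloc[0]) and np.isnan(de["pvalue"].iloc[0])
        assert len(call_degs(de.iloc[[0]])) == 0

    def test_group_swap_flips_log2fc_sign(self):
        counts, design = tiny_counts(shift_gene=3, shift_factor=3.0, seed=8)
        de = de_test_standin(counts, design, ACID_ML)
        swapped = design.copy()
        swapped["condition"] = swapped["condition"].map(
            {"optimal": "acid", "acid": "optimal"}
        ).fillna(swapped["condition"])
        de_swap = de_test_standin(counts, swapped, ACID_ML)
        np.testing.assert_allclose(de["log2fc"], -de_swap["log2fc"], atol=1e-12)


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (-2.1, 0.001, "up_in_stress"),    # e.g. grsB under acid at mid-log
            (2.5, 0.01, "down_in_stress"),
            (-0.9, 1e-10, None),              # fold-change gate
            (-2.0, 0.06, None),               # padj gate
            (1.0, 0.049, "down_in_stress"),   # boundary |lfc| = 1 included
        ],
    )
    def test_threshold_and_direction(self, lfc, padj, expected):
        de = pd.DataFrame(
            {"gene_id": ["g"], "contrast": ["acid_vs_optimal_ML"],
             "log2fc": [lfc], "pvalue": [padj], "padj": [padj]}
        )
        calls = call_degs(de)
        if expected is None:
            assert len(calls) == 0
        else:
            assert calls["direction"].iloc[0] == expected


def degs_frame(pairs, contrast):
    return pd.DataFrame(
        [{"gene_id": g, "contrast": contrast, "direction": d} for g, d in pairs]
    )


class TestVennPartition:
    def test_enumerated_example(self):
        acid = degs_frame([("g1", "up_in_stress"), ("g2", "down_in_stress")],
                          "acid_vs_optimal_ML")
        cold = degs_frame([("g1", "up_in_stress"), ("g3", "up_in_stress")],
                          "cold_vs_optimal_ML")
        part = venn_partition(acid, cold, "ML")
        c = part.counts.set_index("direction")
        assert c.loc["up_in_stress", "n_common"] == 1
        assert c.loc["down_in_stress", "n_unique_acid"] == 1
        assert c.loc["up_in_stress", "n_unique_cold"] == 1
        assert part.conserved()

    def test_disjoint_and_identical_sets(self):
        acid = degs_frame([("g1", "up_in_stress")], "acid_vs_optimal_ES")
        cold = degs_frame([("g2", "up_in_stress")], "cold_vs_optimal_ES")
        assert venn_partition(acid, cold, "ES").counts["n_common"].sum() == 0
        same = degs_frame([("g1", "up_in_stress"), ("g2", "down_in_stress")],
                          "acid_vs_optimal_ES")
        same_cold = same.assign(contrast="cold_vs_optimal_ES")
        part = venn_partition(same, same_cold, "ES")
        assert part.counts["n_common"].sum() == 2
        assert part.counts[["n_unique_acid", "n_unique_cold"]].sum().sum() == 0

    def test_opposite_directions_never_common(self):
        acid = degs_frame([("g1", "up_in_stress")], "acid_vs_optimal_ML")
        cold = degs_frame([("g1", "down_in_stress")], "cold_vs_optimal_ML")
        part = venn_partition(acid, cold, "ML")
        assert part.counts["n_common"].sum() == 0

    def test_phase_mismatch_rejected(self):
        acid = degs_frame([("g1", "up_in_stress")], "acid_vs_optimal_ML")
        cold = degs_frame([("g1", "up_in_stress")], "cold_vs_optimal_ES")
        with pytest.raises(ValueError, match="phase"):
            venn_partition(acid, cold, "ML")


class TestModelEndToEnd:
    def test_truth_recovery_high_counts(self):
        cfg = GeneratorConfig(
            n_genes=300, frac_de=0.15, dispersion=1e-13, lib_size_jitter=0.0,
            base_mean_log=6.0, base_mean_sigma=0.0, seed=9,
        )
        truth = make_truth(cfg)
        counts = gen_counts(cfg, truth)
        res = DifferentialExpressionModel(counts, design_frame()).fit()
        for con, entry in truth.transcript["contrasts"].items():
            lfc_true = np.array(entry["true_log2fc"])
            sub = res.de_table[res.de_table["contrast"] == con]
            est = sub.set_index("gene_id")["log2fc"]
            genes = np.array(truth.transcript["genes"])
            de_idx = np.abs(lfc_true) >= 1
            # CPM normalization absorbs a small composition offset when many
            # genes shift one way; allow for it on top of Poisson noise
            np.testing.assert_allclose(
                est[genes[de_idx]].to_numpy(), lfc_true[de_idx], atol=0.5
            )

    def test_summary_mentions_thresholds(self, small_dataset):
        _, tables = small_dataset
        res = DifferentialExpressionModel(tables["counts"],
                                          tables["design"]).fit()
        assert "padj < 0.05" in res.summary()

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"gene_id": ["g0"], "s1": [-1]})
        with pytest.raises(ValueError, match="negative"):
            DifferentialExpressionModel(df, design_frame())
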