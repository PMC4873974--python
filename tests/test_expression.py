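"""Moderated t: limits, calibration, FDR control, BH oracle, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from comboscreen import (ExpressionMatrix, ExpressionTruth, ModeratedTTest,
                         bh_adjust, call_degs, gen_expression, zscore_by_gene)


def two_group_matrix(values_ctrl, values_trt, genes=None):
    n1, n2 = values_ctrl.shape[1], values_trt.shape[1]
    samples = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    genes = genes or [f"g{i}" for i in range(values_ctrl.shape[0])]
    frame = pd.DataFrame(np.hstack([values_ctrl, values_trt]), index=genes,
                         columns=samples)
    groups = {s: ("control" if s.startswith("c") else "treated")
              for s in samples}
    return ExpressionMatrix(frame, groups)


class TestModeratedT:
    def test_unmoderated_limit_equals_hand_pooled_t(self):
        # gene 1: ctrl (1,2,3), trt (3,4,5): diff=2, s1^2=s2^2=1,
        # pooled s^2=1, se=sqrt(2/3), t = 2/sqrt(2/3) = sqrt(6)
        ctrl = np.array([[1.0, 2.0, 3.0], [5.0, 5.5, 6.0]])
        trt = np.array([[3.0, 4.0, 5.0], [5.0, 5.5, 6.0]])
        data = two_group_matrix(ctrl, trt)
        res = ModeratedTTest(data, moderation=False).fit()
        assert res.d0 == 0.0
        assert res.table.loc["g0", "t_mod"] == pytest.approx(np.sqrt(6.0))
        assert res.table.loc["g0", "log2fc"] == pytest.approx(2.0)
        from scipy import stats
        assert res.table.loc["g0", "p"] == pytest.approx(
            2 * stats.t.sf(np.sqrt(6.0), 4))

    def test_log2fc_of_exact_unit_shift(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(8, 0.3, size=(30, 3))
        trt = ctrl + 1.0
        res = ModeratedTTest(two_group_matrix(ctrl, trt)).fit()
        assert res.table["log2fc"].to_numpy() == pytest.approx(1.0)

    def test_zero_variance_zero_difference_gives_null_call(self):
        ctrl = np.vstack([np.tile([5.0, 5.0, 5.0], (1, 1)),
                          np.random.default_rng(1).normal(0, 1, (20, 3))])
        trt = ctrl.copy()
        res = ModeratedTTest(two_group_matrix(ctrl, trt)).fit()
        assert res.table.iloc[0]["t_mod"] == 0.0
        assert res.table.iloc[0]["p"] == 1.0

    def test_null_type_i_error_calibrated(self):
        # planted null over 2000 genes: raw p < 0.05 within binomial 3 SD
        truth = ExpressionTruth((), {}, sigma=0.25, n_per_group=3)
        mat, sheet = gen_expression(truth, p_genes=2000, seed=42)
        res = ModeratedTTest(ExpressionMatrix.from_frames(mat, sheet)).fit()
        frac = (res.table["p"] < 0.05).mean()
        tol = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < tol

    def test_large_planted_effects_all_flagged(self):
        degs = tuple(f"DEG{i}" for i in range(20))
        truth = ExpressionTruth(degs, {g: 4.0 for g in degs}, sigma=0.1,
                                n_per_group=3)
        mat, sheet = gen_expression(truth, p_genes=500, seed=7)
        res = ModeratedTTest(ExpressionMatrix.from_frames(mat, sheet)).fit()
        assert set(degs) <= set(res.degs)
        assert (res.table.loc[list(degs), "direction"] == "up").all()

    def test_realized_fdr_controlled_over_simulations(self):
        # 10% planted DEGs (log2fc 2, sigma 0.25, n=3), 200 datasets
        fdp = []
        degs = tuple(f"DEG{i:03d}" for i in range(50))
        truth = ExpressionTruth(degs, {g: 2.0 for g in degs}, sigma=0.25,
                                n_per_group=3)
        for seed in range(200):
            mat, sheet = gen_expression(truth, p_genes=500, seed=seed)
            res = ModeratedTTest(ExpressionMatrix.from_frames(mat, sheet)).fit()
            called = res.table.index[res.table["fdr"] <= 0.05]
            if len(called):
                fdp.append(np.mean([g not in degs for g in called]))
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.075

    def test_degenerate_prior_pools_variances(self):
        # equal per-gene variance: moment fit finds no excess spread
        truth = ExpressionTruth((), {}, sigma=0.25, n_per_group=3)
        mat, sheet = gen_expression(truth, p_genes=2000, seed=10)
        res = ModeratedTTest(ExpressionMatrix.from_frames(mat, sheet)).fit()
        assert np.isinf(res.d0)
        assert res.s0_sq == pytest.approx(0.0625, rel=0.15)

    def test_tiny_gene_count_falls_back_to_ordinary_t(self):
        rng = np.random.default_rng(3)
        data = two_group_matrix(rng.normal(0, 1, (4, 3)),
                                rng.normal(0, 1, (4, 3)))
        res = ModeratedTTest(data).fit()
        assert res.d0 == 0.0
        assert any("fell back" in f for f in res.flags)

    def test_missing_values_refused(self):
        frame = pd.DataFrame(np.array([[1.0, np.nan, 2.0, 3.0, 1.0, 2.0]]),
                             index=["g0"],
                             columns=["c0", "c1", "c2", "t0", "t1", "t2"])
        groups = {s: ("control" if s.startswith("c") else "treated")
                  for s in frame.columns}
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(frame, groups)


class TestBHAndDEGCalls:
    def test_bh_step_up_oracle(self):
        # p(i) * m / i with running minimum: all become 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        assert np.all(bh_adjust(p) >= p)
        assert np.all(bh_adjust(p) <= 1.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("fdr,log2fc,expected", [
        (0.04, 1.2, True), (0.04, 0.5, False), (0.06, 3.0, False)])
    def test_deg_rule(self, fdr, log2fc, expected):
        # construct a table whose BH-adjusted p equals the raw p (m=1)
        table = pd.DataFrame({"log2fc": [log2fc], "p": [fdr]}, index=["g"])
        out = call_degs(table, fdr_threshold=0.05, fc_threshold=2.0)
        assert bool(out["is_deg"].iloc[0]) is expected


class TestZScore:
    def test_rows_standardised(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z, flagged = zscore_by_gene(mat)
        assert z.loc["g"].mean() == pytest.approx(0.0)
        assert z.loc["g"].std(ddof=1) == pytest.approx(1.0)
        assert not flagged

    def test_constant_row_zeroed_and_flagged(self):
        mat = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                           index=["flat", "ok"], columns=list("abc"))
        z, flagged = zscore_by_gene(mat)
        assert (z.loc["flat"] == 0).all()
        assert flagged == ["flat"]

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(5, 2, (10, 6)))
        z1, _ = zscore_by_gene(mat)
        z2, _ = zscore_by_gene(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestLimmaCrossCheck:
    def test_matches_limma_on_fixture(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same small matrix."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(17)
        n_genes = 200
        ctrl = rng.normal(8, 1, (n_genes, 3)) * rng.uniform(0.9, 1.1, (n_genes, 1))
        trt = ctrl + rng.normal(0, 0.4, (n_genes, 3))
        trt[:10] += 2.0
        data = two_group_matrix(ctrl, trt)
        res = ModeratedTTest(data).fit()

        mat_file = tmp_path / "mat.tsv"
        data.values.to_csv(mat_file, sep="\t")
        out_file = tmp_path / "limma.tsv"
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat_file}", row.names=1))
design <- cbind(Intercept=1, Treated=c(0,0,0,1,1,1))
fit <- eBayes(lmFit(m, design))
out <- data.frame(gene=rownames(m), t=fit$t[,2], p=fit$p.value[,2],
                  d0=fit$df.prior, s0sq=fit$s2.prior)
write.table(out, "{out_file}", sep="\t", row.names=FALSE, quote=FALSE)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        limma = pd.read_csv(out_file, sep="\t").set_index("gene")
        assert res.table["t_mod"].to_numpy() == pytest.approx(
            limma["t"].to_numpy(), rel=1e-4)
        assert res.table["p"].to_numpy() == pytest.approx(
            limma["p"].to_numpy(), rel=1e-3, abs=1e-12)
        assert res.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-3)
        assert res.s0_sq == pytest.approx(limma["s0sq"].iloc[0], rel=1e-3)
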