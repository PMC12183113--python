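import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solshift import (
    QuantMatrix,
    SampleMeta,
    SolshiftError,
    SolubilityLM,
    bh_adjust,
    build_design,
    classify_significant,
    contrast_vector,
    estimate_eb_hyperparameters,
)
from tests.conftest import toy_meta


def fit_toy(values, meta, moderate=True):
    return SolubilityLM(QuantMatrix(values, scale="modz"), meta).fit(moderate=moderate)


class TestDesign:
    def test_structure_three_by_two_by_five(self):
        meta = toy_meta(n_cases=5, diseases=("CBD", "PiD", "PSP"))
        design = build_design(meta)
        assert design.matrix.shape == (30, 6)
        assert (design.matrix.sum(axis=1) == 1).all()
        assert (design.matrix.sum(axis=0) == 5).all()
        assert np.linalg.matrix_rank(design.matrix.to_numpy()) == 6

    def test_unknown_disease_errors(self):
        meta = toy_meta(n_cases=2)
        meta.table.loc[0, "disease"] = np.nan
        with pytest.raises(SolshiftError, match="unknown disease"):
            build_design(meta)

    def test_singleton_group_errors(self):
        rows = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "case_id": ["c1", "c2", "c1"],
                "disease": ["CBD", "CBD", "CBD"],
                "fraction": ["soluble", "soluble", "insoluble"],
            }
        )
        with pytest.raises(SolshiftError, match="<2 samples"):
            build_design(SampleMeta(rows))

    def test_permuted_sample_order_same_results(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        fit = SolubilityLM(matrix, meta).fit()
        perm = list(reversed(matrix.sample_ids))
        fit2 = SolubilityLM(matrix.subset_samples(perm), meta).fit()
        pd.testing.assert_frame_equal(fit.coefficients, fit2.coefficients)
        res1 = fit.contrast("CBD:insoluble - PSP:insoluble")
        res2 = fit2.contrast("CBD:insoluble - PSP:insoluble")
        pd.testing.assert_frame_equal(res1, res2)

    def test_contrast_parser(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        design = SolubilityLM(matrix, meta).design
        c = contrast_vector(design, "CBD:insoluble - PSP:insoluble")
        as_dict = dict(zip(design.group_labels, c))
        assert as_dict["CBD:insoluble"] == 1 and as_dict["PSP:insoluble"] == -1
        with pytest.raises(SolshiftError, match="sum to 0"):
            contrast_vector(design, {"CBD:insoluble": 1.0})


class TestEmpiricalBayes:
    def test_parameter_recovery_simulation(self):
        """Variances from an inverse-chi2(d0=4, s0^2=0.05) prior are
        recovered within +-15% (d0) and +-5% (s0^2) at 20000 proteins."""
        rng = np.random.default_rng(7)
        d0, s0_2, d, n = 4.0, 0.05, 24, 20000
        sigma2 = s0_2 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        d0_hat, s0_hat = estimate_eb_hyperparameters(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_2) / s0_2 < 0.05

    def test_identical_variances_hit_cap(self):
        d0_hat, s0_hat = estimate_eb_hyperparameters(np.full(200, 0.3), 24)
        assert d0_hat == 1e6
        assert s0_hat == pytest.approx(0.3, rel=0.1)

    def test_degenerate_input_errors(self):
        with pytest.raises(SolshiftError, match=">=10"):
            estimate_eb_hyperparameters(np.array([0.1, 0.2]), 4)

    def test_posterior_variance_between_prior_and_sample(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        fit = SolubilityLM(matrix, meta).fit()
        lo = np.minimum(fit.s2, fit.s0_2)
        hi = np.maximum(fit.s2, fit.s0_2)
        post = fit.posterior_s2
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestModeratedT:
    def test_equal_group_means_estimate_zero(self):
        meta = toy_meta(n_cases=3)
        base = np.array([1.0, -1.0, 0.0] * 4)  # same triple in every group
        rng = np.random.default_rng(9)
        filler = rng.normal(size=(10, len(meta.sample_ids)))
        values = pd.DataFrame(
            np.vstack([base, base + 5, filler]),
            index=["p1", "p2"] + [f"f{i}" for i in range(10)],
            columns=meta.sample_ids,
        )
        fit = fit_toy(values, meta)
        res = fit.contrast("CBD:soluble - PSP:soluble")
        assert res.loc[["p1", "p2"], "log2FC"].abs().max() < 1e-12
        assert (res.loc[["p1", "p2"], "p"] > 0.99).all()

    def test_d0_zero_equals_ordinary_t(self):
        """With no moderation the two-group moderated t reproduces the
        classical pooled-variance two-sample t-statistic."""
        rng = np.random.default_rng(2)
        rows = []
        for d in ("CBD", "PSP"):
            for c in range(5):
                rows.append({"sample_id": f"{d}{c}s", "case_id": f"{d}{c}",
                             "disease": d, "fraction": "soluble"})
                rows.append({"sample_id": f"{d}{c}i", "case_id": f"{d}{c}",
                             "disease": d, "fraction": "insoluble"})
        meta = SampleMeta(pd.DataFrame(rows))
        # restrict to one fraction so the design has exactly two groups
        keep = [r["sample_id"] for r in rows if r["sample_id"].endswith("s")]
        meta = SampleMeta(meta.table[meta.table["sample_id"].isin(keep)])
        values = pd.DataFrame(
            rng.normal(size=(40, 10)), index=[f"p{i}" for i in range(40)],
            columns=keep,
        )
        fit = fit_toy(values, meta, moderate=False)
        assert fit.d0 == 0.0
        res = fit.contrast("CBD:soluble - PSP:soluble")
        cbd = values[keep[:5]].to_numpy()
        psp = values[keep[5:]].to_numpy()
        t_oracle = stats.ttest_ind(cbd, psp, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), t_oracle.statistic, atol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), t_oracle.pvalue, atol=1e-10)

    def test_moderation_limits(self, toy_matrix_meta):
        """d0 -> 0 gives the ordinary t; d0 -> inf gives a z-like statistic
        with the pooled prior variance."""
        matrix, meta = toy_matrix_meta
        fit = SolubilityLM(matrix, meta).fit()
        c = "CBD:insoluble - CBD:soluble"
        fit.d0 = 1e-8
        t_small = fit.contrast(c)["t"]
        est = fit.contrast(c)["log2FC"]
        v = contrast_vector(fit.model.design, c)
        var_c = v @ fit.xtx_inv @ v
        np.testing.assert_allclose(
            t_small, est / np.sqrt(fit.s2 * var_c), rtol=1e-6
        )
        fit.d0 = 1e8
        t_big = fit.contrast(c)["t"]
        np.testing.assert_allclose(
            t_big, est / np.sqrt(fit.s0_2 * var_c), rtol=1e-6
        )

    def test_contrast_linearity(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        fit = SolubilityLM(matrix, meta).fit()
        design = fit.model.design
        c1 = contrast_vector(design, "CBD:insoluble - CBD:soluble")
        c2 = contrast_vector(design, "CBD:soluble - PSP:soluble")
        est_sum = fit.contrast(c1)["log2FC"] + fit.contrast(c2)["log2FC"]
        est_combined = fit.contrast(c1 + c2)["log2FC"]
        np.testing.assert_allclose(est_combined, est_sum, atol=1e-12)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_manual_step_up_oracle(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=30)
            adj = bh_adjust(p)
            perm = rng.permutation(30)
            np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(SolshiftError):
            bh_adjust(np.array([0.1, 1.2]))


class TestClassification:
    def test_all_p_one_empty_set(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        fit = SolubilityLM(matrix, meta).fit()
        res = fit.contrast("CBD:soluble - PSP:soluble")
        res["p"] = 1.0
        res["fdr"] = 1.0
        out = classify_significant(res)
        assert not out["significant"].any()

    def test_thresholds_applied_jointly(self):
        res = pd.DataFrame(
            {
                "log2FC": [1.0, 1.0, 0.3, -0.9],
                "t": [5, 5, 5, -5],
                "p": [1e-5, 0.5, 1e-5, 1e-5],
                "fdr": [1e-4, 0.5, 1e-4, 1e-4],
            },
            index=list("abcd"),
        )
        out = classify_significant(res)
        assert out["significant"].tolist() == [True, False, False, True]


class TestLimmaCrossCheck:
    def test_matches_limma_reference(self, tmp_path):
        """d0, s0^2 and moderated t agree with the reference R implementation
        on a shared small dataset."""
        import shutil

        rscript = shutil.which("Rscript")
        assert rscript, "Rscript (with limma) is part of the supported environment"
        rng = np.random.default_rng(42)
        meta = toy_meta(n_cases=4, diseases=("CBD", "PSP"))
        n = 60
        values = pd.DataFrame(
            rng.normal(size=(n, len(meta.sample_ids))) * rng.uniform(0.5, 2, (n, 1)),
            index=[f"p{i}" for i in range(n)],
            columns=meta.sample_ids,
        )
        fit = fit_toy(values, meta)
        res = fit.contrast("CBD:insoluble - PSP:insoluble")

        mat_path = tmp_path / "m.tsv"
        values.to_csv(mat_path, sep="\t")
        groups = SolubilityLM(
            QuantMatrix(values, scale="modz"), meta
        ).meta.group_labels().str.replace(":", "_")
        grp_path = tmp_path / "g.txt"
        grp_path.write_text("\n".join(groups.to_numpy()))
        out_path = tmp_path / "out.tsv"
        script = tmp_path / "check.R"
        script.write_text(
            f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat_path}", row.names=1, check.names=FALSE))
g <- factor(readLines("{grp_path}"))
design <- model.matrix(~0 + g)
colnames(design) <- levels(g)
fit <- lmFit(m, design)
cm <- makeContrasts(CBD_insoluble - PSP_insoluble, levels=design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1],
                  d0=fit2$df.prior, s0=fit2$s2.prior)
write.table(out, "{out_path}", sep="\\t", quote=FALSE)
"""
        )
        import subprocess

        proc = subprocess.run(
            [rscript, "--vanilla", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        assert fit.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert fit.s0_2 == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-4)
        np.testing.assert_allclose(res["t"], ref.loc[res.index, "t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref.loc[res.index, "p"], rtol=1e-6)
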