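import numpy as np
import pandas as pd
import pytest

from solshift import (
    CohortConfig,
    SolshiftError,
    SolubilityLM,
    evaluate_recovery,
    filter_by_detection,
    generate_cohort,
    generate_peptides,
    impute_knn,
    map_peptides_to_isoform,
    sum_peptide_detections,
)


class TestGenerateCohort:
    def test_same_seed_byte_identical(self):
        cfg = CohortConfig(n_proteins=100, seed=3)
        m1, meta1, _ = generate_cohort(cfg)
        m2, meta2, _ = generate_cohort(CohortConfig(n_proteins=100, seed=3))
        pd.testing.assert_frame_equal(m1.values_df, m2.values_df)
        pd.testing.assert_frame_equal(meta1.table, meta2.table)

    def test_different_seeds_differ_almost_everywhere(self):
        m1, _, _ = generate_cohort(CohortConfig(n_proteins=100, seed=3))
        m2, _, _ = generate_cohort(CohortConfig(n_proteins=100, seed=4))
        a, b = m1.values_df.to_numpy(), m2.values_df.to_numpy()
        both = ~np.isnan(a) & ~np.isnan(b)
        assert (a[both] != b[both]).mean() > 0.99

    def test_zero_noise_zero_effects_identical_samples(self):
        cfg = CohortConfig(
            n_proteins=20, seed=0, residual_sd=1e-12, case_effect_sd=0.0,
            fraction_effect_sd=0.0, dropout_tau=0.0,
        )
        m, meta, _ = generate_cohort(cfg)
        log2 = np.log2(m.values_df)
        assert log2.std(axis=1).max() < 1e-6

    def test_planted_delta_monte_carlo_mean(self):
        """Empirical (ins - sol)_A - (ins - sol)_B averages to the planted
        +1.5 over repeated seeds."""
        diffs = []
        for seed in range(200):
            cfg = CohortConfig(
                n_proteins=12, seed=seed, effects={"PROT0003": {"CBD": 1.5}},
                dropout_tau=0.0,
            )
            m, meta, _ = generate_cohort(cfg)
            log2 = np.log2(m.values_df)
            g = meta.group_labels()
            def gmean(name):
                return log2.loc["PROT0003", g.index[g == name]].mean()
            diffs.append(
                (gmean("CBD:insoluble") - gmean("CBD:soluble"))
                - (gmean("PSP:insoluble") - gmean("PSP:soluble"))
            )
        assert np.mean(diffs) == pytest.approx(1.5, abs=0.05)

    def test_group_means_converge_to_truth(self):
        """Empirical group means approach the truth as cases grow (~1/sqrt n)."""
        errs = {}
        for n_cases in (5, 50, 500):
            cfg = CohortConfig(
                n_proteins=30, seed=1, cases_per_group=n_cases, dropout_tau=0.0,
            )
            m, meta, truth = generate_cohort(cfg)
            log2 = np.log2(m.values_df)
            g = meta.group_labels()
            err = 0.0
            for grp in truth.group_means.columns:
                emp = log2[g.index[g == grp]].mean(axis=1)
                err = max(err, (emp - truth.group_means[grp]).abs().max())
            errs[n_cases] = err
        assert errs[500] < errs[5]
        assert errs[500] < 0.15

    def test_dropout_sparser_at_low_abundance(self, small_cohort):
        matrix, _, truth = small_cohort
        log2 = np.log2(matrix.values_df)
        detected_frac = matrix.observed_mask().mean(axis=1)
        lo = detected_frac[log2.mean(axis=1) < 15]
        hi = detected_frac[log2.mean(axis=1) > 19]
        assert len(lo) and len(hi)
        assert lo.mean() < hi.mean()

    def test_unknown_effect_protein_errors(self):
        with pytest.raises(SolshiftError, match="unknown proteins"):
            generate_cohort(CohortConfig(n_proteins=5, effects={"NOPE": {"CBD": 1.0}}))


class TestGeneratePeptides:
    @pytest.fixture
    def parent(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(10)]
        return pd.Series(2.0 ** rng.normal(18, 1, 10), index=samples)

    @pytest.fixture
    def peptide_frame(self, tau_reference):
        seqs = ["KLDLSNVQSK", "MAEPRQEFEV", "VQIVYK"]
        m = map_peptides_to_isoform(seqs, tau_reference)
        return m.reset_index()[["sequence", "isoform_specificity"]]

    def test_no_noise_sums_proportional_to_parent(self, parent, peptide_frame):
        det, truth = generate_peptides(parent, peptide_frame, four_r_share=1.0,
                                       noise_sd=0.0, seed=2)
        wide = sum_peptide_detections(det)
        for seq in wide.index:
            ratio = wide.loc[seq] / parent
            assert ratio.std() / ratio.mean() < 1e-9  # constant ionization factor

    def test_sums_match_generator_ledger(self, parent, peptide_frame):
        det, truth = generate_peptides(parent, peptide_frame, four_r_share=0.5,
                                       noise_sd=0.2, max_detections=3, seed=5)
        wide = sum_peptide_detections(det)
        assert (truth["n_detections"] >= 1).all()
        for _, row in truth.iterrows():
            assert wide.loc[row["sequence"], row["sample_id"]] == pytest.approx(
                row["total"], rel=1e-9
            )

    def test_structural_zero_when_no_4r(self, parent, peptide_frame):
        det, _ = generate_peptides(parent, peptide_frame, four_r_share=0.0, seed=1)
        wide = sum_peptide_detections(det)
        assert "KLDLSNVQSK" not in wide.index
        assert "MAEPRQEFEV" in wide.index

    def test_mixed_pool_ratio_recovered(self, parent, peptide_frame):
        """At a 30/70 3R/4R mix the 4R-defining vs constitutive abundance
        ratio recovers ~0.7 once ionization factors are divided out."""
        ratios = []
        for seed in range(50):
            det, _ = generate_peptides(parent, peptide_frame, four_r_share=0.7,
                                       noise_sd=0.05, seed=seed)
            wide = sum_peptide_detections(det)
            no_mix, _ = generate_peptides(parent, peptide_frame, four_r_share=1.0,
                                          noise_sd=0.0, seed=seed)
            ref = sum_peptide_detections(no_mix)
            r = (wide.loc["KLDLSNVQSK"] / ref.loc["KLDLSNVQSK"]).mean()
            ratios.append(r)
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.02)


class TestEvaluateRecovery:
    def _result(self, index, sig, est=None):
        df = pd.DataFrame(
            {"log2FC": 0.0 if est is None else est, "significant": False},
            index=index,
        )
        df.loc[sig, "significant"] = True
        return df

    def test_no_effects_no_flags(self):
        cfg = CohortConfig(n_proteins=10, seed=0)
        _, _, truth = generate_cohort(cfg)
        res = self._result(truth.shifts.index, [])
        rep = evaluate_recovery(res, truth, "CBD", "PSP")
        assert rep.power is None and rep.fdp == 0.0 and rep.bias is None

    def test_counts(self):
        cfg = CohortConfig(
            n_proteins=10, seed=0,
            effects={"PROT0001": {"CBD": 1.0}, "PROT0002": {"CBD": 1.0}},
        )
        _, _, truth = generate_cohort(cfg)
        res = self._result(truth.shifts.index, ["PROT0001", "PROT0005"],
                           est=pd.Series(0.9, index=truth.shifts.index))
        rep = evaluate_recovery(res, truth, "CBD", "PSP")
        assert rep.power == 0.5  # 1 of 2 true shifts found
        assert rep.fdp == 0.5  # 1 of 2 flags is null
        assert rep.bias == pytest.approx(-0.1)  # est 0.9 vs true 1.0

    def test_universe_mismatch_errors(self):
        cfg = CohortConfig(n_proteins=10, seed=0)
        _, _, truth = generate_cohort(cfg)
        res = self._result(list(truth.shifts.index[:5]) + ["ALIEN"], [])
        with pytest.raises(SolshiftError, match="universe"):
            evaluate_recovery(res, truth, "CBD", "PSP")


class TestEndToEndRecovery:
    def test_planted_cohort_recovery(self, planted_cohort):
        """50 planted shifts at +1.5 (sd 0.5, n=5) in a 2000-protein cohort:
        discoveries are essentially all true, and the unconditional
        estimates of the planted proteins are unbiased.

        Note the theoretical ceiling on power here: the shift noncentrality
        is 1.5/sqrt(0.25*4/5) ~ 3.35 while the BH cut at 50/2000 prevalence
        sits near |z| ~ 3.4, so roughly half the planted proteins clear it.
        """
        matrix, meta, truth, planted = planted_cohort
        filtered, _ = filter_by_detection(matrix.log2(), 0.5)
        fit = SolubilityLM(impute_knn(filtered, k=10), meta).fit()
        res = fit.solubility_shift("CBD", "PSP")
        rep = evaluate_recovery(res, truth, "CBD", "PSP")
        assert rep.fdp <= 0.10
        assert rep.power >= 0.25  # consistent with the ~0.5 ceiling
        # unconditional estimates (all planted proteins, flagged or not)
        tp = [p for p in planted if p in res.index]
        assert res.loc[tp, "log2FC"].mean() == pytest.approx(1.5, abs=0.2)

    def test_case_pairing_reduces_power_but_controls_fdp(self):
        """With realistic shared case effects, the independent-samples model
        over-estimates the shift variance (case effects cancel in the
        estimate but inflate s^2), costing power while FDP stays
        controlled."""
        planted = [f"PROT{i:04d}" for i in range(1, 51)]
        cfg = CohortConfig(
            n_proteins=2000, seed=5, case_effect_sd=0.3,
            effects={p: {"CBD": 1.5} for p in planted},
        )
        matrix, meta, truth = generate_cohort(cfg)
        filtered, _ = filter_by_detection(matrix.log2(), 0.5)
        fit = SolubilityLM(impute_knn(filtered, k=10), meta).fit()
        rep = evaluate_recovery(fit.solubility_shift("CBD", "PSP"), truth, "CBD", "PSP")
        assert rep.fdp <= 0.10
        # estimator noise is smaller than the model believes: estimates stay tight
        tp = [p for p in planted if p in fit.coefficients.index]
        est = fit.solubility_shift("CBD", "PSP").loc[tp, "log2FC"]
        assert est.mean() == pytest.approx(1.5, abs=0.2)
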