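import numpy as np
import pandas as pd
import pytest

from mirpair.differential import (
    build_design,
    estimate_dispersions,
    fit_nb_glm,
    group_columns,
    ql_f_test,
    run_all_contrasts,
)
from mirpair.normalize import filter_low_expressors, tmm_factors
from mirpair.simulate import SimConfig, simulate_counts


@pytest.fixture
def ctl_sheet(paired_sheet):
    return paired_sheet[paired_sheet["treatment"] == "CTL"]


class TestDesign:
    def test_ctl_subset_dimensions(self, ctl_sheet):
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        assert design.shape == (6, 4)
        assert list(design.columns) == [
            "Intercept",
            "subject[S2]",
            "subject[S3]",
            "compartment[MB]",
        ]

    def test_full_column_rank(self, paired_sheet):
        sub = paired_sheet[paired_sheet["compartment"] == "MB"]
        design = build_design(sub, "treatment", ("CTL", "CLFS", "IHFS"))
        assert np.linalg.matrix_rank(design.to_numpy()) == design.shape[1]

    def test_single_subject_errors(self, ctl_sheet):
        solo = ctl_sheet[ctl_sheet["subject"] == "S1"]
        with pytest.raises(ValueError, match="subject"):
            build_design(solo, "compartment", ("EV", "MB"))

    def test_confounded_design_errors(self):
        # each subject seen in exactly one group: group aliased with subject
        sheet = pd.DataFrame(
            {
                "subject": ["S1", "S1", "S2", "S2"],
                "compartment": ["MB", "MB", "EV", "EV"],
                "treatment": ["CTL"] * 4,
            },
            index=pd.Index([f"x{i}" for i in range(4)], name="sample_id"),
        )
        with pytest.raises(ValueError, match="rank|alias"):
            build_design(sheet, "compartment", ("EV", "MB"))


class TestGlmFit:
    def test_poisson_group_means_give_exact_log2fc(self, ctl_sheet):
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = np.array([[20.0, 20, 20, 10, 10, 10]])  # MB samples first in sheet order
        fit = fit_nb_glm(y, design, np.zeros(6), 0.0)
        assert fit.coefficients["compartment[MB]"].iloc[0] / np.log(2) == pytest.approx(1.0, abs=1e-6)

    def test_intercept_only_fits_offset_weighted_mean(self, ctl_sheet):
        # Poisson intercept MLE: total counts over total effective depth
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"Intercept": np.ones(6)}, index=ctl_sheet.index)
        offsets = np.log(rng.uniform(0.5e6, 2e6, size=6))
        y = rng.poisson(100, size=(5, 6)).astype(float)
        fit = fit_nb_glm(y, design, offsets, 0.0)
        expected = y.sum(axis=1) / np.exp(offsets).sum()
        assert np.allclose(np.exp(fit.coefficients["Intercept"]), expected, rtol=1e-6)

    def test_coefficients_match_generic_glm(self, ctl_sheet):
        """Cross-check against an independent general-purpose NB GLM fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        X = design.to_numpy(float)
        offsets = np.log(rng.uniform(0.9e6, 1.1e6, size=6))
        y = rng.poisson(
            rng.uniform(20, 200, size=(20, 1)) * np.exp(rng.normal(0, 0.3, (20, 6)))
        ).astype(float)
        phi = 0.1
        fit = fit_nb_glm(y, design, offsets, phi)
        for g in range(20):
            ref = sm.GLM(
                y[g], X, family=sm.families.NegativeBinomial(alpha=phi), offset=offsets
            ).fit(tol=1e-12, maxiter=200)
            assert np.max(np.abs(ref.params - fit.coefficients.iloc[g].to_numpy())) < 1e-6


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self, ctl_sheet):
        matrix, _, _ = simulate_counts(
            SimConfig(seed=6, n_mirs=2000, dispersion=0.0, treatments=("CTL",),
                      mean_log_expression=(np.log(100), 0.5))
        )
        kept, _ = filter_low_expressors(matrix)
        f = tmm_factors(kept)
        design = build_design(kept.samples, "compartment", ("EV", "MB"))
        disp = estimate_dispersions(kept.counts, design, f.offsets)
        assert disp.common <= 0.01

    def test_nb_dispersion_recovered(self, ctl_sheet):
        matrix, _, _ = simulate_counts(
            SimConfig(seed=5, n_mirs=2000, dispersion=0.2, treatments=("CTL",),
                      mean_log_expression=(np.log(100), 0.5))
        )
        kept, _ = filter_low_expressors(matrix)
        f = tmm_factors(kept)
        design = build_design(kept.samples, "compartment", ("EV", "MB"))
        disp = estimate_dispersions(kept.counts, design, f.offsets)
        assert 0.1 < disp.common < 0.3

    def test_infinite_prior_collapses_tagwise_to_common(self, ctl_sheet):
        rng = np.random.default_rng(1)
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = rng.poisson(100, size=(50, 6)).astype(float)
        disp = estimate_dispersions(y, design, np.zeros(6), prior_df=1e9)
        assert np.max(np.abs(disp.tagwise - disp.common)) < 1e-6

    def test_all_zero_row_rejected(self, ctl_sheet):
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = np.vstack([np.full(6, 10.0), np.zeros(6)])
        with pytest.raises(ValueError, match="zero"):
            estimate_dispersions(y, design, np.zeros(6))


class TestQlfTest:
    def test_saturated_design_errors(self, ctl_sheet):
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        extra = design.copy()
        extra["e1"] = [1, 0, 0, 0, 0, 0.0]
        extra["e2"] = [0, 1, 0, 0, 0, 0.0]
        y = np.random.default_rng(0).poisson(50, (5, 6)).astype(float)
        fit = fit_nb_glm(y, extra, np.zeros(6), 0.1)
        with pytest.raises(ValueError, match="df"):
            ql_f_test(fit, "compartment[MB]")

    def test_determinism(self, ctl_sheet):
        rng = np.random.default_rng(2)
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = rng.poisson(80, size=(40, 6)).astype(float)
        fit = fit_nb_glm(y, design, np.zeros(6), 0.05)
        t1 = ql_f_test(fit, "compartment[MB]")
        t2 = ql_f_test(fit, "compartment[MB]")
        pd.testing.assert_frame_equal(t1, t2)

    def test_p_monotone_in_f(self, ctl_sheet):
        rng = np.random.default_rng(4)
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = rng.poisson(80, size=(60, 6)).astype(float)
        fit = fit_nb_glm(y, design, np.zeros(6), 0.05)
        table = ql_f_test(fit, "compartment[MB]").sort_values("f_stat")
        assert (table["p_value"].diff().dropna() <= 1e-12).all()

    def test_fdr_column_behind_flag(self, ctl_sheet):
        rng = np.random.default_rng(5)
        design = build_design(ctl_sheet, "compartment", ("EV", "MB"))
        y = rng.poisson(80, size=(30, 6)).astype(float)
        fit = fit_nb_glm(y, design, np.zeros(6), 0.05)
        assert "fdr" not in ql_f_test(fit, "compartment[MB]").columns
        table = ql_f_test(fit, "compartment[MB]", fdr=True)
        assert (table["fdr"] >= table["p_value"] - 1e-15).all()


@pytest.fixture(scope="module")
def planted_run():
    config = SimConfig(
        seed=42, n_mirs=300, dispersion=0.1,
        frac_compartment_de=0.1, planted_log2fc=2.0,
    )
    matrix, _, truth = simulate_counts(config)
    return run_all_contrasts(matrix), truth


class TestAllContrasts:
    def test_structure(self, planted_run):
        result, _ = planted_run
        assert set(result.within_treatment) == {"CTL", "CLFS", "IHFS"}
        assert len(result.between_treatment) == 6
        assert result.joint_kept and result.mb_kept and result.ev_kept

    def test_planted_mb_enriched_mir_has_positive_logfc_everywhere(self, planted_run):
        result, truth = planted_run
        mb_enriched = truth.per_mir.index[
            truth.de_flags["MBvsEV"] & (truth.per_mir["true_log2fc"] > 0)
        ]
        for table in result.within_treatment.values():
            present = [m for m in mb_enriched if m in table.index]
            assert present
            assert (table.loc[present, "log2_fc"] > 0).all()

    def test_null_data_has_no_sign_bias(self):
        matrix, _, _ = simulate_counts(SimConfig(seed=77, n_mirs=300, dispersion=0.1))
        result = run_all_contrasts(matrix)
        medians = [
            abs(t["log2_fc"].median()) for t in result.within_treatment.values()
        ]
        assert np.mean(medians) < 0.1
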