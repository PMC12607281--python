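"""NLME estimation: contracts, self-consistency, EBEs, bootstrap, stability."""

import numpy as np
import pandas as pd
import pytest

from cbgpk import (
    EstimationSettings,
    PopulationModel,
    bootstrap,
    compare_covariate_models,
    compute_ebes,
    convergence_assessment,
    fit_nlme,
    generate_study,
    nca_initial_values,
)
from cbgpk.synthetic_data import StudyDesign

QUICK = EstimationSettings(n_phase1=80, n_phase2=50, n_starts=1, compute_ll=False)


@pytest.fixture(scope="module")
def modest_fit(pop):
    """One moderately sized fit shared by several tests."""
    ds, truth = generate_study(pop, StudyDesign(n_subjects=10), seed=21)
    st = EstimationSettings(n_phase1=250, n_phase2=120, compute_ll=False)
    return ds, truth, fit_nlme(ds, settings=st, seed=8)


class TestContracts:
    def test_fixed_parameter_cannot_be_freed(self, study8):
        ds, _ = study8
        st = EstimationSettings(free_params=("Cl", "Fm"))
        with pytest.raises(ValueError, match="fixed"):
            fit_nlme(ds, fixed={"Fm": 0.75}, settings=st)

    def test_convergence_assessment_needs_two_runs(self, study8, pop):
        ds, _ = study8
        with pytest.raises(ValueError, match="2 runs"):
            convergence_assessment(ds, pop, n_runs=1)

    def test_bootstrap_needs_two_replicates(self, modest_fit):
        ds, _, fit = modest_fit
        with pytest.raises(ValueError):
            bootstrap(ds, fit, n_replicates=1)

    def test_comparison_requires_same_dataset(self, pop):
        st = QUICK
        ds1, _ = generate_study(pop, StudyDesign(n_subjects=3), seed=1)
        ds2, _ = generate_study(pop, StudyDesign(n_subjects=3), seed=2)
        f1 = fit_nlme(ds1, init=pop, settings=st, seed=1)
        f2 = fit_nlme(ds2, init=pop, settings=st, seed=1)
        with pytest.raises(ValueError, match="different datasets"):
            compare_covariate_models(f1, f2)


class TestSelfConsistency:
    def test_noise_free_fit_recovers_truth(self, noise_free_study):
        """With exact data and truth initials, the estimates stay at truth."""
        ds, truth, pop0 = noise_free_study
        st = EstimationSettings(n_phase1=60, n_phase2=40, n_starts=1,
                                compute_ll=False, screen_init=False)
        fit = fit_nlme(ds, init=pop0, settings=st, seed=3)
        for p, tv in pop0.typical.items():
            assert fit.model.typical[p] == pytest.approx(tv, rel=0.02), p
        assert fit.model.fixed["Fm"] == 0.75

    def test_estimates_track_sample_mean_clearance(self, modest_fit):
        """The estimated typical Cl matches the geometric mean of the sample's
        generating clearances (the estimand for this finite sample)."""
        ds, truth, fit = modest_fit
        tr = pd.DataFrame(truth["individuals"])
        gm = np.exp(np.mean(np.log(tr[tr.occasion == 1]["Cl"])))
        assert fit.model.typical["Cl"] == pytest.approx(gm, rel=0.15)
        assert fit.model.b1 == pytest.approx(0.29, abs=0.06)

    def test_complete_likelihood_improves(self, modest_fit):
        _, _, fit = modest_fit
        ll = fit.trace["complete_ll"]
        assert ll.tail(20).mean() > ll.iloc[0] + 100

    def test_correct_fm_beats_misfixed_fm_on_metabolite(self, noise_free_study):
        ds, truth, pop0 = noise_free_study
        st = EstimationSettings(n_phase1=60, n_phase2=40, n_starts=1,
                                compute_ll=False, screen_init=False)
        good = fit_nlme(ds, init=pop0, fixed={"Fm": 0.75}, settings=st, seed=3)
        bad_init = PopulationModel(
            typical=dict(pop0.typical), iiv_percent={}, iov_percent={},
            covariates={k: dict(v) for k, v in pop0.covariates.items()},
            b1=0.0, b2=0.0, fixed={"Fm": 0.5},
        )
        bad = fit_nlme(ds, init=bad_init, fixed={"Fm": 0.5}, settings=st, seed=3)
        err_good = abs(good.model.typical["Clm"] / 0.016 - 1)
        err_bad = abs(bad.model.typical["Clm"] / 0.016 - 1)
        assert err_good < err_bad


class TestEbes:
    def test_subject_without_observations_gets_typical(self, pop):
        ds, _ = generate_study(pop, StudyDesign(n_subjects=4), seed=13)
        df = ds.df[~((ds.df["ID"] == 4) & (ds.df["DVID"] > 0))]
        from cbgpk.synthetic_data import PKDataset

        ds2 = PKDataset(df.copy())
        st = QUICK
        fit = fit_nlme(ds2, init=pop, settings=st, seed=2)
        tab, shrink = compute_ebes(ds2, fit)
        row = tab[tab["ID"] == 4].iloc[0]
        for p in ("Cl", "Vc", "F"):
            assert row[p] == pytest.approx(fit.model.typical[p], rel=1e-3)
            assert row[f"eta_{p}"] == pytest.approx(0.0, abs=1e-4)

    def test_rich_design_shrinkage_modest(self, modest_fit):
        ds, _, fit = modest_fit
        _, shrink = compute_ebes(ds, fit)
        # well-informed parameters shrink little in a rich design
        for p in ("Cl", "Vc"):
            assert abs(shrink[p]) < 40
        assert np.isnan(shrink["Q"])  # no estimated IIV for Q


class TestBootstrap:
    def test_two_replicates_deterministic(self, modest_fit):
        ds, _, fit = modest_fit
        st = EstimationSettings(n_phase1=60, n_phase2=40, n_starts=1, compute_ll=False)
        a = bootstrap(ds, fit, n_replicates=2, seed=7, settings=st)
        b = bootstrap(ds, fit, n_replicates=2, seed=7, settings=st)
        pd.testing.assert_frame_equal(a["replicates"], b["replicates"])
        assert a["n_failed"] + len(a["replicates"]) == 2

    def test_ci_brackets_point_estimate(self, modest_fit):
        ds, _, fit = modest_fit
        st = EstimationSettings(n_phase1=80, n_phase2=50, n_starts=1, compute_ll=False)
        out = bootstrap(ds, fit, n_replicates=6, seed=11, settings=st)
        ci = out["ci"]
        assert (ci["ci_lower"] <= ci["ci_upper"]).all()
        # the point estimate of Cl falls inside its bootstrap interval
        assert ci.loc["typical_Cl", "ci_lower"] <= fit.model.typical["Cl"] * 1.2
        assert ci.loc["typical_Cl", "ci_upper"] >= fit.model.typical["Cl"] * 0.8


class TestConvergenceAssessment:
    def test_dispersion_reported(self, pop):
        ds, _ = generate_study(pop, StudyDesign(n_subjects=6), seed=30)
        st = EstimationSettings(n_phase1=100, n_phase2=60, n_starts=1, compute_ll=False)
        out = convergence_assessment(ds, nca_initial_values(ds), n_runs=2,
                                     perturbation=0.2, seed=5, settings=st)
        assert set(out["cv_percent"]) == set(pop.typical)
        assert len(out["runs"]) == 2
        # a well-identified synthetic study keeps the clearance stable
        assert out["cv_percent"]["Cl"] < 15.0


class TestInitialValues:
    def test_nca_heuristics_in_plausible_range(self, study8):
        ds, _ = study8
        init = nca_initial_values(ds)
        assert 0.5 < init.typical["Cl"] < 5.0
        assert 0.05 < init.typical["F"] < 0.9
        assert init.typical["Q"] > init.typical["Cl"]
        assert "oil" in init.covariates.get("ka", {})
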