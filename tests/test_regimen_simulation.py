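"""Multiple-dose Monte Carlo: superposition identities, accumulation, summaries."""

import numpy as np
import pandas as pd
import pytest

from cbgpk import (
    PopulationModel,
    RegimenSpec,
    mg_per_kg_to_nmol_per_kg,
    monte_carlo_regimen,
    summarize_metrics,
    time_to_steady_state,
)
from conftest import noise_free_population

DOSE = mg_per_kg_to_nmol_per_kg(10.0)


class TestMonteCarloRegimen:
    def test_no_variability_hits_typical_closed_form(self):
        pop0 = noise_free_population()
        spec = RegimenSpec(n_subjects=5, seed=1)
        m = monte_carlo_regimen(pop0, spec)
        parent = m.table[m.table["analyte"] == "parent"]
        # at (near-complete) steady state the interval AUC equals the
        # single-dose AUC to infinity, F*D/Cl
        np.testing.assert_allclose(parent["auc_ss"], 0.28 * DOSE / 1.67, rtol=1e-3)
        assert parent["auc_ss"].std() == pytest.approx(0.0, abs=1e-6)

    def test_infinite_interval_accumulation_is_one(self):
        pop0 = noise_free_population()
        spec = RegimenSpec(interval=2000.0, n_doses=3, n_subjects=2, seed=1)
        m = monte_carlo_regimen(pop0, spec)
        np.testing.assert_allclose(m.table["accumulation"], 1.0, rtol=1e-3)

    def test_last_interval_never_exceeds_single_dose_auc_inf(self, pop):
        spec = RegimenSpec(n_subjects=400, seed=7)
        rng = np.random.default_rng(spec.seed)
        from cbgpk.population_model import sample_parameter_arrays

        pars = sample_parameter_arrays(pop, spec.n_subjects, "micellar", rng)
        m = monte_carlo_regimen(pop, spec, individual_params=pars)
        parent = m.table[m.table["analyte"] == "parent"].sort_values("subject")
        auc_inf = pars["F"] * DOSE / pars["Cl"]
        assert np.all(parent["auc_ss"].to_numpy() <= auc_inf * (1 + 1e-9))
        assert np.all(parent["accumulation"] >= 1.0)

    def test_parent_and_metabolite_accumulate_alike(self, pop):
        m = monte_carlo_regimen(pop, RegimenSpec(n_subjects=300, seed=3))
        t = m.table.pivot(index="subject", columns="analyte", values="accumulation")
        rel = np.abs(t["metabolite"] / t["parent"] - 1)
        assert np.median(rel) < 0.05

    def test_medians_stable_when_doubling_n(self, pop):
        a = monte_carlo_regimen(pop, RegimenSpec(n_subjects=1000, seed=5))
        b = monte_carlo_regimen(pop, RegimenSpec(n_subjects=2000, seed=6))
        for analyte in ("parent", "metabolite"):
            ma = a.table[a.table["analyte"] == analyte]["auc_ss"].median()
            mb = b.table[b.table["analyte"] == analyte]["auc_ss"].median()
            assert ma == pytest.approx(mb, rel=0.08)

    def test_seed_reproducibility(self, pop):
        a = monte_carlo_regimen(pop, RegimenSpec(n_subjects=50, seed=9))
        b = monte_carlo_regimen(pop, RegimenSpec(n_subjects=50, seed=9))
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSummarizeMetrics:
    def test_single_subject_has_zero_cv(self):
        pop0 = noise_free_population()
        m = monte_carlo_regimen(pop0, RegimenSpec(n_subjects=1, seed=1))
        s = summarize_metrics(m)
        assert (s["cv_percent"] == 0).all()

    def test_duplicated_subjects_have_zero_cv(self):
        pop0 = noise_free_population()
        m = monte_carlo_regimen(pop0, RegimenSpec(n_subjects=4, seed=1))
        s = summarize_metrics(m)
        assert np.allclose(s["cv_percent"], 0.0, atol=1e-6)

    def test_micellar_vs_oil_steady_state_close_but_oil_lower(self, pop):
        # common random numbers: same subjects, only the absorption category
        # differs, isolating the formulation effect from Monte Carlo noise
        from cbgpk.population_model import sample_parameter_arrays

        n = 1000
        mic_pars = sample_parameter_arrays(pop, n, "micellar", rng=21)
        oil_pars = sample_parameter_arrays(pop, n, "oil", rng=21)
        mic = summarize_metrics(
            monte_carlo_regimen(pop, RegimenSpec(n_subjects=n), individual_params=mic_pars)
        )
        oil = summarize_metrics(
            monte_carlo_regimen(
                pop, RegimenSpec(n_subjects=n, formulation="oil"), individual_params=oil_pars
            )
        )
        get = lambda s, metric: float(
            s[(s["analyte"] == "parent") & (s["metric"] == metric)]["estimate"].iloc[0]
        )
        a, b = get(mic, "auc_ss"), get(oil, "auc_ss")
        assert abs(a - b) / a < 0.15
        assert b < a  # slower Weibull input delays attainment of steady state

    def test_bad_statistic_rejected(self, pop):
        m = monte_carlo_regimen(pop, RegimenSpec(n_subjects=2, seed=1))
        with pytest.raises(ValueError):
            summarize_metrics(m, statistic="mode")


class TestTimeToSteadyState:
    def _one_compartment_toy(self):
        # effectively one-compartment with t1/2 = 24 h and fast absorption
        return PopulationModel(
            typical={"F": 0.9, "ka": 20.0, "beta": 1.0, "Cl": np.log(2) / 24.0,
                     "Vc": 1.0, "Q": 0.01, "Vp": 0.001, "Vm": 1.0, "Clm": 1.0},
            b1=0.0, b2=0.0,
        )

    def test_toy_closed_form(self):
        # interval AUC fraction after n doses is 1 - 2^-n; 90% needs n = 4
        idx, hours = time_to_steady_state(self._one_compartment_toy(),
                                          RegimenSpec(n_subjects=1, seed=1), 0.9)
        assert idx == 4
        assert hours == 96.0

    def test_threshold_to_zero_gives_first_dose(self):
        idx, _ = time_to_steady_state(self._one_compartment_toy(),
                                      RegimenSpec(n_subjects=1, seed=1), 1e-9)
        assert idx == 1

    def test_typical_micellar_reaches_stationarity_in_days(self, pop):
        spec = RegimenSpec(n_subjects=1, seed=1)
        idx90, _ = time_to_steady_state(pop, spec, 0.9)
        idx95, _ = time_to_steady_state(pop, spec, 0.95)
        assert 4 <= idx90 <= 6
        assert 5 <= idx95 <= 6

    def test_threshold_domain(self, pop):
        with pytest.raises(ValueError):
            time_to_steady_state(pop, RegimenSpec(n_subjects=1, seed=1), 1.5)
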