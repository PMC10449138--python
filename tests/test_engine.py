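import math

import numpy as np
import pandas as pd
import pytest

import serotrace as st
from serotrace import (AssaySpec, ConfigurationError, FOEGrid,
                       InvalidInputError, runserosim, summarize_run)


def everyone_born_at_one(n, t_end=None):
    return st.Demography(pd.DataFrame({"i": range(1, n + 1),
                                       "birth_time": 1}))


def tiny_run(n=5, t_end=10, lam=(0.1,), fixed_history=None, seed=0,
             immunity=st.immunity_model_all_successful, extra=None,
             assay=None, demography=None):
    """Small single-biomarker simulation used across engine tests."""
    dem = demography if demography is not None else everyone_born_at_one(n)
    n = dem.n_individuals
    n_x = len(lam)
    bmap = st.BiomarkerMap(pd.DataFrame({
        "exposure_id": list(range(1, n_x + 1)),
        "biomarker_id": [1] * n_x}))
    pars_rows = []
    for x in range(1, n_x + 1):
        pars_rows += [(x, 1, "boost", 4.0, 0.0, ""),
                      (x, 1, "wane", 0.01, 0.0, "")]
    pars = st.ModelPars(pd.DataFrame(
        pars_rows, columns=["exposure_id", "biomarker_id", "name", "mean",
                            "sd", "distribution"]))
    return runserosim(
        settings=(1, t_end),
        demography=dem,
        biomarker_map=bmap,
        foe=FOEGrid.constant(list(lam), t_start=1, t_end=t_end),
        model_pars=pars,
        exposure_model=st.exposure_model_simple_FOE,
        immunity_model=immunity,
        antibody_model=st.antibody_model_monophasic,
        observation_model=st.observation_model_continuous_noise,
        draw_parameters=st.draw_parameters_fixed_fx,
        fixed_history=fixed_history,
        model_extra_args=extra,
        rng_seed=seed,
        assay=assay or AssaySpec(),
    )


class TestZeroForce:
    def test_no_force_no_events_no_titers(self):
        dem = st.generate_pop_demography(10, range(1, 21), 0.3, rng_seed=9)
        out = tiny_run(t_end=20, lam=(0.0, 0.0), demography=dem)
        z = out.immune_history
        assert np.nansum(z) == 0
        A = out.biomarker_states.values
        assert np.nansum(A) == 0
        assert len(out.kinetics_draws) == 0
        # phi is exactly zero wherever computed
        phi = out.exposure_probabilities
        assert np.nanmax(phi, initial=0.0) == 0.0


class TestFixedHistory:
    def test_fixed_entries_taken_verbatim(self):
        fixed = np.full((5, 10, 1), np.nan)
        fixed[1, 2, 0] = 1.0  # individual 2 exposed at time 3
        out = tiny_run(lam=(0.0,), fixed_history=fixed)
        assert out.immune_history[1, 2, 0] == 1.0
        assert out.fixed_mask[1, 2, 0]
        # no model produced phi for the fixed cell
        assert np.isnan(out.exposure_probabilities[1, 2, 0])
        # the fixed success boosts the biomarker from t=3 onward
        assert out.biomarker_states.values[1, 2, 0] == pytest.approx(4.0)
        assert out.biomarker_states.values[1, 9, 0] == pytest.approx(
            4.0 * (1 - 0.01 * 7))

    def test_fixed_list_form(self):
        out = tiny_run(lam=(0.0,), fixed_history=[(2, 3, 1, 1.0)])
        assert out.immune_history[1, 2, 0] == 1.0

    def test_fixed_conflicting_with_activity_rejected(self):
        dem = st.Demography(pd.DataFrame({
            "i": [1, 2], "birth_time": [1, 5]}))
        fixed = np.full((2, 10, 1), np.nan)
        fixed[1, 0, 0] = 1.0  # individual 2 fixed-exposed before birth
        with pytest.raises(InvalidInputError):
            tiny_run(lam=(0.0,), fixed_history=fixed, demography=dem)


class TestDecompositionAndConservation:
    def test_phi_equals_pe_times_ps_everywhere(self, quickstart_run,
                                               quickstart_inputs):
        out = quickstart_run
        foe = quickstart_inputs["foe"]
        z = out.immune_history
        phi = out.exposure_probabilities
        dem = quickstart_inputs["demography"]
        caps = {1: 1, 2: 1}
        p_e = {x: -math.expm1(-foe.lambda_at(1, 1, x)) for x in (1, 2)}
        for i in (1, 20, 77, 100):
            birth = dem.birth_time(i)
            for t in range(1, 121):
                for x in (1, 2):
                    stored = phi[i - 1, t - 1, x - 1]
                    if not dem.is_active(i, t):
                        assert np.isnan(stored)
                        continue
                    prior = np.nansum(z[i - 1, : t - 1, x - 1])
                    p_s = 1.0
                    if prior >= caps[x]:
                        p_s = 0.0
                    elif x == 2 and (t - birth) < 9:
                        p_s = 0.0
                    assert stored == p_e[x] * p_s

    def test_draw_groups_match_success_count(self, quickstart_run):
        z = quickstart_run.immune_history
        n_success = int(np.nansum(z))
        assert quickstart_run.kinetics_draws.n_event_groups() == n_success


class TestQuickstartContract:
    def test_one_observation_per_individual_alive_at_end(self,
                                                         quickstart_run):
        obs = quickstart_run.observed
        assert len(obs) == 100
        assert (obs["t"] == 120).all() and (obs["b"] == 1).all()
        # no removal in the quickstart: everyone is alive and observed
        assert obs["observed"].notna().all()

    def test_event_caps_never_exceeded(self, quickstart_run):
        z = quickstart_run.immune_history
        per_type = np.nansum(z, axis=1)  # (N, X)
        assert per_type.max() <= 1

    def test_no_vaccination_before_eligible_age(self, quickstart_run,
                                                quickstart_inputs):
        z = quickstart_run.immune_history
        dem = quickstart_inputs["demography"]
        hits = np.argwhere(z[:, :, 1] == 1.0)
        assert len(hits) > 0
        ages = [(t_idx + 1) - dem.birth_time(i_idx + 1)
                for i_idx, t_idx in hits]
        assert min(ages) >= 9

    def test_absent_exactly_where_inactive(self, quickstart_run,
                                           quickstart_inputs):
        dem = quickstart_inputs["demography"]
        active = dem.active_mask(range(1, 121))
        z = quickstart_run.immune_history
        A = quickstart_run.biomarker_states.values
        assert np.array_equal(np.isnan(z[:, :, 0]), ~active)
        assert np.array_equal(np.isnan(z[:, :, 1]), ~active)
        assert np.array_equal(np.isnan(A[:, :, 0]), ~active)

    def test_reproducible_bit_for_bit(self):
        a = st.run_quickstart(rng_seed=33)
        b = st.run_quickstart(rng_seed=33)
        assert np.array_equal(a.immune_history, b.immune_history,
                              equal_nan=True)
        assert np.array_equal(a.biomarker_states.values,
                              b.biomarker_states.values, equal_nan=True)
        pd.testing.assert_frame_equal(a.observed, b.observed)
        pd.testing.assert_frame_equal(a.kinetics_draws.to_frame(),
                                      b.kinetics_draws.to_frame())

    def test_event_counts_near_expected(self):
        # sum of phi approximates the expected number of infections
        out = st.run_quickstart(rng_seed=5)
        phi = out.exposure_probabilities[:, :, 0]
        z = out.immune_history[:, :, 0]
        expected = np.nansum(phi)
        observed = np.nansum(z)
        sd = np.sqrt(np.nansum(phi * (1 - phi)))
        assert abs(observed - expected) < 4 * sd


class TestProtectionAndCeiling:
    def test_biomarker_protection_threshold_blocks_reinfection(self):
        extra = {"midpoint": 0.5, "steepness": 5.0, "mode": "threshold"}
        out = tiny_run(n=20, t_end=30, lam=(1.5,), seed=4,
                       immunity=st.immunity_model_biomarker_protection,
                       extra=extra)
        # titers stay >= midpoint for ~100 steps after a boost of 4, so
        # nobody can be infected twice within 30 steps
        per_type = np.nansum(out.immune_history, axis=1)
        assert per_type.max() <= 1

    def test_titer_ceiling_attenuates_second_boost(self):
        fixed = np.full((5, 10, 1), np.nan)
        fixed[0, 0, 0] = 1.0   # boost 4 at t=1
        fixed[0, 4, 0] = 1.0   # second boost at t=5 under the ceiling
        out = tiny_run(lam=(0.0,), fixed_history=fixed,
                       extra={"titer_ceiling_gradient": 0.1})
        draws = out.kinetics_draws
        assert draws.get(1, 1, 1, 1, "boost") == pytest.approx(4.0)
        # current titer at t=5 is 4*(1-0.01*4)=3.84 -> boost scaled by
        # (1 - 0.1*3.84)
        assert draws.get(1, 5, 1, 1, "boost") == pytest.approx(
            4.0 * (1 - 0.1 * 3.84))


class TestValidationErrors:
    def test_incomplete_foe_window_rejected(self):
        dem = st.generate_pop_demography(2, range(1, 11), 0.0, rng_seed=0)
        bmap = st.BiomarkerMap(pd.DataFrame({"exposure_id": [1],
                                             "biomarker_id": [1]}))
        pars = st.ModelPars(pd.DataFrame(
            [(1, 1, "boost", 4.0, 0.0, "")],
            columns=["exposure_id", "biomarker_id", "name", "mean", "sd",
                     "distribution"]))
        with pytest.raises(ConfigurationError):
            runserosim((1, 10), dem, bmap,
                       FOEGrid.constant([0.1], t_start=1, t_end=5), pars,
                       st.exposure_model_simple_FOE,
                       st.immunity_model_all_successful,
                       st.antibody_model_monophasic,
                       st.observation_model_continuous_noise,
                       st.draw_parameters_fixed_fx)

    def test_unconsumed_extra_arg_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_run(extra={"sensitivty": 0.85})  # typo never consumed

    def test_missing_model_pars_pair_rejected(self):
        dem = st.generate_pop_demography(2, range(1, 6), 0.0, rng_seed=0)
        bmap = st.BiomarkerMap(pd.DataFrame({"exposure_id": [1, 2],
                                             "biomarker_id": [1, 1]}))
        pars = st.ModelPars(pd.DataFrame(
            [(1, 1, "boost", 4.0, 0.0, "")],
            columns=["exposure_id", "biomarker_id", "name", "mean", "sd",
                     "distribution"]))
        with pytest.raises(ConfigurationError):
            runserosim((1, 5), dem, bmap,
                       FOEGrid.constant([0.1, 0.1], t_start=1, t_end=5),
                       pars,
                       st.exposure_model_simple_FOE,
                       st.immunity_model_all_successful,
                       st.antibody_model_monophasic,
                       st.observation_model_continuous_noise,
                       st.draw_parameters_fixed_fx)


class TestSummary:
    def test_zero_event_run_summary(self):
        out = tiny_run(lam=(0.0,))
        s = summarize_run(out)
        assert s["event_counts"] == {1: 0}
        assert all(times == [] for times in s["event_times"].values())

    def test_hand_built_history_counts(self):
        fixed = np.full((5, 10, 2), np.nan)
        fixed[0, 1, 0] = 1.0
        fixed[1, 3, 0] = 1.0
        fixed[2, 4, 1] = 1.0
        out = tiny_run(lam=(0.0, 0.0), fixed_history=fixed)
        s = summarize_run(out)
        assert s["event_counts"] == {1: 2, 2: 1}
        assert s["event_times"][1] == [(2, 1)]
        assert s["event_times"][3] == [(5, 2)]

    def test_seroprevalence_threshold_limit(self):
        fixed = np.full((5, 10, 1), np.nan)
        fixed[0, 0, 0] = 1.0
        out = tiny_run(lam=(0.0,), fixed_history=fixed)
        s = summarize_run(out, seropositivity_threshold=1e-9)
        y = out.observed["observed"].dropna()
        assert s["seroprevalence"] == pytest.approx((y > 0).mean())

    def test_outputs_round_trip_to_disk(self, tmp_path):
        out = tiny_run(lam=(0.1,))
        out.save(tmp_path)
        for name in ("exposure_probabilities", "immune_histories",
                     "biomarker_states", "kinetics_draws",
                     "observed_biomarkers"):
            assert (tmp_path / f"{name}.csv").exists()
        assert (tmp_path / "metadata.json").exists()
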