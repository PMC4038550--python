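"""Generative model: calibration inversion, sampling moments, catalogue."""

import numpy as np
import pytest

import darkbench as db
from darkbench.scenarios import CalibrationWarning, population_to_frame


class TestCalibrateFromDS:
    def test_ideal_reporter_maps_to_zero_component(self):
        assert db.calibrate_from_DS(100, 10, 1.0, 1.0) == (0.0, 0.0)

    def test_inversion_formula(self):
        # spur_mean = (D-1)*af_mean; spur_sd = af_sd*sqrt(S^2-1)
        m, s = db.calibrate_from_DS(100, 10, 2.13, 2.15)
        assert m == pytest.approx(113.0)
        assert s == pytest.approx(10 * np.sqrt(2.15 ** 2 - 1))  # 19.0329

    def test_sub_unity_target_clamps_with_warning(self):
        with pytest.warns(CalibrationWarning):
            m, s = db.calibrate_from_DS(100, 10, 1.07, 0.97)
        assert (m, s) == (pytest.approx(7.0), 0.0)

    @pytest.mark.parametrize("af_mean,af_sd", [(0, 10), (-5, 10), (100, 0)])
    def test_nonpositive_baseline_rejected(self, af_mean, af_sd):
        with pytest.raises(ValueError):
            db.calibrate_from_DS(af_mean, af_sd, 2.0, 2.0)

    def test_forward_monte_carlo_reproduces_targets(self):
        """Calibrated components forward-simulate to the requested (D, S)."""
        af_mean, af_sd, d_t, s_t = 100.0, 10.0, 2.13, 2.15
        m, s = db.calibrate_from_DS(af_mean, af_sd, d_t, s_t)
        sc_ev = db.Scenario("ev", af_mean=af_mean, af_sd=af_sd,
                            spur_mean=m, spur_sd=s)
        sc_af = db.Scenario("af", af_mean=af_mean, af_sd=af_sd)
        n = 400_000
        ev = db.simulate_population(sc_ev, n, seed=1).total_values
        af = db.simulate_population(sc_af, n, seed=2).total_values
        d_hat = ev.mean() / af.mean()
        s_hat = ev.std(ddof=1) / af.std(ddof=1)
        # delta-method SEs for a ratio of independent means / SDs
        se_d = d_t * np.sqrt(2) * (af_sd * s_t / af_mean) / np.sqrt(n)
        assert abs(d_hat - d_t) < 3 * se_d + 1e-3
        assert abs(s_hat - s_t) < 0.02


class TestSimulatePopulation:
    def test_empty_population(self, catalogue):
        pop = db.simulate_population(catalogue["AF_GFP"], 0, seed=0)
        assert pop.n == 0 and len(pop.total_values) == 0

    def test_terminated_vector_reduces_to_autofluorescence(self, catalogue):
        sc = catalogue["pGFP_Star@OD5"]
        assert sc.readthrough == 0.0
        pop = db.simulate_population(sc, 100_000, seed=5)
        assert pop.total_values.mean() == pytest.approx(sc.af_mean, rel=0.01)

    def test_reproducible_given_seed(self, catalogue):
        a = db.simulate_population(catalogue["pGFPamy@OD5"], 1000, seed=42)
        b = db.simulate_population(catalogue["pGFPamy@OD5"], 1000, seed=42)
        c = db.simulate_population(catalogue["pGFPamy@OD5"], 1000, seed=43)
        np.testing.assert_array_equal(a.total_values, b.total_values)
        assert not np.array_equal(a.total_values, c.total_values)

    def test_additivity_of_moments(self):
        """E[F] and Var[F] match the closed form for independent components."""
        sc = db.Scenario("mix", af_mean=100, af_sd=20, spur_mean=80,
                         spur_sd=30, readthrough=0.6, prom_mean=0, prom_sd=0)
        n = 1_000_000
        tot = db.simulate_population(sc, n, seed=9).total_values
        mu, var = sc.expected_mean(), sc.expected_var()
        assert abs(tot.mean() - mu) < 3 * np.sqrt(var / n)
        # SE of sample variance ~ var*sqrt(2/n) for light-tailed data
        assert abs(tot.var(ddof=1) - var) < 4 * var * np.sqrt(2 / n)

    def test_scale_invariance_of_ratios(self, catalogue):
        """Multiplying all AU parameters by c leaves simulated D and S unchanged."""
        from dataclasses import replace
        base_ev = catalogue["pGFPamy@OD5"]
        base_af = catalogue["AF_GFP"]
        c = 7.3
        scaled_ev = replace(base_ev, af_mean=c * base_ev.af_mean,
                            af_sd=c * base_ev.af_sd, spur_mean=c * base_ev.spur_mean,
                            spur_sd=c * base_ev.spur_sd)
        scaled_af = replace(base_af, af_mean=c * base_af.af_mean,
                            af_sd=c * base_af.af_sd)
        n = 20_000
        ev1 = db.simulate_population(base_ev, n, seed=1).total_values
        af1 = db.simulate_population(base_af, n, seed=2).total_values
        ev2 = db.simulate_population(scaled_ev, n, seed=1).total_values
        af2 = db.simulate_population(scaled_af, n, seed=2).total_values
        assert ev1.mean() / af1.mean() == pytest.approx(ev2.mean() / af2.mean())
        assert (ev1.std(ddof=1) / af1.std(ddof=1)
                == pytest.approx(ev2.std(ddof=1) / af2.std(ddof=1)))

    def test_interference_pulls_fusion_below_ev(self, catalogue):
        """With suppression active, the fusion mean sits strictly below the EV mean."""
        ev = db.simulate_population(catalogue["pGFPamy@OD6"], 50_000, seed=3)
        fus = db.simulate_population(catalogue["PrapE_amy@OD6"], 50_000, seed=4)
        assert fus.total_values.mean() < ev.total_values.mean()

    def test_population_frame_columns(self, catalogue):
        pop = db.simulate_population(catalogue["pGFPamy@OD5"], 10, seed=0,
                                     replicate_id="r1")
        frame = population_to_frame(pop)
        assert list(frame.columns) == ["cell_id", "replicate_id", "scenario",
                                       "od600", "af", "spur", "prom", "total"]
        assert len(frame) == 10


class TestCatalogue:
    def test_unknown_name_lists_valid_names(self, catalogue):
        with pytest.raises(KeyError, match="pGFPamy@OD5"):
            db.lookup("nonsense", catalogue)

    def test_star_vectors_have_zero_readthrough(self, catalogue):
        for name in ("pGFP_Star@OD5", "pYFP_Star@OD5", "pCFP_Star@OD5"):
            assert catalogue[name].readthrough == 0.0

    def test_cfp_row_calibration(self, catalogue):
        """pCFPamy spur components invert its printed (1.16, 1.21) row."""
        sc = catalogue["pCFPamy@OD5"]
        assert sc.spur_mean == pytest.approx((1.16 - 1) * sc.af_mean)
        assert sc.spur_sd == pytest.approx(sc.af_sd * np.sqrt(1.21 ** 2 - 1))

    def test_ev_scenarios_have_no_promoter(self, catalogue):
        for name, sc in catalogue.items():
            if not name.startswith("PrapE"):
                assert sc.prom_mean == 0.0

    def test_yaml_round_trip(self, catalogue, tmp_path):
        from darkbench.scenarios import scenarios_from_yaml, scenarios_to_yaml
        path = tmp_path / "cat.yaml"
        scenarios_to_yaml(catalogue.values(), path)
        back = scenarios_from_yaml(path)
        assert back == catalogue
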