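"""Temperature tolerance curves and forcing assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import foodwebmsy as fw
from foodwebmsy.errors import InputError
from foodwebmsy.forcing import (ForcingSeries, ForcingSet, ToleranceCurve,
                                apply_pb_forcing, apply_vulnerability_forcing,
                                build_temperature_forcing,
                                tolerance_multiplier)


class TestToleranceCurve:
    @pytest.mark.parametrize("T,expected", [
        (18.0, 1.0),   # flat left arm
        (20.0, 1.0),   # at optimum
        (23.0, 0.5),   # midpoint of the linear decline
        (26.0, 0.0),   # at the critical temperature
        (27.0, 0.0),   # beyond critical
    ])
    def test_coldwater_curve_values(self, T, expected):
        assert tolerance_multiplier(T, fw.COLDWATER_CURVE) == pytest.approx(expected)

    def test_burbot_curve_matches_independent_piecewise_map(self):
        # linear arm between optimum 18.2 and critical 27.5
        curve = fw.BURBOT_CURVE
        temps = np.linspace(10, 30, 101)
        expect = np.clip((27.5 - temps) / (27.5 - 18.2), 0.0, 1.0)
        got = np.array([tolerance_multiplier(t, curve) for t in temps])
        assert np.allclose(got, expect, atol=1e-12)

    def test_invalid_curve_rejected(self):
        with pytest.raises(InputError):
            ToleranceCurve(T_opt=25.0, T_crit=20.0)

    @given(T=st.floats(-5, 40))
    def test_multiplier_bounded_and_flat_below_optimum(self, T):
        for arm in ("linear", "gaussian"):
            c = ToleranceCurve(T_opt=20.0, T_crit=26.0, right_arm=arm)
            m = tolerance_multiplier(T, c)
            assert 0.0 <= m <= 1.0
            if T <= 20.0:
                assert m == 1.0

    @given(T=st.floats(20, 27), dT=st.floats(0.01, 5))
    def test_nonincreasing_above_optimum(self, T, dT):
        for arm in ("linear", "gaussian"):
            c = ToleranceCurve(T_opt=20.0, T_crit=26.0, right_arm=arm)
            assert tolerance_multiplier(T + dT, c) <= tolerance_multiplier(T, c) + 1e-12


class TestTemperatureForcing:
    def test_mean_over_selected_months(self):
        monthly = pd.DataFrame({"year": [1, 1], "month": [7, 8],
                                "temp_C": [24.0, 26.0]})
        s = build_temperature_forcing(monthly)
        assert s.values.tolist() == [25.0]

    def test_constant_series(self):
        spec = fw.SynthesisSpec(temp_noise_sd=0.0, temp_step=0.0)
        s = build_temperature_forcing(fw.generate_temperature_series(spec))
        assert np.allclose(s.values, spec.temp_baseline)

    def test_missing_month_names_year(self):
        monthly = pd.DataFrame({"year": [3], "month": [7], "temp_C": [24.0]})
        with pytest.raises(InputError, match="year 3"):
            build_temperature_forcing(monthly)

    def test_warming_step_recovered_from_decade_means(self):
        spec = fw.SynthesisSpec(n_years=20, step_year=11, temp_step=0.6,
                                temp_noise_sd=0.0)
        s = build_temperature_forcing(fw.generate_temperature_series(spec))
        assert s.values[10:].mean() - s.values[:10].mean() == pytest.approx(0.6)


class TestApplyForcing:
    def test_pb_multipliers_compose_curve_and_series(self, temp_series):
        s = apply_pb_forcing("coldwater_prey", fw.COLDWATER_CURVE, temp_series)
        expect = [tolerance_multiplier(t, fw.COLDWATER_CURVE)
                  for t in temp_series.values]
        assert np.allclose(s.values, expect)

    def test_at_optimum_identical_to_unforced_bitwise(self, motif_balanced,
                                                      motif_links):
        cool = ForcingSeries("temperature", np.full(30, 18.0))
        fset = ForcingSet()
        fset.add(apply_pb_forcing("coldwater_prey", fw.COLDWATER_CURVE, cool))
        t_forced = fw.simulate(motif_balanced, motif_links, forcing=fset, years=30)
        t_plain = fw.simulate(motif_balanced, motif_links, years=30)
        assert np.array_equal(t_forced.biomass, t_plain.biomass)

    def test_halved_multiplier_halves_production_rate(self, motif_balanced,
                                                      motif_links):
        from foodwebmsy.dynamics import Simulator
        sim = Simulator(motif_balanced, motif_links)
        b = motif_balanced
        i = b.index("coldwater_prey")
        pb_mult = np.ones(len(b.names))
        pb_mult[i] = 0.5
        dB = sim.derivatives(b.B.copy(), b.F_base, pb_mult=pb_mult)
        Qin = b.B[i] * b.QB[i]
        expect = (0.5 * b.g[i] * Qin - b.M2[i] * b.B[i]
                  - (0.5 * b.MO[i] + b.F_base[i]) * b.B[i])
        assert dB[i] == pytest.approx(expect, rel=1e-9)

    def test_vulnerability_multiplier_is_temperature_ratio(self, temp_series):
        s = apply_vulnerability_forcing("mesopredator", temp_series, T_ref=22.0)
        assert np.allclose(s.values, temp_series.values / 22.0)
        assert s.target == ("mesopredator", None)

    def test_multiplier_clipped_at_donor_floor(self, motif_balanced, motif_links):
        lk = next(l for l in motif_links if l.predator == "mesopredator")
        b_prey = motif_balanced.B[lk.prey_idx]
        b_pred = motif_balanced.B[lk.pred_idx]
        # multiplier small enough to push v below 1: clips to v = 1
        clipped = fw.consumption_flux(lk, b_prey, b_pred, vuln_multiplier=0.01)
        links_v1 = fw.init_arena_params(motif_balanced, 1.0)
        lk1 = next(l for l in links_v1 if (l.predator, l.prey) == (lk.predator, lk.prey))
        # an effective v of exactly 1 rescaled from base calibration
        s = 1.0 / lk.v_user
        expect = (s * lk.arena_v * b_prey * b_pred / (s * lk.D + b_pred))
        assert clipped == pytest.approx(expect, rel=1e-12)
        assert clipped < lk.Q_base  # cooler than reference suppresses feeding

    def test_warming_boosts_warm_adapted_consumption(self, motif_links,
                                                     motif_balanced):
        lk = next(l for l in motif_links if l.predator == "mesopredator")
        b_prey = motif_balanced.B[lk.prey_idx]
        b_pred = motif_balanced.B[lk.pred_idx]
        base = fw.consumption_flux(lk, b_prey, b_pred, 1.0)
        for m in (1.05, 1.1, 1.3):
            assert fw.consumption_flux(lk, b_prey, b_pred, m) > base
        # nondecreasing in the multiplier
        fluxes = [fw.consumption_flux(lk, b_prey, b_pred, m)
                  for m in np.linspace(0.5, 2.0, 16)]
        assert np.all(np.diff(fluxes) >= -1e-12)

    def test_cold_group_equilibrium_monotone_in_warming(self, motif_balanced,
                                                        motif_links):
        finals = []
        for temp in (20.0, 23.0, 24.5):
            fset = ForcingSet()
            fset.add(apply_pb_forcing(
                "coldwater_prey", fw.COLDWATER_CURVE,
                ForcingSeries("temperature", np.full(60, temp))))
            traj = fw.simulate(motif_balanced, motif_links, forcing=fset, years=60)
            finals.append(traj.series("coldwater_prey")[-1])
        assert finals[0] > finals[1] > finals[2]


class TestForcingSet:
    def test_unknown_targets_rejected(self, motif_balanced, motif_links):
        fset = ForcingSet()
        fset.add(ForcingSeries("pb_multiplier", np.ones(5), target="nope"))
        with pytest.raises(InputError, match="nope"):
            fset.compile(motif_balanced.names, motif_links, 5)

    def test_short_series_extended_by_holding_last(self, motif_balanced,
                                                   motif_links):
        fset = ForcingSet()
        fset.add(ForcingSeries("pb_multiplier", np.array([1.0, 0.5]),
                               target="coldwater_prey"))
        pb, _, _ = fset.compile(motif_balanced.names, motif_links, 6)
        i = motif_balanced.index("coldwater_prey")
        assert pb[:, i].tolist() == [1.0, 0.5, 0.5, 0.5, 0.5, 0.5]

    def test_temperature_series_must_be_mapped_first(self):
        with pytest.raises(InputError):
            ForcingSet().add(ForcingSeries("temperature", np.ones(3)))
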