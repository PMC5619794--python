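"""Sum-of-squares objective and vulnerability calibration."""

import numpy as np
import pytest

import foodwebmsy as fw
from foodwebmsy.core import CatchTable, DietMatrix, FoodWebModel, FunctionalGroup
from foodwebmsy.dynamics import Trajectory, make_f_schedule
from foodwebmsy.errors import InputError
from foodwebmsy.fitting import ObservationSeries, ObservationSet


def flat_trajectory(names, values, years=5):
    times = np.arange(years + 1, dtype=float)
    bio = np.tile(np.asarray(values, dtype=float), (years + 1, 1))
    return Trajectory(names, times, bio, np.zeros_like(bio))


class TestObjective:
    def test_perfect_prediction_gives_zero(self):
        traj = flat_trajectory(["a"], [3.0])
        obs = ObservationSet([ObservationSeries(
            "s", "a", "absolute_biomass", [0, 1, 2], [3.0, 3.0, 3.0])])
        assert fw.objective_ss(traj, obs) == pytest.approx(0.0, abs=1e-15)

    def test_relative_series_scale_invariant(self):
        traj = flat_trajectory(["a"], [3.0])
        vals = np.array([2.0, 2.5, 3.5])
        base = fw.objective_ss(traj, ObservationSet([ObservationSeries(
            "s", "a", "relative_abundance", [0, 1, 2], vals)]))
        for c in (7.3, 0.01, 100.0):
            scaled = fw.objective_ss(traj, ObservationSet([ObservationSeries(
                "s", "a", "relative_abundance", [0, 1, 2], c * vals)]))
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_two_point_hand_value(self):
        # obs = (1, e), pred = (1, 1), absolute: SS = 0 + (log e)^2 = 1
        traj = flat_trajectory(["a"], [1.0], years=1)
        obs = ObservationSet([ObservationSeries(
            "s", "a", "absolute_biomass", [0, 1], [1.0, np.e])])
        assert fw.objective_ss(traj, obs) == pytest.approx(1.0, rel=1e-12)

    def test_series_order_invariance(self):
        traj = flat_trajectory(["a", "b"], [3.0, 4.0])
        s1 = ObservationSeries("s1", "a", "absolute_biomass", [0, 1], [2.0, 5.0])
        s2 = ObservationSeries("s2", "b", "relative_abundance", [0, 1], [1.0, 9.0])
        assert fw.objective_ss(traj, ObservationSet([s1, s2])) == pytest.approx(
            fw.objective_ss(traj, ObservationSet([s2, s1])), rel=1e-14)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(InputError):
            ObservationSeries("s", "a", "absolute_biomass", [0], [0.0])

    def test_uncovered_year_rejected(self):
        traj = flat_trajectory(["a"], [3.0], years=2)
        obs = ObservationSet([ObservationSeries(
            "s", "a", "absolute_biomass", [5], [1.0])])
        with pytest.raises(InputError, match="year"):
            fw.objective_ss(traj, obs)

    def test_closed_form_q_is_geometric_mean_ratio(self):
        traj = flat_trajectory(["a"], [2.0])
        obs = ObservationSet([ObservationSeries(
            "s", "a", "relative_abundance", [0, 1], [8.0, 2.0])])
        _, qs = fw.objective_ss(traj, obs, return_q=True)
        assert qs["s"] == pytest.approx(np.sqrt(8.0 * 2.0) / 2.0, rel=1e-12)


def _disconnected_web():
    """Two independent chains; observations only see the first."""
    groups = [
        FunctionalGroup("p1", "producer", B=50.0, PB=20.0),
        FunctionalGroup("p2", "producer", B=40.0, PB=20.0),
        FunctionalGroup("waste", "detritus", B=10.0),
        FunctionalGroup("c1", "consumer", B=5.0, PB=2.0, QB=10.0),
        FunctionalGroup("c2", "consumer", B=4.0, PB=2.0, QB=10.0),
    ]
    diet = DietMatrix.from_dict({"c1": {"p1": 1.0}, "c2": {"p2": 1.0}},
                                [g.name for g in groups])
    return fw.solve_mass_balance(FoodWebModel(
        groups, diet, CatchTable({"c1": 1.0, "c2": 1.0})))


class TestSensitivityRanking:
    def test_disconnected_link_has_zero_effect_and_ranks_last(self):
        b = _disconnected_web()
        links = fw.init_arena_params(b, 2.0)
        sched = make_f_schedule(b, 15, {"c1": 0.1 * np.linspace(1, 3, 15),
                                        "c2": 0.25 * np.linspace(1, 3, 15)})
        obs = fw.generate_observations(b, links, noise_cv=0.0, seed=0,
                                       years=15, groups=["c1"],
                                       f_schedule=sched)
        ranked = fw.rank_vulnerability_sensitivity(b, obs, links,
                                                   f_schedule=sched)
        assert ranked[-1][0].predator == "c2"
        assert ranked[-1][1] == pytest.approx(0.0, abs=1e-12)

    def test_generating_link_ranks_first(self, motif_balanced):
        b = motif_balanced
        sched = make_f_schedule(
            b, 22, {"piscivore": b.F_base[b.index("piscivore")]
                    * np.linspace(1, 4, 22)})
        links_true = fw.init_arena_params(b, {("piscivore", "forage_fish"): 15.0})
        obs = fw.generate_observations(b, links_true, noise_cv=0.0, seed=0,
                                       years=22, f_schedule=sched)
        links0 = fw.init_arena_params(b, 2.0)
        ranked = fw.rank_vulnerability_sensitivity(b, obs, links0,
                                                   f_schedule=sched)
        assert (ranked[0][0].predator, ranked[0][0].prey) == ("piscivore",
                                                              "forage_fish")
        again = fw.rank_vulnerability_sensitivity(b, obs, links0,
                                                  f_schedule=sched)
        assert [(l.predator, l.prey) for l, _ in ranked] == \
               [(l.predator, l.prey) for l, _ in again]


class TestFit:
    def fishing_history(self, b, years=22):
        return make_f_schedule(
            b, years, {"piscivore": b.F_base[b.index("piscivore")]
                       * np.linspace(1, 4, years)})

    def test_final_ss_never_exceeds_initial(self, motif_balanced):
        b = motif_balanced
        sched = self.fishing_history(b)
        links = fw.init_arena_params(b, 2.0)
        obs = fw.generate_observations(b, links, noise_cv=0.05, seed=4,
                                       years=22, f_schedule=sched)
        fit = fw.fit_vulnerabilities(b, obs, links,
                                     fit_pairs=[("piscivore", "forage_fish")],
                                     f_schedule=sched, maxiter=30, restarts=1)
        assert fit.ss_final <= fit.ss_initial + 1e-12
        assert fit.trace[0] == fit.ss_initial

    def test_single_link_recovery_within_20_percent(self, motif_balanced):
        b = motif_balanced
        sched = self.fishing_history(b)
        links_true = fw.init_arena_params(b, {("piscivore", "forage_fish"): 15.0})
        obs = fw.generate_observations(b, links_true, noise_cv=0.05, seed=7,
                                       years=22, f_schedule=sched)
        links0 = fw.init_arena_params(b, 2.0)
        fit = fw.fit_vulnerabilities(b, obs, links0,
                                     fit_pairs=[("piscivore", "forage_fish")],
                                     f_schedule=sched, maxiter=60, restarts=2)
        assert fit.v_fitted[0] == pytest.approx(15.0, rel=0.20)

    def test_forcing_aware_fit_beats_forcing_blind_fit(self, motif_balanced,
                                                       temp_series):
        from foodwebmsy.forcing import ForcingSet, apply_pb_forcing
        b = motif_balanced
        sched = self.fishing_history(b)
        fset = ForcingSet()
        fset.add(apply_pb_forcing("coldwater_prey", fw.COLDWATER_CURVE,
                                  temp_series))
        links_true = fw.init_arena_params(b, {("piscivore", "forage_fish"): 10.0})
        obs = fw.generate_observations(b, links_true, forcing=fset,
                                       noise_cv=0.05, seed=21, years=22,
                                       f_schedule=sched)
        links0 = fw.init_arena_params(b, 2.0)
        kwargs = dict(fit_pairs=[("piscivore", "forage_fish")],
                      f_schedule=sched, maxiter=50, restarts=2)
        with_f = fw.fit_vulnerabilities(b, obs, links0, forcing=fset, **kwargs)
        without = fw.fit_vulnerabilities(b, obs, links0, forcing=None, **kwargs)
        assert with_f.ss_final < without.ss_final

    def test_selection_by_sensitivity_when_pairs_not_given(self, motif_balanced):
        b = motif_balanced
        sched = self.fishing_history(b)
        links = fw.init_arena_params(b, 2.0)
        obs = fw.generate_observations(b, links, noise_cv=0.02, seed=3,
                                       years=22, f_schedule=sched)
        fit = fw.fit_vulnerabilities(b, obs, links, top_k=2,
                                     f_schedule=sched, maxiter=20, restarts=1)
        assert len(fit.pairs) == 2
        assert all(1.0 <= v <= 1e5 for v in fit.v_fitted)
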