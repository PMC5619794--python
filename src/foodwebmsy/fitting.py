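"""Calibration of vulnerability parameters against time series.

The objective is a log-scale sum of squares between observed and predicted
series.  Relative-abundance indices carry an unknown catchability q which
has a closed-form minimizer on the log scale (the geometric-mean ratio of
observed to predicted), so it never enters the search space.  Vulnerability
search runs derivative-free (Nelder-Mead) on log(v - 1), restarted from a
few spread-out initial points because the surface is rugged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import BalancedModel
from .dynamics import Simulator, Trajectory, TrophicLink, init_arena_params
from .errors import InputError

KINDS = ("absolute_biomass", "relative_abundance", "catch")


@dataclass
class ObservationSeries:
    """One observed time series for one group."""

    series_id: str
    group: str
    kind: str
    years: np.ndarray
    values: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InputError(f"series {self.series_id!r}: unknown kind {self.kind!r}")
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise InputError(f"series {self.series_id!r}: years/values length mismatch")
        if (self.values <= 0).any():
            raise InputError(
                f"series {self.series_id!r}: nonpositive observation incompatible "
                "with log-scale residuals")


@dataclass
class ObservationSet:
    series: list[ObservationSeries] = field(default_factory=list)

    def __iter__(self):
        return iter(self.series)

    def __len__(self):
        return len(self.series)

    @property
    def max_year(self) -> int:
        return max(int(s.years.max()) for s in self.series)


def objective_ss(trajectory: Trajectory, observations: ObservationSet,
                 return_q: bool = False):
    """Weighted log-residual sum of squares.

    SS = sum_series sum_years w (log obs - log(q pred))^2, q = 1 for
    absolute series and the closed-form geometric-mean ratio for relative
    ones (so rescaling a relative series leaves SS unchanged).
    """
    annual = trajectory.annual()
    years = np.round(annual.times).astype(int)
    year_pos = {int(y): k for k, y in enumerate(years)}

    ss = 0.0
    qs: dict[str, float] = {}
    for s in observations:
        missing = [int(y) for y in s.years if int(y) not in year_pos]
        if missing:
            raise InputError(
                f"series {s.series_id!r}: prediction does not cover year(s) {missing}")
        idx = [year_pos[int(y)] for y in s.years]
        what = "catch" if s.kind == "catch" else "biomass"
        pred = annual.series(s.group, what)[idx]
        pred = np.maximum(pred, 1e-300)
        resid = np.log(s.values) - np.log(pred)
        if s.kind == "relative_abundance":
            logq = float(np.mean(resid))
            resid = resid - logq
            qs[s.series_id] = float(np.exp(logq))
        else:
            qs[s.series_id] = 1.0
        ss += s.weight * float(np.sum(resid ** 2))
    return (ss, qs) if return_q else ss


def _vmap(links: list[TrophicLink]) -> dict[tuple[str, str], float]:
    return {(lk.predator, lk.prey): lk.v_user for lk in links}


def _ss_for_vmap(balanced: BalancedModel, vmap, observations, forcing,
                 years, f_schedule, dt, producer_model) -> float:
    links = init_arena_params(balanced, vmap)
    sim = Simulator(balanced, links, forcing=forcing, dt=dt,
                    producer_model=producer_model)
    traj = sim.run(years, f_schedule=f_schedule)
    return objective_ss(traj, observations)


def rank_vulnerability_sensitivity(balanced: BalancedModel,
                                   observations: ObservationSet,
                                   links: list[TrophicLink],
                                   perturbation: float = 2.0,
                                   forcing=None,
                                   years: int | None = None,
                                   f_schedule=None,
                                   dt: float = 1.0 / 12.0,
                                   producer_model: str = "saturating"):
    """Rank links by |change in SS| under a one-at-a-time v perturbation.

    Deterministic: ties broken by (predator, prey) name.  Returns a list of
    (link, delta_ss) sorted most-influential first.
    """
    if years is None:
        years = observations.max_year
    base_vmap = _vmap(links)
    ss0 = _ss_for_vmap(balanced, base_vmap, observations, forcing,
                       years, f_schedule, dt, producer_model)
    out = []
    for lk in links:
        vmap = dict(base_vmap)
        vmap[(lk.predator, lk.prey)] = max(lk.v_user * perturbation, 1.0)
        ss = _ss_for_vmap(balanced, vmap, observations, forcing,
                          years, f_schedule, dt, producer_model)
        out.append((lk, abs(ss - ss0)))
    out.sort(key=lambda t: (-t[1], t[0].predator, t[0].prey))
    return out


@dataclass
class FitResult:
    pairs: list[tuple[str, str]]
    v_initial: list[float]
    v_fitted: list[float]
    ss_initial: float
    ss_final: float
    trace: list[float]
    converged: bool
    n_eval: int

    def to_dict(self) -> dict:
        return {
            "links": [{"predator": p, "prey": q, "v_initial": vi, "v_fitted": vf}
                      for (p, q), vi, vf in zip(self.pairs, self.v_initial, self.v_fitted)],
            "ss_initial": self.ss_initial,
            "ss_final": self.ss_final,
            "converged": self.converged,
            "n_eval": self.n_eval,
            "trace": self.trace,
        }


V_MIN, V_MAX = 1.0, 1e5


def _to_z(v: float) -> float:
    return float(np.log(max(v, V_MIN) - 1.0 + 1e-6))


def _to_v(z: float) -> float:
    return float(np.clip(1.0 + np.exp(z) - 1e-6, V_MIN, V_MAX))


def fit_vulnerabilities(balanced: BalancedModel,
                        observations: ObservationSet,
                        links: list[TrophicLink],
                        fit_pairs: list[tuple[str, str]] | None = None,
                        top_k: int = 5,
                        forcing=None,
                        years: int | None = None,
                        f_schedule=None,
                        dt: float = 1.0 / 12.0,
                        producer_model: str = "saturating",
                        maxiter: int = 120,
                        restarts: int = 3) -> FitResult:
    """Minimize the SS objective over the vulnerabilities of selected links.

    ``fit_pairs`` names the links to calibrate; if omitted the ``top_k``
    most SS-sensitive links are selected first.  The search is bounded to
    v in [1, 1e5] on a log scale.  Non-convergence is a warning, not an
    error: the best point seen is returned, and the final SS never exceeds
    the initial one because the starting point is always a candidate.
    """
    if years is None:
        years = observations.max_year
    if fit_pairs is None:
        if top_k < 1:
            raise InputError("top_k must be at least 1")
        ranked = rank_vulnerability_sensitivity(
            balanced, observations, links, forcing=forcing, years=years,
            f_schedule=f_schedule, dt=dt, producer_model=producer_model)
        fit_pairs = [(lk.predator, lk.prey) for lk, _ in ranked[:top_k]]

    base_vmap = _vmap(links)
    for pair in fit_pairs:
        if pair not in base_vmap:
            raise InputError(f"no trophic link {pair[0]!r} -> {pair[1]!r} to fit")
    v_init = [base_vmap[p] for p in fit_pairs]

    n_eval = 0

    def ss_of(zvec) -> float:
        nonlocal n_eval
        n_eval += 1
        vmap = dict(base_vmap)
        for pair, z in zip(fit_pairs, zvec):
            vmap[pair] = _to_v(z)
        return _ss_for_vmap(balanced, vmap, observations, forcing,
                            years, f_schedule, dt, producer_model)

    z0 = np.array([_to_z(v) for v in v_init])
    ss_init = ss_of(z0)

    starts = [z0]
    for v_start in (5.0, 50.0):
        if restarts > len(starts):
            starts.append(np.full(len(fit_pairs), _to_z(v_start)))
    starts = starts[:max(restarts, 1)]

    best_z, best_ss = z0, ss_init
    trace: list[float] = [ss_init]
    converged = False
    for z_start in starts:
        res = minimize(ss_of, z_start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4,
                                "fatol": 1e-8, "disp": False})
        trace.append(float(res.fun))
        if res.fun < best_ss:
            best_ss, best_z = float(res.fun), np.asarray(res.x)
        converged = converged or bool(res.success)

    if not converged:
        warnings.warn("vulnerability fit did not converge within the iteration "
                      "budget; returning best point found", RuntimeWarning)

    return FitResult(
        pairs=list(fit_pairs),
        v_initial=v_init,
        v_fitted=[_to_v(z) for z in best_z],
        ss_initial=ss_init,
        ss_final=best_ss,
        trace=trace,
        converged=converged,
        n_eval=n_eval,
    )
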