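"""MSY and Fmsy reference points from equilibrium yield sweeps.

Fishing mortality on one target group is stepped up a staircase (default
25 equally spaced F values from 0, each held 20 years so the system
equilibrates — a 500-year run), while every other group keeps its base F.
Two framings:

* single-species ("ss"): all non-target biomasses frozen at base — the
  classic assumption that the rest of the system does not respond;
* ecosystem ("es"): the whole web responds dynamically.

The equilibrium yield at each step is F times the mean target biomass over
the last 5 years of the block.  MSY is the maximum equilibrium yield; Fmsy
is the lowest grid F within 1% of that maximum (yield curves can be flat
on top, so the flat-range width is reported as a diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BalancedModel
from .dynamics import DEFAULT_DT, Simulator, TrophicLink, make_f_schedule
from .errors import InputError

FLAT_TOL = 0.01  # relative band defining "within reach of the maximum"
EQUIL_WINDOW = 5  # years averaged at the end of each block


def f_staircase_schedule(F_max: float, n_steps: int = 25,
                         years_per_step: int = 20) -> np.ndarray:
    """Annual target-F values: a nondecreasing staircase from 0 to F_max."""
    if F_max <= 0:
        raise InputError("F_max must be positive")
    if n_steps < 2:
        raise InputError("need at least 2 staircase steps")
    if years_per_step < 1:
        raise InputError("each step must last at least one year")
    grid = np.linspace(0.0, F_max, n_steps)
    return np.repeat(grid, years_per_step)


def default_f_max(balanced: BalancedModel, target: str) -> float:
    """Bracket the yield peak for lightly and heavily fished groups alike."""
    j = balanced.index(target)
    return float(max(3.0 * balanced.F_base[j], 1.5 * balanced.PB[j]))


@dataclass
class MSYResult:
    target: str
    mode: str                  # "ss" | "es"
    forcing: bool
    F_grid: np.ndarray
    eq_yield: np.ndarray
    eq_biomass: np.ndarray
    equilibrated: np.ndarray   # bool per step
    MSY: float
    Fmsy: float
    B_at_msy: float
    flat_width: float          # F range within FLAT_TOL of the maximum
    yield_q: dict | None = None    # Monte Carlo quartiles, filled by mc_msy
    biomass_q: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "target": self.target, "mode": self.mode, "forcing": self.forcing,
            "MSY": self.MSY, "Fmsy": self.Fmsy, "B_at_msy": self.B_at_msy,
            "flat_width": self.flat_width,
            "F_grid": self.F_grid.tolist(),
            "eq_yield": self.eq_yield.tolist(),
            "eq_biomass": self.eq_biomass.tolist(),
            "equilibrated": self.equilibrated.astype(bool).tolist(),
        }
        if self.yield_q is not None:
            d["yield_q"] = {k: v.tolist() for k, v in self.yield_q.items()}
            d["biomass_q"] = {k: v.tolist() for k, v in self.biomass_q.items()}
        return d


def _block_stats(times, bio, cat, j, F_val, t_end, years_per_step):
    """Equilibrium yield/biomass from the tail of one staircase block."""
    window = min(EQUIL_WINDOW, years_per_step)
    sel = (times >= t_end - window - 1e-9) & (times <= t_end + 1e-9)
    b_mean = float(bio[sel, j].mean())
    y_mean = F_val * b_mean
    b_first = float(bio[sel, j][0])
    b_last = float(bio[sel, j][-1])
    if b_last <= 1e-12 * max(b_first, 1.0) or b_first <= 0:
        ok = True  # collapsed to the floor: stationary
    else:
        rate = (b_last / b_first) ** (1.0 / window) - 1.0
        ok = abs(rate) <= 0.01
    return y_mean, b_mean, ok


def equilibrium_yield(balanced: BalancedModel, links: list[TrophicLink],
                      target: str, F: float, mode: str = "es", forcing=None,
                      years: int = 20, dt: float = DEFAULT_DT,
                      producer_model: str = "saturating") -> dict:
    """Equilibrium yield and biomass for one constant target F.

    Runs from the base state for ``years`` and averages the final window.
    Non-equilibration is flagged in the result, not fatal.
    """
    if F < 0:
        raise InputError("F must be non-negative")
    mode = _check_mode(mode)
    frozen = _frozen_set(balanced, target, mode)
    sim = Simulator(balanced, links, forcing=forcing, dt=dt,
                    producer_model=producer_model, frozen=frozen)
    sched = make_f_schedule(balanced, years, {target: F})
    traj = sim.run(years, f_schedule=sched)
    j = balanced.index(target)
    y, b, ok = _block_stats(traj.times, traj.biomass, traj.catch, j, F,
                            float(years), years)
    return {"yield": y, "biomass": b, "equilibrated": ok}


def _check_mode(mode: str) -> str:
    mode = mode.lower()
    if mode not in ("ss", "es"):
        raise InputError(f"mode must be 'ss' or 'es', got {mode!r}")
    return mode


def _frozen_set(balanced: BalancedModel, target: str, mode: str) -> set[str]:
    if target not in balanced.names:
        raise InputError(f"unknown target group {target!r}")
    if mode == "ss":
        return set(balanced.names) - {target}
    return set()


def estimate_msy(balanced: BalancedModel, links: list[TrophicLink],
                 target: str, mode: str = "es", forcing=None,
                 F_max: float | None = None, n_steps: int = 25,
                 years_per_step: int = 20, dt: float = DEFAULT_DT,
                 producer_model: str = "saturating") -> MSYResult:
    """Run the F staircase and extract MSY / Fmsy for one target group."""
    mode = _check_mode(mode)
    if F_max is None:
        F_max = default_f_max(balanced, target)
    frozen = _frozen_set(balanced, target, mode)

    f_target = f_staircase_schedule(F_max, n_steps, years_per_step)
    years = n_steps * years_per_step
    sched = make_f_schedule(balanced, years, {target: f_target})

    sim = Simulator(balanced, links, forcing=forcing, dt=dt,
                    producer_model=producer_model, frozen=frozen)
    traj = sim.run(years, f_schedule=sched)

    j = balanced.index(target)
    grid = np.linspace(0.0, F_max, n_steps)
    eq_y = np.empty(n_steps)
    eq_b = np.empty(n_steps)
    eq_ok = np.empty(n_steps, dtype=bool)
    for k, F_val in enumerate(grid):
        t_end = (k + 1) * years_per_step
        eq_y[k], eq_b[k], eq_ok[k] = _block_stats(
            traj.times, traj.biomass, traj.catch, j, F_val, t_end, years_per_step)

    msy = float(eq_y.max())
    near = np.where(eq_y >= (1.0 - FLAT_TOL) * msy)[0] if msy > 0 else np.array([0])
    k_msy = int(near[0])  # lowest F within the flat band
    flat_width = float(grid[near[-1]] - grid[near[0]]) if msy > 0 else 0.0

    return MSYResult(
        target=target, mode=mode, forcing=forcing is not None,
        F_grid=grid, eq_yield=eq_y, eq_biomass=eq_b, equilibrated=eq_ok,
        MSY=msy, Fmsy=float(grid[k_msy]), B_at_msy=float(eq_b[k_msy]),
        flat_width=flat_width,
    )
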