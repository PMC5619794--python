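"""Seeded generators: balanced food webs, temperature series, observations.

Everything downstream is exercised on synthetic systems with the
statistical structure the analysis assumes:

* a fixed lake-like motif — piscivore / forage fish / cold-water
  stenothermal prey / warm-adapted mesopredator / invertebrate /
  producer + detritus — whose diet table is deliberately constant so that
  directional experiments (warming hurts the stenotherm, warming helps the
  warm-adapted predator, ecosystem vs single-species MSY) are stable;
* random demand-capped webs: consumer biomasses are drawn so that committed
  predation never exceeds 85% of any prey's production, which makes every
  seeded web balance by construction;
* a mid-summer (July-August) temperature regime with a warming step between
  decades, plus observation series = simulated trajectories with
  multiplicative lognormal noise.

Every artifact is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CONSUMER, DETRITUS, PRODUCER, BalancedModel, CatchTable,
                   DietMatrix, FoodWebModel, FunctionalGroup, solve_mass_balance)
from .dynamics import DEFAULT_DT, Simulator, TrophicLink
from .errors import InputError
from .fitting import ObservationSeries, ObservationSet
from .forcing import ToleranceCurve

# thermal limits for the two stenotherm archetypes (deg C): the cold-water
# prey uses the cisco-like optimum-below-20 / lethal-26 pair; a burbot-like
# curve (optimum 18.2, critical 27.5) is provided for sensitivity work
COLDWATER_CURVE = ToleranceCurve(T_opt=20.0, T_crit=26.0)
BURBOT_CURVE = ToleranceCurve(T_opt=18.2, T_crit=27.5)


@dataclass
class SynthesisSpec:
    """Knobs for the generators; defaults are the study conditions."""

    n_groups: int = 8
    motif: bool = False
    connectance: float = 0.4
    b_producer: tuple[float, float] = (50.0, 200.0)
    pb_producer: tuple[float, float] = (20.0, 100.0)
    pb_consumer: tuple[float, float] = (0.5, 5.0)
    ge_range: tuple[float, float] = (0.15, 0.3)
    noise_cv: float = 0.05
    temp_baseline: float = 22.0
    temp_step: float = 0.6
    step_year: int = 11
    temp_noise_sd: float = 0.25
    n_years: int = 22
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 4:
            raise InputError("need at least producer, detritus and two consumers")
        if not (0.0 < self.connectance <= 1.0):
            raise InputError("connectance must be in (0, 1]")
        if not (1 <= self.step_year <= self.n_years):
            raise InputError("step year outside the series range")


# ---------------------------------------------------------------------------
# the lake motif
# ---------------------------------------------------------------------------

MOTIF_GROUPS = ("producer", "detritus", "invertebrate", "forage_fish",
                "coldwater_prey", "mesopredator", "piscivore")

#: fixed diet fractions (predator -> {prey: fraction}); constant by design
MOTIF_DIETS = {
    "invertebrate": {"producer": 0.8, "detritus": 0.2},
    "forage_fish": {"invertebrate": 0.9, "producer": 0.05, "detritus": 0.05},
    "coldwater_prey": {"invertebrate": 1.0},
    "mesopredator": {"forage_fish": 0.5, "invertebrate": 0.5},
    "piscivore": {"forage_fish": 0.6, "coldwater_prey": 0.3, "invertebrate": 0.1},
}

MOTIF_CATCHES = {"forage_fish": 2.0, "coldwater_prey": 1.0,
                 "mesopredator": 0.3, "piscivore": 1.2}


def motif_foodweb() -> FoodWebModel:
    """The fixed 7-group lake motif.

    The cold-water prey and the forage fish share the invertebrate pool
    (the competition channel) and the piscivore eats the forage fish (the
    top-down channel).  Biomass of the forage fish and the invertebrate is
    solved from a fixed EE of 0.9; the rest solve for EE.
    """
    groups = [
        FunctionalGroup("producer", PRODUCER, B=100.0, PB=80.0),
        FunctionalGroup("detritus", DETRITUS, B=50.0),
        FunctionalGroup("invertebrate", CONSUMER, PB=25.0, QB=100.0, EE=0.9),
        FunctionalGroup("forage_fish", CONSUMER, PB=1.8, QB=7.0, EE=0.9),
        FunctionalGroup("coldwater_prey", CONSUMER, B=15.0, PB=0.9, QB=4.5),
        FunctionalGroup("mesopredator", CONSUMER, B=8.0, PB=0.6, QB=3.0),
        FunctionalGroup("piscivore", CONSUMER, B=12.0, PB=0.5, QB=2.5),
    ]
    diet = DietMatrix.from_dict(MOTIF_DIETS, list(MOTIF_GROUPS))
    return FoodWebModel(groups=groups, diet=diet,
                        catches=CatchTable(dict(MOTIF_CATCHES)))


# ---------------------------------------------------------------------------
# random webs
# ---------------------------------------------------------------------------

def generate_foodweb(spec: SynthesisSpec, seed: int | None = None) -> FoodWebModel:
    """A random solvable web: one producer, one detritus, n-2 consumers.

    Consumers are trophically ordered (each eats only lower-indexed
    groups), and biomasses are capped against prey production, so the
    solved EE of every group stays below 1 by construction.
    """
    if spec.motif:
        return motif_foodweb()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_groups
    names = ["producer", "detritus"] + [f"consumer_{k}" for k in range(1, n - 1)]

    b_prod = rng.uniform(*spec.b_producer)
    pb_prod = rng.uniform(*spec.pb_producer)
    b_det = rng.uniform(20.0, 100.0)

    groups = [
        FunctionalGroup("producer", PRODUCER, B=b_prod, PB=pb_prod),
        FunctionalGroup("detritus", DETRITUS, B=b_det),
    ]
    diets: dict[str, dict[str, float]] = {}
    # remaining consumable production per group (85% headroom commitment cap)
    avail = {"producer": 0.85 * b_prod * pb_prod, "detritus": np.inf}

    B_vals = {"producer": b_prod, "detritus": b_det}
    for k in range(2, n):
        name = names[k]
        lower = names[:k]
        prey = [p for p in lower if rng.uniform() < spec.connectance]
        if not prey:
            prey = ["producer" if k == 2 else str(rng.choice(lower))]
        w = rng.dirichlet(np.ones(len(prey)))
        # first-level consumers turn over fast, upper levels slowly
        lo, hi = spec.pb_consumer
        pb = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if k == 2:
            pb *= 10.0
        ge = rng.uniform(*spec.ge_range)
        qb = pb / ge

        caps = [avail[p] / (qb * wi) for p, wi in zip(prey, w) if np.isfinite(avail[p])]
        b_cap = min(caps) if caps else 0.3 * b_det
        b = float(rng.uniform(0.2, 0.8) * b_cap)
        for p, wi in zip(prey, w):
            if np.isfinite(avail[p]):
                avail[p] -= b * qb * wi
        avail[name] = 0.85 * b * pb
        B_vals[name] = b
        groups.append(FunctionalGroup(name, CONSUMER, B=b, PB=pb, QB=qb))
        diets[name] = {p: float(wi) for p, wi in zip(prey, w)}

    # light fishing on roughly half the consumers; headroom guarantees EE < 1
    catches = {}
    for k in range(2, n):
        if rng.uniform() < 0.5:
            name = names[k]
            g = groups[k]
            catches[name] = float(rng.uniform(0.02, 0.1) * g.PB * B_vals[name])

    diet = DietMatrix.from_dict(diets, names)
    return FoodWebModel(groups=groups, diet=diet, catches=CatchTable(catches))


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def generate_temperature_series(spec: SynthesisSpec,
                                seed: int | None = None) -> pd.DataFrame:
    """Monthly (year, month, temp_C) table with a mid-series warming step.

    July-August values sit at the baseline, plus the step from
    ``step_year`` on, plus seeded noise; the other months sit well below
    every tolerance limit so only the warm season matters.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for year in range(1, spec.n_years + 1):
        warm = spec.temp_baseline + (spec.temp_step if year >= spec.step_year else 0.0)
        for month in range(1, 13):
            if month in (7, 8):
                t = warm + rng.normal(0.0, spec.temp_noise_sd)
            else:
                t = spec.temp_baseline - 8.0
            rows.append((year, month, t))
    return pd.DataFrame(rows, columns=["year", "month", "temp_C"])


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

def generate_observations(balanced: BalancedModel, links: list[TrophicLink],
                          forcing=None, noise_cv: float = 0.05,
                          seed: int = 0, years: int | None = None,
                          groups: list[str] | None = None,
                          relative: tuple[str, ...] = (),
                          f_schedule: np.ndarray | None = None,
                          dt: float = DEFAULT_DT,
                          producer_model: str = "saturating",
                          weight: float = 1.0) -> ObservationSet:
    """Observation series = simulated trajectories x lognormal noise.

    ``relative`` names groups whose series are additionally scaled by a
    random per-series constant (a survey catchability, to exercise the
    closed-form q in the objective).  ``noise_cv = 0`` returns the exact
    trajectories.
    """
    rng = np.random.default_rng(seed)
    if years is None:
        years = 22
    sim = Simulator(balanced, links, forcing=forcing, dt=dt,
                    producer_model=producer_model)
    traj = sim.run(years, f_schedule=f_schedule).annual()
    yrs = np.round(traj.times).astype(int)

    if groups is None:
        groups = [nm for nm, cl in zip(balanced.names, balanced.group_class)
                  if cl == CONSUMER]

    sigma = float(np.sqrt(np.log(1.0 + noise_cv ** 2)))
    series = []
    for nm in groups:
        vals = traj.series(nm, "biomass").copy()
        if sigma > 0:
            vals = vals * np.exp(rng.normal(0.0, sigma, size=len(vals)))
        kind = "relative_abundance" if nm in relative else "absolute_biomass"
        if kind == "relative_abundance":
            vals = vals * float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        series.append(ObservationSeries(
            series_id=f"{nm}_survey", group=nm, kind=kind,
            years=yrs, values=vals, weight=weight))
    return ObservationSet(series)
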