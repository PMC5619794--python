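"""Parameter uncertainty on MSY estimates by rejection Monte Carlo.

Each trial multiplies every group's B, P/B, Q/B and (input) EE by an
independent draw with mean 1 and coefficient of variation ``cv``, re-solves
the mass balance for the originally missing parameters, and keeps the
candidate only if the re-balanced model passes the consistency check
(no EE beyond 1 plus tolerance).  Accepted candidates are pushed through
the full staircase MSY estimation; the spread across runs is summarized as
per-F-step quartiles.

Draws are bounded (truncated normal): the truncation bounds sit at ±2
pre-truncation standard deviations and the pre-truncation scale is inflated
so the realized CV of the draws equals ``cv`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import BalancedModel, DETRITUS, FoodWebModel, consistency_check, solve_mass_balance
from .dynamics import init_arena_params
from .errors import FoodWebError, InputError, MonteCarloError
from .msy import MSYResult, estimate_msy

TRUNC = 2.0
# sd of a standard normal truncated at +-2: realized CV = _SHRINK * scale
_SHRINK = float(np.sqrt(1.0 - 4.0 * stats.norm.pdf(2.0)
                        / (2.0 * stats.norm.cdf(2.0) - 1.0)))


@dataclass
class MCConfig:
    cv: float = 0.1
    n_success: int = 80
    ee_tolerance: float = 0.01
    max_attempts: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise InputError("cv must be non-negative")
        if self.n_success < 1:
            raise InputError("need at least one successful run")
        if self.max_attempts is None:
            self.max_attempts = 50 * self.n_success
        if self.max_attempts < self.n_success:
            raise InputError("max_attempts must be at least n_success")


def draw_multipliers(size: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-1 bounded multipliers whose realized CV equals cv."""
    if cv == 0:
        return np.ones(size)
    scale = cv / _SHRINK
    u = rng.uniform(stats.norm.cdf(-TRUNC), stats.norm.cdf(TRUNC), size=size)
    return 1.0 + scale * stats.norm.ppf(u)


def perturb_model(balanced: BalancedModel, cv: float,
                  rng: np.random.Generator):
    """One MC trial: perturbed candidate, success flag, re-balanced model.

    EE is perturbed only where it was an input; originally solved
    parameters are blanked and re-derived so every candidate is internally
    consistent before being checked.  Failure is a flag, never an error.
    """
    try:
        candidate_groups = []
        for g, solved in zip(balanced.groups, balanced.solved_param):
            if g.group_class == DETRITUS:
                mult = draw_multipliers(1, cv, rng)
                candidate_groups.append(replace(g, B=g.B * float(mult[0]), EE=None))
                continue
            mult = draw_multipliers(4, cv, rng)
            params = {
                "B": g.B * float(mult[0]),
                "PB": g.PB * float(mult[1]),
                "QB": None if g.QB is None else g.QB * float(mult[2]),
                # EE perturbed only where it was an input to the balance
                "EE": g.EE * float(mult[3]) if solved in ("B", "PB", "QB") else g.EE,
            }
            if solved is not None:
                params[solved] = None
            else:
                params["EE"] = None  # fully specified: EE is re-derived anyway
            candidate_groups.append(replace(g, **params))
        candidate = FoodWebModel(groups=candidate_groups, diet=balanced.diet,
                                 catches=balanced.catches)
    except FoodWebError:
        # an out-of-range perturbed input (e.g. EE above 1) is just a
        # rejected trial
        return None, False, None
    try:
        solved_model = solve_mass_balance(candidate)
    except FoodWebError:
        return candidate, False, None
    report = consistency_check(solved_model)
    return candidate, report.passed, solved_model


@dataclass
class MCResult:
    """Point estimate plus the Monte Carlo envelope."""

    point: MSYResult
    per_run_yield: np.ndarray    # (n_success, n_steps)
    per_run_biomass: np.ndarray
    per_run_msy: np.ndarray
    per_run_fmsy: np.ndarray
    attempts: int
    successes: int
    config: MCConfig = field(repr=False, default=None)

    @property
    def yield_quartiles(self) -> dict[str, np.ndarray]:
        return {q: np.percentile(self.per_run_yield, p, axis=0)
                for q, p in (("q25", 25), ("q50", 50), ("q75", 75))}

    @property
    def biomass_quartiles(self) -> dict[str, np.ndarray]:
        return {q: np.percentile(self.per_run_biomass, p, axis=0)
                for q, p in (("q25", 25), ("q50", 50), ("q75", 75))}


def mc_msy(balanced: BalancedModel, target: str, mode: str = "es",
           forcing=None, mc_config: MCConfig | None = None,
           v_user=2.0, ee_tolerance: float | None = None,
           **msy_kwargs) -> MCResult:
    """Staircase MSY under parameter uncertainty.

    Runs trials until exactly ``n_success`` candidates pass the
    mass-balance check, evaluates each through :func:`estimate_msy` on the
    same F grid as the unperturbed point estimate, and attaches per-step
    yield/biomass quartiles.  Fully reproducible from the config seed.
    """
    cfg = mc_config or MCConfig()
    if ee_tolerance is not None:
        cfg.ee_tolerance = ee_tolerance
    rng = np.random.default_rng(cfg.seed)

    links0 = init_arena_params(balanced, v_user)
    point = estimate_msy(balanced, links0, target, mode=mode, forcing=forcing,
                         **msy_kwargs)
    f_max = float(point.F_grid[-1])
    msy_kwargs = dict(msy_kwargs)
    msy_kwargs["F_max"] = f_max  # same grid for every run

    yields, biomasses, msys, fmsys = [], [], [], []
    attempts = 0
    successes = 0
    while successes < cfg.n_success:
        if attempts >= cfg.max_attempts:
            raise MonteCarloError(
                f"only {successes} successful candidates after {attempts} "
                f"attempts (target {cfg.n_success})",
                attempts=attempts, successes=successes)
        attempts += 1
        _, ok, solved = perturb_model(balanced, cfg.cv, rng)
        if not ok:
            continue
        report = consistency_check(solved, ee_tolerance=cfg.ee_tolerance)
        if not report.passed:
            continue
        successes += 1
        links = init_arena_params(solved, v_user)
        res = estimate_msy(solved, links, target, mode=mode, forcing=forcing,
                           **msy_kwargs)
        yields.append(res.eq_yield)
        biomasses.append(res.eq_biomass)
        msys.append(res.MSY)
        fmsys.append(res.Fmsy)

    out = MCResult(
        point=point,
        per_run_yield=np.array(yields),
        per_run_biomass=np.array(biomasses),
        per_run_msy=np.array(msys),
        per_run_fmsy=np.array(fmsys),
        attempts=attempts,
        successes=successes,
        config=cfg,
    )
    point.yield_q = out.yield_quartiles
    point.biomass_q = out.biomass_quartiles
    return out
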