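"""Static trophic mass balance.

A food web is a set of functional groups (biomass pools) tied together by a
diet-composition matrix and a catch table.  At the base state every group's
production is fully accounted for::

    B_i (P/B)_i = Y_i + sum_j B_j (Q/B)_j DC_ji + B_i (P/B)_i (1 - EE_i) + BA_i + E_i

i.e. production goes to fishery catch, predation, "other" mortality,
biomass accumulation and net migration.  Per group at most one of
{B, P/B, Q/B, EE} may be left blank; the solver completes the set so the
balance holds to machine precision.

Within a group, consumption partitions exactly into production, respiration
and unassimilated food.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EnergyPartitionError, InputError, MassBalanceError

CONSUMER = "consumer"
PRODUCER = "producer"
DETRITUS = "detritus"

GROUP_CLASSES = (CONSUMER, PRODUCER, DETRITUS)

#: parameters that may be solved by the mass-balance routine
SOLVABLE = ("B", "PB", "QB", "EE")


@dataclass
class FunctionalGroup:
    """One biomass pool: a species or an aggregate modeled as a single stock.

    Units: B in the model-wide biomass unit (e.g. tonnes); PB and QB per
    year; EE and GS dimensionless; BA and Emig in biomass per year.
    A ``None`` in B/PB/QB/EE marks the parameter the solver must fill in.
    """

    name: str
    group_class: str = CONSUMER
    B: float | None = None
    PB: float | None = None
    QB: float | None = None
    EE: float | None = None
    BA: float = 0.0
    Emig: float = 0.0
    GS: float | None = None

    def __post_init__(self):
        if self.group_class not in GROUP_CLASSES:
            raise InputError(f"group {self.name!r}: unknown class {self.group_class!r}")
        if self.group_class in (PRODUCER, DETRITUS):
            if self.QB not in (None, 0.0):
                raise InputError(f"group {self.name!r}: {self.group_class} cannot consume (QB given)")
            self.QB = None
        if self.group_class == DETRITUS:
            # passive pool: no production parameters, EE is diagnostic only
            self.PB = None
            self.EE = None
            if self.B is None:
                raise InputError(f"detritus group {self.name!r} requires a biomass")
        if self.GS is None:
            self.GS = 0.2 if self.group_class == CONSUMER else 0.0
        self._validate_ranges()

    def _validate_ranges(self):
        if self.B is not None and self.B < 0:
            raise InputError(f"group {self.name!r}: negative biomass")
        if self.PB is not None and self.PB <= 0 and self.group_class != DETRITUS:
            raise InputError(f"group {self.name!r}: P/B must be positive")
        if self.QB is not None and self.QB <= 0:
            raise InputError(f"group {self.name!r}: Q/B must be positive")
        if self.EE is not None and not (0.0 <= self.EE <= 1.0):
            raise InputError(f"group {self.name!r}: EE outside [0, 1]")
        if not (0.0 <= self.GS < 1.0):
            raise InputError(f"group {self.name!r}: GS outside [0, 1)")

    @property
    def missing_param(self) -> str | None:
        """Which of B/PB/QB/EE the solver must provide (None if complete)."""
        if self.group_class == DETRITUS:
            return None
        candidates = ["B", "PB", "EE"] + (["QB"] if self.group_class == CONSUMER else [])
        missing = [p for p in candidates if getattr(self, p) is None]
        if len(missing) > 1:
            raise MassBalanceError(
                f"group {self.name!r}: {len(missing)} unknowns ({', '.join(missing)}) "
                "but only one balance equation per group",
                group=self.name,
            )
        return missing[0] if missing else None


class DietMatrix:
    """Diet fractions, prey-by-predator.

    ``frac.loc[prey, predator]`` is the fraction of *prey* in the diet of
    *predator*.  Each consumer column plus its import fraction sums to one;
    producer and detritus columns are all zero.
    """

    def __init__(self, frac: pd.DataFrame, import_fraction: pd.Series | None = None):
        self.frac = frac.astype(float)
        if import_fraction is None:
            import_fraction = pd.Series(0.0, index=frac.columns)
        self.import_fraction = import_fraction.astype(float).reindex(frac.columns).fillna(0.0)

    @classmethod
    def from_dict(cls, diets: dict[str, dict[str, float]], names: list[str]) -> "DietMatrix":
        """Build from ``{predator: {prey: fraction, ..., "import": f}}``."""
        frac = pd.DataFrame(0.0, index=names, columns=names)
        imp = pd.Series(0.0, index=names)
        for pred, d in diets.items():
            for prey, f in d.items():
                if prey == "import":
                    imp[pred] = f
                else:
                    frac.loc[prey, pred] = f
        return cls(frac, imp)

    def validate(self, groups: list[FunctionalGroup], atol: float = 1e-9):
        byname = {g.name: g for g in groups}
        vals = self.frac.to_numpy()
        if (vals < -atol).any() or (vals > 1 + atol).any():
            raise InputError("diet matrix entries must lie in [0, 1]")
        for name in self.frac.columns:
            g = byname.get(name)
            if g is None:
                raise InputError(f"diet matrix column {name!r} is not a known group")
            total = float(self.frac[name].sum() + self.import_fraction[name])
            if g.group_class == CONSUMER:
                if abs(total - 1.0) > atol:
                    raise InputError(
                        f"diet of predator {name!r} sums to {total:.6g}, expected 1"
                    )
            elif total > atol:
                raise InputError(f"{g.group_class} group {name!r} must have an all-zero diet column")

    def fraction(self, prey: str, predator: str) -> float:
        return float(self.frac.loc[prey, predator])


@dataclass
class CatchTable:
    """Fishery removals per group, biomass per year."""

    Y: dict[str, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        y = self.Y.get(name, 0.0)
        if y < 0:
            raise InputError(f"negative catch for group {name!r}")
        return y


@dataclass
class FoodWebModel:
    """The unbalanced input: groups, diet matrix, catches."""

    groups: list[FunctionalGroup]
    diet: DietMatrix
    catches: CatchTable = field(default_factory=CatchTable)

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate group name(s): {', '.join(dup)}")
        self.diet.frac = self.diet.frac.reindex(index=names, columns=names).fillna(0.0)
        self.diet.import_fraction = self.diet.import_fraction.reindex(names).fillna(0.0)
        self.diet.validate(self.groups)
        for name in self.catches.Y:
            if name not in names:
                raise InputError(f"catch table references unknown group {name!r}")

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def group(self, name: str) -> FunctionalGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class BalancedModel:
    """A completed model plus the derived flows the dynamics need.

    Arrays are aligned with ``names``.  ``M2`` is predation mortality,
    ``MO = PB (1-EE)`` other mortality, ``g = PB/QB`` net growth efficiency,
    ``R`` respiration flux (biomass/yr).  ``det_export_rate`` closes each
    detritus pool's budget at the base state.
    """

    names: list[str]
    group_class: list[str]
    groups: list[FunctionalGroup]
    diet: DietMatrix
    catches: CatchTable
    B: np.ndarray
    PB: np.ndarray
    QB: np.ndarray
    EE: np.ndarray
    GS: np.ndarray
    BA: np.ndarray
    Emig: np.ndarray
    Y: np.ndarray
    F_base: np.ndarray
    M2: np.ndarray
    MO: np.ndarray
    g: np.ndarray
    R: np.ndarray
    det_export_rate: np.ndarray
    #: which parameter the solver filled per group (None if input-complete)
    solved_param: list = field(default_factory=list)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def is_consumer(self) -> np.ndarray:
        return np.array([c == CONSUMER for c in self.group_class])

    @property
    def is_producer(self) -> np.ndarray:
        return np.array([c == PRODUCER for c in self.group_class])

    @property
    def is_detritus(self) -> np.ndarray:
        return np.array([c == DETRITUS for c in self.group_class])

    def to_foodweb(self) -> FoodWebModel:
        """Re-wrap the completed parameters as an input model (no unknowns)."""
        return FoodWebModel(groups=[replace(g) for g in self.groups],
                            diet=self.diet, catches=self.catches)


def _predation_on(i: int, B: np.ndarray, QB: np.ndarray, dc: np.ndarray) -> float:
    """Total consumption of prey i: sum_j B_j QB_j DC_ji."""
    qb = np.where(np.isnan(QB), 0.0, QB)
    b = np.where(np.isnan(B), 0.0, B)
    return float(np.sum(b * qb * dc[i, :]))


def _match_qb_unknowns(model: FoodWebModel, dc: np.ndarray) -> dict[int, int]:
    """Assign each missing-QB group to the balance equation of one of its prey.

    A group's own equation never contains its own Q/B (unless it eats
    itself), so a spare equation — a prey with no unknown of its own — must
    pin it.  Maximum bipartite matching guarantees a consistent assignment
    or proves none exists.
    """
    names = model.names
    missing = [i for i, g in enumerate(model.groups) if g.missing_param == "QB"]
    if not missing:
        return {}
    determined = {i for i, g in enumerate(model.groups)
                  if g.group_class != DETRITUS and g.missing_param is None}
    G = nx.Graph()
    left = [f"qb:{j}" for j in missing]
    G.add_nodes_from(left, bipartite=0)
    for j in missing:
        for i in determined:
            if dc[i, j] > 0:
                G.add_edge(f"qb:{j}", f"eq:{i}")
    matching = nx.algorithms.bipartite.maximum_matching(G, top_nodes=left) if G.edges else {}
    out = {}
    for j in missing:
        key = f"qb:{j}"
        if key not in matching:
            raise MassBalanceError(
                f"group {names[j]!r}: missing Q/B cannot be determined — no prey "
                "with a spare (fully specified) balance equation",
                group=names[j], parameter="QB",
            )
        out[j] = int(matching[key].split(":")[1])
    return out


def solve_mass_balance(model: FoodWebModel, max_iter: int = 1000,
                       tol: float = 1e-12) -> BalancedModel:
    """Complete the missing parameters so every group's balance holds.

    Group-by-group Gauss-Seidel: each group's own equation is rearranged for
    its unknown; missing Q/B values are pinned by a matched prey equation.
    Groups with no unknown get their EE recomputed from the balance (EE is
    fundamentally an output of the bookkeeping).

    Raises :class:`MassBalanceError` for structurally unsolvable systems or
    negative solved values.
    """
    groups = model.groups
    names = model.names
    n = len(groups)
    dc = model.diet.frac.to_numpy()  # dc[prey, predator]

    missing = [g.missing_param for g in groups]  # validates multiplicity
    qb_assign = _match_qb_unknowns(model, dc)

    B = np.array([g.B if g.B is not None else np.nan for g in groups])
    PB = np.array([g.PB if g.PB is not None else np.nan for g in groups])
    QB = np.array([g.QB if g.QB is not None else np.nan for g in groups])
    EE = np.array([g.EE if g.EE is not None else np.nan for g in groups])
    BA = np.array([g.BA for g in groups])
    Emig = np.array([g.Emig for g in groups])
    Y = np.array([model.catches.get(nm) for nm in names])

    # starting guesses
    for i, g in enumerate(groups):
        if missing[i] == "B":
            B[i] = 1.0
        elif missing[i] == "PB":
            PB[i] = 1.0
        elif missing[i] == "QB":
            QB[i] = 1.0
        elif missing[i] == "EE" or (g.group_class != DETRITUS and np.isnan(EE[i])):
            EE[i] = 0.5

    nondet = [i for i, g in enumerate(groups) if g.group_class != DETRITUS]
    # EE is recomputed for groups whose own unknown is EE and for fully
    # specified groups — except those whose equation was matched to pin a
    # predator's Q/B (there the given EE is load-bearing).
    matched_eqs = set(qb_assign.values())
    solve_ee = [i for i in nondet
                if missing[i] == "EE" or (missing[i] is None and i not in matched_eqs)]

    for _ in range(max_iter):
        delta = 0.0

        def upd(arr, i, new, param):
            nonlocal delta
            if not math.isfinite(new):
                raise MassBalanceError(
                    f"group {names[i]!r}: solving {param} produced a non-finite value",
                    group=names[i], parameter=param)
            old = arr[i]
            scale = max(abs(new), abs(old), 1e-30)
            delta = max(delta, abs(new - old) / scale)
            arr[i] = new

        for i in nondet:
            removals = Y[i] + BA[i] + Emig[i]
            if missing[i] == "B":
                pred_other = _predation_on(i, B, QB, dc) - (
                    0.0 if np.isnan(QB[i]) else B[i] * QB[i] * dc[i, i])
                denom = PB[i] * EE[i] - (0.0 if np.isnan(QB[i]) else QB[i] * dc[i, i])
                if denom <= 0:
                    raise MassBalanceError(
                        f"group {names[i]!r}: production (PB*EE) cannot cover its own "
                        "cannibalism — B unsolvable", group=names[i], parameter="B")
                upd(B, i, (removals + pred_other) / denom, "B")
            elif missing[i] == "PB":
                upd(PB, i, (removals + _predation_on(i, B, QB, dc)) / (B[i] * EE[i]), "PB")
            elif missing[i] == "QB":
                k = qb_assign[i]
                pred_other = _predation_on(k, B, QB, dc) - B[i] * QB[i] * dc[k, i]
                num = B[k] * PB[k] * EE[k] - Y[k] - BA[k] - Emig[k] - pred_other
                upd(QB, i, num / (B[i] * dc[k, i]), "QB")
        for i in solve_ee:
            upd(EE, i, (Y[i] + BA[i] + Emig[i] + _predation_on(i, B, QB, dc))
                / (B[i] * PB[i]), "EE")

        if delta < tol:
            break
    else:
        raise MassBalanceError(
            f"mass-balance iteration did not converge below {tol:g} "
            f"in {max_iter} iterations")

    # feasibility of solved values
    for i in nondet:
        for param, arr in (("B", B), ("PB", PB), ("QB", QB), ("EE", EE)):
            val = arr[i]
            if param == "QB" and groups[i].group_class != CONSUMER:
                continue
            if np.isnan(val):
                continue
            if val < 0:
                raise MassBalanceError(
                    f"group {names[i]!r}: solved {param} = {val:.6g} is negative",
                    group=names[i], parameter=param)
        if EE[i] < 0:
            raise MassBalanceError(
                f"group {names[i]!r}: solved EE = {EE[i]:.6g} is negative",
                group=names[i], parameter="EE")

    # residual check of the master equation
    for i in nondet:
        prod = B[i] * PB[i]
        resid = prod - Y[i] - _predation_on(i, B, QB, dc) - prod * (1 - EE[i]) - BA[i] - Emig[i]
        if abs(resid) > 1e-8 * max(prod, 1e-30):
            raise MassBalanceError(
                f"group {names[i]!r}: balance residual {resid:.3g} exceeds tolerance",
                group=names[i])

    # derived flows
    M2 = np.zeros(n)
    MO = np.full(n, np.nan)
    gge = np.full(n, np.nan)
    R = np.full(n, np.nan)
    GS = np.array([g.GS for g in groups])
    for i in nondet:
        M2[i] = _predation_on(i, B, QB, dc) / B[i] if B[i] > 0 else 0.0
        MO[i] = PB[i] * (1 - EE[i])
        if groups[i].group_class == CONSUMER:
            gge[i] = PB[i] / QB[i]
            if not (0.0 < gge[i] < 1.0):
                raise MassBalanceError(
                    f"group {names[i]!r}: net growth efficiency P/Q = {gge[i]:.4g} "
                    "outside (0, 1)", group=names[i])
            R[i] = B[i] * (QB[i] * (1 - GS[i]) - PB[i])
            if R[i] < 0:
                raise MassBalanceError(
                    f"group {names[i]!r}: negative respiration — consumption cannot "
                    "cover production plus unassimilated food", group=names[i])

    det_idx = [i for i, g in enumerate(groups) if g.group_class == DETRITUS]
    det_export = np.full(n, np.nan)
    if det_idx:
        qcons = np.nansum(np.where(np.isnan(QB), 0.0, QB) * np.where(np.isnan(B), 0.0, B))
        inflow_total = float(np.nansum([MO[i] * B[i] for i in nondet])
                             + np.nansum([GS[i] * B[i] * QB[i] for i in nondet
                                          if groups[i].group_class == CONSUMER]))
        bdet_total = sum(B[d] for d in det_idx)
        for d in det_idx:
            M2[d] = _predation_on(d, B, QB, dc) / B[d] if B[d] > 0 else 0.0
            share = B[d] / bdet_total if bdet_total > 0 else 1.0 / len(det_idx)
            detritivory = M2[d] * B[d]
            det_export[d] = ((inflow_total * share - detritivory) / B[d]
                             if B[d] > 0 else 0.0)

    # EE above 1 must survive into the completed groups so the consistency
    # check can report it, so it is assigned after construction (plain
    # attribute writes skip the range validation in __post_init__).
    completed = []
    for i, g in enumerate(groups):
        c = replace(
            g,
            B=float(B[i]),
            PB=None if np.isnan(PB[i]) else float(PB[i]),
            QB=None if np.isnan(QB[i]) else float(QB[i]),
            EE=None,
        )
        if g.group_class != DETRITUS:
            c.EE = float(EE[i])
        completed.append(c)

    F_base = np.where(B > 0, Y / np.where(B > 0, B, 1.0), 0.0)

    return BalancedModel(
        names=names, group_class=[g.group_class for g in groups],
        groups=completed, diet=model.diet, catches=model.catches,
        B=B, PB=PB, QB=QB, EE=EE, GS=GS, BA=BA, Emig=Emig, Y=Y,
        F_base=F_base, M2=M2, MO=MO, g=gge, R=R, det_export_rate=det_export,
        solved_param=list(missing),
    )


@dataclass
class GroupCheck:
    name: str
    EE: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class ConsistencyReport:
    """Per-group pass/fail; overall pass is the conjunction."""

    per_group: dict[str, GroupCheck]
    diet_ok: bool
    diet_problems: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.diet_ok and all(c.passed for c in self.per_group.values())

    @property
    def failing_groups(self) -> list[str]:
        return [n for n, c in self.per_group.items() if not c.passed]


def consistency_check(model: BalancedModel, ee_tolerance: float = 0.01) -> ConsistencyReport:
    """Report which groups exceed EE = 1 + tolerance and whether the diet
    matrix invariants hold.  Pure report: never raises."""
    per_group: dict[str, GroupCheck] = {}
    for i, name in enumerate(model.names):
        if model.group_class[i] == DETRITUS:
            continue
        ee = float(model.EE[i])
        reasons = []
        if not np.isfinite(ee):
            reasons.append("EE undefined")
        elif ee > 1.0 + ee_tolerance:
            reasons.append(f"EE = {ee:.4g} exceeds 1 + {ee_tolerance:g}")
        per_group[name] = GroupCheck(name=name, EE=ee, passed=not reasons, reasons=reasons)

    diet_problems = []
    frac = model.diet.frac
    imp = model.diet.import_fraction
    vals = frac.to_numpy()
    if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
        diet_problems.append("diet entries outside [0, 1]")
    for j, name in enumerate(model.names):
        total = float(frac[name].sum() + imp[name])
        if model.group_class[j] == CONSUMER and abs(total - 1.0) > 1e-9:
            diet_problems.append(f"diet of {name!r} sums to {total:.6g}")
        if model.group_class[j] != CONSUMER and total > 1e-9:
            diet_problems.append(f"non-consumer {name!r} has nonzero diet")
    return ConsistencyReport(per_group=per_group, diet_ok=not diet_problems,
                             diet_problems=diet_problems)


def energy_partition(group: FunctionalGroup, Q: float) -> dict[str, float]:
    """Split a consumption flux into production, respiration, unassimilated.

    Exact by construction: production = (P/Q) Q, unassimilated = GS Q,
    respiration = the remainder.  Infeasible parameter sets (P/Q + GS > 1)
    raise :class:`EnergyPartitionError`.
    """
    if group.group_class != CONSUMER:
        raise EnergyPartitionError(f"group {group.name!r} is not a consumer")
    if group.PB is None or group.QB is None:
        raise EnergyPartitionError(f"group {group.name!r}: PB and QB required")
    if Q < 0:
        raise EnergyPartitionError("consumption must be non-negative")
    g = group.PB / group.QB
    if Q > 0 and g + group.GS > 1.0:
        raise EnergyPartitionError(
            f"group {group.name!r}: P/Q + GS = {g + group.GS:.4g} > 1, "
            "respiration would be negative")
    production = g * Q
    unassimilated = group.GS * Q
    respiration = Q - production - unassimilated
    return {"production": production, "respiration": respiration,
            "unassimilated": unassimilated}
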