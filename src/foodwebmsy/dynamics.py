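"""Biomass dynamics with foraging-arena predation.

Each group's rate of change is

    dB_i/dt = g_i * sum_j Q_ji  -  sum_j Q_ij  +  I_i  -  (MO_i + F_i + e_i) B_i

with consumption fluxes mediated by vulnerability: the prey pool is split
into vulnerable and invulnerable fractions, and the exchange rate between
them bounds how fast predation can respond to predator abundance.  The
standard arena closure

    Q = a v B_prey B_pred / (2 v + a B_pred)

is calibrated per link so that (i) flux at base biomasses equals the static
base flux and (ii) the link's predation mortality saturates at v_user times
its base value as predator biomass grows.  Algebraically this collapses to

    Q = v B_prey B_pred / (D + B_pred),   D = B_pred0 (v_user - 1),
    v = v_user Q_base / B_prey0

which is the form evaluated here.  v_user = 1 gives pure donor control
(flux independent of predator biomass); large v_user approaches
Lotka-Volterra mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BalancedModel, CONSUMER, DETRITUS, PRODUCER
from .errors import CalibrationError, InputError, SimulationError

DEFAULT_V = 2.0
DEFAULT_DT = 1.0 / 12.0


@dataclass
class TrophicLink:
    """One predator-prey interaction with its calibrated arena constants."""

    predator: str
    prey: str
    pred_idx: int
    prey_idx: int
    dc: float
    v_user: float
    Q_base: float
    arena_v: float | None = None  # exchange rate into the vulnerable pool (1/yr)
    arena_a: float | None = None  # effective search rate (inf for v_user = 1)
    D: float | None = None        # = 2 arena_v / arena_a = B_pred0 (v_user - 1)

    @property
    def calibrated(self) -> bool:
        return self.arena_v is not None


def init_arena_params(balanced: BalancedModel,
                      v_user: float | dict[tuple[str, str], float] = DEFAULT_V
                      ) -> list[TrophicLink]:
    """Create calibrated links for every nonzero diet entry.

    ``v_user`` is a single setting applied to all links or a
    ``{(predator, prey): v}`` mapping (missing pairs get the default).
    """
    if isinstance(v_user, dict):
        vmap = dict(v_user)
        getv = lambda p, q: float(vmap.get((p, q), DEFAULT_V))
    else:
        v0 = float(v_user)
        getv = lambda p, q: v0

    dc = balanced.diet.frac
    links: list[TrophicLink] = []
    for j, pred in enumerate(balanced.names):
        if balanced.group_class[j] != CONSUMER:
            continue
        for i, prey in enumerate(balanced.names):
            f = float(dc.loc[prey, pred])
            if f <= 0:
                continue
            v = getv(pred, prey)
            if v < 1.0:
                raise InputError(f"link {pred!r} -> {prey!r}: vulnerability "
                                 f"{v} below the donor-control floor of 1")
            q_base = balanced.B[j] * balanced.QB[j] * f
            b_prey0 = balanced.B[i]
            b_pred0 = balanced.B[j]
            if b_prey0 <= 0 or b_pred0 <= 0:
                continue  # base flux undefined for an empty pool
            arena_v = v * q_base / b_prey0
            D = b_pred0 * (v - 1.0)
            arena_a = np.inf if v == 1.0 else 2.0 * arena_v / D
            links.append(TrophicLink(
                predator=pred, prey=prey, pred_idx=j, prey_idx=i, dc=f,
                v_user=v, Q_base=q_base, arena_v=arena_v, arena_a=arena_a, D=D))
    return links


def consumption_flux(link: TrophicLink, B_prey: float, B_pred: float,
                     vuln_multiplier: float = 1.0) -> float:
    """Arena consumption flux (biomass/yr) at the given biomasses.

    A vulnerability multiplier scales the exchange rate (the search-rate
    calibration stays at base), clipped so the effective setting never
    drops below the donor-control floor of 1.
    """
    if not link.calibrated:
        raise CalibrationError(
            f"link {link.predator!r} -> {link.prey!r} has no arena parameters")
    if B_prey < 0 or B_pred < 0:
        raise InputError("biomasses must be non-negative")
    if B_prey == 0 or B_pred == 0:
        return 0.0
    s = max(vuln_multiplier * link.v_user, 1.0) / link.v_user
    return s * link.arena_v * B_prey * B_pred / (s * link.D + B_pred)


@dataclass
class SimState:
    """Instantaneous simulation state."""

    time: float
    biomass: np.ndarray
    pb_multiplier: np.ndarray | None = None
    vuln_multiplier: np.ndarray | None = None
    F: np.ndarray | None = None


@dataclass
class Trajectory:
    """Dense output of a simulation run."""

    names: list[str]
    times: np.ndarray          # (T,)
    biomass: np.ndarray        # (T, n)
    catch: np.ndarray          # (T, n), instantaneous F * B

    def to_frame(self):
        import pandas as pd
        T, n = self.biomass.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, n),
            "group": np.tile(self.names, T),
            "biomass": self.biomass.ravel(),
            "catch": self.catch.ravel(),
        })

    def annual(self) -> "Trajectory":
        """Samples at (approximately) integer years."""
        keep = np.isclose(self.times, np.round(self.times), atol=1e-9)
        return Trajectory(self.names, self.times[keep],
                          self.biomass[keep], self.catch[keep])

    def series(self, group: str, what: str = "biomass") -> np.ndarray:
        j = self.names.index(group)
        return getattr(self, what)[:, j]


class Simulator:
    """Precompiled right-hand side plus a fixed-step RK4 integrator.

    Annual forcing values (P/B multipliers, vulnerability multipliers,
    fishing mortality, biomass overrides) are held constant within each
    simulated year.  Frozen groups (static-ecosystem mode) and
    biomass-forced groups have zero derivative.
    """

    def __init__(self, balanced: BalancedModel, links: list[TrophicLink],
                 forcing=None, dt: float = DEFAULT_DT,
                 producer_model: str = "saturating",
                 floor_frac: float = 1e-9,
                 frozen: set[str] | None = None):
        steps = round(1.0 / dt)
        if not np.isclose(steps * dt, 1.0):
            raise InputError("dt must divide one year")
        if producer_model not in ("saturating", "logistic"):
            raise InputError(f"unknown producer model {producer_model!r}")
        self.balanced = balanced
        self.links = links
        self.forcing = forcing
        self.dt = dt
        self.producer_model = producer_model
        n = len(balanced.names)
        self.n = n
        self.names = balanced.names

        for lk in links:
            if not lk.calibrated:
                raise CalibrationError(
                    f"link {lk.predator!r} -> {lk.prey!r} is not calibrated")

        self.B0 = balanced.B.copy()
        self.floor = floor_frac * self.B0
        self.is_consumer = balanced.is_consumer
        self.is_producer = balanced.is_producer
        self.is_detritus = balanced.is_detritus
        self.GS = balanced.GS
        self.g = np.where(np.isnan(balanced.g), 0.0, balanced.g)
        self.MO = np.where(np.isnan(balanced.MO), 0.0, balanced.MO)
        self.F_base = balanced.F_base.copy()
        self.PB0 = np.where(np.isnan(balanced.PB), 0.0, balanced.PB)
        qb = np.where(np.isnan(balanced.QB), 0.0, balanced.QB)
        self.imp_rate = qb * balanced.diet.import_fraction.to_numpy()
        # net migration split: positive Emig = per-biomass emigration rate,
        # negative = constant immigration flux
        emig = balanced.Emig
        with np.errstate(divide="ignore", invalid="ignore"):
            self.e_rate = np.where((emig > 0) & (self.B0 > 0), emig / np.where(self.B0 > 0, self.B0, 1.0), 0.0)
        self.I = np.where(emig < 0, -emig, 0.0)

        self.prey_idx = np.array([lk.prey_idx for lk in links], dtype=int)
        self.pred_idx = np.array([lk.pred_idx for lk in links], dtype=int)
        self.link_v = np.array([lk.arena_v for lk in links])
        self.link_D = np.array([lk.D for lk in links])
        self.link_vuser = np.array([lk.v_user for lk in links])

        self.det_idx = np.where(self.is_detritus)[0]
        self.det_export = np.where(np.isnan(balanced.det_export_rate), 0.0,
                                   balanced.det_export_rate)
        btot = self.B0[self.det_idx].sum()
        self.det_share = (self.B0[self.det_idx] / btot if btot > 0
                          else np.full(len(self.det_idx), 1.0 / max(len(self.det_idx), 1)))

        frozen = frozen or set()
        unknown = frozen - set(self.names)
        if unknown:
            raise InputError(f"cannot freeze unknown group(s): {sorted(unknown)}")
        self.frozen_mask = np.array([nm in frozen for nm in self.names])

        # producer production P(B), calibrated so P(B0) = PB0 B0 and the
        # maximum specific rate is twice the base P/B
        self.prod_h = np.where(self.B0 > 0, 1.0 / np.where(self.B0 > 0, self.B0, 1.0), 0.0)

        # Detritus pools turning over much faster than the step grid are
        # treated as quasi-steady (they relax within a fraction of a step;
        # explicit integration of such a pool is unstable and a QSS snap is
        # the better approximation).  Everything else gets enough substeps
        # to keep the base-state spectral radius inside the RK4 stability
        # region.
        det_turnover = np.zeros(self.n)
        for d in self.det_idx:
            det_turnover[d] = balanced.M2[d] + max(self.det_export[d], 0.0)
        # frozen lanes keep the QSS classification (so static- and
        # dynamic-mode runs step identically) but are never snapped
        self.qss_mask = self.is_detritus & (det_turnover * dt > 2.0)
        self.n_sub = self._auto_substeps()

    def _auto_substeps(self) -> int:
        """Substeps per dt from the base-state Jacobian spectral radius.

        Frozen lanes are deliberately *not* excluded, so static- and
        dynamic-ecosystem runs of the same web use identical stepping.
        """
        B0 = self.B0
        f0 = self.derivatives(B0, self.F_base, _respect_frozen=False)
        J = np.zeros((self.n, self.n))
        for k in range(self.n):
            h = max(1e-6 * abs(B0[k]), 1e-12)
            Bp = B0.copy()
            Bp[k] += h
            J[:, k] = (self.derivatives(Bp, self.F_base,
                                        _respect_frozen=False) - f0) / h
        lam = float(np.max(np.abs(np.linalg.eigvals(J)))) if self.n else 0.0
        return max(1, int(np.ceil(lam * self.dt / 2.2)))

    # ---- forcing matrices -------------------------------------------------
    def _compile_forcing(self, n_years: int):
        n, L = self.n, len(self.links)
        pb = np.ones((n_years, n))
        vm = np.ones((n_years, L))
        ov = np.full((n_years, n), np.nan)
        if self.forcing is not None:
            pb_map, vm_map, ov_map = self.forcing.compile(self.names, self.links, n_years)
            if pb_map is not None:
                pb = pb_map
            if vm_map is not None:
                vm = vm_map
            if ov_map is not None:
                ov = ov_map
        return pb, vm, ov

    # ---- right-hand side --------------------------------------------------
    def _fluxes(self, B: np.ndarray, vuln_mult: np.ndarray | None):
        """Arena fluxes and their per-group sums at the given state."""
        n = self.n
        if len(self.links):
            if vuln_mult is None:
                sv = self.link_v
                sD = self.link_D
            else:
                s = np.maximum(vuln_mult * self.link_vuser, 1.0) / self.link_vuser
                sv = s * self.link_v
                sD = s * self.link_D
            Bp = B[self.prey_idx]
            Bq = B[self.pred_idx]
            den = sD + Bq
            num = sv * Bp * Bq
            flux = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            Qin = np.bincount(self.pred_idx, weights=flux, minlength=n)
            Qout = np.bincount(self.prey_idx, weights=flux, minlength=n)
        else:
            Qin = np.zeros(n)
            Qout = np.zeros(n)
        Qin = Qin + self.imp_rate * B
        return Qin, Qout

    def derivatives(self, B: np.ndarray, F: np.ndarray,
                    pb_mult: np.ndarray | None = None,
                    vuln_mult: np.ndarray | None = None,
                    forced_mask: np.ndarray | None = None,
                    _respect_frozen: bool = True) -> np.ndarray:
        """dB/dt at the given state; forced/frozen/quasi-steady groups
        return 0 (quasi-steady detritus is snapped, not integrated)."""
        if pb_mult is None:
            pb_mult = np.ones(self.n)
        Qin, Qout = self._fluxes(B, vuln_mult)

        MO_eff = pb_mult * self.MO
        prod = pb_mult * self.g * Qin  # consumers
        if self.is_producer.any():
            if self.producer_model == "saturating":
                pprod = 2.0 * self.PB0 * B / (1.0 + self.prod_h * B)
            else:  # logistic
                pprod = np.maximum(self.PB0 * B * (2.0 - self.prod_h * B), 0.0)
            prod = np.where(self.is_producer, pb_mult * pprod, prod)

        dB = prod - Qout + self.I - (MO_eff + F + self.e_rate) * B

        if len(self.det_idx):
            nondet = ~self.is_detritus
            inflow = float(np.sum((MO_eff * B)[nondet])
                           + np.sum((self.GS * Qin)[self.is_consumer]))
            dB[self.det_idx] = (inflow * self.det_share
                                - Qout[self.det_idx]
                                - self.det_export[self.det_idx] * B[self.det_idx])
            dB[self.qss_mask] = 0.0

        if _respect_frozen:
            dB[self.frozen_mask] = 0.0
        if forced_mask is not None:
            dB[forced_mask] = 0.0
        return dB

    def _qss_snap(self, B: np.ndarray, pb_mult: np.ndarray,
                  vuln_mult: np.ndarray) -> np.ndarray:
        """Relax fast-turnover detritus pools to their balance point."""
        if not self.qss_mask.any():
            return B
        for _ in range(2):
            Qin, Qout = self._fluxes(B, vuln_mult)
            MO_eff = pb_mult * self.MO
            nondet = ~self.is_detritus
            inflow = float(np.sum((MO_eff * B)[nondet])
                           + np.sum((self.GS * Qin)[self.is_consumer]))
            for pos, d in enumerate(self.det_idx):
                if not self.qss_mask[d] or self.frozen_mask[d] or B[d] <= 0:
                    continue
                k_rate = Qout[d] / B[d] + self.det_export[d]
                if k_rate > 1e-12:
                    B[d] = inflow * self.det_share[pos] / k_rate
        return B

    # ---- integration ------------------------------------------------------
    def run(self, years: float, f_schedule: np.ndarray | None = None) -> Trajectory:
        """Integrate with fixed-step RK4.

        ``f_schedule`` is a (ceil(years), n) array of annual fishing
        mortalities; default holds every group at its base F.
        """
        if years <= 0:
            raise InputError("years must be positive")
        n_steps = round(years / self.dt)
        n_years = int(np.ceil(years - 1e-9))
        if f_schedule is None:
            f_schedule = np.tile(self.F_base, (n_years, 1))
        elif f_schedule.shape != (n_years, self.n):
            raise InputError(f"f_schedule must have shape ({n_years}, {self.n})")

        pb_m, vm_m, ov_m = self._compile_forcing(n_years)
        ov_mask = np.isfinite(ov_m)
        ov_vals = np.where(ov_mask, ov_m, 0.0)

        dt = self.dt
        times = np.arange(n_steps + 1) * dt
        bio = np.empty((n_steps + 1, self.n))

        def year_of(t):
            return min(int(np.floor(t + 1e-9)), n_years - 1)

        year_mid = np.array([year_of(k * dt + dt / 2.0) for k in range(n_steps)],
                            dtype=np.int64)
        year_next = np.array([year_of((k + 1) * dt) for k in range(n_steps)],
                             dtype=np.int64)

        from ._kernels import rk4_run
        status = rk4_run(
            self.B0.copy(), n_steps, self.n_sub, dt, year_mid, year_next,
            np.ascontiguousarray(f_schedule, dtype=float), pb_m, vm_m,
            ov_vals, ov_mask,
            self.prey_idx, self.pred_idx, self.link_v, self.link_D,
            self.link_vuser, self.imp_rate, self.g, self.MO, self.PB0,
            self.prod_h, self.GS, self.I, self.e_rate,
            self.is_consumer, self.is_producer, self.is_detritus,
            self.frozen_mask, self.qss_mask,
            self.det_idx.astype(np.int64), self.det_share, self.det_export,
            self.producer_model == "logistic", self.B0, self.floor, bio)
        if status != 0:
            t_bad = status * dt
            bad = [self.names[i] for i in np.where(~np.isfinite(bio[status]))[0]]
            raise SimulationError(
                f"non-finite biomass (groups {bad or 'unknown'}) at "
                f"t = {t_bad:.4f} yr", time=t_bad)

        sample_years = np.minimum(np.floor(times + 1e-9).astype(int), n_years - 1)
        cat = f_schedule[sample_years] * bio
        return Trajectory(self.names, times, bio, cat)


def biomass_derivatives(state: SimState, balanced: BalancedModel,
                        links: list[TrophicLink], forcing=None,
                        frozen: set[str] | None = None) -> np.ndarray:
    """One-shot evaluation of the rate vector at an arbitrary state."""
    sim = Simulator(balanced, links, forcing=None, frozen=frozen)
    F = state.F if state.F is not None else balanced.F_base
    fmask = None
    if forcing is not None:
        n_years = max(int(np.floor(state.time)) + 1, 1)
        pb_m, vm_m, ov_m = Simulator(balanced, links, forcing=forcing)._compile_forcing(n_years)
        yr = min(int(np.floor(state.time + 1e-9)), n_years - 1)
        return sim.derivatives(state.biomass, F, pb_m[yr], vm_m[yr],
                               np.isfinite(ov_m[yr]))
    return sim.derivatives(state.biomass, F, state.pb_multiplier,
                           state.vuln_multiplier, fmask)


def make_f_schedule(balanced: BalancedModel, years: int,
                    overrides: dict[str, float | np.ndarray] | None = None
                    ) -> np.ndarray:
    """Annual F matrix: base F everywhere, with per-group overrides."""
    sched = np.tile(balanced.F_base, (years, 1))
    for name, val in (overrides or {}).items():
        j = balanced.index(name)
        sched[:, j] = val
    return sched


def simulate(balanced: BalancedModel, links: list[TrophicLink], forcing=None,
             f_schedule: np.ndarray | None = None, years: float = 100.0,
             dt: float = DEFAULT_DT, producer_model: str = "saturating",
             frozen: set[str] | None = None) -> Trajectory:
    """Convenience wrapper: build a Simulator and run it."""
    sim = Simulator(balanced, links, forcing=forcing, dt=dt,
                    producer_model=producer_model, frozen=frozen)
    return sim.run(years, f_schedule=f_schedule)
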