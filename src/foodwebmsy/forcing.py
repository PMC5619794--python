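"""Environmental forcing: temperature series mapped onto model parameters.

A temperature-sensitive group gets a tolerance curve: its realized P/B is
the base P/B times a multiplier that is 1 at (or below, for a flat left
arm) the optimum and declines to 0 at the critical temperature.  A
warm-advantaged predator instead gets its prey-vulnerability scaled in
direct proportion to temperature relative to a reference.  Forcing values
are annual and held constant within each simulated year; series shorter
than a run are extended by holding their last value (a sustained regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class ToleranceCurve:
    """Piecewise thermal response in [0, 1].

    Flat at 1 up to ``T_opt``; declines to 0 at ``T_crit`` (linear by
    default, optionally a truncated-Gaussian arm for sensitivity work);
    0 beyond critical.  Arms are independent: no symmetry is imposed.
    """

    T_opt: float
    T_crit: float
    left_arm: str = "flat"
    right_arm: str = "linear"

    def __post_init__(self):
        if not self.T_crit > self.T_opt:
            raise InputError("T_crit must exceed T_opt")
        if self.left_arm != "flat":
            raise InputError(f"unsupported left arm {self.left_arm!r}")
        if self.right_arm not in ("linear", "gaussian"):
            raise InputError(f"unsupported right arm {self.right_arm!r}")


def tolerance_multiplier(T: float, curve: ToleranceCurve) -> float:
    """P/B multiplier at temperature T (degrees C)."""
    if T <= curve.T_opt:
        return 1.0
    if T >= curve.T_crit:
        return 0.0
    if curve.right_arm == "linear":
        return (curve.T_crit - T) / (curve.T_crit - curve.T_opt)
    # truncated Gaussian: sigma set so the curve is ~0.011 at T_crit,
    # then renormalized to hit 0 there exactly
    sigma = (curve.T_crit - curve.T_opt) / 3.0
    raw = math.exp(-0.5 * ((T - curve.T_opt) / sigma) ** 2)
    floor = math.exp(-4.5)
    return max((raw - floor) / (1.0 - floor), 0.0)


@dataclass
class ForcingSeries:
    """Year-indexed values (year 0 = first simulated year).

    ``kind`` is one of temperature / pb_multiplier / vuln_multiplier /
    biomass_override.  ``target`` is a group name, or for vulnerability a
    ``(predator, prey)`` pair where prey ``None`` means all prey of that
    predator.
    """

    kind: str
    values: np.ndarray
    target: object = None

    KINDS = ("temperature", "pb_multiplier", "vuln_multiplier", "biomass_override")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise InputError(f"unknown forcing kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind in ("pb_multiplier", "vuln_multiplier") and (self.values < 0).any():
            raise InputError("multipliers must be non-negative")


def build_temperature_forcing(monthly: pd.DataFrame, months=(7, 8),
                              years: list[int] | None = None) -> ForcingSeries:
    """Collapse a (year, month, temp_C) table to one value per year.

    The annual value is the mean over the selected months (the warm-season
    window that matters for thermal stress); remaining months are ignored.
    """
    required = {"year", "month", "temp_C"}
    if not required.issubset(monthly.columns):
        raise InputError(f"temperature table needs columns {sorted(required)}")
    if years is None:
        years = sorted(monthly["year"].unique())
    vals = []
    for y in years:
        sub = monthly[monthly["year"] == y]
        have = set(sub["month"])
        missing = [m for m in months if m not in have]
        if missing:
            raise InputError(f"year {y}: missing month(s) {missing} in temperature table")
        vals.append(float(sub[sub["month"].isin(months)]["temp_C"].mean()))
    return ForcingSeries(kind="temperature", values=np.array(vals))


def apply_pb_forcing(group: str, curve: ToleranceCurve,
                     temperature: ForcingSeries) -> ForcingSeries:
    """Map a temperature series through a tolerance curve for one group."""
    if temperature.kind != "temperature":
        raise InputError("expected a temperature series")
    mult = np.array([tolerance_multiplier(t, curve) for t in temperature.values])
    return ForcingSeries(kind="pb_multiplier", values=mult, target=group)


def apply_vulnerability_forcing(predator: str, temperature: ForcingSeries,
                                T_ref: float, prey: str | None = None
                                ) -> ForcingSeries:
    """Vulnerability multiplier in direct proportion to temperature.

    multiplier(year) = T(year) / T_ref; the effective vulnerability is
    clipped at the donor-control floor of 1 when applied.  At T = T_ref the
    dynamics are identical to the unforced run.
    """
    if temperature.kind != "temperature":
        raise InputError("expected a temperature series")
    if T_ref <= 0:
        raise InputError("T_ref must be positive")
    mult = temperature.values / T_ref
    return ForcingSeries(kind="vuln_multiplier", values=mult, target=(predator, prey))


def _extend(values: np.ndarray, n_years: int) -> np.ndarray:
    if len(values) >= n_years:
        return values[:n_years]
    return np.concatenate([values, np.full(n_years - len(values), values[-1])])


@dataclass
class ForcingSet:
    """All active forcings for a run; compiled to matrices by the simulator."""

    series: list[ForcingSeries] = field(default_factory=list)

    def add(self, s: ForcingSeries) -> "ForcingSet":
        if s.kind == "temperature":
            raise InputError("temperature series must be mapped to a multiplier "
                             "series before being added to a ForcingSet")
        self.series.append(s)
        return self

    @property
    def has_overrides(self) -> bool:
        return any(s.kind == "biomass_override" for s in self.series)

    def compile(self, names: list[str], links, n_years: int):
        """Return (pb_mult, vuln_mult, overrides) year-by-target matrices."""
        n = len(names)
        pb = None
        vm = None
        ov = None
        for s in self.series:
            if s.kind == "pb_multiplier":
                if s.target not in names:
                    raise InputError(f"pb forcing targets unknown group {s.target!r}")
                if pb is None:
                    pb = np.ones((n_years, n))
                pb[:, names.index(s.target)] *= _extend(s.values, n_years)
            elif s.kind == "vuln_multiplier":
                pred, prey = s.target
                idx = [k for k, lk in enumerate(links)
                       if lk.predator == pred and (prey is None or lk.prey == prey)]
                if not idx:
                    raise InputError(
                        f"vulnerability forcing targets no existing link "
                        f"({pred!r} -> {prey or 'any'!r})")
                if vm is None:
                    vm = np.ones((n_years, len(links)))
                ext = _extend(s.values, n_years)
                for k in idx:
                    vm[:, k] *= ext
            elif s.kind == "biomass_override":
                if s.target not in names:
                    raise InputError(f"biomass override targets unknown group {s.target!r}")
                if ov is None:
                    ov = np.full((n_years, n), np.nan)
                ov[:, names.index(s.target)] = _extend(s.values, n_years)
        return pb, vm, ov
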