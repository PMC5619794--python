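"""File formats, run configuration, and the full-scenario orchestrator.

All tables are plain CSV (UTF-8, '.' decimal, header row required; a blank
cell means "absent"), configuration is YAML, reports are JSON.  Group
names are the join key everywhere: case-sensitive, whitespace-trimmed.
Outputs are written atomically (temp file + rename) and a manifest records
input checksums, the seed and the settings, so a rerun with the same
config reproduces byte-identical numeric tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, fitting, forcing as forcing_mod, montecarlo, msy as msy_mod, synth
from .core import (CatchTable, DietMatrix, FoodWebModel, FunctionalGroup,
                   consistency_check, solve_mass_balance)
from .errors import InputError

log = logging.getLogger("foodwebmsy")

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# atomic writes and checksums
# ---------------------------------------------------------------------------

def _atomic_write(path: Path, text: str):
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: Path):
    _atomic_write(Path(path), df.to_csv(index=False, float_format=FLOAT_FMT))


def write_json(obj, path: Path):
    _atomic_write(Path(path), json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], file: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{file}: missing column(s) {missing}", file=file)


def _opt(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_model(directory: str | Path) -> FoodWebModel:
    """Load groups.csv, diet.csv and catch.csv into a typed model.

    Every invariant is validated at load; each problem is reported with
    the file (and row) it came from.
    """
    d = Path(directory)
    for fname in ("groups.csv", "diet.csv", "catch.csv"):
        if not (d / fname).exists():
            raise InputError(f"missing input file {fname} in {d}", file=fname)

    gdf = pd.read_csv(d / "groups.csv")
    _require_columns(gdf, ["name", "class"], "groups.csv")
    groups = []
    for k, row in gdf.iterrows():
        try:
            groups.append(FunctionalGroup(
                name=str(row["name"]).strip(),
                group_class=str(row["class"]).strip(),
                B=_opt(row, "B"), PB=_opt(row, "PB"), QB=_opt(row, "QB"),
                EE=_opt(row, "EE"),
                BA=_opt(row, "BA") or 0.0, Emig=_opt(row, "Emig") or 0.0,
                GS=_opt(row, "GS"),
            ))
        except InputError as e:
            raise InputError(f"groups.csv row {k + 2}: {e}", file="groups.csv",
                             row=k + 2) from e
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise InputError(f"groups.csv: duplicate group name(s) {dup}",
                         file="groups.csv")

    ddf = pd.read_csv(d / "diet.csv", index_col=0)
    ddf.index = [str(i).strip() for i in ddf.index]
    ddf.columns = [str(c).strip() for c in ddf.columns]
    imp = ddf.loc["import"] if "import" in ddf.index else pd.Series(0.0, index=ddf.columns)
    frac = ddf.drop(index="import", errors="ignore")
    unknown = [r for r in frac.index if r not in names]
    if unknown:
        raise InputError(f"diet.csv: unknown prey row(s) {unknown}", file="diet.csv")
    unknown = [c for c in frac.columns if c not in names]
    if unknown:
        raise InputError(f"diet.csv: unknown predator column(s) {unknown}",
                         file="diet.csv")
    for col in frac.columns:
        total = float(frac[col].fillna(0.0).sum() + (imp[col] if col in imp else 0.0))
        if total > 1.0 + 1e-9:
            raise InputError(
                f"diet.csv: diet of predator {col!r} sums to {total:.6g} > 1",
                file="diet.csv")
    diet = DietMatrix(frac.fillna(0.0), imp.astype(float))

    cdf = pd.read_csv(d / "catch.csv")
    _require_columns(cdf, ["name", "Y"], "catch.csv")
    catches = {}
    for k, row in cdf.iterrows():
        nm = str(row["name"]).strip()
        if nm not in names:
            raise InputError(f"catch.csv row {k + 2}: unknown group {nm!r}",
                             file="catch.csv", row=k + 2)
        catches[nm] = float(row["Y"])

    try:
        return FoodWebModel(groups=groups, diet=diet, catches=CatchTable(catches))
    except InputError as e:
        raise InputError(f"model in {d}: {e}") from e


def write_model(model: FoodWebModel, directory: str | Path):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in model.groups:
        rows.append({
            "name": g.name, "class": g.group_class,
            "B": g.B, "PB": g.PB, "QB": g.QB, "EE": g.EE,
            "BA": g.BA, "Emig": g.Emig, "GS": g.GS,
        })
    write_csv(pd.DataFrame(rows), d / "groups.csv")

    frac = model.diet.frac.copy()
    frac.loc["import"] = model.diet.import_fraction
    _atomic_write(d / "diet.csv", frac.to_csv(float_format=FLOAT_FMT))

    cat = pd.DataFrame(
        [{"name": nm, "Y": y} for nm, y in sorted(model.catches.Y.items())],
        columns=["name", "Y"])
    write_csv(cat, d / "catch.csv")


def read_vulnerabilities(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path)
    _require_columns(df, ["predator", "prey", "v_user"], str(path))
    return {(str(r["predator"]).strip(), str(r["prey"]).strip()): float(r["v_user"])
            for _, r in df.iterrows()}


def write_vulnerabilities(vmap: dict[tuple[str, str], float], path: str | Path):
    rows = [{"predator": p, "prey": q, "v_user": v}
            for (p, q), v in sorted(vmap.items())]
    write_csv(pd.DataFrame(rows, columns=["predator", "prey", "v_user"]), Path(path))


def read_observations(path: str | Path) -> fitting.ObservationSet:
    df = pd.read_csv(path)
    _require_columns(df, ["series_id", "group", "kind", "year", "value"], str(path))
    series = []
    for sid, sub in df.groupby("series_id", sort=True):
        series.append(fitting.ObservationSeries(
            series_id=str(sid), group=str(sub["group"].iloc[0]),
            kind=str(sub["kind"].iloc[0]),
            years=sub["year"].to_numpy(dtype=int),
            values=sub["value"].to_numpy(dtype=float),
            weight=float(sub["weight"].iloc[0]) if "weight" in sub else 1.0))
    return fitting.ObservationSet(series)


def write_observations(obs: fitting.ObservationSet, path: str | Path):
    rows = []
    for s in obs:
        for y, v in zip(s.years, s.values):
            rows.append({"series_id": s.series_id, "group": s.group,
                         "kind": s.kind, "year": int(y), "value": v,
                         "weight": s.weight})
    write_csv(pd.DataFrame(rows), Path(path))


def write_trajectory(traj: dynamics.Trajectory, path: str | Path):
    write_csv(traj.to_frame(), Path(path))


# ---------------------------------------------------------------------------
# forcing configuration
# ---------------------------------------------------------------------------

def build_forcing(cfg: dict, temperature: pd.DataFrame | None = None,
                  base_dir: str | Path = ".") -> forcing_mod.ForcingSet:
    """Assemble a ForcingSet from a config mapping.

    Keys: ``temperature_csv`` (unless a table is passed directly),
    ``pb_targets`` [{group, T_opt, T_crit, right_arm?}], ``vuln_targets``
    [{predator, T_ref, prey?}], ``biomass_overrides`` [{group, values}].
    """
    fs = forcing_mod.ForcingSet()
    temp_series = None
    if temperature is None and cfg.get("temperature_csv"):
        temperature = pd.read_csv(Path(base_dir) / cfg["temperature_csv"])
    if temperature is not None:
        temp_series = forcing_mod.build_temperature_forcing(temperature)
    for t in cfg.get("pb_targets", []):
        if temp_series is None:
            raise InputError("pb forcing requires a temperature series")
        curve = forcing_mod.ToleranceCurve(
            T_opt=float(t["T_opt"]), T_crit=float(t["T_crit"]),
            right_arm=t.get("right_arm", "linear"))
        fs.add(forcing_mod.apply_pb_forcing(t["group"], curve, temp_series))
    for t in cfg.get("vuln_targets", []):
        if temp_series is None:
            raise InputError("vulnerability forcing requires a temperature series")
        fs.add(forcing_mod.apply_vulnerability_forcing(
            t["predator"], temp_series, float(t["T_ref"]), t.get("prey")))
    for t in cfg.get("biomass_overrides", []):
        fs.add(forcing_mod.ForcingSeries(
            kind="biomass_override", values=np.asarray(t["values"], dtype=float),
            target=t["group"]))
    return fs


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    out_dir: str = "results/run"
    model_dir: str | None = None       # read an existing model ...
    synth: dict = field(default_factory=dict)   # ... or generate one
    seed: int = 0
    dt: float = 1.0 / 12.0
    years: int = 22
    v_user: float = 2.0
    vulnerabilities_csv: str | None = None
    forcing: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)     # enabled, top_k, maxiter, restarts
    msy: dict = field(default_factory=dict)     # targets, modes, forcing, n_steps, ...
    mc: dict = field(default_factory=dict)      # enabled, target, cv, n_success
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InputError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)


def run_scenario(config: RunConfig) -> dict:
    """Balance -> simulate -> fit -> MSY (with/without forcing) -> MC.

    Writes every stage's tables under ``config.out_dir`` plus a manifest
    with input checksums, the seed and the settings.  Any stage error
    aborts with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    manifest = {"seed": rng_seed, "stages": [], "inputs": {},
                "settings": {k: v for k, v in vars(config).items()}}
    bundle: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                outputs = fn()
            except Exception as e:
                raise type(e)(f"stage {name!r}: {e}") from e
            manifest["stages"].append({"name": name, "outputs": sorted(outputs or [])})
            log.info("stage %s done", name)
            return outputs
        return wrap

    # -- synth ---------------------------------------------------------------
    @stage("synth")
    def _synth():
        spec = synth.SynthesisSpec(**{**config.synth, "seed": rng_seed}) \
            if config.synth or config.model_dir is None else None
        outputs = []
        if spec is not None:
            model = synth.generate_foodweb(spec)
            mdir = out / "inputs"
            write_model(model, mdir)
            temp = synth.generate_temperature_series(spec, seed=rng_seed + 1)
            write_csv(temp, mdir / "temperature.csv")
            bundle["model_dir"] = mdir
            bundle["spec"] = spec
            outputs = ["inputs/groups.csv", "inputs/diet.csv", "inputs/catch.csv",
                       "inputs/temperature.csv"]
        else:
            bundle["model_dir"] = Path(config.model_dir)
        return outputs

    # -- balance ---------------------------------------------------------------
    @stage("balance")
    def _balance():
        mdir = bundle["model_dir"]
        for f in ("groups.csv", "diet.csv", "catch.csv"):
            p = mdir / f
            if p.exists():
                manifest["inputs"][str(p)] = sha256_file(p)
        model = read_model(mdir)
        balanced = solve_mass_balance(model)
        report = consistency_check(balanced)
        rows = [{"name": nm, "class": cl, "B": b, "PB": pb, "QB": qb, "EE": ee,
                 "M2": m2, "MO": mo, "g": gg}
                for nm, cl, b, pb, qb, ee, m2, mo, gg in zip(
                    balanced.names, balanced.group_class, balanced.B,
                    balanced.PB, balanced.QB, balanced.EE, balanced.M2,
                    balanced.MO, balanced.g)]
        write_csv(pd.DataFrame(rows), out / "balance.csv")
        write_json({"passed": report.passed,
                    "failing_groups": report.failing_groups,
                    "diet_problems": report.diet_problems},
                   out / "balance_report.json")
        bundle["balanced"] = balanced
        return ["balance.csv", "balance_report.json"]

    # -- links & forcing shared by later stages -------------------------------
    balanced = bundle["balanced"]
    if config.vulnerabilities_csv:
        vmap = read_vulnerabilities(Path(config.vulnerabilities_csv))
        links = dynamics.init_arena_params(balanced, vmap)
    else:
        links = dynamics.init_arena_params(balanced, config.v_user)
    bundle["links"] = links

    temp_table = None
    tpath = Path(bundle["model_dir"]) / "temperature.csv"
    if tpath.exists():
        temp_table = pd.read_csv(tpath)
    fset = build_forcing(config.forcing, temperature=temp_table) \
        if config.forcing else None
    bundle["forcing"] = fset

    # -- simulate --------------------------------------------------------------
    @stage("simulate")
    def _simulate():
        traj = dynamics.simulate(balanced, links, forcing=fset,
                                 years=config.years, dt=config.dt)
        write_trajectory(traj, out / "trajectory.csv")
        bundle["trajectory"] = traj
        return ["trajectory.csv"]

    # -- fit -------------------------------------------------------------------
    @stage("fit")
    def _fit():
        fit_cfg = dict(config.fit)
        if not fit_cfg.get("enabled", bool(fit_cfg)):
            return []
        outputs = ["fit.json"]
        obs_path = fit_cfg.get("observations_csv")
        if obs_path:
            obs = read_observations(obs_path)
            manifest["inputs"][obs_path] = sha256_file(Path(obs_path))
        else:
            obs = synth.generate_observations(
                balanced, links, forcing=fset, seed=rng_seed + 2,
                noise_cv=fit_cfg.get("noise_cv", 0.05), years=config.years,
                dt=config.dt)
            write_observations(obs, out / "observations.csv")
            outputs.append("observations.csv")
        result = fitting.fit_vulnerabilities(
            balanced, obs, links, top_k=fit_cfg.get("top_k", 5),
            forcing=fset, years=config.years, dt=config.dt,
            maxiter=fit_cfg.get("maxiter", 120),
            restarts=fit_cfg.get("restarts", 3))
        write_json(result.to_dict(), out / "fit.json")
        bundle["fit"] = result
        return outputs

    # -- msy -------------------------------------------------------------------
    @stage("msy")
    def _msy():
        msy_cfg = dict(config.msy)
        targets = msy_cfg.get("targets", [])
        outputs = []
        rows = []
        for target in targets:
            for mode in msy_cfg.get("modes", ["ss", "es"]):
                for use_forcing in msy_cfg.get("forcing", [False, True] if fset else [False]):
                    res = msy_mod.estimate_msy(
                        balanced, links, target, mode=mode,
                        forcing=fset if use_forcing else None,
                        F_max=msy_cfg.get("f_max"),
                        n_steps=msy_cfg.get("n_steps", 25),
                        years_per_step=msy_cfg.get("years_per_step", 20),
                        dt=config.dt)
                    tag = f"{target}_{mode}{'_T' if use_forcing else ''}"
                    steps = pd.DataFrame({
                        "F": res.F_grid, "equilibrium_yield": res.eq_yield,
                        "equilibrium_biomass": res.eq_biomass,
                        "equilibrated_flag": res.equilibrated})
                    write_csv(steps, out / f"msy_{tag}.csv")
                    outputs.append(f"msy_{tag}.csv")
                    rows.append({"target": target, "mode": mode,
                                 "forcing": use_forcing, "MSY": res.MSY,
                                 "Fmsy": res.Fmsy, "B_at_msy": res.B_at_msy,
                                 "flat_width": res.flat_width})
        if rows:
            write_csv(pd.DataFrame(rows), out / "msy_summary.csv")
            outputs.append("msy_summary.csv")
        bundle["msy_summary"] = rows
        return outputs

    # -- mc --------------------------------------------------------------------
    @stage("mc")
    def _mc():
        mc_cfg = dict(config.mc)
        if not mc_cfg.get("enabled", bool(mc_cfg)):
            return []
        cfg = montecarlo.MCConfig(
            cv=mc_cfg.get("cv", 0.1), n_success=mc_cfg.get("n_success", 80),
            seed=mc_cfg.get("seed", rng_seed))
        target = mc_cfg["target"]
        res = montecarlo.mc_msy(
            balanced, target, mode=mc_cfg.get("mode", "es"),
            forcing=fset if mc_cfg.get("forcing", False) else None,
            mc_config=cfg, v_user=config.v_user,
            n_steps=mc_cfg.get("n_steps", 25),
            years_per_step=mc_cfg.get("years_per_step", 20), dt=config.dt)
        yq, bq = res.yield_quartiles, res.biomass_quartiles
        qdf = pd.DataFrame({
            "F": res.point.F_grid,
            "yield_q25": yq["q25"], "yield_q50": yq["q50"], "yield_q75": yq["q75"],
            "biomass_q25": bq["q25"], "biomass_q50": bq["q50"],
            "biomass_q75": bq["q75"]})
        write_csv(qdf, out / f"mc_{target}_quartiles.csv")
        runs = pd.DataFrame(res.per_run_yield,
                            columns=[f"F_{f:.6g}" for f in res.point.F_grid])
        runs.insert(0, "run", np.arange(len(runs)))
        write_csv(runs, out / f"mc_{target}_runs.csv")
        bundle["mc"] = res
        return [f"mc_{target}_quartiles.csv", f"mc_{target}_runs.csv"]

    write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
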