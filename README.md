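# foodwebmsy

Trophic mass-balance food-web models, foraging-arena biomass dynamics,
temperature forcing, vulnerability calibration, and single-species vs
ecosystem MSY reference points with Monte Carlo uncertainty.

## The problem

Fisheries reference points such as MSY (maximum sustainable yield) and
F<sub>msy</sub> (the fishing mortality attaining it) are usually computed
one stock at a time, holding the rest of the ecosystem fixed.  But when a
target species is fished down, predation pressure on its prey relaxes, its
competitors and predators shift, and — in lakes warming decade by decade —
the productivity of cold-water stenotherms (cisco- and burbot-like groups)
falls while warm-adapted species (smallmouth-bass-like groups) feed more
effectively.  This package implements the full pipeline needed to quantify
those effects on reference points for a lake-like food web:

1. **Static mass balance.**  Each functional group's production is fully
   allocated:

   `B_i (P/B)_i = Y_i + Σ_j B_j (Q/B)_j DC_ji + B_i (P/B)_i (1 − EE_i) + BA_i + E_i`

   where B is biomass, P/B production rate, Q/B consumption rate, DC the
   diet composition, Y fishery catch, EE the ecotrophic efficiency, BA
   biomass accumulation and E net migration.  Per group, any one of
   {B, P/B, Q/B, EE} may be left blank and is solved for.  EE > 1 flags an
   unbalanced (over-demanded) group.

2. **Biomass dynamics.**  `dB_i/dt = g_i Σ_j Q_ji − Σ_j Q_ij + I_i −
   (MO_i + F_i + e_i) B_i`, with consumption Q governed by the
   foraging-arena closure: prey biomass is split into vulnerable and
   invulnerable pools, and the exchange rate — the vulnerability
   v ∈ [1, ∞) — interpolates between donor control (v = 1) and
   Lotka-Volterra mass action (v large).

3. **Forcing.**  A July–August temperature series maps through a tolerance
   curve (flat below the optimum, declining to zero at the critical
   temperature) to a P/B multiplier for stenotherms, or scales a
   warm-adapted predator's prey vulnerabilities in direct proportion to
   temperature.

4. **Fitting.**  Vulnerabilities are calibrated to abundance/catch time
   series by minimizing a log-scale sum of squares (closed-form
   catchability for relative indices), with or without the forcing active.

5. **Reference points.**  The target's F is stepped up a 25-step,
   20-years-per-step staircase (500 years); equilibrium yield per step is
   F times the mean biomass of the last 5 years.  Single-species mode
   (`ss`) freezes all non-target biomasses at base; ecosystem mode (`es`)
   lets the web respond.  Monte Carlo uncertainty perturbs B, P/B, Q/B, EE
   with CV = 0.1, rejects mass-balance violators, and summarizes 80
   successful runs as interquartile envelopes.

## Worked example

The bundled synthetic lake motif (piscivore / forage fish / cold-water
prey / warm-adapted mesopredator / invertebrate / producer / detritus) is
built, balanced and pushed through the whole pipeline by the numbered
drivers:

```bash
python analysis/01_build_web.py
python analysis/02_simulate_scenarios.py
python analysis/03_fit_vulnerabilities.py
python analysis/04_msy_reference_points.py
python analysis/05_monte_carlo.py
```

`04_msy_reference_points.py` prints (ss = single-species, es = ecosystem,
T = temperature forcing; yields in model biomass units per year):

```
framing           ss     es   ssT    esT
target
coldwater_prey 2.758  3.931 0.510  1.253
forage_fish    6.968 14.106 6.923 16.738
mesopredator   0.956  1.203 0.972  1.707
piscivore      1.621  2.280 1.621  1.903

readings:
  piscivore ecosystem MSY exceeds single-species by 41% (prey release compensation)
  warming cuts the cold-water prey's ecosystem MSY 3.93 -> 1.25 (-68%)
  warming lifts the warm-adapted mesopredator's ecosystem MSY 1.203 -> 1.707 (+41.8%)
```

The ecosystem framing raises the piscivore's MSY because fishing it down
releases its forage prey (compensation a frozen ecosystem cannot express);
the warm regime depresses the cold-water stenotherm's reference points
through its P/B and raises the warm-adapted mesopredator's through its
feeding.  `05_monte_carlo.py` then reports, for the piscivore:

```
successes/attempts: 80/134 (rejection rate 40.3%)
point estimate: MSY = 2.280 at Fmsy = 0.406
MSY quartiles: 2.096 / 2.338 / 2.495
```

A `foodwebmsy` command-line tool exposes the same stages
(`synth`, `balance`, `simulate`, `fit`, `msy`, `mc`, `run`); see
`foodwebmsy --help`.

## Layout

- `src/foodwebmsy/` — the library: `core` (mass balance), `dynamics`
  (arena simulation), `forcing`, `fitting`, `msy`, `montecarlo`, `synth`
  (seeded generators), `io` (CSV/YAML/JSON + scenario runner), `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, numerics and
  limitations.
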