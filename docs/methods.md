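# Methods

## Static mass balance

A food web is a set of functional groups (single-biomass pools) joined by
a diet-composition matrix `DC[prey, predator]` and a catch table.  The
balance allocates each group's production to catch, predation, "other"
mortality, biomass accumulation and net migration.  Per group at most one
of {B, P/B, Q/B, EE} may be missing:

- **B, P/B, EE** are solved from the group's own equation by direct
  rearrangement, iterated Gauss–Seidel over inter-group dependencies
  (tolerance 1e-12 on the relative update, 1000 iterations maximum —
  webs of ≤ 50 groups converge in a handful of sweeps).
- **Q/B** never appears in its owner's equation (absent cannibalism), so a
  missing Q/B is pinned by the equation of one of the group's prey that
  has no unknown of its own.  The assignment of Q/B unknowns to spare prey
  equations is a maximum bipartite matching; if no complete matching
  exists the system is structurally unsolvable and the offending group is
  named in the error.
- Fully specified groups get their EE recomputed from the balance: EE is
  fundamentally an output of the bookkeeping, and recomputing it keeps the
  residual invariant (< 1e-8 relative) true for every group.

Solved values must be non-negative, net growth efficiency g = P/Q must lie
in (0, 1), and respiration Q − P − GS·Q must be non-negative (GS is the
unassimilated fraction, default 0.2 for consumers — the conventional
value — and 0 otherwise).  BA and net migration default to 0.

**Detritus** is a passive pool: it has biomass but no P/B, Q/B or EE, and
never fails balance.  Its inflow is all non-detritus "other" mortality
plus unassimilated consumption (split across pools in proportion to their
base biomass when there are several); outflow is detritivory plus an
export term calibrated so the pool is exactly stationary at the base
state.

The consistency check is a pure report: a group fails iff its EE exceeds
1 + tolerance (default 0.01 — "some tolerance" beyond exact balance) or a
diet-column invariant is broken; the overall flag is the conjunction.

## Foraging-arena dynamics

Rates of change follow
`dB_i/dt = g_i ΣQ_ji − ΣQ_ij + I_i − (MO_i + F_i + e_i) B_i`.
Consumption per link uses the canonical arena closure
`Q = a v B_prey B_pred / (2v + a B_pred)` with the two constants solved
from two calibration conditions: (i) flux at base biomasses equals the
static base flux `B_pred (Q/B)_pred DC`; (ii) as predator biomass grows,
the link's predation mortality saturates at `v_user` times its base value.
Algebraically this collapses to

    Q = v B_prey B_pred / (D + B_pred),
    v = v_user Q_base / B_prey0,   D = B_pred0 (v_user − 1),

which is the form evaluated (identical function, exact at the
donor-control limit `v_user = 1`, where Q = v B_prey independently of the
predator).  Default `v_user` is 2 — the conventional mixed
top-down/bottom-up setting.  A vulnerability forcing multiplier scales the
exchange rate while the search-rate constant stays at its base
calibration; only then does a multiplier above 1 actually increase feeding
(re-deriving both constants from the scaled v would leave the base flux
invariant and make the forcing inert).  The effective setting is clipped
at the donor-control floor of 1.

**Producers** need self-limitation (there is no consumption term to
saturate): production is `P(B) = 2 (P/B)₀ B / (1 + B/B₀)` — equal to the
base production at B₀, with a maximum specific rate of twice the base
P/B.  A `logistic` alternative `P(B) = (P/B)₀ B (2 − B/B₀)` makes a
single fished stock exactly Schaefer-logistic with `r = 2(P/B)₀ − MO` and
`K = r B₀ / (P/B)₀`, which the tests use as a closed-form oracle.  Both
coincide with the base production at the base state, so the static
balance is always the dynamic equilibrium.

**P/B forcing** scales a group's realized production rate and its other
mortality jointly (MO = P/B_eff (1 − EE)), so a multiplier of 1 changes
nothing and a multiplier below 1 is a genuine productivity loss rather
than a biomass rescaling.

**Integration** is fixed-step classical RK4 on a monthly grid
(dt = 1/12 yr), chosen for determinism and bit-reproducibility.  Two
numerical safeguards:

- *Stiff detritus pools.*  Detritus pools fed by fast producers can turn
  over hundreds of times per year; explicitly integrating such a pool on
  a monthly grid is unstable, and its relaxation time is far below the
  grid anyway.  Pools whose base turnover exceeds 2/dt are therefore
  treated as quasi-steady: their balance point is re-solved (two
  fixed-point sweeps) after every substep.  At the base state the snap
  reproduces the calibrated biomass exactly.
- *Automatic substepping.*  The spectral radius of the base-state Jacobian
  (computed numerically once per simulator) sets the number of substeps
  per dt so that λ·dt_sub stays inside the RK4 stability region (margin
  2.2).  Frozen lanes are deliberately *not* excluded from the Jacobian,
  so static-ecosystem and dynamic-ecosystem runs of the same web use
  identical stepping — which is what makes the two modes bit-identical
  for a trophically isolated target.

Annual forcing values, fishing mortalities and biomass overrides are step
functions held constant within each simulated year.  Biomass-forced
groups (stocked or immigration-dominated species) contribute to others'
predation and consumption but their own derivative is ignored; they track
their override series exactly at sample times.  A biomass floor of 1e-9
times the base biomass prevents negative states; floored groups may
recover.  The long-run integrator is a compiled (numba) kernel mirroring
the reference Python right-hand side.

## Temperature forcing

Tolerance curves are flat at 1 up to the optimum and decline linearly to
0 at the critical temperature (a truncated-Gaussian right arm is available
for sensitivity work; the linear default is the minimal assumption given
only two printed thresholds per species).  The bundled archetypes are a
cold-water prey curve (optimum 20 °C, upper lethal 26 °C) and a
burbot-like curve (optimum 18.2 °C, critical 27.5 °C; the printed stress
onset at 23.7 °C is available as a user-selectable knee but the default
ignores it).  Annual forcing values are the mean of the July–August
temperatures — the warm-season window that matters for thermal stress;
the other months are assumed within tolerance.  Vulnerability forcing for
the warm-adapted predator is direct proportionality, multiplier =
T / T_ref with T_ref the base-year temperature (a non-linear relation is
out of scope).  Series shorter than a run are extended by holding the
last value: a sustained regime.

## Fitting

The objective is `SS = Σ_series Σ_years w (log obs − log(q pred))²`.
Absolute-biomass and catch series use q = 1; relative-abundance series use
the closed-form minimizer log q = mean(log obs − log pred) (the
geometric-mean ratio), which makes SS invariant to rescaling a relative
series.  Log-scale residuals are the standard choice for strictly
positive survey indices with multiplicative error.

Sensitivity ranking perturbs one link's v at a time (default ×2) and
orders links by |ΔSS|, ties broken lexicographically by (predator, prey).
The fit itself runs Nelder–Mead on log(v − 1) of the selected links
(bounds [1, 1e5]), restarted from up to three spread-out initial points
(the current setting, v = 5, v = 50) because the surface is rugged and
flattens as v grows.  The starting point is always a candidate, so the
final SS never exceeds the initial one; hitting the iteration budget is a
warning, not an error.  With the forcing flag on, the forcing series is
active during every objective evaluation.

Identifiability caveat: at base fishing with no forcing the system sits at
its calibrated equilibrium *for every v* — vulnerabilities are only
identifiable from perturbed data (a fishing-mortality history and/or an
environmental forcing), which is how the synthetic observation scenarios
are constructed.

## Reference points

`estimate_msy` runs one continuous simulation in which the target's F
climbs a staircase of `n_steps = 25` equally spaced values from 0 to
F_max, each held for `years_per_step = 20` (500 years total); non-target
groups keep their base F, and biomass-forced groups stay forced.
Equilibrium yield per step is F times the mean target biomass over the
last 5 years of the block; a block whose biomass still trends more than
1%/yr over that window is flagged non-equilibrated (not fatal).  F_max
defaults to max(3 F_base, 1.5 P/B) per target, which brackets the yield
peak for both lightly and heavily fished groups.  Because yield curves
can be flat-topped, Fmsy is reported as the *lowest* grid F within 1% of
the maximum yield, with the width of that flat band as a diagnostic.
Single-species mode freezes every non-target biomass at base (the
classical assumption); ecosystem mode frees them.

## Monte Carlo

Each trial multiplies every group's B, P/B, Q/B — and EE where EE was an
input — by independent mean-1 draws; originally solved parameters are
blanked and re-derived so every candidate is internally consistent, then
the candidate must pass the consistency check (rejection otherwise).
Draws are truncated normal: bounds at ±2 pre-truncation standard
deviations, with the pre-truncation scale inflated by 1/0.8796 so the
realized CV of the draws equals the configured cv (0.1 by default)
exactly.  Diet fractions are deliberately not perturbed.  Trials continue
until exactly `n_success = 80` candidates succeed (attempt budget
50 × n_success); each success runs the full staircase on the same F grid
as the unperturbed point estimate, and the 25th/50th/75th percentiles of
yield and biomass per F step form the envelope.  Everything is a pure
function of the seed.

## Synthetic data

The generators define the study conditions:

- **Lake motif** (fixed, not drawn): 7 groups wired so the cold-water
  prey and the forage fish compete for the invertebrate pool and the
  piscivore eats the forage fish.  Diet fractions are a constant in-code
  table so directional experiments are stable across seeds.  The forage
  fish and invertebrate enter with EE fixed at 0.9 and biomass solved —
  the survey-poor groups — while the rest solve for EE.
- **Random webs**: one producer, one detritus pool, trophically ordered
  consumers whose biomasses are drawn *demand-aware* — committed
  predation never exceeds 85% of any prey's production, and fishing takes
  at most another 10% — so every seeded web balances by construction
  (EE ≤ 0.95).
- **Temperature**: monthly tables with July–August at a 22.0 °C baseline
  (a realistic mid-summer average for a north-temperate lake, sitting
  between the cold-water optimum and lethal limits so warming bites), a
  +0.6 °C regime step at year 11 of 22 (the observed decade-to-decade
  difference the scenario emulates) and N(0, 0.25 °C) noise.
- **Observations**: simulated trajectories times lognormal noise
  (CV 0.05 by default); relative series get an extra random per-series
  scale to exercise the closed-form catchability.

What passing tests on these data do and do not show: the generators share
the model family with the estimators (no model misspecification, no
age/size structure, no zero-inflated or autocorrelated survey error), so
recovery results certify the machinery — identifiability under realistic
noise and forcing — not robustness to structural error in field data.

## Problem sizes used by the test suite

Mass-balance checks run 200 seeded webs; equilibrium preservation runs 41
webs for 100 years; the fine-grid MSY oracle uses 250 independent
equilibrations on a 4-group web; vulnerability recovery uses 20 seeded
22-year observation sets with 1–3 perturbed links; Monte Carlo runs the
full 80-success protocol on the motif, twice, to verify bytewise
reproducibility.

## Known limitations

- Juvenile/adult splits are separate groups linked only by diet: there is
  no stanza growth bookkeeping, so ontogenetic biomass transfer is not
  conserved across stanzas.
- No mediation functions, no handling-time saturation beyond the arena
  closure, no sub-annual diet switching, no spatial structure.
- Net migration is a crude split (positive = per-biomass emigration,
  negative = constant immigration).
- The Monte Carlo perturbs the four core parameters only; diet and
  vulnerability uncertainty are out of scope.
- The quasi-steady detritus treatment assumes fast pools relax within a
  month; slow detritus pools (turnover ≤ 2/dt) are integrated explicitly.
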