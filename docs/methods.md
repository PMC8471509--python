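# Methods

## Emission model

The source strength of a powder-handling task is
`S(t) = DI · H · dM/dt · LC_bag · LC_LEV` (mg min⁻¹), non-zero while the
task schedule is active. `DI` is the EN 15051 dustiness index of the
handled material for the chosen test method (continuous drop, CD, or
rotating drum, RD) and size fraction (inhalable or respirable), in
mg kg⁻¹. `H` is the dimensionless handling-energy factor relating the
mechanical energy of the real process to that of the dustiness test;
the packaged defaults are 1 for the big-bag lines (L, M) and 0.5 for
the small-bag line (H). `dM/dt` is the mass throughput in kg min⁻¹
(530–850 kg min⁻¹ for lines L/M; line H is only known as a 100–250
kg min⁻¹ range and must be chosen per run — the loader refuses to guess).

Local controls are stored as **retained fractions** (1 − efficacy);
user-facing interfaces take "percent reduction", the convention in
which control efficacies are reported, and convert exactly once at the
boundary. This avoids scattered `1 − x` conversions, the classic source
of sign errors in this arithmetic. Packaged bag-enclosure retentions
are 0.3 / 0.2 / 0.1 for lines L / M / H; the LEV retention defaults to
0.3 (70 % reduction), the base value of the sensitivity sweep.

All internal units are mg, m³ and minutes; air-change rates (h⁻¹) are
converted at the boundary (`ach_from_flows` / `flows_from_ach`).

### Dustiness-method scaling

Because the CD test drives far more inhalable mass airborne than the RD
test for the same materials (per-material CD/RD ratio mean 25.1, range
17.1–53.5 in the packaged table; respirable mean 1.24), a handling
factor calibrated against one method cannot be reused with the other
for the inhalable fraction. `corrected_h(h, ratio_mean, decimals)`
performs the rescaling `h / ratio_mean` (rounded as published:
1 → 0.04, 0.5 → 0.02 at two decimals). The evaluation layer can re-score
a stratum under a rescaled H through `summarize(..., modelled_scale=…)`,
since the models are linear in H.

## Box models

Both models assume instantaneous mixing within each compartment and
removal by ventilation only; deposition and coagulation are neglected,
which biases inhalable predictions high more than respirable ones.

One box: `V dC/dt = S + Q·C₀ − Q·C` with `Q = Q_GV + Q_LEV`.

Two box: the near field (default volume 8 m³, a 2 m-radius hemisphere
around the source, configurable) exchanges `β_i = β + Q_LEV,NF` with
the far field; the far field receives make-up air `(Q_GV + Q_LEV)·C₀`
and loses `Q_GV·C_FF` plus `β_i·C_FF` back to the near field:

```
V_NF dC_NF/dt = S + β_i·C_FF − β_i·C_NF
V_FF dC_FF/dt = (Q_GV + Q_LEV)·C₀ + β·C_NF − β_i·C_FF − Q_GV·C_FF
```

These equations are implemented **literally**: the near field loses
`β_i·C_NF` while the far field regains only `β·C_NF` — the difference
`Q_LEV,NF·C_NF` is the air captured by the exhaust. A consequence of
the literal form is that the room-level air balance is open by
`Q_LEV − Q_LEV,NF` whenever the duct exhaust flow (300 / 40 m³ min⁻¹
for the packaged halls) differs from the FF→NF draw attributed to the
LEV (10 / 5 m³ min⁻¹). The two flows are deliberately kept as separate
named parameters (`q_lev`, `q_lev_nf`), the room exhaust flow is the
one entering the make-up term, and `air_balance_report` surfaces the
imbalance as a warning without "fixing" it — fidelity to the standard
formulation is preferred over a physical reinterpretation the data
could not arbitrate.

Steady states are closed-form:

* one box: `C = (S + Q·C₀)/Q`;
* two box: `C_FF = [β·S/β_i + (Q_GV+Q_LEV)·C₀] / (Q_LEV,NF + Q_GV)`,
  `C_NF = C_FF + S/β_i` — the NF−FF contrast depends only on `S` and
  `β_i`, which is what makes `β` recoverable from paired NF/FF data.

### Transient solution and numerics

The source is piecewise-constant, so transients are solved exactly per
segment: scalar exponential relaxation for the one box, and for the two
box the 2×2 linear system `dC/dt = A·C + b` via eigen-decomposition of
`A` (real, distinct eigenvalues in the physically meaningful region);
if the eigenvalues come within a relative 10⁻⁹ of each other the
propagator falls back to a matrix exponential, which handles the
degenerate case without special-casing. A numerical integrator
(`method="numeric"`, LSODA at relative tolerance 10⁻⁸) solves the same
segments independently and agrees with the closed form to better than
10⁻⁶ relative in the test suite — it serves as the cross-check oracle,
never as the primary path. The default output grid is 1 minute,
matching the time resolution of the optical monitors such campaigns
use. Initial conditions default to the background `C₀` (room starts in
equilibrium with incoming air). Task averages are trapezoidal time
integrals with linearly interpolated window endpoints.

## Sensitivity analysis

`run_oat` varies exactly one parameter per sweep: the LEV percent
reduction `{50, 70, 80, 90}` (base 70 %) or the inter-zonal flow
`β ∈ {0.25, 0.5, 1, 2.5, 5, 10}` m³ min⁻¹ (5 most likely, spanning
literature values 0.24–30). A `β` sweep moves `β_i = β + Q_LEV,NF`
consistently, because the LEV-induced draw is a property of the exhaust
and not of the room air movement being varied. With zero background the
models are linear in the retained LEV fraction, so the 50→90 %
reduction sweep scales concentrations as 0.5 : 0.1 — an exact 80 %
drop, independent of every other parameter.

## Evaluation metrics

Model skill is scored on the modelled/measured task-average ratio with
inclusive upper band edges: under < 0.5 ≤ accurate ≤ 2 < slight-over
≤ 5 < high-over, plus MAE, R² (squared Pearson of modelled vs measured
— the simplest reading; no transformation is applied), Spearman with
average ranks, and the fraction of cases where measurement exceeds
model. Classification can round ratios to a stated precision first:
published tables print one decimal, and a raw 5.03 printed as 5.0
belongs in the ≤ 5 group when reproducing published counts. Reported
R²/Spearman on fifteen clustered points are fragile — the packaged
reproduction treats only band percentages and MAE as checkable.

The reproduction report classifies the *published rounded ratios*
rather than ratios re-divided from rounded concentrations: two
respirable cases sit exactly on the ratio-2 edge, where the printed
ratio (2.1) preserves the authors' unrounded value while the re-divided
one (2.00, 2.03) does not. MAE always comes from the concentration
pairs. `summarize()` itself defaults to raw ratios; the printed-ratio
path is opt-in.

## Packaged reference tables

`dustbox/data` carries the dustiness table (7 materials × 2 methods ×
2 fractions), per-line emission parameters, the paired
modelled/measured table (15 replicate tasks × 2 models × 2 DI methods ×
2 fractions, with event-excluded measurement variants kept as separate
columns, never merged), and scenario defaults for the three filling
lines. Loading validates shape, replicate counts, the
inhalable ≥ respirable invariant, and recomputes every printed ratio
from its concentration pair with a tolerance that propagates the
rounding of all three printed numbers. Two cells fail any such
tolerance — the Feldspar 2 R2 respirable CD rows print identical
with/without-event ratios although the measured value changes — and are
kept verbatim as documented known inconsistencies (`KNOWN_INCONSISTENT`).

Day-specific air-change rates and task durations for the original
campaign are not available, so the scenario files carry nominal
open-door general-ventilation flows (1050 / 200 m³ min⁻¹, giving ACH
around 35–39 h⁻¹); exact reproduction of the published modelled
concentrations is therefore out of scope, and the model solvers are
validated by closed forms, cross-solver agreement and parameter
recovery instead.

## Synthetic campaigns

The generator emulates stationary worker-area monitoring: a box-model
truth series at 1-minute resolution, each step multiplied by lognormal
noise (default GSD 1.5, the conventional shape and spread for
occupational concentrations; GSD 1.3 for recovery studies) and offset
by an additive truncated-normal background, then averaged over the task
window. One seeded generator drives all replicates; the seed is logged
in every output. What the generator does **not** emulate: instrument
size channels and optical-to-mass conversion, autocorrelated process
fluctuations (noise is independent per minute), background dynamics
(forklift traffic comes and goes in reality), or emission-rate drift
within a task. Passing recovery tests therefore show the inference
machinery is correct under the stated noise model, not that `β` is this
identifiable in any real hall.

`recover_beta` fits `β` by least squares on log concentrations over a
log-spaced grid (0.05–100 m³ min⁻¹, 60 points) with bounded local
refinement between the best point's neighbours; log residuals make the
fit scale-free across the orders of magnitude separating NF and FF.
`recover_source` exploits linearity in `S`: the estimate is the
geometric mean of observed/unit-response ratios. Noiseless recovery is
exact to optimizer tolerance; at GSD 1.3 with 50 replicates the median
`β` estimate lands within a few percent of truth (the acceptance run
reports the realized error).

## Design choices and limitations

* Steady states, not time averages, are used wherever the published
  comparison is a task-level number; task averages of transients are
  available (`time_weighted_average`) when a schedule matters.
* The line-H mass flow is a free parameter by design; every API that
  needs it fails loudly rather than silently picking a value.
* Validation compares against printed values at their printing
  precision (one unit in the last printed digit); nothing tighter is
  claimed, because nothing tighter is recoverable from rounded tables.
* Problem sizes in the test and acceptance runs (10–25 randomized
  scenarios, 50-replicate campaigns, 240-minute tasks on 1-minute
  grids) were chosen as the smallest sizes at which the Monte-Carlo
  statements stabilize across seeds.
* No deposition, coagulation, size resolution, ≥3-box topologies or
  CFD; no global (variance-based) sensitivity analysis; no hypothesis
  testing or uncertainty intervals on the evaluation metrics.
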