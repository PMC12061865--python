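# Methods

## Model

`serocircuit` couples three subsystems:

1. **Neural masses.** Each region (PFC, SCC) is a reduced two-population
   (excitatory/inhibitory) mean-field model. The state per region is the
   NMDA gating fraction `S_E` and GABA gating fraction `S_I`; population
   rates are static functions of the input currents through the
   soft-rectifying transfer curve `H(I) = g(I−I_thr)/(1−exp(−d·g·(I−I_thr)))`.
   The two regions are coupled by weak long-range NMDA projections onto the
   excitatory populations (SCC→PFC constant 0.01, PFC→SCC 0.005, each
   multiplied by the receiving region's `J_NMDA`).

2. **Serotonergic currents.** A dimensionless variable `M_5HT` per region
   relaxes (τ = 120 ms) toward a sigmoid of extracellular serotonin,
   `J_5HT/(1+exp(−β([5HT]+1)))`. It enters the regional currents weighted
   by receptor density `R` with region-specific sign: positive in PFC
   (excitatory 5HT2A dominate), negative in SCC (inhibitory 5HT1A
   dominate). The `+1` nM offset in the sigmoid argument is kept exactly as
   published; it is a fixed 1 nM shift with no mechanistic reading, and at
   operating concentrations (tens of nM) it is numerically negligible.

3. **Serotonin kinetics.** Extracellular serotonin obeys
   `d[5HT]/dt = α·C_BR·r_E·X1 − Vmax·[5HT]/(Km+[5HT])·X2`: synthesis
   proportional to the region's excitatory rate (raphe drive follows
   cortical activity through fiber density `C_BR`), Michaelis–Menten
   reuptake. Inflammation multiplies synthesis by `X1 ≤ 1` and reuptake by
   `X2 ≥ 1`; both are gated by a Heaviside on cytokine excess with
   `θ(0) = 0`, so the control condition (degree exactly 1) leaves kinetics
   untouched. The anti-inflammatory blocker `B` scales the cytokine term
   inside both factors; `B = 1` reduces the treated expressions to the
   untreated ones. Raising `B` lowers `X1` and raises `X2`; `B < 1` moves
   both toward identity.

Assumptions inherited from this model class: no spatial or laminar
structure, no spiking, no conduction delays, no 5HT1A autoreceptor
(somato-dendritic) dynamics, no dopamine; serotonin synthesis tracks the
region's own excitatory rate instantaneously.

## Units

All internal quantities use seconds / Hz / nA / nM. The published tables
mix conventions (time constants in ms, the NMDA kinetic parameter γ quoted
per-ms); the config loader converts: τ_NMDA = 0.1 s, τ_GABA = 0.01 s,
τ_5HT = 0.12 s, γ = 0.641, so the excitatory gating fixed point takes the
standard form `S_E* = γτr/(1+γτr)` and Vmax (nM/s) needs no rescaling.
Shipped defaults (`src/serocircuit/data/default_params.yaml`) reproduce the
published tables in their printed units.

### Noise convention

The gating equations carry additive Gaussian noise of amplitude
σ = 0.01. We interpret σ in the same millisecond frame as the rest of the
parameter table: the Euler–Maruyama kick per step is `σ·sqrt(Δt/1 ms)`,
i.e. a diffusion amplitude of 0.01 per √ms (≈ 0.316 per √s). The
alternative per-√s reading produces replicate-to-replicate dispersions
~30× smaller than the published standard errors, whereas the per-√ms
reading reproduces them almost exactly (e.g. control PFC serotonin sem
0.41 vs 0.35 nM; rate sems 0.022 vs 0.02 Hz at n = 100); it also brings the
stochastic means of all headline PFC observables within a few percent of
the published values. Noise enters only the gating equations; the
serotonergic current and serotonin kinetics integrate deterministically.

## Simulation protocol

Euler–Maruyama with dt = 0.1 ms, 7 s of model time, the first 1 s discarded
as transient (70,000 steps, 60,000 retained), 100 replicates per condition.
Observables are per-replicate time-averages of post-transient serotonin and
excitatory rate, summarised as mean ± sem (sample sd / √n) over replicates.
"Activity" is the time-averaged excitatory population rate: a rate model
has no spectral peak, and the published activity values are population
rates in Hz.

Initial conditions are random per replicate: `S_E, S_I ~ U(0, 0.5)`,
`M ~ U(0, 1)`, `[5HT] ~ U(40, 80)` nM — gating in the lower half of its
range, serotonin bracketing the physiological operating point. The 1 s
transient absorbs most of the choice; the slowest deterministic mode has a
~0.5 s time constant, so noise-free trajectory-vs-oracle consistency checks
use a 3 s transient within a 9 s window (with the published 1 s transient a
relaxation tail of ~0.15% can survive in the 6 s average).

Reproducibility: each replicate r owns a counter-based random stream
(Philox keyed by `base_seed + r`). Streams are independent of batch
composition, so a condition's summary is bit-identical whether it runs
alone, inside `run_replicates`, or stacked with other conditions in
`run_conditions_batch`; the battery is invariant to execution order and to
subset selection. After each step the state is clamped (`S_E ∈ [0,1]`,
`S_I ≥ 0`, `[5HT] ≥ 0`); a non-finite or unbounded (>1e6) state raises an
error naming the offending variable.

## Deterministic oracle

`steady_state_oracle` finds the noise-free fixed point of the full coupled
8-dimensional system: coarse forward relaxation (20 s of model time at
dt = 0.5 ms; the attractor is stable) followed by a hybrid-Newton polish of
the drift, verified to residual < 1e−10. The serotonin component agrees
with the scalar closed form `[5HT]* = Km·u/(1−u)`, `u = αC_BR r_E X1/(Vmax X2)`
to < 1e−8 nM, and decoupled single-region rates match an independent 1-D
bracketing solve of `r = H_E(I_E(r))` to < 1e−8 Hz.

## Conditions, treatments, variants

The grid is 4 degrees (1, 1.25, 1.4, 2.3) × 4 treatments × 3 variants = 48
conditions. Treatments: `none` (Km = 170, B = 1), `ssri` (Km = 200),
`antiinflammatory` (B = 0.55), `combined` (both). Degrees use the rounded
table values; `degree_of_inflammation` exists for the raw concentration
route (e.g. 3.35/2.69 = 1.245 → mild). Variants:

* `nmda_excitotoxicity`: SCC τ_NMDA × 1.05 (kynurenine-pathway NMDA
  agonism slows NMDA decay in the SCC).
* `receptor_reduction`: SCC receptor density R × 0.92 ("about 8%" taken as
  exactly 0.92). The scaling targets the SCC only: it models the reduced
  postsynaptic 5HT1A density of the SCC, and scaling the PFC's 5HT2A
  density as well would depress PFC serotonin by ~14%, which the variant is
  not meant to do. PFC insensitivity is verified by test, not assumed.

"Restoration" in the ordinal test suite is asymmetric for serotonin — a
treated mean counts as restored when it is not more than 10% *below* the
untreated control mean (a treatment that overshoots control has remedied
the deficiency) — and symmetric (±10% of control) for activity, where both
hypo- and hyperactivity are pathological. Replicate sems here are so small
(~0.02 Hz) that a ±2·sem band around control would reject values that
differ from control by under 2%, including several published values
described as restored; the 10% band matches the stochastic tolerance used
throughout.

## Problem sizes

The default battery (48 conditions × 100 replicates × 70,000 steps,
integrated as one vectorized batch) completes in about two minutes on one
core; the acceptance script's six conditions run in ~20 s. The noise-free
consistency checks integrate all 48 conditions simultaneously.

## Known limitations and discrepancies

* **SCC serotonin level.** With the published parameter tables, the
  serotonin fixed point is tied to the region's own excitatory rate:
  `[5HT]* = Km·u/(1−u)` reaches ~65 nM only at r_E ≈ 4.8 Hz (Km = 170).
  The published SCC control pair (65.21 nM at 3.79 Hz) is therefore not
  jointly attainable at any noise level — sweeping the noise amplitude, the
  SCC rate passes 3.79 Hz where SCC serotonin is ≈50 nM, and serotonin
  reaches 65 nM only where the rate exceeds 4.3 Hz. Our SCC serotonin
  levels run ~10–18% below the published ones (PFC levels agree within a
  few percent); the full ordinal structure (decrease with degree, treatment
  responses) is unaffected.
* **SCC rate volatility.** Under the adopted noise convention the SCC
  operates near a noise-induced transition: individual replicate
  time-averages span ~2.7–6.5 Hz, and the n = 100 mean varies by ~±0.15 Hz
  across base seeds. SCC rates typically land 6–17% above the published
  control/severe values.
* **NMDA-variant serotonin direction.** Slowing SCC NMDA decay raises the
  SCC rate (as published); since synthesis is linear in that rate with
  unchanged X1/X2, SCC serotonin must rise with it under the model
  equations. A serotonin *reduction* under this variant is not reproducible
  from the published parameter set, and the published NMDA-variant SCC
  rates sit ~20% below ours.
* The synthetic protocol emulates replicate-level Monte-Carlo summaries of
  a stationary stochastic process. It does not emulate patient
  heterogeneity, pharmacokinetics (doses are provenance labels only),
  autoreceptor regulation, or long-term treatment outcomes — passing tests
  say nothing about those.
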