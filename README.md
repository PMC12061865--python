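# serocircuit

A stochastic dynamic mean-field simulator of immune–serotonin–brain
interactions in a two-region cingulo-frontal circuit, with in-silico drug
interventions.

## The problem

Inflammation is a recognised driver of chronic and treatment-resistant
depression: elevated pro-inflammatory cytokines (notably TNFα) divert
tryptophan away from serotonin synthesis via the IDO/kynurenine pathway and
upregulate serotonin transporters, depleting extracellular serotonin.
Because the prefrontal cortex (PFC) is dominated by *excitatory* 5HT2A
receptors while the subcallosal cingulate cortex (SCC) is dominated by
*inhibitory* 5HT1A receptors, the same serotonin deficit pushes the two
regions in opposite directions — frontal hypoactivity and limbic
hyperactivity, the classic depressive circuit signature.

`serocircuit` implements this loop as a reusable simulator for
computational-psychiatry work: given a cytokine "degree of inflammation"
and a drug intervention, it predicts steady-state extracellular serotonin
(nM) and population activity (Hz) in both regions, with replicate means and
standard errors.

## The model

Each region `n ∈ {PFC, SCC}` is a reduced Wong–Wang-type neural mass with
excitatory/inhibitory populations. Firing rates follow the soft-rectifying
transfer function

    r = g (I − I_thr) / (1 − exp(−d g (I − I_thr)))

and the synaptic gating variables evolve as

    dS_E/dt = −S_E/τ_NMDA + (1 − S_E) γ r_E + noise
    dS_I/dt = −S_I/τ_GABA + r_I + noise

Regional input currents collect recurrent excitation, local inhibitory
feedback, the external drive `W·Io`, long-range NMDA coupling between the
regions, and a serotonergic current `±W_5HT·R·M_5HT` that *adds* in PFC
(5HT2A) and *subtracts* in SCC (5HT1A). The serotonergic current variable
`M_5HT` relaxes toward a sigmoid of the extracellular serotonin
concentration, which itself follows synthesis/reuptake kinetics

    d[5HT]/dt = α C_BR r_E X1 − Vmax [5HT]/(Km + [5HT]) X2

— synthesis proportional to regional excitatory activity, Michaelis–Menten
reuptake. Inflammation enters through the degree `deg = [Cyt]/[Cyt]b`
(TNFα fold-elevation over basal; 1 / 1.25 / 1.4 / 2.3 for control / mild /
moderate / severe):

    X1 = c1^m / (c1^m + θ·B·deg^m)      (synthesis suppression, ≤ 1)
    X2 = 1 + c2·θ·B·deg                 (reuptake enhancement, ≥ 1)

with `θ` the Heaviside gate on cytokine excess and `B ∈ (0,1]` an
anti-inflammatory blocker. Treatments are parameter edits: SSRI raises
`Km` 170→200 nM (lower transporter affinity), anti-inflammatory sets
`B = 0.55`, combined does both. Two mechanistic variants scale the SCC NMDA
time constant (×1.05, glutamate excitotoxicity) or the SCC receptor density
(×0.92, reduced postsynaptic 5HT1A density).

The coupled 8-dimensional system is integrated with Euler–Maruyama
(dt = 0.1 ms, 7 s per run, 1 s transient discarded, 100 replicates per
condition); a deterministic fixed-point oracle provides the noise-free
reference. See `docs/methods.md` for conventions, assumptions and known
limitations.

## Worked example

Noise-free fixed point of the severe-inflammation condition under combined
SSRI + anti-inflammatory treatment:

```
$ serocircuit oracle --degree severe --treatment combined
PFC: serotonin 60.8423 nM, r_E 4.6221 Hz, r_I 13.9874 Hz, S_E 0.22856, S_I 0.13987, M 0.62122
SCC: serotonin 32.2854 nM, r_E 2.9157 Hz, r_I 7.5963 Hz, S_E 0.15747, S_I 0.07596, M 0.56618
```

The same condition simulated stochastically (here 10 replicates for speed):

```
$ serocircuit simulate --degree severe --treatment combined --reps 10 --seed 7
condition treatment  variant region   observable      mean      sem  n  seed
   severe  combined baseline    PFC serotonin_nM 65.844708 1.005534 10     7
   severe  combined baseline    PFC      rate_hz  4.904010 0.056144 10     7
   severe  combined baseline    SCC serotonin_nM 56.121804 2.264686 10     7
   severe  combined baseline    SCC      rate_hz  4.413675 0.139845 10     7
```

Reading: despite severe inflammation (2.3-fold TNFα elevation), the
combined treatment holds PFC serotonin near the untreated control level
(~66 nM) and keeps both regions' activity close to control (PFC ~4.9 Hz,
SCC ~4.2–4.4 Hz); under severe inflammation *without* treatment PFC
serotonin collapses to ~45 nM. Noise rectification through the convex
transfer function makes the stochastic means sit above the noise-free fixed
point — that difference is part of the model's behaviour, not an error.

Other entry points:

```bash
serocircuit battery --out-dir results           # full 48-condition grid, tidy CSV + provenance
serocircuit battery --degrees control,severe --treatments none,combined
serocircuit compare --results results/results.csv   # regression vs shipped reference table
```

or from Python:

```python
from serocircuit import (ModelParams, SimulationSettings, ConditionSpec,
                         TREATMENTS, build_condition_params, run_replicates)

params = build_condition_params(ConditionSpec("severe", TREATMENTS["combined"]))
summary = run_replicates(params, SimulationSettings(n_reps=100, base_seed=1))
print(summary.serotonin_mean, summary.rate_E_mean)   # [PFC, SCC]
```

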