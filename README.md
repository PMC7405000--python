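# gutdial

Modelling toolkit for **simultaneous starch digestion and absorption** in
dialysis-membrane simulators of the human small intestine.

Bench systems of this kind couple a stirred feed tank — where gelatinized
starch is hydrolysed by α-amylase into reducing sugars (glucose, maltose,
dextrins) — to a hollow-fiber dialysis module whose membrane stands in for
the intestinal wall: products small enough to pass the molecular-weight
cut-off cross into a dialysate tank, the "bloodstream" side.  `gutdial`
implements the phenomenological models needed to design, interpret and
scale such experiments, plus a synthetic-data generator so the whole
pipeline is testable without a wet lab.

## Models

**Generation kinetics.**  The cumulative reducing-sugar mass follows a
first-order law,

```
rs(t) = rs∞ · (1 − e^(−k·t))
```

with plateau `rs∞` (g) and degradation rate constant `k` (1/min).
`FirstOrderKinetics(...).fit()` estimates both by bounded nonlinear least
squares and returns a results object with standard errors, residual
diagnostics and a `summary()` table.

**Membrane transfer.**  Diffusive and convective transport are lumped into
a volumetric conductance `c = K·A_T + K_UF·ΔP` (m³/min), attenuated by a
dimensionless, time-varying fouling resistance `R_MT`:

```
N_rs = (c / R_MT) · (C_F − C_D)        [g/min]
```

Forward simulation is available in two modes: a *quasi-steady* scheme in
which the membrane carries exactly the generated mass each interval, and a
*two-compartment* balance that integrates accumulation in both tanks along
with the ultrafiltration water flux `K_UF·ΔP` (which drifts the feed
volume and can overflow the feed tank).  The inverse problems are also
implemented: calibrating `c` from a pure-solute run via the log-linear
relation `ln((C_F−C_D)/(C_0−C_D)) = −c·t/V_F`, and recovering `R_MT(t)`
from a digestion run.

**Efficiencies and scale-up.**  Run summaries report starch digested
(`100·rs/M0`), membrane efficiency (`100·M_rsD/(M_rsF+M_rsD)`) and
expected overall efficiency (`100·M_rsD/M_T` relative to the batch
maximum).  The scale-up module maps runs to human-intestine reference
conditions (≈96.4% transfer of hydrolytic products, 0.5 L, 30 m², 3
mL/min, 180 min) and computes the operating time needed to transfer the
physiological absorbed mass.

## Worked example

```python
from gutdial import fit_first_order
from gutdial.synthetic import (BATCH_PARAMS, NoiseModel,
                               generate_batch_run, make_schedule)

curve = generate_batch_run(BATCH_PARAMS, make_schedule(),
                           NoiseModel(cv=0.05, seed=1))
print(fit_first_order(curve, m0=20.0).summary())
```

```
First-order reducing-sugar generation fit
==============================================
observations                                18
residual norm (g)                     0.375702
R-squared                               0.9973
----------------------------------------------
param             estimate         std err
rs_inf (g)         6.61033           0.106
k (1/min)        0.0380642         0.00125
----------------------------------------------
m0 (g)                  20
conversion (%)                            33.1
```

One synthetic batch campaign (18 aliquots, 5% assay noise) recovers the
generating plateau 6.7 g and rate constant 0.037 1/min to within one
standard error; the conversion line says ~33% of the 20 g starch load is
digestible within the hour.  Simulating the three flow-ratio presets and
summarising them:

```python
from gutdial import summarize_run
from gutdial.synthetic import FIXTURE_MEMBRANE, PRESETS, generate_iids_run

for name in ("250/400", "400/400", "400/250"):
    series = generate_iids_run(PRESETS[name], FIXTURE_MEMBRANE, NoiseModel(cv=0.0))
    summary, table = summarize_run(series, PRESETS[name].params,
                                   batch_max=6.7, m0=20.0, flow_ratio=name)
```

```
flow_ratio  starch_digested_pct  membrane_eff_pct  expected_overall_eff_pct
   250/400                  8.8              43.3                      11.4
   400/400                 12.7              48.8                      18.6
   400/250                 21.8              87.6                      57.1
```

The 250/400 run (negative transmembrane pressure) overflows the feed tank
and truncates at 25 min; the 400/250 run transfers the most sugar — high
pressure pushes water and solute toward the dialysate and keeps the feed
concentrated.  The same stages are scriptable from the shell via the
`gutdial` CLI (`generate`, `fit`, `simulate`, `fouling`, `metrics`,
`scaleup`).

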