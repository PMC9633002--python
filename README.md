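# gal1kinetics

Single-cell repression kinetics of Gal1-GFP in budding yeast: dilution
compensation of lineage-tracked fluorescence traces, closed-form kinetic
model fitting, BIC classification of repressing vs. non-repressing cells,
and population timing statistics — with a Gillespie simulator so the whole
pipeline is testable against known ground truth.

## The problem

When *Saccharomyces cerevisiae* is shifted from galactose to glucose, the
galactokinase gene *GAL1* is repressed. Time-lapse microfluidic
experiments track a Gal1-GFP fusion in hundreds of single cells across
alternating carbon-source phases (repressions r1, r2 separated by a
galactose induction), at one image every 3 min. Two confounders stand
between the raw traces and the question "how fast does each cell shut
production off?":

1. **Dilution** — budding hands ~1/3 of a mother's fluorescence to its
   daughter, lowering the mother's total signal without any degradation;
2. **Mixed populations** — after a few hours of galactose, some cells
   never induced Gal1 and therefore cannot show repression kinetics.

`gal1kinetics` addresses both: it builds *artificial non-dividing cells*
by summing the total fluorescence (mean × segmented area) of each mother
and all progeny born during the repression window, then fits two nested
kinetic models per trace and classifies cells by model selection.

## The models

Without repression (uninduced cells):

    dGFP/dt = r_basal − r_deg · GFP
    GFP(t)  = r_basal/r_deg · (1 − e^(−r_deg·t)) + GFP_0 · e^(−r_deg·t)

With repression: production at rate `r_prod` until the *repression
response delay* `t_delay`, then switched off:

    t ≤ t_delay:  as above with r_prod in place of r_basal
    t > t_delay:  GFP(t) = GFP(t_delay) · e^(−r_deg·(t − t_delay))

Each trace is fitted by multi-start maximum likelihood (Latin-hypercube
starts in log10 space, bounded L-BFGS-B, escalating 20→50→100→200 starts
until ≥5 agree within 0.1 logL). A Gaussian noise model with constant
variance σ² is the default; a moment-equation noise model with total
variance σ² + Var(t) is available. Classification uses
`BIC = ln(n)·k − 2·logL`: a cell has repression kinetics iff
`BIC_repression < BIC_no_repression − 10`. Downstream, bootstrap peak
times of the population mean and exact median/sign tests (Bonferroni,
m = 12) compare repressions r1 and r2.

## Worked example

Simulate the four-cell degradation benchmark (`GFP_0 = 100` molecules,
`t_delay = 0.5 h`, `r_prod = 100/h`, measurement noise σ = 5; degradation
0.5, 0.2, 0.04 and 0 per hour), fit both models and classify:

```python
from gal1kinetics import (OptimizationConfig, s3_benchmark,
                          as_compensated_trace, truncate_and_rescale,
                          fit_both_models, classify_trace)

bench = s3_benchmark(seed=1)
config = OptimizationConfig(seed=1)
for label, sim in bench.items():
    trace = truncate_and_rescale(as_compensated_trace(sim, mother_id=label))
    fit_rep, fit_norep = fit_both_models(trace, config=config)
    sel = classify_trace(fit_rep, fit_norep, n=len(trace.times),
                         mother_id=label)
    print(f"{label:10s}  r_deg={sim.settings.r_deg:4.2f}/h  "
          f"t_delay_hat={fit_rep.theta_hat.t_delay:.2f} h  "
          f"dBIC={sel.delta_bic:6.1f}  {sel.label}")
```

Output:

```
fast        r_deg=0.50/h  t_delay_hat=0.40 h  dBIC=  34.3  with_repression
slow        r_deg=0.20/h  t_delay_hat=0.60 h  dBIC=  41.1  with_repression
super_slow  r_deg=0.04/h  t_delay_hat=0.45 h  dBIC=  13.6  with_repression
none        r_deg=0.00/h  t_delay_hat=0.50 h  dBIC=   7.0  without_repression
```

The three cells with nonzero degradation are recognized as repressing
(ΔBIC > 10) with shut-off delays scattered around the true 0.5 h — the
residual scatter is the intrinsic stochasticity of a single birth–death
path. The degradation-free cell is the designed failure case: with nothing
decaying after shut-off the trace carries no repression signature, so the
simpler model wins even though its delay estimate happens to be accurate.

The same flow is available from the shell:

```
gal1kinetics simulate cohort --seed 5 --n-mothers 50 --out-dir sim
gal1kinetics preprocess --cells sim/cells_r1.csv \
    --measurements sim/measurements_r1.csv --config phases.yaml \
    --repression r1 --out traces_r1.csv
gal1kinetics fit --traces traces_r1.csv --seed 2 \
    --out-fits fits.csv --out-selection selection.csv
gal1kinetics analyze --traces-r1 traces_r1.csv --traces-r2 traces_r2.csv \
    --out-dir results/
```

Input format: one CSV row per tracked cell (`cell_id`, `mother_id`,
`first_frame`, `last_frame`) plus a long-format CSV of per-frame
measurements (`cell_id`, `frame`, `mean_fluorescence`, `area`), and a
YAML phase schedule. See `docs/methods.md` for the full model and design
documentation.

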