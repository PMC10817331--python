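# vernal

Modeling toolkit for vernalization-induced flowering activation in legumes.
It has two layers:

1. **Feed-forward-loop theory** (`vernal.ffl_theory`): a coherent FFL in
   which an upstream input X activates a target Z directly and through a
   configurable number of intermediate activator branches Y_i, with
   saturating (Michaelis–Menten) kinetics combined additively (OR logic).
   The module provides the right-hand side, a simulator, the closed-form
   steady state, and steady-state perturbation analysis demonstrating that
   multiple branches buffer single-branch variation while amplifying
   upstream signals.

2. **Data-driven model selection for PIM activation**
   (`vernal.pim_models`, `vernal.fitting`, `vernal.model_selection`): four
   candidate single-state ODE models (H1–H4) of PIM activation by a delayed
   FTa1 signal and three SOC1 factors, driven by regulator time courses
   interpolated from expression data.  Models are fit by weighted least
   squares (per-point 1/sd² weights, first timepoint used as the initial
   condition) with multi-start simulated annealing, and ranked by the
   small-sample-corrected Akaike criterion
   `AICc = 2k + V_min + (2k² + 2k)/(m − k − 1)`.

Supporting modules: `vernal.core_data` (the five-gene × four-condition
expression dataset type and its long-CSV/JSON formats) and
`vernal.synthetic_data` (a generator emulating the qualitative structure of
the empirical time courses, including a mechanistic mode that produces PIM
from a known hypothesis model for parameter-recovery and model-selection
experiments).

## CLI

```bash
# integrate the feed-forward loop (YAML config: n_branches, parameters,
# input signal spec, horizon); writes t, Y1..Yn, Z columns
vernal simulate-ffl --config ffl.yaml --out ffl.csv

# generate a synthetic dataset (long CSV: gene, genotype, vernalized, day,
# mean, sd); --mechanistic H1 --params truth.yaml also emits the ground truth
vernal synth --seed 1 --out data.csv

# fit hypothesis models (multi-start simulated annealing within bounds);
# writes parameter, restart-ensemble and per-condition trajectory tables
vernal fit --data data.csv --hypothesis all --restarts 100 --seed 1 --out fits/

# rank the fitted models by AICc
vernal compare fits/ --out comparison.csv
```

Externally digitized datasets in the same long-CSV schema can be loaded
with `vernal.synthetic_data.load_digitized` (or passed directly to
`vernal fit`); they are flagged as empirical.

## Notes

- Expression values are dimensionless (reference-gene normalized); mRNA
  levels stand in for protein concentrations, with the proportionality
  constant absorbed into the dissociation constants.
- Default fitting bounds: rates and degradation in (0, 10], dissociation
  constants in (0, 1000], transport delay in [0, 15] days.
- `m` in AICc defaults to conditions × (timepoints − 1) — 16 for the
  standard 4 × 5 design — and is overridable everywhere it appears.
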