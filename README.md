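# methaneval

Evaluation toolkit for paired observed-vs-simulated dry matter intake (DMI)
and enteric methane data from cattle feeding trials. It provides:

- **dataset** — typed records for animal observations and diet compositions,
  CSV readers/writers with validation, non-structural-carbohydrate derivation
  by difference, and assembly of paired observed/simulated series with diet
  group labels. A six-diet tropical forage composition table ships as a
  packaged fixture.
- **metrics** — the full accuracy/precision/agreement descriptor suite for
  paired series: mean S/O ratio and its CV, regression slope (with or without
  intercept) and slope tests, mean bias %, R², model efficiency, mean square
  prediction error with its exact bias/slope/random partition, and the
  concordance correlation coefficient with its accuracy (Ca) and precision
  (R) factors. Population moments (divide by n) are used throughout so the
  MSPE partition sums to 100% exactly.
- **evaluation** — the analysis pipeline: evaluate all records and,
  optionally, the with/without-Leucaena diet subsets, then write report
  tables (markdown or CSV, display-rounded) or full-precision JSON.
- **stub_model** — a pluggable predictor interface plus a deterministic
  stoichiometric stub predictor of intake and methane from diet composition.
  The binding contract is the direction of the methane response to each
  composition variable (NDF −, NSC −, fat −, ash −, protein +, digestibility +),
  not the constants.
- **sensitivity** — one-at-a-time min/max substitution design over a diet
  table, consensus response signs across base diets, and a standardized PCA
  of the run matrix.
- **synthetic_data** — a lognormal-noise generator of paired datasets with
  configurable simulated/observed ratios per diet group, plus a
  parameter-recovery harness.

## CLI

A single `methaneval` entry point with four subcommands
(exit codes: 0 ok, 1 validation, 2 I/O, 3 internal):

```sh
# generate a synthetic paired dataset (24 records: 6 diets x 4 steers)
methaneval simulate --seed 42 --out records.csv

# evaluate methane predictions, with the diet-group split
methaneval evaluate --records records.csv --variable ch4 \
    --split-by leucaena --mode moment --out report.md --json report.json

# predict intake and methane for each packaged diet with the stub model
methaneval predict --bw 206 --out predictions.csv

# one-at-a-time sensitivity analysis of the stub predictor
methaneval sensitivity --bw 206 --levels 2 --out runs.csv --summary summary.json
```

`--diets D.csv` overrides the packaged composition table everywhere;
`simulate --config gen.yaml` accepts generator-parameter overrides
(flags win over the file).

## Python API

```python
from methaneval import (
    GeneratorConfig, generate, default_diets, to_paired, evaluate,
)

records = generate(GeneratorConfig(seed=42))
paired = to_paired(records, "ch4", default_diets())
metrics = evaluate(paired)
print(metrics.ccc, metrics.ca, metrics.r)   # ccc == ca * r
```

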