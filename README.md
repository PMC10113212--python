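# lineup-mpt

Model-based lineup-fairness analysis. The package implements a
two-high-threshold (2-HT) multinomial processing tree model for six-category
eyewitness identification data (suspect identification / filler
identification / rejection, in culprit-present and culprit-absent lineups),
fits it jointly across experimental conditions by maximum likelihood under
equality restrictions, and provides the surrounding inference and
fairness toolkit:

* **`lineup_mpt.model`** — parameters, condition metadata, predicted category
  probabilities, expected counts, response-table CSV I/O.
* **`lineup_mpt.restrictions`** — declarative equality/fixing restrictions
  across conditions (the "base model" device), with nesting checks.
* **`lineup_mpt.fit`** — joint ML fitting with seeded multi-start
  optimisation, G² goodness of fit, ΔG² nested-model tests, standard errors
  from the expected information matrix, Cohen's w, and noncentral chi-square
  sensitivity analysis.
* **`lineup_mpt.fairness`** — Tredoux's E, proportion of suspect selections,
  the pooled two-proportion z-test, resultant fairness measures from
  culprit-absent identifications, and identification rates.
* **`lineup_mpt.simulate`** — synthetic eyewitness and mock-witness data with
  exactly the statistical structure the estimator assumes, plus a
  parameter-recovery harness.
* **`lineup_mpt.fixtures`** — three bundled four-condition datasets
  (`exp2`, `exp3`, `exp4`: published observed response frequencies for
  simultaneous/sequential lineups with morphed/non-morphed fillers),
  validated at load time.
* **`lineup_mpt.eqn`** — export/import of the model structure in the de facto
  MPT equation-file dialect.

## CLI

```sh
lineup-mpt reproduce exp2            # full published analysis, computed vs published
lineup-mpt fit --fixture exp2 --seed 1 --format json --eqn model.eqn
lineup-mpt fit --csv tables.csv --restrictions restrictions.yaml
lineup-mpt compare --fixture exp2 --equal b:sim_morphed,sim_nonmorphed
lineup-mpt fairness --csv choices.csv        # mock-witness measures
lineup-mpt fairness --fixture exp2           # resultant measures
lineup-mpt simulate --design design.yaml --seed 1 --out tables.csv
```

Restriction configs are YAML:

```yaml
share:
  - {param: dA, conditions: all}
  - {param: dP, conditions: [sim_morphed, sim_nonmorphed]}
fix:
  - {param: b, conditions: [seq_morphed], value: 0.0}
```

Every artifact-writing run logs to stderr and drops a JSON manifest (seed,
arguments, version) next to its output.

## Library example

```python
from lineup_mpt import load_fixture, base_restrictions, fit_model, compare_nested

tables = load_fixture("exp2")
base = fit_model(tables, base_restrictions(), seed=1)
restricted = fit_model(tables, base_restrictions().share("b", ["sim_morphed", "sim_nonmorphed"]), seed=1)
print(base.summary())
print(compare_nested(base, restricted).summary())
```
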