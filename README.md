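# modact

Metabolic module activity inference from gene expression, by signal
propagation on reaction graphs — with downstream differential testing,
class prediction, in-silico knock-out (KO) simulation, automatic optimal-KO
search, and survival association.

## Method in brief

A metabolic module is a small directed graph of reaction nodes (edges point
from the simpler toward the more complex metabolite). Each node's catalytic
activity `n_i` is computed from the [0,1]-rescaled expression of its genes:
enzymatic complexes score the minimum over their subunits (AND), alternative
isoenzymes combine by probabilistic OR. Activities propagate along edges:

```
S_i = n_i * (1 - prod_{a in preds(i)} (1 - S_a))
```

with entry nodes receiving one virtual unit input (so `S_entry = n_entry`).
Acyclic modules are evaluated in one topological pass; cyclic modules by
least-fixed-point iteration from zero. The module's activity is the
propagated value at its terminal node(s) — the quantity compared across
conditions, fed to classifiers, perturbed by KOs, and stratified for
survival analysis.

## CLI

```bash
modact simulate --config sim.yaml --out-dir data/      # synthetic inputs + truth.json
modact validate-modules --modules data/modules.json
modact activities  --expr data/expr.tsv --modules data/modules.json --out act.tsv
modact compare     --expr data/expr.tsv --design data/design.tsv \
                   --modules data/modules.json --group1 A --group2 B --out diff.tsv
modact predict-train --expr data/expr.tsv --design data/design.tsv \
                   --modules data/modules.json --algorithm rf --k 5 --repeats 50 \
                   --seed 1 --out model.bin --cv-out cv.tsv
modact predict-apply --model model.bin --expr data/expr.tsv \
                   --modules data/modules.json --out probs.tsv
modact ko          --expr data/expr.tsv --sample s1 --modules data/modules.json \
                   --spec genes.tsv --threshold 2 --out ko.tsv
modact drug        --expr data/expr.tsv --sample s1 --modules data/modules.json \
                   --drug-map drugs.tsv --drugs drugA,drugB --out drug.tsv
modact auto-ko     --expr data/expr.tsv --design data/design.tsv \
                   --modules data/modules.json --source B --target A --seed 1 \
                   --out ranking.tsv
modact survival    --expr data/expr.tsv --modules data/modules.json \
                   --surv data/surv.tsv --percentile 0.2 --out surv_res.tsv
```

Outputs are TSVs with a commented `# key=value` metadata header
(`--no-timestamp` makes them byte-reproducible). Exit codes: 0 success,
1 data error, 2 usage error. A YAML file passed to the top-level
`--config` supplies per-subcommand defaults; flags win.

### Input formats

- **Module graphs** (JSON): `{"modules": [{"module_id", "name", "species",
  "nodes": [{"node_id", "label", "groups": [{"semantics": "complex"|"single",
  "genes": [...]}]}], "edges": [["src","dst"], ...],
  "entry_ids": [...], "terminal_ids": [...]}]}` — entry/terminal
  declarations are required for cyclic modules.
- **Expression** (TSV): header `gene<TAB>sample1<TAB>...`, numeric body,
  empty/`NA` cells imputed after rescaling.
- **Design** (TSV, no header): `sample<TAB>label`.
- **Survival** (TSV with header): `sample<TAB>time<TAB>event` (event 1 =
  observed, 0 = censored).
- **Drug targets** (TSV, no header): `drug<TAB>gene<TAB>inhibit|activate`.
- **Intervention spec** (TSV, no header): `gene<TAB>action[<TAB>value]`
  with actions `ko_hard` (set 0), `ko_soft` (×0.01), `overexpress` (set 1),
  `scale` (×value), `set` (:=value).

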