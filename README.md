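# mechsim

Quantitative comparison of enzyme reactions and stepwise catalytic
mechanisms from bond-change information.

Each reaction is represented as the **set of bond changes** (bond formed
`f`, cleaved `c`, increased in order `i`, decreased in order `d`,
identified by an unordered element pair) in the overall transformation, and
its mechanism as an ordered sequence of steps, each carrying its own
bond-change set. The package computes:

- **Overall reaction similarity** — Tanimoto coefficient between the two
  overall bond-change sets, maximized over the two reaction directions
  (reversing a reaction inverts every bond change).
- **Mechanistic similarity** — per-step Tanimoto coefficients fill a
  similarity matrix; a global alignment with zero gap penalties yields a
  score `S`, converted to a mechanism-level Tanimoto `S/(n1+n2−S)`.
  Direction and (where curation allows) circular permutation of steps are
  searched explicitly. A local-alignment variant and exhaustive
  identical-step detection are also provided.
- **Size normalization** — every score can be divided by the maximum
  attainable given the two set sizes / step counts
  (`min/(min+max−min)`), so that a perfect subset scores 1.
- **Significance statistics** — dataset-vs-background confusion matrices at
  every observed cutoff, precision/recall/F-measure/MCC, F-optimal and
  empirical 5%-significance cutoffs, enrichment factors, and ROC curves
  with trapezium-rule AUC. Background sets are assembled by seeded
  iterative random selection so that no two entries share an EC
  sub-subclass or a structural superfamily.
- **Synthetic fixtures** — a seeded generator for reaction entries, analog
  pairs (controlled perturbations) and background ensembles, so the whole
  pipeline is testable without any external data.

Preprocessing follows the published protocol: spontaneous (non-enzymatic)
steps are removed and the overall reaction re-annotated accordingly;
stereochemistry-only (`involved`) records are stripped on input.

## Data formats

Reaction collections are JSON (see `schema/reaction.schema.json`) or TSV
(one row per reaction part, changes encoded `f:C-O;c:O-H`). Example record:

```json
{
  "id": "M0047",
  "ec": "3.1.3.48",
  "superfamilies": ["3.90.190.10"],
  "overall": [{"kind": "c", "bond": ["O", "P"]}, {"kind": "f", "bond": ["O", "P"]}],
  "mechanism": [
    {"index": 1, "spontaneous": false,
     "changes": [{"kind": "c", "bond": ["O", "P"]}, {"kind": "f", "bond": ["O", "P"]}]}
  ],
  "permutation_allowed": true
}
```

`permutation_allowed` marks mechanisms whose end-of-sequence proton
transfers may be circularly permuted; a curated reference whitelist is
applied by default when the flag is absent.

## CLI

```sh
mechsim validate reactions.json
mechsim compare reactions.json M0044 M0047 [--rotations {none,whitelist,all}] [--json]
mechsim all-vs-all reactions.json [--against other.json] --out pairs.tsv
mechsim stats --dataset ds_pairs.tsv --background bg_pairs.tsv \
    --column mech_raw --alpha 0.05 --out-dir stats/
mechsim synth --seed 1 --n-background 85 --n-analog-pairs 95 --out synth.json
```

`stats` writes a per-cutoff metrics table (`threshold_metrics.tsv`), ROC
points (`roc_points.csv`) and a JSON summary with the F-optimal cutoff, the
5%-significance cutoff, the AUC and two-tier similarity labels
(`highly_similar` / `distantly_similar` / `non_similar`).

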