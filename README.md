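# psforge

Engineering protein liquid–liquid phase separation (LLPS) by single
amino-acid edits.

Many proteins form membraneless condensates by phase separation, and a
single substitution or deletion can strengthen or abolish that
behaviour — with real functional consequences for proteins such as
TDP43 or the innate-immunity DNA sensor cGAS. `psforge` is a
desk-scale toolkit for *directed* PS engineering, aimed at
computational biologists who want a fully testable pipeline they can
run on a laptop:

1. **Contact prediction** — a lightweight transformer maps a single
   sequence (no MSA) to a symmetric residue contact-probability map
   under the 10 Å Cα adjacency rule, trained with structure-derived
   contact matrices as pseudo-labels.
2. **PS scoring** — a twin-tower graph model (GIN + GAT message
   passing, attention readout, NT-Xent contrastive term, two auxiliary
   classification towers) scores the PS behaviour of a possibly
   mutated protein from its residue graph: `PS(x) ∈ [0, 1]`.
3. **Mutation recommendation** — a genetic algorithm searches edit
   space for the objective

   `fit(x) = PS(x) − PS(x_org)`

   in either direction (enhance or suppress), with an exhaustive
   single-site scan as the verification oracle.
4. **Transfer learning** — protein-specific fine-tuning on a small
   1:1-balanced mutant panel with the lower encoder blocks frozen,
   reporting paired before/after AUROC/F1 on a leakage-checked
   held-out split.

Mutations use the compact field notation: `R106C` (Arg106→Cys), `H5-`
(His5 deleted). Everything trains on synthetic, seeded data with
declared closed-form ground truth — no downloads — so every stage is
verifiable against brute-force oracles. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Recommend PS-enhancing single edits for a toy sequence, scored by the
package's declared synthetic PS rule:

```bash
$ psforge make-fixtures --out fixtures --seed 3 --n-structures 2 --panel-size 10
fixtures written to fixtures

$ printf '>toy\nMKGSYWAE\n' > toy.fasta
$ psforge recommend --fasta toy.fasta --out rec.json \
    --population 40 --generations 30 --max-edits 1 --top 3 --seed 11
token(s)               fitness
A7F                     0.1497
A7W                     0.1497
A7Y                     0.1497
```

Each line is a candidate edit with its fitness — the increase in PS
score it causes relative to the wild type. Here the search recovers
the analytically correct optimum: on this 8-residue toy under the
composition rule, replacing the alanine at position 7 with any
aromatic residue raises the PS score by 0.1497, and the three reported
candidates are exact ties (ranked by token order). `rec.json` carries
the full ranked list,
the per-generation best/mean fitness trace (non-decreasing best, by
elitism), the config echo, and the seed.

Score one specific mutant against a structure instead:

```bash
$ psforge rcm --pdb fixtures/toy_0.pdb --out toy_0.rcm.txt
44 residues -> toy_0.rcm.txt
```

The library surface mirrors the CLI: `parse_mutation_token`,
`apply_mutation_set`, `compute_rcm`, `build_residue_graph`,
`train_contact_predictor`, `train_psdm`, `score_ps`, `run_ga`,
`fine_tune` are all importable from `psforge`.

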