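# Methods

This note documents the models, the synthetic benchmark, the numerical
choices, and the limits of what the test suite demonstrates.

## Problem setting

Liquid–liquid phase separation (LLPS) drives the formation of
membraneless organelles; single amino-acid substitutions or deletions
can strengthen or abolish a protein's PS propensity, with functional
consequences (TDP43 and the DNA sensor cGAS are prominent examples).
`psforge` implements a desk-scale pipeline for *directed* PS
engineering: score the PS behaviour of a mutated protein, search
mutation space for edits that move the score in a requested direction,
and specialize the scorer to one protein from a small labelled mutant
panel.

## Mutation notation

Tokens use the compact field notation: `R106C` (substitution), `H5-`
(single-residue deletion). Published figures often typeset the deletion
marker with a typographic hyphen; any Unicode dash is normalized to the
ASCII `-` on input and all output is ASCII. Positions are 1-based in
every user-facing token and table; internal matrix indices are 0-based.
Multi-site edit sets are applied in descending position order so a
deletion never shifts the coordinates of an edit still to be applied;
two edits at one position are rejected. Only the 20 canonical amino
acids are modelled; insertions and multi-residue indels are out of
scope. Edit sets mixing substitutions and deletions are permitted but
flagged in reports, since most published panels are single-kind.

## Residue contact maps

Two residues are adjacent when their Cα atoms lie within 10 Å
(inclusive at the boundary — "within" is read as ≤, and the tie
behaviour is tested). The diagonal is fixed to 1 by convention but
excluded from every training loss and evaluation. Residues without a
resolved Cα (missing atoms, numbering gaps, altloc-only junk) are
masked, never imputed: their rows and columns carry no contacts, and a
placeholder identity at numbering gaps is never consumed because the
residue stays masked downstream. Alternate locations resolve to the
highest-occupancy conformer, first wins on ties.

Residue graphs take the masked off-diagonal contacts as edges and
always add backbone edges between sequential neighbours, so message
passing has a connected chain even when contacts are sparse or masked.

### Node features

Per residue: 20-dim one-hot, Kyte–Doolittle hydropathy, formal charge
at pH 7 (His counted +0.1), an aromaticity flag (F/W/Y/H), and a
TOP-IDP-style disorder propensity; the four scale columns are z-scored
across the alphabet. Two further blocks are appended:

* **local context** — windowed G/S, F/W/Y, and |net charge| fractions
  (±4 residues, clipped at the termini). These are the composition
  features PS predictors conventionally use; low-complexity context is
  poorly recoverable by a depth-3 message-passing encoder alone, and
  making it explicit is both cheaper and closer to field practice.
* **mutation annotation** — an edited-site flag plus the parent
  residue's full feature vector at that site (zeros elsewhere and for
  wild-type input). A mutation's effect is not identifiable from the
  mutant sequence alone; the annotation tells the encoder what changed.
  A deleted site annotates the residue now occupying its position.

## Contact predictor

A lightweight transformer maps a single sequence (no MSA, no templates)
to a symmetric contact-probability map: learned residue embeddings plus
sinusoidal positional encodings, two pre-norm attention blocks (4
heads, width 64), and a low-rank bilinear pair head. Pair logits are
averaged with their transpose *before* the sigmoid, so symmetry is
guaranteed by construction. Training is per-pair binary cross-entropy
against structure-derived contact matrices used as pseudo-labels, with
a positive-class weight defaulting to the per-example #non-contacts /
#contacts ratio (contacts are sparse); the degenerate single-class case
falls back to weight 1. Defaults (width 64, 2 layers, max length 256,
60 epochs, Adam 3e-3) are desk-scale choices that train in tens of
seconds on one CPU; all are configurable.

Evaluation uses precision@k: the k highest-probability off-diagonal
upper-triangle pairs at sequence separation ≥ `min_separation`
(default 6, the medium/long-range convention; 0/1 available for
raw-matrix comparisons), ties broken by (lower i, lower j). The metric
is invariant under strictly monotone transforms of the map.

## Phase-separation scorer

A shared graph encoder feeds three sigmoid towers plus a contrastive
projection head ("twin-tower" multi-task learning):

* target tower — significance of a mutation-driven PS change;
* auxiliary tower 1 — a pathogenicity surrogate (benign vs pathogenic
  mutants);
* auxiliary tower 2 — PS-capable vs non-PS classification;
* NT-Xent (temperature 0.5) over two stochastically augmented views of
  each graph: non-backbone edge dropout (p = 0.2) and node-feature
  masking (p = 0.1). Backbone edges are never dropped, so a view stays
  a valid residue graph of the same protein.

The encoder alternates GIN and GAT blocks (hidden width 64, depth 3:
GIN→GAT→GIN) with an attention-weighted mean readout; the heads are
single linear layers. Sharing the encoder across towers is what lets
the auxiliary tasks inject consistent structural information into the
target task. Total loss = 1.0·BCE(target) + 0.5·BCE(aux1) +
0.5·BCE(aux2) + 0.5·NT-Xent; a zero weight removes its term exactly,
so the zero-aux configuration is loss-identical to plain supervised
training (asserted by a component-trace identity test). The contrastive
term is computed on a seeded 64-graph draw per epoch to cap the cost of
its two extra encoder passes.

Training is full-batch Adam at 1e-2 for 250 epochs with a stratified
80/20 train/validation split. Optional cosine learning-rate decay and
tail weight averaging are available but off by default: on this
benchmark both measurably reduced held-out AUROC relative to plain
constant-rate training, a variance trade-off worth revisiting on
larger data. Depth-wise, 3 blocks with explicit context features
out-performed depth 5 without them at half the cost.

The ablation harness trains the full model and four knockouts (no GIN,
no GAT, no attention readout, no contrastive term) and reports
validation AUROC and parameter counts. No ordering among the variants
is asserted: the harness demonstrates that each configuration runs and
reports, not that every component helps on every dataset.

Scoring a protein end to end: apply the edit set, obtain a contact map
(either the transformer's prediction binarized at 0.5, or a supplied
structure's contact matrix — deletions drop the corresponding
row/column of the parent matrix), build the annotated residue graph,
encode, and read the target tower's sigmoid. Scores are deterministic
given model, seed, and input.

## Genetic algorithm

The objective is the signed fitness fit(x) = PS(x) − PS(x_org); for
`direction="decrease"` the GA maximizes the negation but always reports
the signed value, which lies in [−1, 1] for any scorer into [0, 1] and
is 0 at the wild type by construction. One generation: elites copied
unchanged (5%), a fresh random-immigrant fraction (10%) to keep
exploration alive after the population converges on one good edit,
then tournament selection (size 3; ties prefer fewer edits, then token
order), uniform crossover (each parental edit inherited with
probability 0.5, same-position conflicts resolved for the fitter
parent, capped at `max_edits`), and a mutation operator that adds,
removes, or resamples one edit (rate 0.3 per child). Every unique
candidate is scored once (cached); elitism makes the best-of-generation
trace non-decreasing, which is asserted on every run. An exhaustive
single-site scan (19L substitutions + L deletions) provides the exact
oracle for desk-scale verification. An optional BLOSUM62-softmax bias
for substitution sampling is available (off by default) as a hook for
preferring naturalistic exchanges.

Defaults: population 200, 50 generations, crossover 0.9; the toy
verification problem uses population 40 and 30 generations over a
160-candidate space.

## Transfer learning

Protein-specific fine-tuning mirrors small-panel practice: balance the
labelled panel 1:1 by seeded undersampling of the majority class
(never duplication), split 80/20 stratified, freeze the lower encoder
units — counting [input projection, message-passing blocks…, readout]
from the input side, default 2 — and fine-tune the rest plus the target
head with plain BCE (auxiliary towers are not re-used by default).
Frozen parameters are asserted bitwise unchanged after tuning. The
transfer gain is reported as paired before/after AUROC and F1 on the
held-out split, whose disjointness from the tuning records is enforced,
not assumed. Early stopping monitors the training loss with patience
10; zero epochs returns a model identical to the base.

## Synthetic benchmark

All labels come from a *declared* closed-form rule

    score(s) = logistic(8·f_arom + 4·f_GS − 3·f_|charge| − 2)

with f_arom the F/W/Y fraction, f_GS the maximum G/S fraction over
sliding windows of 8 residues, and f_|charge| = |#(K,R) − #(D,E)| / L.
The shape loosely follows the composition heuristics of the PS
literature (aromatic content up, low-complexity G/S stretches up, net
charge down), but the rule is a test oracle, not a scientific claim:
its job is to make every generated label recomputable to the last bit,
which the suite asserts with zero tolerance.

* A mutation counts as a *significant* PS change when |Δscore| ≥ 0.1;
  generated examples avoid a ±0.02 band around that threshold so the
  datasets are separable by design (the continuous |Δscore| is kept on
  every record as the ground-truth signal behind the binary label).
* Dataset sequences are 24 residues long, drawn with a randomly boosted
  composition group (aromatic, G/S, charged, or none) so both classes
  are populated; targets mix single-edit mutants with some unmutated
  negatives. The pathogenicity surrogate uses the same functional form
  with perturbed weights (6.5, 3.0, −4.5, −1.6).
* The transfer panel uses a *shifted* rule (w_arom −4, w_charge +2) so
  a scorer pretrained on the base rule is measurably mis-calibrated on
  the target protein. Because single edits on a 32-residue parent
  rarely clear the absolute 0.1 threshold under the shifted weights,
  the panel's significance cutoff is quantile-based over the parent's
  exhaustive single-edit space: positives are drawn from the top 40%
  of |Δscore|, negatives from the bottom 40%. The default panel is 138
  mutants at exactly 1:1 (69/69); odd sizes are rejected.
* Toy structures: ideal helices (rise 1.5 Å, 100°/residue, radius
  2.3 Å) whose contact map is the closed-form band |i−j| ≤ s — s = 6 at
  the 10 Å threshold, cross-checked against the brute-force distance
  oracle — and self-avoiding random chains (step 3.8 Å, exclusion
  3.6 Å) used as generic folds for dataset graphs. All generators are
  bit-reproducible under their seeds.

### What passing does and does not show

The generator emulates composition-driven label structure, class
balance, and protein-specific distribution shift. It does not emulate
real PS energetics, multivalent interaction networks, the length
scales of real intrinsically disordered regions, or experimental label
noise. Passing therefore
demonstrates that the pipeline's machinery — contact learning, graph
encoding, multi-task training, GA search, transfer protocol — recovers
declared structure at desk scale; it says nothing about accuracy on
real proteins, which requires real labelled data.

## Numerical choices

* All neural components run on a small reverse-mode autodiff engine
  over float64 numpy arrays written for this package; determinism is
  exact given seeds, which is what makes the bitwise reproducibility
  promises testable. Gradients are verified against finite differences.
* Softmaxes are max-shifted; the logistic is computed in its stable
  two-branch form; BCE clamps probabilities by 1e-7.
* AUROC uses the Mann–Whitney convention (half credit for ties); F1 is
  0 when positives exist but nothing is predicted positive; the
  decision threshold is 0.5 unless overridden.
* Problem sizes used by the verification runs: 200/80/80 training
  records with a 120-record fresh held-out set for the scorer, 50
  helix examples for the contact predictor, the 160-candidate toy
  space for the GA, 138-mutant panels for transfer. These sizes train
  in tens of seconds to a few minutes on one CPU and were chosen as
  the smallest scales at which the properties of interest are stable.

## Known limitations

* The contact predictor's toy family is positional (band contacts), so
  it exercises the architecture and evaluation machinery rather than
  real fold prediction.
* Significance labels require the mutation annotation channel; scoring
  an unannotated mutant sequence treats it as wild type.
* The GA models no epistasis beyond what the scorer expresses, and no
  structural constraints on edits.
* Graphs are dense in memory (n ≤ 300 by default), which is fine at
  desk scale but not for proteome-wide runs.
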