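"""Synthetic benchmark generators with declared, recomputable ground truth.

Everything the pipeline's tests train and evaluate on is generated
here, with no external downloads:

* toy chain structures (ideal helices and self-avoiding random chains)
  whose contact maps are known analytically or by brute force;
* a *declared* closed-form phase-separation propensity rule over
  sequences — ``score = logistic(w_a f_arom + w_g f_GS - w_c f_|charge|
  + b)`` — that plays the role of experimental PS labels;
* labelled target/auxiliary datasets for the twin-tower scorer; and
* a protein-specific retraining panel (138 mutants, 1:1 classes by
  default) labelled under a *shifted* rule so a pretrained scorer is
  measurably mis-calibrated on it.

The rule is a test oracle, not a scientific claim: it is loosely shaped
like the composition heuristics of the PS literature (aromatic content
up, glycine/serine low-complexity stretches up, net charge down) so the
learning task is realistic, but its only job is to make every label
recomputable to the last bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

from .graphs import NodeFeatureTable, ResidueGraph, build_residue_graph, mutation_annotation
from .mutations import (
    MutationSet,
    MutationSpec,
    apply_mutation_set,
    format_mutation_token,
)
from .psmodel import AuxiliaryDataset, GraphRecord
from .sequences import CANONICAL_AA, ProteinSequence
from .structure import StructureModel, compute_rcm

AROMATIC = set("FWY")
GS = set("GS")
POSITIVE = set("KR")
NEGATIVE = set("DE")


class GenerationError(RuntimeError):
    """Infeasible chain geometry or unreachable class balance."""


# -- the declared scoring rule --------------------------------------------


@dataclass(frozen=True)
class SyntheticRuleConfig:
    """Closed-form PS propensity rule (printed defaults).

    score = logistic(w_arom * f_arom + w_gs * f_GS_window
                     - w_charge * f_|net charge| + intercept)

    where f_arom is the F/W/Y fraction, f_GS_window the maximum G/S
    fraction over sliding windows of ``window`` residues, and
    f_|net charge| = |#(K,R) - #(D,E)| / length.
    """

    w_arom: float = 8.0
    w_gs: float = 4.0
    w_charge: float = 3.0
    intercept: float = -2.0
    window: int = 8
    label_threshold: float = 0.5
    #: |Δscore| at or above this marks a "significant PS-ability change"
    delta_threshold: float = 0.1
    #: separability margin: generated examples avoid |Δ| within
    #: (delta_threshold - margin, delta_threshold + margin)
    margin: float = 0.02

    def shifted(self) -> "SyntheticRuleConfig":
        """Target-protein rule for transfer-learning benchmarks
        (w_arom - 4, w_charge + 2)."""
        return replace(self, w_arom=self.w_arom - 4.0, w_charge=self.w_charge + 2.0)

    def pathogenicity(self) -> "SyntheticRuleConfig":
        """Correlated surrogate rule for the pathogenicity auxiliary task."""
        return replace(self, w_arom=6.5, w_gs=3.0, w_charge=4.5, intercept=-1.6)


def _logistic(u: float) -> float:
    return 1.0 / (1.0 + math.exp(-u))


def ground_truth_ps_score(
    seq: ProteinSequence | str, cfg: SyntheticRuleConfig | None = None
) -> float:
    """Pure, deterministic rule score in [0, 1]."""
    cfg = cfg or SyntheticRuleConfig()
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    length = len(residues)
    f_arom = sum(c in AROMATIC for c in residues) / length
    w = min(cfg.window, length)
    gs_flags = np.fromiter((c in GS for c in residues), dtype=float, count=length)
    window_sums = np.convolve(gs_flags, np.ones(w), mode="valid")
    f_gs = float(window_sums.max()) / w
    net = sum(c in POSITIVE for c in residues) - sum(c in NEGATIVE for c in residues)
    f_charge = abs(net) / length
    u = cfg.w_arom * f_arom + cfg.w_gs * f_gs - cfg.w_charge * f_charge + cfg.intercept
    return _logistic(u)


def ground_truth_label(
    seq: ProteinSequence | str, cfg: SyntheticRuleConfig | None = None
) -> int:
    cfg = cfg or SyntheticRuleConfig()
    return int(ground_truth_ps_score(seq, cfg) >= cfg.label_threshold)


def delta_score(
    parent: ProteinSequence, muts: MutationSet, cfg: SyntheticRuleConfig | None = None
) -> float:
    """Rule-score change caused by an edit set: score(mutant) - score(parent)."""
    cfg = cfg or SyntheticRuleConfig()
    mutant = apply_mutation_set(parent, muts)
    return ground_truth_ps_score(mutant, cfg) - ground_truth_ps_score(parent, cfg)


# -- toy structures --------------------------------------------------------


@dataclass(frozen=True)
class ToyStructureSpec:
    family: str = "ideal-helix"  # or "self-avoiding-chain"
    length: int = 30
    rise: float = 1.5       # Å per residue along the axis (helix)
    turn_deg: float = 100.0  # rotation per residue (helix)
    radius: float = 2.3     # helix radius, Å
    step: float = 3.8       # Cα-Cα step, Å (random chain)
    exclusion: float = 3.6  # self-avoidance radius, Å (random chain)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise GenerationError("toy structures need length >= 2")
        if self.family not in ("ideal-helix", "self-avoiding-chain"):
            raise GenerationError(f"unknown toy family {self.family!r}")


def helix_contact_bandwidth(
    threshold: float = 10.0,
    rise: float = 1.5,
    turn_deg: float = 100.0,
    radius: float = 2.3,
    max_check: int = 512,
) -> int:
    """Closed-form contact band of the ideal helix.

    For sequence separation k the Cα distance is
    ``d(k)^2 = (rise*k)^2 + (2 r sin(k*turn/2))^2``; the contact map is
    the band |i-j| <= s with s the largest k whose d(k) <= threshold.
    Raises if the geometry does not actually produce a clean band
    (i.e. some k <= s exceeds the threshold).
    """
    def dist(k: int) -> float:
        chord = 2.0 * radius * abs(math.sin(math.radians(turn_deg) * k / 2.0))
        return math.hypot(rise * k, chord)

    s = 0
    for k in range(1, max_check + 1):
        if dist(k) <= threshold:
            s = k
        elif rise * k > threshold:
            break
    for k in range(1, s + 1):
        if dist(k) > threshold:
            raise GenerationError(
                "helix geometry does not yield a clean contact band "
                f"(separation {k} exceeds the threshold but {s} does not)"
            )
    return s


def _helix_coords(spec: ToyStructureSpec) -> np.ndarray:
    i = np.arange(spec.length)
    theta = np.radians(spec.turn_deg) * i
    return np.column_stack(
        (spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * i)
    )


def _self_avoiding_coords(spec: ToyStructureSpec, rng: np.random.Generator) -> np.ndarray:
    for _restart in range(25):
        coords = [np.zeros(3)]
        failed = False
        for _ in range(spec.length - 1):
            placed = False
            for _try in range(60):
                v = rng.normal(size=3)
                v *= spec.step / np.linalg.norm(v)
                cand = coords[-1] + v
                prior = np.array(coords[:-1]) if len(coords) > 1 else None
                if prior is None or np.min(
                    np.linalg.norm(prior - cand, axis=1)
                ) >= spec.exclusion:
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.array(coords)
    raise GenerationError(
        f"could not grow a self-avoiding chain of length {spec.length} "
        f"(step {spec.step}, exclusion {spec.exclusion})"
    )


def generate_toy_structure(
    spec: ToyStructureSpec, sequence: ProteinSequence | None = None
) -> StructureModel:
    """Seeded toy Cα trace; sequence defaults to a uniform random one."""
    rng = np.random.default_rng(spec.seed)
    if spec.family == "ideal-helix":
        coords = _helix_coords(spec)
    else:
        coords = _self_avoiding_coords(spec, rng)
    if sequence is None:
        letters = rng.choice(list(CANONICAL_AA), size=spec.length)
        sequence = ProteinSequence(
            id=f"{spec.family}-{spec.length}-{spec.seed}", residues="".join(letters)
        )
    if len(sequence) != spec.length:
        raise GenerationError("sequence length disagrees with structure spec")
    return StructureModel(sequence, coords, np.ones(spec.length, dtype=bool))


# -- sequence sampling -----------------------------------------------------

_COMPOSITION_GROUPS = (None, tuple(AROMATIC), tuple(GS), tuple(POSITIVE | NEGATIVE))


def sample_sequence(
    rng: np.random.Generator, length: int, seq_id: str = "synthetic"
) -> ProteinSequence:
    """Random sequence with a randomly boosted composition group, so the
    rule's score distribution spans both classes."""
    weights = np.ones(20)
    group = _COMPOSITION_GROUPS[rng.integers(len(_COMPOSITION_GROUPS))]
    if group is not None:
        boost = rng.uniform(2.0, 8.0)
        for aa in group:
            weights[CANONICAL_AA.index(aa)] *= boost
    probs = weights / weights.sum()
    letters = rng.choice(list(CANONICAL_AA), size=length, p=probs)
    return ProteinSequence(id=seq_id, residues="".join(letters))


def enumerate_single_edits(parent: ProteinSequence) -> list[MutationSet]:
    """All 19 L substitutions + L deletions as singleton edit sets."""
    out = []
    for pos in range(1, len(parent) + 1):
        ref = parent.residue_at(pos)
        for alt in CANONICAL_AA:
            if alt != ref:
                out.append(MutationSet([MutationSpec(pos, ref, alt)]))
        out.append(MutationSet([MutationSpec(pos, ref, kind="deletion")]))
    return out


# -- graph-bearing records -------------------------------------------------


def _graph_for(
    seq: ProteinSequence,
    seed: int,
    features: NodeFeatureTable,
    annotation: dict[int, str] | None = None,
    threshold: float = 10.0,
) -> ResidueGraph:
    """Residue graph over a seeded self-avoiding-chain structure."""
    spec = ToyStructureSpec(
        family="self-avoiding-chain", length=len(seq), seed=seed
    )
    model = generate_toy_structure(spec, seq)
    return build_residue_graph(compute_rcm(model, threshold), seq, features, annotation)


def _classified_edits(
    parent: ProteinSequence, cfg: SyntheticRuleConfig
) -> tuple[list[tuple[MutationSet, float]], list[tuple[MutationSet, float]]]:
    """Single edits split into significant / non-significant pools with a
    separability margin around the |Δscore| threshold."""
    pos_pool, neg_pool = [], []
    for muts in enumerate_single_edits(parent):
        d = abs(delta_score(parent, muts, cfg))
        if d >= cfg.delta_threshold + cfg.margin:
            pos_pool.append((muts, d))
        elif d <= cfg.delta_threshold - cfg.margin:
            neg_pool.append((muts, d))
    return pos_pool, neg_pool


def _mutant_record(
    parent: ProteinSequence,
    muts: MutationSet,
    label: int,
    signal: float,
    seed: int,
    features: NodeFeatureTable,
    role: str,
) -> GraphRecord:
    mutant = apply_mutation_set(parent, muts)
    graph = _graph_for(mutant, seed, features, mutation_annotation(parent, muts))
    return GraphRecord(
        graph=graph,
        label=label,
        signal=signal,
        meta={
            "parent": parent.residues,
            "parent_id": parent.id,
            "tokens": muts.tokens(),
            "role": role,
        },
    )


def _sample_mutant_records(
    n: int,
    rule: SyntheticRuleConfig,
    rng: np.random.Generator,
    features: NodeFeatureTable,
    role: str,
    length: int,
    unmutated_negative_fraction: float = 0.25,
    max_parent_tries: int | None = None,
) -> list[GraphRecord]:
    """Balanced mutation-change records: positives carry a significant
    |Δscore| edit, negatives a non-significant edit or no edit at all."""
    max_parent_tries = max_parent_tries or (20 * n + 200)
    records: list[GraphRecord] = []
    want = [1, 0] * (n // 2) + [1] * (n % 2)
    tries = 0
    while want:
        tries += 1
        if tries > max_parent_tries:
            raise GenerationError(
                f"class balance unreachable for role {role!r} after "
                f"{max_parent_tries} parent draws"
            )
        parent = sample_sequence(rng, length, f"{role}-parent-{tries}")
        label = want[-1]
        if label == 0 and rng.random() < unmutated_negative_fraction:
            graph = _graph_for(parent, int(rng.integers(2**31)), features)
            records.append(
                GraphRecord(graph, 0, signal=0.0,
                            meta={"parent": parent.residues,
                                  "parent_id": parent.id,
                                  "tokens": [], "role": role})
            )
            want.pop()
            continue
        pos_pool, neg_pool = _classified_edits(parent, rule)
        pool = pos_pool if label == 1 else neg_pool
        if not pool:
            continue
        muts, d = pool[rng.integers(len(pool))]
        records.append(
            _mutant_record(parent, muts, label, d,
                           int(rng.integers(2**31)), features, role)
        )
        want.pop()
    rng.shuffle(records)
    return records


def sample_labeled_datasets(
    n_target: int,
    n_aux1: int,
    n_aux2: int,
    seed: int,
    length: int = 24,
    rule: SyntheticRuleConfig | None = None,
) -> tuple[list[GraphRecord], AuxiliaryDataset, AuxiliaryDataset]:
    """Target + two auxiliary datasets, all labels recomputable.

    target: single-edit mutants (plus some unmutated sequences) labelled
    by significance of the rule-score change;
    aux1 ("pathogenicity"): mutants labelled the same way under a
    correlated perturbed rule;
    aux2 ("ps_classification"): plain sequences labelled by the rule
    score against 0.5.
    """
    if min(n_target, n_aux1, n_aux2) < 4:
        raise GenerationError("dataset sizes must be >= 4")
    rule = rule or SyntheticRuleConfig()
    features = NodeFeatureTable.default()
    rng = np.random.default_rng(seed)

    target = _sample_mutant_records(
        n_target, rule, rng, features, "target", length
    )
    aux1_records = _sample_mutant_records(
        n_aux1, rule.pathogenicity(), rng, features, "pathogenicity", length,
        unmutated_negative_fraction=0.0,
    )

    aux2_records: list[GraphRecord] = []
    need = {1: n_aux2 - n_aux2 // 2, 0: n_aux2 // 2}
    tries = 0
    while need[0] + need[1] > 0:
        tries += 1
        if tries > 200 * n_aux2:
            raise GenerationError("class balance unreachable for aux2")
        seq = sample_sequence(rng, length, f"aux2-{tries}")
        score = ground_truth_ps_score(seq, rule)
        label = int(score >= rule.label_threshold)
        if need[label] == 0:
            continue
        need[label] -= 1
        graph = _graph_for(seq, int(rng.integers(2**31)), features)
        aux2_records.append(
            GraphRecord(graph, label, signal=score,
                        meta={"parent": seq.residues, "parent_id": seq.id,
                              "tokens": [], "role": "ps_classification"})
        )
    rng.shuffle(aux2_records)

    return (
        target,
        AuxiliaryDataset("pathogenicity", aux1_records),
        AuxiliaryDataset("ps_classification", aux2_records),
    )


# -- protein-specific retraining panel ------------------------------------


@dataclass
class PanelRecord:
    """One labelled mutant of the retraining panel."""

    parent_id: str
    token: str
    label: int
    signal: float
    graph: ResidueGraph


def default_panel_parent(seed: int = 0, length: int = 32) -> ProteinSequence:
    """A parent whose shifted-rule score sits away from saturation, so
    single edits can move it measurably."""
    rng = np.random.default_rng(seed)
    shifted = SyntheticRuleConfig().shifted()
    for i in range(2000):
        seq = sample_sequence(rng, length, f"panel-parent-{seed}-{i}")
        if 0.25 <= ground_truth_ps_score(seq, shifted) <= 0.75:
            return ProteinSequence(id=f"panel-parent-{seed}", residues=seq.residues)
    raise GenerationError("no suitable panel parent found")


def make_retraining_panel(
    parent_seq: ProteinSequence,
    n: int = 138,
    seed: int = 0,
    rule: SyntheticRuleConfig | None = None,
) -> list[PanelRecord]:
    """Exactly ``n`` single-site mutants of one parent at 1:1 class balance.

    Labels come from the *shifted* rule: the panel's significance cutoff
    is quantile-based over the parent's exhaustive single-edit space
    (positives drawn from the top 40% of |Δscore|, negatives from the
    bottom 40%), emulating protein-specific behaviour a base model
    pretrained on the unshifted rule has not seen.
    """
    if n % 2:
        raise GenerationError(f"panel size must be even for 1:1 balance, got {n}")
    if len(parent_seq) < 20:
        raise GenerationError("panel parent must have length >= 20")
    rule = rule or SyntheticRuleConfig()
    shifted = rule.shifted()
    features = NodeFeatureTable.default()
    rng = np.random.default_rng(seed)

    edits = enumerate_single_edits(parent_seq)
    deltas = np.array([abs(delta_score(parent_seq, m, shifted)) for m in edits])
    order = np.argsort(deltas, kind="stable")
    k = int(0.4 * len(edits))
    neg_pool, pos_pool = order[:k], order[-k:]
    if min(len(neg_pool), len(pos_pool)) < n // 2:
        raise GenerationError(
            f"parent admits only {min(len(neg_pool), len(pos_pool))} edits per "
            f"class, need {n // 2}"
        )
    chosen_pos = rng.choice(pos_pool, size=n // 2, replace=False)
    chosen_neg = rng.choice(neg_pool, size=n // 2, replace=False)

    panel: list[PanelRecord] = []
    for label, chosen in ((1, chosen_pos), (0, chosen_neg)):
        for idx in chosen:
            muts = edits[idx]
            mutant = apply_mutation_set(parent_seq, muts)
            graph = _graph_for(
                mutant, int(rng.integers(2**31)), features,
                mutation_annotation(parent_seq, muts),
            )
            panel.append(
                PanelRecord(
                    parent_id=parent_seq.id,
                    token=format_mutation_token(muts.specs[0]),
                    label=label,
                    signal=float(deltas[idx]),
                    graph=graph,
                )
            )
    rng.shuffle(panel)
    return panel


# -- contact-predictor training sets --------------------------------------


def make_contact_training_set(
    n_examples: int,
    seed: int,
    min_length: int = 30,
    max_length: int = 48,
    threshold: float = 10.0,
) -> list:
    """Ideal-helix sequences paired with their exact contact matrices."""
    from .contact_model import ContactTrainingExample

    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n_examples):
        length = int(rng.integers(min_length, max_length + 1))
        spec = ToyStructureSpec(
            family="ideal-helix", length=length, seed=int(rng.integers(2**31))
        )
        model = generate_toy_structure(spec)
        examples.append(ContactTrainingExample(model.sequence, compute_rcm(model, threshold)))
    return examples
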