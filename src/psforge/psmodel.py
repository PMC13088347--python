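"""Phase-separation scoring with a twin-tower graph-contrastive model.

A shared graph encoder (GIN and GAT message passing with a
self-attention readout) feeds three sigmoid classification towers:

* the *target* tower — does this (possibly mutated) protein show a
  significant change in phase-separation behaviour;
* auxiliary tower 1 — a pathogenicity surrogate (benign vs pathogenic
  style labels on mutants);
* auxiliary tower 2 — PS-capable vs non-PS protein classification;

plus an NT-Xent contrastive term over stochastically augmented views
(edge dropout + feature masking) of the same graph.  Sharing the
encoder across towers is what lets the auxiliary tasks transfer
consistent structural information into the target task.

The model's scalar output (the PS score) is the sigmoid of the target
tower and lives in [0, 1]; the genetic-algorithm fitness downstream is
the difference of two such scores.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import metrics
from .contact_model import ContactPredictor, contact_map_to_rcm, predict_contact_map
from .graphs import (
    FEATURE_DIM,
    NodeFeatureTable,
    ResidueGraph,
    build_residue_graph,
    mutation_annotation,
)
from .mutations import MutationSet
from .nn import Adam, Tensor
from .nn.layers import (
    AttentionReadout,
    GATLayer,
    GINLayer,
    Linear,
    MeanReadout,
    MLP,
    Module,
)
from .sequences import ProteinSequence
from .structure import ResidueContactMatrix, StructureModel, compute_rcm


class PSModelError(RuntimeError):
    """Configuration or training failures of the PS scorer."""


@dataclass
class GraphEncoderConfig:
    enable_gin: bool = True
    enable_gat: bool = True
    enable_self_attention: bool = True
    hidden: int = 64
    depth: int = 3
    readout: str = "attention"
    temperature: float = 0.5
    p_edge: float = 0.2
    p_feat: float = 0.1
    w_target: float = 1.0
    w_aux1: float = 0.5
    w_aux2: float = 0.5
    w_contrastive: float = 0.5
    #: graphs drawn (seeded, per epoch) for the contrastive term; caps the
    #: cost of the two extra encoder passes on large target sets
    contrastive_batch: int = 64
    learning_rate: float = 1e-2
    #: cosine decay of the learning rate to this fraction of its start
    #: value; 1.0 keeps the rate constant
    lr_floor_fraction: float = 1.0
    epochs: int = 250
    validation_fraction: float = 0.2
    #: optionally average the weights of the final fraction of epochs
    #: (stochastic weight averaging); 0 returns the last epoch's weights
    tail_average_fraction: float = 0.0
    max_nodes: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.enable_gin or self.enable_gat or self.enable_self_attention):
            raise PSModelError("at least one encoder component must be enabled")
        for name in ("w_target", "w_aux1", "w_aux2", "w_contrastive"):
            if getattr(self, name) < 0:
                raise PSModelError(f"{name} must be non-negative")
        for name in ("p_edge", "p_feat"):
            if not 0 <= getattr(self, name) < 1:
                raise PSModelError(f"{name} must lie in [0, 1)")
        if self.hidden <= 0 or self.depth < 0:
            raise PSModelError("hidden width must be positive, depth >= 0")
        if self.temperature <= 0:
            raise PSModelError("contrastive temperature must be positive")


@dataclass
class GraphRecord:
    """One labelled graph; ``signal`` is the generator's continuous
    ground-truth quantity behind the binary label (when known)."""

    graph: ResidueGraph
    label: int
    signal: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class AuxiliaryDataset:
    role: str  # "pathogenicity" | "ps_classification"
    records: list[GraphRecord]

    def __post_init__(self) -> None:
        if self.role not in ("pathogenicity", "ps_classification"):
            raise PSModelError(f"unknown auxiliary role {self.role!r}")
        labels = {r.label for r in self.records}
        if labels != {0, 1}:
            raise PSModelError(
                f"auxiliary dataset {self.role!r} must contain both classes"
            )


@dataclass(frozen=True)
class PSScore:
    value: float
    model_id: str
    input_digest: str


# -- model ----------------------------------------------------------------


class PhaseSeparationModel(Module):
    """Shared graph encoder + three sigmoid towers + projection head."""

    def __init__(self, cfg: GraphEncoderConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden
        self.input_proj = Linear(rng, FEATURE_DIM, d)
        kinds: list[str] = []
        for i in range(cfg.depth):
            if cfg.enable_gin and cfg.enable_gat:
                kinds.append("gin" if i % 2 == 0 else "gat")
            elif cfg.enable_gin:
                kinds.append("gin")
            elif cfg.enable_gat:
                kinds.append("gat")
        self.blocks = [
            GINLayer(rng, d, d) if kind == "gin" else GATLayer(rng, d, d)
            for kind in kinds
        ]
        self.block_kinds = kinds
        use_attn = cfg.enable_self_attention and cfg.readout == "attention"
        self.readout = AttentionReadout(rng, d) if use_attn else MeanReadout()
        self.head_target = Linear(rng, d, 1)
        self.head_aux1 = Linear(rng, d, 1)
        self.head_aux2 = Linear(rng, d, 1)
        self.projection = MLP(rng, d, d, d)
        self._refs: dict = {}  # non-trainable attachments (contact predictor)

    # encoder ------------------------------------------------------------

    def embed_batch(self, feats: Tensor, adj: Tensor) -> Tensor:
        """(B, n, F), (B, n, n) -> (B, hidden) graph embeddings."""
        h = self.input_proj(feats).relu()
        for block in self.blocks:
            h = block(h, adj)
        return self.readout(h)

    def head_probs(self, emb: Tensor, head: str = "target") -> Tensor:
        layer = {"target": self.head_target, "aux1": self.head_aux1,
                 "aux2": self.head_aux2}[head]
        return layer(emb).sigmoid().reshape(emb.shape[0])

    # attachments --------------------------------------------------------

    @property
    def contact_predictor(self) -> ContactPredictor | None:
        return self._refs.get("contact")

    def attach_contact_predictor(self, model: ContactPredictor) -> None:
        self._refs["contact"] = model

    @property
    def model_id(self) -> str:
        cfg = self.cfg
        return f"ps-scorer(h={cfg.hidden},depth={cfg.depth},seed={cfg.seed})"


def _stack(records: Sequence[GraphRecord]) -> list[tuple[Tensor, Tensor, np.ndarray, np.ndarray]]:
    """Group records by node count into dense (feats, adj, labels, idx) batches."""
    by_n: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_n.setdefault(rec.graph.node_count, []).append(i)
    groups = []
    for n in sorted(by_n):
        idx = np.array(by_n[n])
        feats = np.stack([records[i].graph.node_features for i in idx])
        adj = np.stack([records[i].graph.adjacency.astype(float) for i in idx])
        labels = np.array([records[i].label for i in idx], dtype=float)
        groups.append((Tensor(feats), Tensor(adj), labels, idx))
    return groups


def encode_graph(model: PhaseSeparationModel, g: ResidueGraph) -> np.ndarray:
    """Permutation-invariant fixed-width embedding of one residue graph."""
    if g.node_count < 1:
        raise PSModelError("cannot encode an empty graph")
    from .nn import no_grad

    with no_grad():
        feats = Tensor(g.node_features[None])
        adj = Tensor(g.adjacency.astype(float)[None])
        return model.embed_batch(feats, adj).data[0]


# -- augmentation & losses -------------------------------------------------


def augment_view(
    g: ResidueGraph, p_edge: float, p_feat: float, seed: int | np.random.Generator
) -> ResidueGraph:
    """Random view for contrastive learning.

    Non-backbone edges are dropped independently with probability
    ``p_edge``; node feature rows are zero-masked with probability
    ``p_feat``.  Backbone edges are never dropped and the node count is
    preserved, so the view stays a valid residue graph of the same
    protein.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = g.node_count
    adj = g.adjacency.astype(bool).copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    non_backbone = ju - iu > 1
    drop = non_backbone & (rng.random(iu.size) < p_edge)
    adj[iu[drop], ju[drop]] = adj[ju[drop], iu[drop]] = False
    feats = g.node_features.copy()
    mask_rows = rng.random(n) < p_feat
    feats[mask_rows] = 0.0
    return ResidueGraph(adj.astype(np.uint8), feats)


def _bce(probs: Tensor, labels: np.ndarray) -> Tensor:
    eps = 1e-7
    y = Tensor(labels)
    nll = -(y * (probs + eps).log() + (1.0 - y) * (1.0 - probs + eps).log())
    return nll.mean()


def nt_xent(z: Tensor, temperature: float = 0.5) -> Tensor:
    """Normalized temperature-scaled cross entropy.

    ``z`` holds 2B projected embeddings where rows i and i+B are the two
    views of the same graph; every other row in the batch is a negative.
    """
    two_b = z.shape[0]
    if two_b < 4 or two_b % 2:
        raise PSModelError("contrastive batch needs >= 2 graphs, two views each")
    b = two_b // 2
    norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
    zn = z / norm
    sim = (zn @ zn.swapaxes(-1, -2)) * (1.0 / temperature)
    sim = sim + Tensor(np.eye(two_b) * -1e9)  # self-similarity excluded
    soft = sim.softmax(axis=-1)
    pos = np.zeros((two_b, two_b))
    pos[np.arange(two_b), (np.arange(two_b) + b) % two_b] = 1.0
    picked = (soft * Tensor(pos)).sum(axis=-1)
    return -((picked + 1e-12).log().mean())


def twin_tower_loss(
    model: PhaseSeparationModel,
    target_batch: Sequence[GraphRecord] | None,
    aux1_batch: Sequence[GraphRecord] | None,
    aux2_batch: Sequence[GraphRecord] | None,
    contrastive_records: Sequence[GraphRecord] | None,
    rng: np.random.Generator | None = None,
    weights: tuple[float, float, float, float] | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Weighted multi-task loss; a zero weight removes its term exactly.

    Returns the total loss tensor plus the individually reported
    component values.
    """
    cfg = model.cfg
    w_t, w_1, w_2, w_c = weights or (
        cfg.w_target, cfg.w_aux1, cfg.w_aux2, cfg.w_contrastive
    )
    if w_t == w_1 == w_2 == w_c == 0:
        raise PSModelError("all loss weights are zero")
    rng = rng or np.random.default_rng(cfg.seed)
    total: Tensor | None = None
    components: dict[str, float] = {}

    def add(term: Tensor, weight: float, name: str) -> None:
        nonlocal total
        components[name] = term.item()
        weighted = term * weight
        total = weighted if total is None else total + weighted

    for name, weight, head, batch in (
        ("target", w_t, "target", target_batch),
        ("aux1", w_1, "aux1", aux1_batch),
        ("aux2", w_2, "aux2", aux2_batch),
    ):
        if weight == 0 or batch is None:
            continue
        if len(batch) == 0:
            raise PSModelError(f"empty {name} batch with non-zero weight")
        term: Tensor | None = None
        for feats, adj, labels, _ in _stack(batch):
            emb = model.embed_batch(feats, adj)
            part = _bce(model.head_probs(emb, head), labels) * (
                len(labels) / len(batch)
            )
            term = part if term is None else term + part
        add(term, weight, name)

    if w_c > 0 and contrastive_records:
        term = None
        count = 0
        for feats, adj, _labels, idx in _stack(contrastive_records):
            if len(idx) < 2:
                continue
            views_a, views_b = [], []
            for i in idx:
                g = contrastive_records[i].graph
                views_a.append(augment_view(g, cfg.p_edge, cfg.p_feat, rng))
                views_b.append(augment_view(g, cfg.p_edge, cfg.p_feat, rng))
            fa = Tensor(np.stack([v.node_features for v in views_a]))
            aa = Tensor(np.stack([v.adjacency.astype(float) for v in views_a]))
            fb = Tensor(np.stack([v.node_features for v in views_b]))
            ab = Tensor(np.stack([v.adjacency.astype(float) for v in views_b]))
            za = model.projection(model.embed_batch(fa, aa))
            zb = model.projection(model.embed_batch(fb, ab))
            z = _concat_rows(za, zb)
            part = nt_xent(z, cfg.temperature) * len(idx)
            term = part if term is None else term + part
            count += len(idx)
        if term is not None:
            add(term * (1.0 / count), w_c, "contrastive")

    if total is None:
        raise PSModelError("no loss terms were computed")
    return total, components


def _concat_rows(a: Tensor, b: Tensor) -> Tensor:
    from .nn.autograd import concat

    return concat([a, b], axis=0)


# -- training -------------------------------------------------------------


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def predict_records(
    model: PhaseSeparationModel, records: Sequence[GraphRecord],
    head: str = "target",
) -> np.ndarray:
    """Sigmoid tower outputs for a list of graph records (eval mode)."""
    from .nn import no_grad

    scores = np.empty(len(records))
    with no_grad():
        for feats, adj, _labels, idx in _stack(records):
            emb = model.embed_batch(feats, adj)
            scores[idx] = model.head_probs(emb, head).data
    return scores


def train_psdm(
    target: Sequence[GraphRecord],
    aux1: AuxiliaryDataset | None,
    aux2: AuxiliaryDataset | None,
    cfg: GraphEncoderConfig | None = None,
) -> tuple[PhaseSeparationModel, dict]:
    """Train the twin-tower scorer; returns (model, training report).

    The target set is split into stratified train/validation parts;
    the report carries per-epoch component losses and the final
    validation AUROC.
    """
    cfg = cfg or GraphEncoderConfig()
    labels = np.array([r.label for r in target])
    if len(np.unique(labels)) < 2:
        raise PSModelError("target dataset must contain both classes")
    rng = np.random.default_rng(cfg.seed + 10_000)
    train_idx, val_idx = _stratified_split(labels, cfg.validation_fraction, rng)
    train_recs = [target[i] for i in train_idx]
    val_recs = [target[i] for i in val_idx]

    model = PhaseSeparationModel(cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    trace: list[dict[str, float]] = []
    val_labels = np.array([r.label for r in val_recs])
    tail_start = int(np.ceil(cfg.epochs * (1 - cfg.tail_average_fraction)))
    tail_sum: list[np.ndarray] | None = None
    tail_count = 0
    for _epoch in range(cfg.epochs):
        # cosine learning-rate decay
        frac = 0.5 * (1 + np.cos(np.pi * _epoch / max(cfg.epochs - 1, 1)))
        opt.lr = cfg.learning_rate * (
            cfg.lr_floor_fraction + (1 - cfg.lr_floor_fraction) * frac
        )
        opt.zero_grad()
        contrastive: list[GraphRecord] | None = None
        if cfg.w_contrastive > 0:
            if len(train_recs) > cfg.contrastive_batch:
                pick = rng.choice(len(train_recs), size=cfg.contrastive_batch,
                                  replace=False)
                contrastive = [train_recs[int(i)] for i in pick]
            else:
                contrastive = train_recs
        loss, components = twin_tower_loss(
            model,
            train_recs,
            aux1.records if (aux1 and cfg.w_aux1 > 0) else None,
            aux2.records if (aux2 and cfg.w_aux2 > 0) else None,
            contrastive,
            rng=rng,
        )
        if not np.isfinite(loss.data):
            raise PSModelError(f"non-finite loss at epoch {_epoch}")
        loss.backward()
        opt.step()
        components["total"] = loss.item()
        trace.append(components)
        if cfg.tail_average_fraction > 0 and _epoch >= tail_start:
            state = model.state_arrays()
            if tail_sum is None:
                tail_sum = state
            else:
                for acc, arr in zip(tail_sum, state):
                    acc += arr
            tail_count += 1

    if tail_sum is not None and tail_count > 1:
        model.load_state_arrays([acc / tail_count for acc in tail_sum])
    report = {
        "trace": trace,
        "validation_auroc": metrics.auroc(
            predict_records(model, val_recs), val_labels
        ),
        "tail_averaged_epochs": tail_count,
        "n_train": len(train_recs),
        "n_validation": len(val_recs),
        "config": asdict(cfg),
        "seed": cfg.seed,
    }
    return model, report


# -- end-to-end scoring ----------------------------------------------------


def _rcm_for_mutant(
    structure: StructureModel, muts: MutationSet, threshold: float = 10.0
) -> ResidueContactMatrix:
    """Parent-structure contact matrix with deleted residues removed."""
    rcm = compute_rcm(structure, threshold)
    del_pos = sorted(s.position - 1 for s in muts if s.is_deletion)
    if not del_pos:
        return rcm
    keep = np.setdiff1d(np.arange(rcm.n), del_pos)
    return ResidueContactMatrix(
        rcm.entries[np.ix_(keep, keep)], rcm.mask[keep], rcm.threshold
    )


def score_ps(
    model: PhaseSeparationModel,
    seq: ProteinSequence,
    contact_source: str = "predicted",
    muts: MutationSet | None = None,
    structure: StructureModel | None = None,
    features: NodeFeatureTable | None = None,
    binarize_threshold: float = 0.5,
) -> PSScore:
    """PS score of a (possibly mutated) protein in [0, 1].

    Pipeline: apply mutations -> contact map (transformer prediction or
    the supplied structure's contact matrix) -> annotated residue graph
    -> shared encoder -> target tower sigmoid.
    """
    muts = muts or MutationSet()
    from .mutations import apply_mutation_set

    mutant = apply_mutation_set(seq, muts)
    annotation = mutation_annotation(seq, muts) if len(muts) else None
    if contact_source == "predicted":
        predictor = model.contact_predictor
        if predictor is None:
            raise PSModelError(
                "contact_source='predicted' requires an attached contact predictor"
            )
        rcm = contact_map_to_rcm(
            predict_contact_map(predictor, mutant), binarize_threshold
        )
    elif contact_source == "structure":
        if structure is None:
            raise PSModelError("contact_source='structure' requires a StructureModel")
        if structure.n != len(seq):
            raise PSModelError(
                f"structure has {structure.n} residues, sequence {len(seq)}"
            )
        rcm = _rcm_for_mutant(structure, muts)
    else:
        raise PSModelError(f"unknown contact source {contact_source!r}")

    if rcm.n > model.cfg.max_nodes:
        raise PSModelError(
            f"graph of {rcm.n} residues exceeds configured maximum "
            f"{model.cfg.max_nodes}"
        )
    graph = build_residue_graph(rcm, mutant, features, annotation)
    emb = encode_graph(model, graph)
    from .nn import no_grad

    with no_grad():
        value = float(model.head_probs(Tensor(emb[None]), "target").data[0])
    digest = hashlib.sha1(
        (mutant.residues + "|" + "+".join(muts.tokens())).encode()
    ).hexdigest()[:16]
    return PSScore(value=value, model_id=model.model_id, input_digest=digest)


def make_sequence_scorer(
    model: PhaseSeparationModel,
    contact_source: str = "predicted",
    structure: StructureModel | None = None,
) -> Callable[[ProteinSequence, MutationSet | None], float]:
    """Close over a model as a plain ``(seq, muts) -> [0,1]`` scorer for the GA."""

    def scorer(seq: ProteinSequence, muts: MutationSet | None = None) -> float:
        return score_ps(
            model, seq, contact_source=contact_source, muts=muts,
            structure=structure,
        ).value

    return scorer


# -- user-supplied labelled datasets ---------------------------------------


def load_labeled_dataset_csv(
    path: str | Path,
    features: NodeFeatureTable | None = None,
    contact_predictor: ContactPredictor | None = None,
    seed: int = 0,
    threshold: float = 10.0,
) -> dict[str, list[GraphRecord]]:
    """Read a labelled dataset table into graph records, grouped by role.

    Columns: ``id``, ``label`` (0/1), ``role`` (``target`` |
    ``pathogenicity`` | ``ps_classification``), and either ``sequence``
    (the full, possibly mutated sequence) or ``parent_sequence`` +
    ``token`` (a mutation applied to a parent, which also fills the
    annotation channel).  Contact maps come from the supplied predictor
    when given, otherwise from seeded self-avoiding-chain folds.
    """
    import csv as _csv

    from .mutations import apply_mutation_set, parse_mutation_token

    features = features or NodeFeatureTable.default()
    rng = np.random.default_rng(seed)
    out: dict[str, list[GraphRecord]] = {}
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        for i, row in enumerate(reader):
            role = row.get("role", "target").strip()
            annotation = None
            if row.get("token"):
                parent = ProteinSequence(row["id"], row["parent_sequence"])
                muts = MutationSet([parse_mutation_token(row["token"])])
                seq = apply_mutation_set(parent, muts)
                annotation = mutation_annotation(parent, muts)
            else:
                seq = ProteinSequence(row["id"], row["sequence"])
            if contact_predictor is not None:
                rcm = contact_map_to_rcm(
                    predict_contact_map(contact_predictor, seq)
                )
            else:
                from .synthetic import ToyStructureSpec, generate_toy_structure

                spec = ToyStructureSpec(
                    family="self-avoiding-chain", length=len(seq),
                    seed=int(rng.integers(2**31)),
                )
                rcm = compute_rcm(generate_toy_structure(spec, seq), threshold)
            graph = build_residue_graph(rcm, seq, features, annotation)
            out.setdefault(role, []).append(
                GraphRecord(graph, int(row["label"]),
                            meta={"parent_id": row["id"],
                                  "tokens": [row["token"]] if row.get("token")
                                  else [], "role": role, "row": i})
            )
    return out


# -- ablation harness ------------------------------------------------------


ABLATION_VARIANTS = ("full", "no_gin", "no_gat", "no_attention", "no_contrastive")


def ablation_configs(base: GraphEncoderConfig) -> dict[str, GraphEncoderConfig]:
    """The four single-component knockouts next to the full model."""
    variants = {}
    for name in ABLATION_VARIANTS:
        kwargs = asdict(base)
        if name == "no_gin":
            kwargs["enable_gin"] = False
        elif name == "no_gat":
            kwargs["enable_gat"] = False
        elif name == "no_attention":
            kwargs["enable_self_attention"] = False
        elif name == "no_contrastive":
            kwargs["w_contrastive"] = 0.0
        variants[name] = GraphEncoderConfig(**kwargs)
    return variants


def run_ablation(
    target: Sequence[GraphRecord],
    aux1: AuxiliaryDataset | None,
    aux2: AuxiliaryDataset | None,
    base_cfg: GraphEncoderConfig,
) -> dict[str, dict]:
    """Train every ablation variant and report validation AUROC + size.

    No ordering among variants is asserted anywhere: the harness only
    guarantees that each configuration runs and reports.
    """
    out = {}
    for name, cfg in ablation_configs(base_cfg).items():
        model, report = train_psdm(target, aux1, aux2, cfg)
        out[name] = {
            "validation_auroc": report["validation_auroc"],
            "n_parameters": int(sum(p.data.size for p in model.parameters())),
        }
    return out


# -- checkpointing ---------------------------------------------------------


def save_ps_model(model: PhaseSeparationModel, path: str | Path) -> None:
    buf = io.BytesIO()
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(buf, config=json.dumps(asdict(model.cfg)), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_ps_model(path: str | Path) -> PhaseSeparationModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = GraphEncoderConfig(**json.loads(str(data["config"])))
        model = PhaseSeparationModel(cfg)
        model.load_state_arrays(
            [data[f"arr_{i}"] for i in range(len(model.parameters()))]
        )
    return model
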