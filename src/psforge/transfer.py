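"""Protein-specific fine-tuning of a trained PS scorer.

The protocol mirrors how small mutant panels are used in practice:
balance the labelled panel 1:1 by undersampling the majority class,
freeze the lower encoder blocks so general feature extraction is
preserved, fine-tune the rest on the panel, and quantify the transfer
gain as paired before/after metrics on a held-out split that is
enforced (not assumed) to be disjoint from the tuning records.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import metrics
from .nn import Adam
from .psmodel import (
    GraphRecord,
    PhaseSeparationModel,
    _bce,
    _stack,
    _stratified_split,
    predict_records,
)
from .synthetic import PanelRecord


class TransferError(RuntimeError):
    """Balancing, freezing, or leakage violations."""


@dataclass
class TLConfig:
    #: number of encoder units frozen from the input side, counting
    #: [input projection, message-passing blocks..., readout]; the target
    #: head is always trainable.
    freeze_blocks: int = 2
    epochs: int = 30
    learning_rate: float = 5e-3
    patience: int = 10
    balance: str = "undersample"
    heldout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise TransferError("epochs must be >= 0")
        if self.freeze_blocks < 0:
            raise TransferError("freeze_blocks must be >= 0")
        if self.balance != "undersample":
            raise TransferError(f"unknown balance strategy {self.balance!r}")


def _as_graph_records(records: Sequence) -> list[GraphRecord]:
    out = []
    for r in records:
        if isinstance(r, GraphRecord):
            out.append(r)
        elif isinstance(r, PanelRecord):
            out.append(
                GraphRecord(r.graph, r.label, r.signal,
                            meta={"parent_id": r.parent_id, "token": r.token})
            )
        else:
            raise TransferError(f"unsupported record type {type(r).__name__}")
    return out


def balance_one_to_one(records: Sequence, seed: int = 0) -> list:
    """Subsample the majority class (seeded, uniform) to the minority size."""
    labels = np.array([r.label for r in records])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise TransferError("both classes must be present to balance 1:1")
    rng = np.random.default_rng(seed)
    n_min = min(int((labels == c).sum()) for c in classes)
    kept: list[int] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        kept.extend(int(i) for i in idx)
    return [records[i] for i in sorted(kept)]


def _freezable_units(model: PhaseSeparationModel) -> list:
    units = [model.input_proj, *model.blocks]
    if hasattr(model.readout, "parameters") and model.readout.parameters():
        units.append(model.readout)
    return units


def _clone(model: PhaseSeparationModel) -> PhaseSeparationModel:
    clone = PhaseSeparationModel(copy.deepcopy(model.cfg))
    clone.load_state_arrays(model.state_arrays())
    clone._refs = dict(model._refs)
    return clone


def fine_tune(
    base_model: PhaseSeparationModel,
    records: Sequence,
    cfg: TLConfig | None = None,
) -> tuple[PhaseSeparationModel, dict]:
    """Fine-tune a copy of ``base_model`` on a balanced mutant panel.

    Frozen units are bitwise unchanged afterwards.  The report carries
    before/after held-out AUROC/F1 on a stratified split plus the
    training-loss trace.  ``epochs=0`` returns a model identical to the
    base.
    """
    cfg = cfg or TLConfig()
    records = _as_graph_records(records)
    units_total = len(_freezable_units(base_model))
    if cfg.freeze_blocks > units_total:
        raise TransferError(
            f"freeze policy asks for {cfg.freeze_blocks} frozen units but the "
            f"encoder has only {units_total}"
        )

    balanced = balance_one_to_one(records, seed=cfg.seed)
    labels = np.array([r.label for r in balanced])
    rng = np.random.default_rng(cfg.seed + 77)
    tune_idx, held_idx = _stratified_split(labels, cfg.heldout_fraction, rng)
    tune_recs = [balanced[i] for i in tune_idx]
    held_recs = [balanced[i] for i in held_idx]

    tuned = _clone(base_model)
    frozen_units = _freezable_units(tuned)[: cfg.freeze_blocks]
    frozen_params = [p for u in frozen_units for p in u.parameters()]
    frozen_ids = {id(p) for p in frozen_params}
    trainable = [p for p in tuned.parameters() if id(p) not in frozen_ids]
    # aux towers and projection head are left out of the fine-tuning loss;
    # their weights only move through the shared (unfrozen) encoder.
    frozen_before = [p.data.copy() for p in frozen_params]

    opt = Adam(trainable, lr=cfg.learning_rate)
    trace: list[float] = []
    best_loss, stale = np.inf, 0
    for _epoch in range(cfg.epochs):
        opt.zero_grad()
        loss = None
        for feats, adj, y, _ in _stack(tune_recs):
            emb = tuned.embed_batch(feats, adj)
            part = _bce(tuned.head_probs(emb, "target"), y) * (len(y) / len(tune_recs))
            loss = part if loss is None else loss + part
        if not np.isfinite(loss.data):
            raise TransferError(f"non-finite fine-tuning loss at epoch {_epoch}")
        loss.backward()
        opt.step()
        trace.append(loss.item())
        if loss.item() < best_loss - 1e-6:
            best_loss, stale = loss.item(), 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    for p, before in zip(frozen_params, frozen_before):
        if not np.array_equal(p.data, before):  # pragma: no cover - contract
            raise TransferError("frozen parameters changed during fine-tuning")

    gain = evaluate_transfer_gain(base_model, tuned, held_recs, tune_recs)
    report = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "n_tuning": len(tune_recs),
        "n_heldout": len(held_recs),
        "n_frozen_parameters": int(sum(p.data.size for p in frozen_params)),
        "loss_trace": trace,
        **gain,
    }
    return tuned, report


def evaluate_transfer_gain(
    base: PhaseSeparationModel,
    tuned: PhaseSeparationModel,
    heldout: Sequence,
    tuning_records: Sequence = (),
) -> dict:
    """Paired before/after AUROC and F1 on identical held-out data.

    Raises on any overlap between tuning and held-out records (leakage
    is checked by (parent, token) identity, falling back to graph
    features).
    """
    heldout = _as_graph_records(heldout)
    tuning = _as_graph_records(tuning_records)

    def ident(rec: GraphRecord):
        if "token" in rec.meta or "tokens" in rec.meta:
            return (rec.meta.get("parent_id"),
                    rec.meta.get("token") or tuple(rec.meta.get("tokens", ())))
        return rec.graph.node_features.tobytes()

    overlap = {ident(r) for r in heldout} & {ident(r) for r in tuning}
    if overlap:
        raise TransferError(
            f"tuning/held-out leakage: {len(overlap)} shared record(s)"
        )

    labels = np.array([r.label for r in heldout])
    scores_before = predict_records(base, heldout)
    scores_after = predict_records(tuned, heldout)
    return {
        "auroc_before": metrics.auroc(scores_before, labels),
        "auroc_after": metrics.auroc(scores_after, labels),
        "f1_before": metrics.f1(scores_before, labels),
        "f1_after": metrics.f1(scores_after, labels),
    }
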