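"""Sequence-to-contact-map prediction with a lightweight transformer.

The predictor maps a single protein sequence (no multiple-sequence
alignment, no templates) to a symmetric matrix of residue-residue
contact probabilities under the 10 Å Cα adjacency definition.  It is
trained as a per-pair binary classifier against contact matrices
derived from structures, which serve as pseudo-labels; contact sparsity
is handled with a positive-class weight.

Pairwise logits are averaged with their transpose *before* the sigmoid,
so output symmetry holds by construction rather than by luck of the
attention weights.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Parameter, Tensor
from .nn.layers import Linear, Module, TransformerBlock, sinusoidal_positions
from .sequences import ProteinSequence
from .structure import ResidueContactMatrix


class ContactModelError(RuntimeError):
    """Capacity violations or failed training runs."""


@dataclass
class ContactModelConfig:
    """Architecture and training hyperparameters (desk-scale defaults)."""

    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    positional_encoding: str = "sinusoidal"
    dropout: float = 0.0
    learning_rate: float = 3e-3
    epochs: int = 60
    batch_size: int = 8
    pos_weight: float | None = None  # None = per-example #neg/#pos
    max_length: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_model", "n_layers", "n_heads", "epochs", "batch_size",
                     "max_length"):
            if getattr(self, name) <= 0:
                raise ContactModelError(f"{name} must be positive")
        if self.positional_encoding != "sinusoidal":
            raise ContactModelError(
                f"unknown positional encoding {self.positional_encoding!r}"
            )


@dataclass
class ContactProbabilityMap:
    """Symmetric contact probabilities in [0, 1]; diagonal reported as 1."""

    entries: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class ContactTrainingExample:
    sequence: ProteinSequence
    rcm: ResidueContactMatrix

    def __post_init__(self) -> None:
        if len(self.sequence) != self.rcm.n:
            raise ContactModelError(
                f"sequence length {len(self.sequence)} != contact matrix "
                f"size {self.rcm.n} for {self.sequence.id!r}"
            )


class ContactPredictor(Module):
    """Learned residue embeddings + sinusoidal positions -> transformer ->
    low-rank bilinear pair head."""

    def __init__(self, cfg: ContactModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.embedding = Parameter(rng.normal(0.0, 0.5, size=(20, d)))
        self.blocks = [
            TransformerBlock(rng, d, cfg.n_heads) for _ in range(cfg.n_layers)
        ]
        self.pair_u = Linear(rng, d, d)
        self.pair_v = Linear(rng, d, d)
        self.pair_bias = Parameter(np.zeros(1))

    # -- forward ----------------------------------------------------------

    def _encode(self, seq: ProteinSequence) -> Tensor:
        length = len(seq)
        onehot = np.zeros((1, length, 20))
        onehot[0, np.arange(length), seq.indices()] = 1.0
        x = Tensor(onehot) @ self.embedding
        x = x + Tensor(sinusoidal_positions(length, self.cfg.d_model)[None])
        for block in self.blocks:
            x = block(x)
        return x

    def pair_logits(self, seq: ProteinSequence) -> Tensor:
        """Symmetrized pairwise logits, shape (1, L, L)."""
        if len(seq) > self.cfg.max_length:
            raise ContactModelError(
                f"sequence {seq.id!r} has length {len(seq)} > configured "
                f"maximum {self.cfg.max_length}"
            )
        if len(seq) < 2:
            raise ContactModelError("contact prediction needs length >= 2")
        h = self._encode(seq)
        raw = (self.pair_u(h) @ self.pair_v(h).swapaxes(-1, -2)) * (
            1.0 / np.sqrt(self.cfg.d_model)
        ) + self.pair_bias
        return (raw + raw.swapaxes(-1, -2)) * 0.5


def predict_contact_map(
    model: ContactPredictor, seq: ProteinSequence
) -> ContactProbabilityMap:
    """Deterministic symmetric contact probabilities for one sequence."""
    from .nn import no_grad

    with no_grad():
        probs = model.pair_logits(seq).sigmoid().data[0]
    np.fill_diagonal(probs, 1.0)
    return ContactProbabilityMap(
        probs,
        provenance={"model": "contact-predictor", "seed": model.cfg.seed,
                    "sequence_id": seq.id},
    )


def contact_map_to_rcm(
    cmap: ContactProbabilityMap, threshold: float = 0.5
) -> ResidueContactMatrix:
    """Binarize a probability map into a fully-resolved contact matrix."""
    entries = (cmap.entries >= threshold).astype(np.uint8)
    entries = np.maximum(entries, entries.T)
    np.fill_diagonal(entries, 1)
    return ResidueContactMatrix(entries, np.ones(cmap.n, dtype=bool), threshold)


def _example_loss(
    model: ContactPredictor, ex: ContactTrainingExample, pos_weight: float | None
) -> Tensor:
    """Weighted per-pair BCE over off-diagonal unmasked pairs."""
    logits = model.pair_logits(ex.sequence)
    y = ex.rcm.entries.astype(float)
    weight = np.outer(ex.rcm.mask, ex.rcm.mask).astype(float)
    np.fill_diagonal(weight, 0.0)
    n_pos = float((y * weight).sum())
    n_neg = float(((1 - y) * weight).sum())
    w_pos = pos_weight if pos_weight is not None else (
        n_neg / n_pos if n_pos > 0 and n_neg > 0 else 1.0
    )
    weight = weight * np.where(y > 0, w_pos, 1.0)
    p = logits.sigmoid()
    eps = 1e-7
    nll = -(Tensor(y[None]) * (p + eps).log()
            + Tensor((1 - y)[None]) * (1 - p + eps).log())
    wt = Tensor(weight[None])
    return (nll * wt).sum() / float(weight.sum())


def train_contact_predictor(
    examples: list[ContactTrainingExample],
    cfg: ContactModelConfig | None = None,
) -> tuple[ContactPredictor, list[float]]:
    """Train on pseudo-labelled examples; returns (model, epoch loss trace)."""
    cfg = cfg or ContactModelConfig()
    if len(examples) < 2:
        raise ContactModelError("need at least 2 training examples")
    model = ContactPredictor(cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    trace: list[float] = []
    order = np.arange(len(examples))
    for _epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            total = None
            for idx in batch:
                loss = _example_loss(model, examples[idx], cfg.pos_weight)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            if not np.isfinite(total.data):
                raise ContactModelError(
                    f"non-finite training loss at epoch {_epoch}: {total.data}"
                )
            total.backward()
            opt.step()
            epoch_losses.append(total.item())
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


# -- checkpointing --------------------------------------------------------


def save_contact_model(model: ContactPredictor, path: str | Path) -> None:
    """Single-file checkpoint embedding config, seed and all weights."""
    buf = io.BytesIO()
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(buf, config=json.dumps(asdict(model.cfg)), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_contact_model(path: str | Path) -> ContactPredictor:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ContactModelConfig(**json.loads(str(data["config"])))
        model = ContactPredictor(cfg)
        n = len(model.parameters())
        model.load_state_arrays([data[f"arr_{i}"] for i in range(n)])
    return model
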