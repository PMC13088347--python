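"""Featurized residue graphs built from contact matrices.

Nodes carry per-residue physicochemical features; edges come from the
off-diagonal contacts of a masked contact matrix, plus guaranteed
backbone edges between sequential neighbours so message passing always
has a connected chain to walk on.

The node feature vector is
``[20-dim one-hot | hydrophobicity | formal charge at pH 7 | aromaticity |
disorder propensity]`` (scales z-scored over the alphabet), optionally
followed by a mutation-annotation block
``[edited flag | 20-dim parent-residue one-hot]`` that marks residues
changed relative to a parent sequence.  The annotation block is all
zeros for wild-type input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .mutations import MutationSet
from .sequences import AA_INDEX, CANONICAL_AA, ProteinSequence
from .structure import ResidueContactMatrix

# Kyte-Doolittle hydropathy
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
# net formal charge at pH 7 (His partially protonated)
_CHARGE = {aa: 0.0 for aa in CANONICAL_AA}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})
_AROMATIC = {"F", "W", "Y", "H"}
# TOP-IDP-style disorder propensity (higher = more disorder-prone)
_DISORDER = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.02, "T": 0.059,
    "A": 0.06, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

BASE_FEATURE_DIM = 24
#: local sequence-context block: windowed G/S (low-complexity), aromatic,
#: and absolute net-charge fractions around each residue — the
#: composition features phase-separation predictors conventionally use.
CONTEXT_DIM = 3
CONTEXT_HALFWIDTH = 4
#: mutation-annotation block: edited flag + the parent residue's full
#: base feature vector (one-hot + scales), so the physicochemical change
#: at the site is directly visible to the encoder.
ANNOTATION_DIM = 1 + BASE_FEATURE_DIM
FEATURE_DIM = BASE_FEATURE_DIM + CONTEXT_DIM + ANNOTATION_DIM

_CONTEXT_GS = frozenset("GS")
_CONTEXT_AROMATIC = frozenset("FWY")
_CHARGE_SIGN = {"K": 1, "R": 1, "D": -1, "E": -1}


def sequence_context_features(seq: "ProteinSequence") -> np.ndarray:
    """Per-residue windowed composition, shape (n, CONTEXT_DIM).

    For each residue the window spans ``CONTEXT_HALFWIDTH`` neighbours on
    either side (clipped at the termini): G/S fraction, F/W/Y fraction,
    and |net charge| fraction within the window.
    """
    n = len(seq)
    gs = np.fromiter((c in _CONTEXT_GS for c in seq.residues), float, n)
    arom = np.fromiter((c in _CONTEXT_AROMATIC for c in seq.residues), float, n)
    charge = np.fromiter(
        (_CHARGE_SIGN.get(c, 0) for c in seq.residues), float, n
    )
    out = np.empty((n, CONTEXT_DIM))
    for i in range(n):
        lo, hi = max(0, i - CONTEXT_HALFWIDTH), min(n, i + CONTEXT_HALFWIDTH + 1)
        width = hi - lo
        out[i, 0] = gs[lo:hi].sum() / width
        out[i, 1] = arom[lo:hi].sum() / width
        out[i, 2] = abs(charge[lo:hi].sum()) / width
    return out


class GraphError(ValueError):
    """Dimension mismatches or structurally invalid graph input."""


@dataclass(frozen=True)
class NodeFeatureTable:
    """Per-amino-acid feature matrix, shape (20, BASE_FEATURE_DIM).

    Scale columns are z-scored across the 20-letter alphabet by default
    so no single scale dominates message passing.
    """

    table: np.ndarray

    @classmethod
    def default(cls, zscore: bool = True) -> "NodeFeatureTable":
        rows = []
        for aa in CANONICAL_AA:
            onehot = [1.0 if b == aa else 0.0 for b in CANONICAL_AA]
            rows.append(
                onehot
                + [_HYDROPATHY[aa], _CHARGE[aa],
                   1.0 if aa in _AROMATIC else 0.0, _DISORDER[aa]]
            )
        table = np.array(rows, dtype=float)
        if zscore:
            scales = table[:, 20:]
            table[:, 20:] = (scales - scales.mean(0)) / scales.std(0)
        if not np.all(np.isfinite(table)):
            raise GraphError("non-finite node feature value")
        return cls(table)

    def features_for(self, seq: ProteinSequence) -> np.ndarray:
        return self.table[seq.indices()]


@dataclass
class ResidueGraph:
    """Undirected residue graph: dense adjacency (no self loops) + features."""

    adjacency: np.ndarray
    node_features: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        self.node_features = np.asarray(self.node_features, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise GraphError("adjacency must be square")
        if self.node_features.shape[0] != n:
            raise GraphError("node feature count disagrees with adjacency size")
        if np.any(np.diag(self.adjacency)):
            raise GraphError("self-loop in residue graph")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise GraphError("adjacency must be symmetric")

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Sorted undirected edge list with 1-based residue indices."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]

    @property
    def backbone(self) -> np.ndarray:
        """Boolean matrix marking sequential-neighbour (backbone) edges."""
        n = self.node_count
        bb = np.zeros((n, n), dtype=bool)
        idx = np.arange(n - 1)
        bb[idx, idx + 1] = bb[idx + 1, idx] = True
        return bb & (self.adjacency > 0)


def mutation_annotation(
    parent: ProteinSequence, muts: MutationSet
) -> dict[int, str]:
    """Map 1-based *mutant-coordinate* positions to the parent residue edited there.

    Substituted sites map to the parent residue they replaced; a deleted
    site annotates the residue now occupying its (shifted) position, or
    the last residue when the deletion was terminal.
    """
    ann: dict[int, str] = {}
    new_length = len(parent) - sum(1 for s in muts if s.is_deletion)
    for spec in muts:
        shift = sum(
            1 for other in muts if other.is_deletion and other.position < spec.position
        )
        pos = spec.position - shift
        if spec.is_deletion:
            pos = min(pos, new_length)
        ann[pos] = spec.ref_aa
    return ann


def build_residue_graph(
    rcm: ResidueContactMatrix,
    seq: ProteinSequence,
    features: NodeFeatureTable | None = None,
    annotation: Mapping[int, str] | None = None,
) -> ResidueGraph:
    """Graph = masked off-diagonal contacts ∪ backbone edges, with node features.

    Contacts touching a masked residue are dropped; backbone edges are
    always present so every node has a neighbour when n >= 2.
    ``annotation`` (1-based position -> parent residue) fills the
    mutation-annotation feature block.
    """
    if rcm.n != len(seq):
        raise GraphError(
            f"contact matrix size {rcm.n} != sequence length {len(seq)}"
        )
    features = features or NodeFeatureTable.default()
    n = rcm.n
    valid = np.outer(rcm.mask, rcm.mask)
    adj = (rcm.entries.astype(bool) & valid)
    np.fill_diagonal(adj, False)
    if n >= 2:
        idx = np.arange(n - 1)
        adj[idx, idx + 1] = adj[idx + 1, idx] = True

    feats = np.zeros((n, FEATURE_DIM), dtype=float)
    feats[:, :BASE_FEATURE_DIM] = features.features_for(seq)
    feats[:, BASE_FEATURE_DIM : BASE_FEATURE_DIM + CONTEXT_DIM] = (
        sequence_context_features(seq)
    )
    ann_start = BASE_FEATURE_DIM + CONTEXT_DIM
    if annotation:
        for pos, parent_aa in annotation.items():
            if not 1 <= pos <= n:
                raise GraphError(f"annotation position {pos} out of range 1..{n}")
            if parent_aa not in AA_INDEX:
                raise GraphError(f"non-canonical annotation residue {parent_aa!r}")
            feats[pos - 1, ann_start] = 1.0
            feats[pos - 1, ann_start + 1 :] = features.table[AA_INDEX[parent_aa]]
    return ResidueGraph(adj.astype(np.uint8), feats)


def write_edge_list(graph: ResidueGraph, path: str | Path) -> None:
    """Plain-text undirected edge list (1-based, one ``i j`` pair per line)."""
    with open(path, "w") as fh:
        fh.write(f"{graph.node_count}\n")
        for i, j in graph.edges():
            fh.write(f"{i} {j}\n")
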