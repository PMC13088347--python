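"""Residue graph construction and node features."""

import numpy as np
import pytest

from psforge.graphs import (
    ANNOTATION_DIM,
    BASE_FEATURE_DIM,
    CONTEXT_DIM,
    CONTEXT_HALFWIDTH,
    FEATURE_DIM,
    sequence_context_features,
    GraphError,
    NodeFeatureTable,
    ResidueGraph,
    build_residue_graph,
    mutation_annotation,
)
from psforge.mutations import MutationSet, MutationSpec
from psforge.sequences import AA_INDEX, ProteinSequence
from psforge.structure import ResidueContactMatrix


def _rcm(entries, mask=None, threshold=10.0):
    entries = np.asarray(entries, dtype=np.uint8)
    mask = np.ones(entries.shape[0], bool) if mask is None else np.asarray(mask)
    return ResidueContactMatrix(entries, mask, threshold)


def test_feature_table_shape_and_finiteness():
    table = NodeFeatureTable.default()
    assert table.table.shape == (20, BASE_FEATURE_DIM)
    assert np.all(np.isfinite(table.table))
    # one-hot block is the identity over the alphabet
    np.testing.assert_array_equal(table.table[:, :20], np.eye(20))


def test_three_residue_graph_edges():
    rcm = _rcm([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
    g = build_residue_graph(rcm, ProteinSequence("t", "AGS"))
    assert g.edges() == [(1, 2), (2, 3)]


def test_backbone_guarantee_with_empty_contacts():
    rcm = _rcm(np.eye(4, dtype=np.uint8))
    g = build_residue_graph(rcm, ProteinSequence("t", "ACDE"))
    assert g.edges() == [(1, 2), (2, 3), (3, 4)]
    degrees = g.adjacency.sum(axis=0)
    assert np.all(degrees >= 1)


def test_edge_count_matches_set_union_oracle(rng):
    n = 30
    upper = rng.random((n, n)) < 0.1
    entries = np.triu(upper, 1)
    entries = (entries | entries.T | np.eye(n, dtype=bool)).astype(np.uint8)
    g = build_residue_graph(_rcm(entries), ProteinSequence("t", "A" * n))
    contacts = {
        (i + 1, j + 1)
        for i, j in zip(*np.nonzero(np.triu(entries, 1)))
    }
    backbone = {(i, i + 1) for i in range(1, n)}
    assert set(g.edges()) == contacts | backbone


def test_masked_contacts_are_dropped():
    entries = np.ones((3, 3), dtype=np.uint8)
    g = build_residue_graph(
        _rcm(entries, mask=[True, True, False]), ProteinSequence("t", "AGS")
    )
    # masked residue keeps only its backbone edge
    assert set(g.edges()) == {(1, 2), (2, 3)}


def test_dimension_mismatch_raises():
    with pytest.raises(GraphError, match="size 2"):
        build_residue_graph(_rcm(np.eye(2, dtype=np.uint8)), ProteinSequence("t", "AGS"))


def test_no_self_loops_and_symmetry(rng):
    n = 20
    upper = np.triu(rng.random((n, n)) < 0.2, 1)
    entries = (upper | upper.T | np.eye(n, dtype=bool)).astype(np.uint8)
    g = build_residue_graph(_rcm(entries), ProteinSequence("t", "A" * n))
    assert np.all(np.diag(g.adjacency) == 0)
    assert np.array_equal(g.adjacency, g.adjacency.T)


def test_permutation_consistency(rng):
    """Relabeling residues then building equals building then relabeling.

    Backbone edges and windowed context follow the *new* sequential
    ordering by design, so the check covers the per-residue feature
    blocks (identity + annotation) and the contact-derived structure.
    """
    n = 15
    seq = ProteinSequence("t", "ACDEFGHIKLMNPQR")
    upper = np.triu(rng.random((n, n)) < 0.25, 1)
    entries = (upper | upper.T | np.eye(n, dtype=bool)).astype(np.uint8)
    g = build_residue_graph(_rcm(entries), seq)

    perm = rng.permutation(n)
    g_perm = build_residue_graph(
        _rcm(entries[np.ix_(perm, perm)]),
        ProteinSequence("t", "".join(seq.residues[i] for i in perm)),
    )
    ctx = slice(BASE_FEATURE_DIM, BASE_FEATURE_DIM + CONTEXT_DIM)
    base_and_ann = np.delete(g.node_features[perm], np.r_[ctx], axis=1)
    permuted = np.delete(g_perm.node_features, np.r_[ctx], axis=1)
    np.testing.assert_allclose(permuted, base_and_ann)
    np.testing.assert_allclose(
        g_perm.node_features[:, ctx],
        sequence_context_features(
            ProteinSequence("t", "".join(seq.residues[i] for i in perm))
        ),
    )


def test_annotation_block_marks_parent_residue():
    parent = ProteinSequence("p", "MRAYV")
    muts = MutationSet([MutationSpec(2, "R", "C")])
    ann = mutation_annotation(parent, muts)
    assert ann == {2: "R"}
    entries = np.eye(5, dtype=np.uint8)
    g = build_residue_graph(
        _rcm(entries), ProteinSequence("m", "MCAYV"), annotation=ann
    )
    assert g.node_features.shape == (5, FEATURE_DIM)
    table = NodeFeatureTable.default()
    ann = BASE_FEATURE_DIM + CONTEXT_DIM
    assert g.node_features[1, ann] == 1.0
    np.testing.assert_allclose(
        g.node_features[1, ann + 1 :], table.table[AA_INDEX["R"]]
    )
    # other rows carry a zero annotation block
    assert np.all(g.node_features[[0, 2, 3, 4], ann:] == 0)


def test_sequence_context_features_hand_example():
    seq = ProteinSequence("c", "GGGGYKKKKK")
    ctx = sequence_context_features(seq)
    # residue 1 (0-based 0): window = first 5 residues "GGGGY"
    assert ctx[0, 0] == pytest.approx(4 / 5)
    assert ctx[0, 1] == pytest.approx(1 / 5)
    # residue 10: window = last 5 residues, all K -> |charge| fraction 1
    assert ctx[9, 2] == pytest.approx(1.0)
    # aromatic Y at position 5 appears in mid windows
    assert ctx[4, 1] == pytest.approx(1 / 9)


def test_annotation_for_deletion_shifts_position():
    parent = ProteinSequence("p", "MRAYV")
    muts = MutationSet([MutationSpec(2, "R", kind="deletion")])
    assert mutation_annotation(parent, muts) == {2: "R"}
    # terminal deletion annotates the last remaining residue
    muts_end = MutationSet([MutationSpec(5, "V", kind="deletion")])
    assert mutation_annotation(parent, muts_end) == {4: "V"}


def test_mixed_set_annotation_positions():
    parent = ProteinSequence("p", "MRAYVW")
    muts = MutationSet(
        [MutationSpec(2, "R", kind="deletion"), MutationSpec(5, "V", "K")]
    )
    # deletion at 2 shifts position 5 down to 4 in mutant coordinates
    assert mutation_annotation(parent, muts) == {2: "R", 4: "V"}
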