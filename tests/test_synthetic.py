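"""Synthetic generators: declared rules, toy structures, datasets."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from psforge.mutations import MutationSet, parse_mutation_token
from psforge.sequences import ProteinSequence
from psforge.structure import compute_rcm
from psforge.synthetic import (
    GenerationError,
    SyntheticRuleConfig,
    ToyStructureSpec,
    default_panel_parent,
    delta_score,
    generate_toy_structure,
    ground_truth_label,
    ground_truth_ps_score,
    helix_contact_bandwidth,
    make_retraining_panel,
    sample_labeled_datasets,
)


def test_rule_closed_form_values():
    # poly-A: all composition terms zero -> logistic(intercept)
    assert ground_truth_ps_score("A" * 20) == pytest.approx(
        1 / (1 + math.exp(2)), abs=1e-12
    )
    assert ground_truth_label("A" * 20) == 0
    # all-aromatic: f_arom = 1 -> logistic(8 - 2)
    assert ground_truth_ps_score("Y" * 10) == pytest.approx(
        1 / (1 + math.exp(-6)), abs=1e-12
    )
    assert ground_truth_label("Y" * 10) == 1


def test_rule_reversal_invariance(rng, random_sequence):
    for _ in range(20):
        seq = random_sequence(30)
        assert ground_truth_ps_score(seq.residues) == pytest.approx(
            ground_truth_ps_score(seq.residues[::-1])
        )


def test_rule_is_pure():
    assert ground_truth_ps_score("GSGSGSGSWY") == ground_truth_ps_score("GSGSGSGSWY")


def test_helix_band_matches_distance_oracle():
    spec = ToyStructureSpec(family="ideal-helix", length=30)
    model = generate_toy_structure(spec)
    s = helix_contact_bandwidth(10.0, spec.rise, spec.turn_deg, spec.radius)
    band = (
        np.abs(np.subtract.outer(np.arange(30), np.arange(30))) <= s
    ).astype(int)
    rcm = compute_rcm(model, 10.0)
    np.testing.assert_array_equal(rcm.entries, band)
    # and against the brute-force oracle directly
    oracle = (squareform(pdist(model.calpha_coords)) <= 10.0).astype(int)
    np.fill_diagonal(oracle, 1)
    np.testing.assert_array_equal(rcm.entries, oracle)


def test_toy_structures_reproduce_under_seed():
    spec = ToyStructureSpec(family="self-avoiding-chain", length=40, seed=8)
    a = generate_toy_structure(spec)
    b = generate_toy_structure(spec)
    np.testing.assert_array_equal(a.calpha_coords, b.calpha_coords)
    assert a.sequence.residues == b.sequence.residues


def test_chain_steps_have_configured_length():
    spec = ToyStructureSpec(family="self-avoiding-chain", length=50, seed=3)
    coords = generate_toy_structure(spec).calpha_coords
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    np.testing.assert_allclose(steps, spec.step, atol=1e-9)


def test_chain_respects_exclusion_radius():
    spec = ToyStructureSpec(family="self-avoiding-chain", length=50, seed=3)
    coords = generate_toy_structure(spec).calpha_coords
    d = squareform(pdist(coords))
    off = d[np.abs(np.subtract.outer(np.arange(50), np.arange(50))) > 1]
    assert off.min() >= spec.exclusion - 1e-9


def test_datasets_labels_recompute_exactly():
    """Every generated label agrees with the declared closed form."""
    rule = SyntheticRuleConfig()
    target, aux1, aux2 = sample_labeled_datasets(40, 20, 20, seed=5)
    assert len(target) == 40
    for rec in target:
        parent = ProteinSequence("p", rec.meta["parent"])
        if rec.meta["tokens"]:
            muts = MutationSet.from_tokens(rec.meta["tokens"])
            d = abs(delta_score(parent, muts, rule))
        else:
            d = 0.0
        assert rec.signal == pytest.approx(d)
        assert rec.label == int(d >= rule.delta_threshold)
    path_rule = rule.pathogenicity()
    for rec in aux1.records:
        parent = ProteinSequence("p", rec.meta["parent"])
        muts = MutationSet.from_tokens(rec.meta["tokens"])
        assert rec.label == int(
            abs(delta_score(parent, muts, path_rule)) >= path_rule.delta_threshold
        )
    for rec in aux2.records:
        score = ground_truth_ps_score(rec.meta["parent"], rule)
        assert rec.signal == pytest.approx(score)
        assert rec.label == int(score >= rule.label_threshold)


def test_dataset_balance_and_determinism():
    t1, a1, b1 = sample_labeled_datasets(30, 10, 10, seed=9)
    t2, _, _ = sample_labeled_datasets(30, 10, 10, seed=9)
    t3, _, _ = sample_labeled_datasets(30, 10, 10, seed=10)
    assert [r.label for r in t1] == [r.label for r in t2]
    assert [r.meta["parent"] for r in t1] == [r.meta["parent"] for r in t2]
    assert [r.meta["parent"] for r in t1] != [r.meta["parent"] for r in t3]
    for records in (t1, a1.records, b1.records):
        frac = np.mean([r.label for r in records])
        assert 0.4 <= frac <= 0.6


def test_dataset_minimum_size_enforced():
    with pytest.raises(GenerationError, match=">= 4"):
        sample_labeled_datasets(2, 10, 10, seed=0)


def test_retraining_panel_counts_and_validity():
    parent = default_panel_parent(seed=2)
    panel = make_retraining_panel(parent, n=138, seed=2)
    assert len(panel) == 138
    labels = [r.label for r in panel]
    assert sum(labels) == 69 and len(labels) - sum(labels) == 69
    # every token validates against the parent
    for rec in panel:
        spec = parse_mutation_token(rec.token)
        assert parent.residue_at(spec.position) == spec.ref_aa
    # tokens are unique
    assert len({r.token for r in panel}) == 138


def test_small_panel_is_half_and_half():
    parent = default_panel_parent(seed=4)
    panel = make_retraining_panel(parent, n=10, seed=4)
    assert sum(r.label for r in panel) == 5


def test_odd_panel_size_rejected():
    parent = default_panel_parent(seed=1)
    with pytest.raises(GenerationError, match="even"):
        make_retraining_panel(parent, n=137, seed=1)


def test_shifted_rule_prints_configured_perturbation():
    base = SyntheticRuleConfig()
    shifted = base.shifted()
    assert shifted.w_arom == base.w_arom - 4
    assert shifted.w_charge == base.w_charge + 2
    assert shifted.w_gs == base.w_gs
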