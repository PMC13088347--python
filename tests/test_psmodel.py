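"""Twin-tower PS scorer: encoder invariants, losses, training, scoring."""

import numpy as np
import pytest

from psforge.graphs import NodeFeatureTable, ResidueGraph, build_residue_graph
from psforge.mutations import MutationSet
from psforge.nn import Tensor
from psforge.psmodel import (
    AuxiliaryDataset,
    GraphEncoderConfig,
    GraphRecord,
    PhaseSeparationModel,
    PSModelError,
    augment_view,
    encode_graph,
    load_ps_model,
    nt_xent,
    run_ablation,
    save_ps_model,
    score_ps,
    train_psdm,
    twin_tower_loss,
)
from psforge.sequences import ProteinSequence
from psforge.structure import ResidueContactMatrix
from psforge.synthetic import (
    ToyStructureSpec,
    generate_toy_structure,
    sample_labeled_datasets,
)

SMALL = GraphEncoderConfig(hidden=16, depth=2, epochs=4, seed=0,
                           contrastive_batch=16)


def _random_graph(rng, n=12, p=0.25, seq=None):
    seq = seq or ProteinSequence("g", "".join(rng.choice(list("ACDEFGHIKL"), n)))
    upper = np.triu(rng.random((n, n)) < p, 1)
    entries = (upper | upper.T | np.eye(n, dtype=bool)).astype(np.uint8)
    rcm = ResidueContactMatrix(entries, np.ones(n, bool), 10.0)
    return build_residue_graph(rcm, seq)


def _permute_graph(g: ResidueGraph, perm: np.ndarray) -> ResidueGraph:
    return ResidueGraph(
        g.adjacency[np.ix_(perm, perm)], g.node_features[perm]
    )


def test_embedding_permutation_invariance(rng):
    model = PhaseSeparationModel(SMALL)
    g = _random_graph(rng)
    perm = rng.permutation(g.node_count)
    emb = encode_graph(model, g)
    emb_perm = encode_graph(model, _permute_graph(g, perm))
    np.testing.assert_allclose(emb, emb_perm, atol=1e-5)


def test_embeddings_distinguish_random_graphs(rng):
    """Non-degeneracy: distinct graphs land measurably apart."""
    model = PhaseSeparationModel(SMALL)
    distances = []
    for _ in range(20):
        a = encode_graph(model, _random_graph(rng))
        b = encode_graph(model, _random_graph(rng))
        distances.append(np.linalg.norm(a - b))
    assert min(distances) > 1e-6


def test_single_node_graph_encodes_without_error():
    model = PhaseSeparationModel(SMALL)
    g = build_residue_graph(
        ResidueContactMatrix(np.ones((1, 1), np.uint8), np.ones(1, bool), 10.0),
        ProteinSequence("one", "M"),
    )
    emb = encode_graph(model, g)
    assert np.all(np.isfinite(emb))


def test_augment_identity_at_zero_rates(rng):
    g = _random_graph(rng)
    view = augment_view(g, 0.0, 0.0, seed=1)
    np.testing.assert_array_equal(view.adjacency, g.adjacency)
    np.testing.assert_array_equal(view.node_features, g.node_features)


def test_augment_seeding_contract(rng):
    g = _random_graph(rng, n=20, p=0.5)
    a = augment_view(g, 0.5, 0.3, seed=42)
    b = augment_view(g, 0.5, 0.3, seed=42)
    np.testing.assert_array_equal(a.adjacency, b.adjacency)
    np.testing.assert_array_equal(a.node_features, b.node_features)


def test_augment_never_drops_backbone(rng):
    g = _random_graph(rng, n=20, p=0.5)
    view = augment_view(g, 0.99, 0.0, seed=0)
    idx = np.arange(19)
    assert np.all(view.adjacency[idx, idx + 1] == 1)
    assert view.node_count == g.node_count


def test_augment_survival_matches_binomial_oracle(rng):
    """Non-backbone edge survival over 50 seeds within the binomial 99% CI."""
    from scipy.stats import binom

    g = _random_graph(rng, n=40, p=0.5)
    non_backbone = int(
        np.triu(g.adjacency, 2).sum()
    )
    p_drop = 0.3
    survived = 0
    for seed in range(50):
        view = augment_view(g, p_drop, 0.0, seed=seed)
        survived += int(np.triu(view.adjacency, 2).sum())
    n_total = 50 * non_backbone
    lo, hi = binom.ppf([0.005, 0.995], n_total, 1 - p_drop)
    assert lo <= survived <= hi


def test_nt_xent_matches_hand_computation():
    """2-graph batch with fixed embeddings at temperature 0.5."""
    z = np.array(
        [[1.0, 0.0], [0.0, 1.0], [1.0, 0.1], [0.1, 1.0]]
    )  # rows 0/2 and 1/3 are the positive pairs
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    sim = zn @ zn.T / 0.5
    expected = 0.0
    for i, j in ((0, 2), (1, 3), (2, 0), (3, 1)):
        denom = sum(np.exp(sim[i, k]) for k in range(4) if k != i)
        expected += -np.log(np.exp(sim[i, j]) / denom)
    expected /= 4
    value = nt_xent(Tensor(z), temperature=0.5).item()
    assert value == pytest.approx(expected, abs=1e-9)


def _records(rng, n, n_nodes=10):
    return [
        GraphRecord(_random_graph(rng, n_nodes), label=int(i % 2))
        for i in range(n)
    ]


def test_weight_zeroing_removes_terms_exactly(rng):
    model = PhaseSeparationModel(SMALL)
    target = _records(rng, 6)
    aux = _records(rng, 4)
    total, comps = twin_tower_loss(
        model, target, aux, None, None, weights=(1.0, 0.0, 0.0, 0.0),
        rng=np.random.default_rng(0),
    )
    assert set(comps) == {"target"}
    assert total.item() == pytest.approx(comps["target"])


def test_all_zero_weights_rejected(rng):
    model = PhaseSeparationModel(SMALL)
    with pytest.raises(PSModelError, match="zero"):
        twin_tower_loss(model, _records(rng, 4), None, None, None,
                        weights=(0, 0, 0, 0))


def test_perfect_target_batch_hits_bce_floor(rng):
    """Drive the head towards saturation: loss approaches the clamp floor."""
    model = PhaseSeparationModel(SMALL)
    recs = _records(rng, 4)
    probs = Tensor(np.array([1.0 - 1e-7, 1e-7, 1.0 - 1e-7, 1e-7]))
    from psforge.psmodel import _bce

    labels = np.array([1.0, 0.0, 1.0, 0.0])
    assert _bce(probs, labels).item() < 1e-6


def test_training_rejects_single_class(rng):
    recs = [GraphRecord(_random_graph(rng), label=1) for _ in range(6)]
    with pytest.raises(PSModelError, match="both classes"):
        train_psdm(recs, None, None, SMALL)


def test_training_is_seeded_and_reports(rng):
    target, aux1, aux2 = sample_labeled_datasets(16, 8, 8, seed=3, length=16)
    cfg = GraphEncoderConfig(hidden=16, depth=2, epochs=3, seed=7,
                             contrastive_batch=8)
    _m1, r1 = train_psdm(target, aux1, aux2, cfg)
    _m2, r2 = train_psdm(target, aux1, aux2, cfg)
    assert r1["trace"] == r2["trace"]
    assert {"target", "aux1", "aux2", "contrastive", "total"} <= set(
        r1["trace"][0]
    )
    assert 0.0 <= r1["validation_auroc"] <= 1.0


def test_zero_aux_weights_equal_plain_supervised(rng):
    """Component-trace identity: w1=w2=wc=0 is plain supervised training."""
    target, aux1, aux2 = sample_labeled_datasets(16, 8, 8, seed=3, length=16)
    cfg_plain = GraphEncoderConfig(hidden=16, depth=2, epochs=3, seed=7,
                                   w_aux1=0.0, w_aux2=0.0, w_contrastive=0.0)
    _m, r_with_aux_data = train_psdm(target, aux1, aux2, cfg_plain)
    _m, r_no_aux_data = train_psdm(target, None, None, cfg_plain)
    assert r_with_aux_data["trace"] == r_no_aux_data["trace"]
    assert set(r_no_aux_data["trace"][0]) == {"target", "total"}


def test_ablation_harness_runs_all_variants(rng):
    target, aux1, aux2 = sample_labeled_datasets(12, 8, 8, seed=5, length=16)
    base = GraphEncoderConfig(hidden=16, depth=2, epochs=2, seed=1,
                              contrastive_batch=8)
    results = run_ablation(target, aux1, aux2, base)
    assert set(results) == {"full", "no_gin", "no_gat", "no_attention",
                            "no_contrastive"}
    sizes = {name: r["n_parameters"] for name, r in results.items()}
    assert sizes["no_gin"] != sizes["full"]
    assert sizes["no_attention"] < sizes["full"]


def test_score_ps_range_and_determinism():
    seq = ProteinSequence("p", "MKTAYIAKQRQISFVKSHFSRQLEERLG")
    structure = generate_toy_structure(
        ToyStructureSpec(family="self-avoiding-chain", length=len(seq), seed=4), seq
    )
    model = PhaseSeparationModel(GraphEncoderConfig(hidden=16, depth=2, seed=0))
    muts = MutationSet.from_tokens(["K2W"])
    a = score_ps(model, seq, "structure", muts=muts, structure=structure)
    b = score_ps(model, seq, "structure", muts=muts, structure=structure)
    assert 0.0 <= a.value <= 1.0
    assert a.value == b.value and a.input_digest == b.input_digest


def test_score_ps_structure_deletion_shrinks_graph():
    seq = ProteinSequence("p", "MKTAYIAKQRQISFVKSHFSRQLEERLG")
    structure = generate_toy_structure(
        ToyStructureSpec(family="self-avoiding-chain", length=len(seq), seed=4), seq
    )
    model = PhaseSeparationModel(GraphEncoderConfig(hidden=16, depth=2, seed=0))
    out = score_ps(model, seq, "structure",
                   muts=MutationSet.from_tokens(["K2-"]), structure=structure)
    assert 0.0 <= out.value <= 1.0


def test_score_ps_propagates_reference_mismatch():
    from psforge.mutations import MutationError

    seq = ProteinSequence("p", "MKTAYIAKQRQISFVKSHFSRQLEERLG")
    structure = generate_toy_structure(
        ToyStructureSpec(family="self-avoiding-chain", length=len(seq), seed=4), seq
    )
    model = PhaseSeparationModel(GraphEncoderConfig(hidden=16, depth=2, seed=0))
    with pytest.raises(MutationError, match="mismatch"):
        score_ps(model, seq, "structure",
                 muts=MutationSet.from_tokens(["W2A"]), structure=structure)


def test_labeled_dataset_csv_loader(tmp_path):
    from psforge.psmodel import load_labeled_dataset_csv

    path = tmp_path / "data.csv"
    path.write_text(
        "id,sequence,parent_sequence,token,label,role\n"
        "p1,MKGSYWAEMKGSYWAE,,,1,target\n"
        "p2,,MKGSYWAEMKGSYWAE,K2W,0,target\n"
        "p3,GSGSGSGSGSGSGSGS,,,1,ps_classification\n"
    )
    groups = load_labeled_dataset_csv(path, seed=3)
    assert {len(v) for v in groups.values()} == {2, 1}
    mutant = groups["target"][1]
    assert mutant.meta["tokens"] == ["K2W"]
    # annotation channel is set on the edited node
    from psforge.graphs import BASE_FEATURE_DIM, CONTEXT_DIM

    assert mutant.graph.node_features[1, BASE_FEATURE_DIM + CONTEXT_DIM] == 1.0


def test_checkpoint_round_trip(tmp_path, rng):
    model = PhaseSeparationModel(SMALL)
    g = _random_graph(rng)
    path = tmp_path / "ps.ckpt.npz"
    save_ps_model(model, path)
    loaded = load_ps_model(path)
    np.testing.assert_array_equal(encode_graph(model, g), encode_graph(loaded, g))
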