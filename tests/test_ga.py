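"""Genetic-algorithm engine and its exhaustive oracle."""

import numpy as np
import pytest

from psforge.ga import (
    Candidate,
    GAConfig,
    GAError,
    exhaustive_single_site_scan,
    fitness,
    from_sequence_scorer,
    initialize_population,
    run_ga,
)
from psforge.graphs import _HYDROPATHY
from psforge.mutations import MutationSet, apply_mutation_set
from psforge.sequences import ProteinSequence
from psforge.synthetic import ground_truth_ps_score

TOY = ProteinSequence("toy", "MKGSYWAE")
RULE = from_sequence_scorer(ground_truth_ps_score)


def test_fitness_arithmetic_and_identity():
    fit = fitness(
        ProteinSequence("x", "AA"), ProteinSequence("o", "AY"),
        lambda s: {"AA": 0.82, "AY": 0.31}[s.residues],
    )
    assert fit.value == pytest.approx(0.51)
    same = ProteinSequence("o", "AY")
    assert fitness(same, same, lambda s: 0.7).value == 0.0


def test_fitness_bounded_for_unit_interval_scorers(rng):
    """Any scorer into [0,1] keeps fit in [-1,1] over random candidates."""
    for _ in range(1000):
        a, b = rng.random(), rng.random()
        value = fitness(
            ProteinSequence("x", "AA"), ProteinSequence("o", "AY"),
            lambda s, _v=(a, b): _v[0] if s.residues == "AA" else _v[1],
        ).value
        assert -1.0 <= value <= 1.0


def test_initial_population_contracts():
    cfg = GAConfig(population=10, generations=1, max_edits=1, seed=3)
    pop = initialize_population(TOY, cfg)
    assert len(pop) == 10
    for cand in pop:
        assert len(cand.muts) == 1
        apply_mutation_set(TOY, cand.muts)  # validates
    again = initialize_population(TOY, cfg)
    assert [c.key for c in pop] == [c.key for c in again]


def test_initialization_uniform_over_positions():
    """10 000 single-edit draws: per-position counts within multinomial 99% CI."""
    from scipy.stats import binom

    cfg = GAConfig(population=10_000, generations=1, max_edits=1, seed=5)
    pop = initialize_population(TOY, cfg)
    positions = [c.muts.specs[0].position for c in pop]
    counts = np.bincount(positions, minlength=9)[1:]
    lo, hi = binom.ppf([0.005, 0.995], 10_000, 1 / 8)
    # Bonferroni across the 8 positions keeps the joint test near 99%
    assert np.all((counts >= lo) & (counts <= hi))


def test_sequence_shorter_than_max_edits_rejected():
    with pytest.raises(GAError, match="shorter"):
        initialize_population(ProteinSequence("s", "MK"), GAConfig(max_edits=3))


def test_elitism_and_monotone_best_fitness():
    cfg = GAConfig(population=10, generations=15, elite_fraction=0.2,
                   max_edits=1, seed=2, top_n=3)
    report = run_ga(TOY, cfg, RULE)
    best = [entry["best_oriented"] for entry in report.trace]
    assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))


def test_crossover_children_subset_of_parent_edits(rng):
    from psforge.ga import _crossover

    cfg = GAConfig(population=4, max_edits=2, seed=0)
    a = Candidate(MutationSet.from_tokens(["G3A"]), fitness=0.5)
    b = Candidate(MutationSet.from_tokens(["Y5-"]), fitness=0.1)
    seen = set()
    for _ in range(60):
        child = _crossover(a, b, rng, cfg, sign=1.0)
        key = tuple(sorted(str(s) for s in child))
        seen.add(key)
        tokens = {t for c in (a, b) for t in c.muts.tokens()}
        child_tokens = set(MutationSet(child).tokens())
        assert child_tokens <= tokens
    assert len(seen) == 4  # {}, {G3A}, {Y5-}, {G3A, Y5-} all reachable


def _optimal_set(scan):
    """All candidates tied with the scan's argmax (degenerate rule optima)."""
    best = scan[0]["fitness"]
    return {tuple(e["tokens"]) for e in scan
            if e["fitness"] == pytest.approx(best, abs=1e-12)}


def test_ga_matches_exhaustive_oracle_on_toy_problem():
    scan = exhaustive_single_site_scan(TOY, RULE)
    assert len(scan) == 8 * 19 + 8  # 160 candidates
    cfg = GAConfig(population=40, generations=30, max_edits=1, seed=11, top_n=1)
    report = run_ga(TOY, cfg, RULE)
    assert report.ranked[0]["fitness"] == pytest.approx(scan[0]["fitness"])
    assert tuple(report.ranked[0]["tokens"]) in _optimal_set(scan)


def test_ga_decrease_matches_exhaustive_argmin():
    scan = exhaustive_single_site_scan(TOY, RULE, direction="decrease")
    cfg = GAConfig(population=40, generations=30, max_edits=1, seed=11,
                   direction="decrease", top_n=1)
    report = run_ga(TOY, cfg, RULE)
    assert report.ranked[0]["fitness"] == pytest.approx(scan[0]["fitness"])
    assert tuple(report.ranked[0]["tokens"]) in _optimal_set(scan)


def test_constant_scorer_gives_zero_fitness_and_tie_break_order():
    constant = from_sequence_scorer(lambda s: 0.5)
    cfg = GAConfig(population=12, generations=3, max_edits=2, seed=4, top_n=5)
    report = run_ga(TOY, cfg, constant)
    assert all(entry["fitness"] == 0.0 for entry in report.ranked)
    keys = [(e["n_edits"], tuple(e["tokens"])) for e in report.ranked]
    assert keys == sorted(keys)  # fewer edits first, then token order


def test_ga_beats_equal_budget_random_search():
    """Over 5 seeds the GA's best >= best of an equal-size uniform sample."""
    for seed in range(5):
        cfg = GAConfig(population=30, generations=10, max_edits=2, seed=seed,
                       top_n=1)
        report = run_ga(TOY, cfg, RULE)
        budget = report.n_scorer_calls
        rand_cfg = GAConfig(population=budget, generations=1, max_edits=2,
                            seed=seed + 100)
        sample = initialize_population(TOY, rand_cfg)
        base = ground_truth_ps_score(TOY)
        rand_best = max(
            ground_truth_ps_score(apply_mutation_set(TOY, c.muts)) - base
            for c in sample
        )
        assert report.ranked[0]["fitness"] >= rand_best - 1e-12


def test_fitness_cache_bounds_scorer_calls():
    calls = {"n": 0}

    def counting(seq, _muts):
        calls["n"] += 1
        return ground_truth_ps_score(seq)

    cfg = GAConfig(population=20, generations=10, max_edits=1, seed=9)
    report = run_ga(TOY, cfg, counting)
    assert calls["n"] == report.n_scorer_calls
    assert report.n_scorer_calls <= report.n_unique_candidates + 1  # + wild-type


def test_scan_ranks_positions_by_monotone_scorer():
    """A scorer monotone in one position's hydropathy ranks that position's
    substitutions in hydropathy order."""
    pos = 4  # S in MKGSYWAE

    def scorer(seq: ProteinSequence) -> float:
        h = _HYDROPATHY[seq.residues[pos - 1]]
        return (h + 4.5) / 9.0  # affine map of Kyte-Doolittle into [0,1]

    scan = exhaustive_single_site_scan(
        TOY, from_sequence_scorer(scorer), allowed_kinds=("substitution",)
    )
    at_pos = [e for e in scan if e["tokens"][0].startswith(f"S{pos}")]
    hydro = [_HYDROPATHY[e["tokens"][0][-1]] for e in at_pos]
    assert hydro == sorted(hydro, reverse=True)


def test_scorer_outside_unit_interval_rejected():
    bad = from_sequence_scorer(lambda s: 1.5)
    with pytest.raises(GAError, match="outside"):
        run_ga(TOY, GAConfig(population=4, generations=1, seed=0), bad)
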