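"""Genetic-algorithm search over single/few-site mutation space.

The objective is the signed fitness ``fit(x) = PS(x) - PS(x_org)``: the
change in predicted phase-separation score caused by an edit set.  The
GA maximizes it when searching for PS-enhancing edits and maximizes its
negation when ``direction="decrease"``; the reported fitness is always
the signed quantity.

Scorers are callables ``scorer(mutant_seq, muts) -> [0, 1]`` so that
models which want to see the edit annotation (the PS scorer) and plain
sequence functions (the synthetic rule, via :func:`from_sequence_scorer`)
both plug in.  An exhaustive single-site scan is provided as the
verification oracle for desk-scale problems.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np

from .mutations import MutationSet, MutationSpec, apply_mutation_set
from .sequences import CANONICAL_AA, ProteinSequence

MutantScorer = Callable[[ProteinSequence, MutationSet], float]


class GAError(RuntimeError):
    """Invalid configuration or scorer failure with candidate context."""


@dataclass(frozen=True)
class FitnessValue:
    """Signed fitness with its two score components."""

    value: float
    ps_mutant: float
    ps_original: float


@dataclass
class GAConfig:
    population: int = 200
    generations: int = 50
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.3
    #: fraction of each generation replaced by fresh random candidates
    #: ("random immigrants"), keeping exploration alive once the
    #: population has converged on one good edit
    immigrant_fraction: float = 0.1
    elite_fraction: float = 0.05
    max_edits: int = 2
    allowed_kinds: tuple[str, ...] = ("substitution", "deletion")
    direction: str = "increase"
    #: optional exchangeability-biased substitution sampling (BLOSUM62
    #: softmax); off by default.
    natural_bias: bool = False
    top_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise GAError("population must be >= 2")
        if not 0 <= self.elite_fraction <= 0.5:
            raise GAError("elite fraction must lie in [0, 0.5]")
        if self.max_edits < 1:
            raise GAError("max_edits must be >= 1")
        if self.direction not in ("increase", "decrease"):
            raise GAError(f"direction must be increase|decrease, got {self.direction!r}")
        if not set(self.allowed_kinds) <= {"substitution", "deletion"}:
            raise GAError(f"unknown edit kinds {self.allowed_kinds}")


@dataclass
class Candidate:
    muts: MutationSet
    fitness: float | None = None
    born: int = 0

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(self.muts.tokens())


@dataclass
class RecommendationReport:
    ranked: list[dict]
    trace: list[dict]
    config: dict
    seed: int
    n_scorer_calls: int
    n_unique_candidates: int


def from_sequence_scorer(
    fn: Callable[[ProteinSequence], float]
) -> MutantScorer:
    """Adapt a pure sequence->score function to the GA scorer interface."""

    def scorer(mutant: ProteinSequence, _muts: MutationSet) -> float:
        return fn(mutant)

    return scorer


def fitness(
    x: ProteinSequence,
    x_org: ProteinSequence,
    scorer: Callable[[ProteinSequence], float],
) -> FitnessValue:
    """fit(x) = PS(x) - PS(x_org) for a pure sequence scorer."""
    ps_x = float(scorer(x))
    ps_org = float(scorer(x_org))
    return FitnessValue(value=ps_x - ps_org, ps_mutant=ps_x, ps_original=ps_org)


# -- operators -------------------------------------------------------------

_BLOSUM_CACHE: dict[str, np.ndarray] = {}


def _blosum_probs(ref: str) -> np.ndarray:
    """Substitution distribution over the 19 alternatives ∝ exp(BLOSUM62/2)."""
    if ref not in _BLOSUM_CACHE:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        scores = np.array([mat[ref, alt] for alt in CANONICAL_AA], dtype=float)
        w = np.exp(scores / 2.0)
        w[CANONICAL_AA.index(ref)] = 0.0
        _BLOSUM_CACHE[ref] = w / w.sum()
    return _BLOSUM_CACHE[ref]


def _random_edit(
    parent: ProteinSequence,
    rng: np.random.Generator,
    cfg: GAConfig,
    taken: set[int],
) -> MutationSpec | None:
    free = [p for p in range(1, len(parent) + 1) if p not in taken]
    if not free:
        return None
    pos = int(free[rng.integers(len(free))])
    ref = parent.residue_at(pos)
    kind = cfg.allowed_kinds[rng.integers(len(cfg.allowed_kinds))]
    if kind == "deletion":
        return MutationSpec(pos, ref, kind="deletion")
    if cfg.natural_bias:
        alt = str(rng.choice(list(CANONICAL_AA), p=_blosum_probs(ref)))
    else:
        alts = [a for a in CANONICAL_AA if a != ref]
        alt = alts[rng.integers(len(alts))]
    return MutationSpec(pos, ref, alt)


def _random_candidate(
    parent: ProteinSequence, rng: np.random.Generator, cfg: GAConfig, born: int
) -> Candidate:
    n_edits = int(rng.integers(1, cfg.max_edits + 1))
    specs: list[MutationSpec] = []
    taken: set[int] = set()
    for _ in range(n_edits):
        spec = _random_edit(parent, rng, cfg, taken)
        if spec is None:
            break
        specs.append(spec)
        taken.add(spec.position)
    return Candidate(MutationSet(specs), born=born)


def initialize_population(
    x_org: ProteinSequence, cfg: GAConfig, seed: int | None = None
) -> list[Candidate]:
    """Distinct-where-possible random 1..max_edits candidates."""
    if len(x_org) < cfg.max_edits:
        raise GAError(
            f"sequence length {len(x_org)} shorter than max_edits {cfg.max_edits}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pop: list[Candidate] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(pop) < cfg.population:
        cand = _random_candidate(x_org, rng, cfg, born=0)
        attempts += 1
        if cand.key in seen and attempts < 30 * cfg.population:
            continue
        seen.add(cand.key)
        pop.append(cand)
    return pop


def _rank_key(cand: Candidate, sign: float):
    return (-sign * cand.fitness, len(cand.muts), cand.key)


class _FitnessCache:
    """Each unique candidate is scored at most once per run."""

    def __init__(self, parent: ProteinSequence, scorer: MutantScorer) -> None:
        self.parent = parent
        self.scorer = scorer
        self.cache: dict[tuple[str, ...], float] = {}
        self.calls = 0
        self.base = self._score(MutationSet())

    def _score(self, muts: MutationSet) -> float:
        mutant = apply_mutation_set(self.parent, muts)
        self.calls += 1
        try:
            value = float(self.scorer(mutant, muts))
        except Exception as exc:  # pragma: no cover - propagation path
            raise GAError(
                f"scorer failed on candidate {'+'.join(muts.tokens()) or 'wild-type'}: {exc}"
            ) from exc
        if not 0.0 <= value <= 1.0:
            raise GAError(
                f"scorer returned {value} outside [0, 1] for "
                f"{'+'.join(muts.tokens()) or 'wild-type'}"
            )
        return value

    def fitness(self, cand: Candidate) -> float:
        key = cand.key
        if key not in self.cache:
            self.cache[key] = self._score(cand.muts) - self.base
        cand.fitness = self.cache[key]
        return cand.fitness


def _tournament(
    pop: list[Candidate], rng: np.random.Generator, cfg: GAConfig, sign: float
) -> Candidate:
    picks = [pop[int(i)] for i in rng.integers(len(pop), size=cfg.tournament)]
    return min(picks, key=lambda c: _rank_key(c, sign))


def _crossover(
    a: Candidate, b: Candidate, rng: np.random.Generator, cfg: GAConfig, sign: float
) -> list[MutationSpec]:
    """Child inherits each parental edit independently with probability 0.5;
    same-position conflicts resolve in favour of the fitter parent."""
    fitter, other = sorted((a, b), key=lambda c: _rank_key(c, sign))
    specs: dict[int, MutationSpec] = {}
    for cand in (fitter, other):  # fitter first wins position conflicts
        for spec in cand.muts:
            if rng.random() < 0.5 and spec.position not in specs:
                specs[spec.position] = spec
    chosen = list(specs.values())
    if len(chosen) > cfg.max_edits:
        keep = rng.choice(len(chosen), size=cfg.max_edits, replace=False)
        chosen = [chosen[int(i)] for i in sorted(keep)]
    return chosen


def _mutate(
    specs: list[MutationSpec],
    parent: ProteinSequence,
    rng: np.random.Generator,
    cfg: GAConfig,
) -> list[MutationSpec]:
    """Add, remove, or resample one edit."""
    ops = ["resample"]
    if len(specs) < cfg.max_edits:
        ops.append("add")
    if len(specs) >= 1:
        ops.append("remove")
    op = ops[rng.integers(len(ops))]
    specs = list(specs)
    taken = {s.position for s in specs}
    if op == "add" or (op == "resample" and not specs):
        new = _random_edit(parent, rng, cfg, taken)
        if new is not None:
            specs.append(new)
    elif op == "remove":
        specs.pop(int(rng.integers(len(specs))))
    else:
        idx = int(rng.integers(len(specs)))
        taken.discard(specs[idx].position)
        new = _random_edit(parent, rng, cfg, taken)
        if new is not None:
            specs[idx] = new
    return specs


def step_generation(
    pop: list[Candidate],
    x_org: ProteinSequence,
    cfg: GAConfig,
    cache: _FitnessCache,
    rng: np.random.Generator,
    generation: int,
) -> tuple[list[Candidate], dict]:
    """One evolution step: elitism, tournament selection, crossover, mutation."""
    sign = 1.0 if cfg.direction == "increase" else -1.0
    for cand in pop:
        cache.fitness(cand)
    ranked = sorted(pop, key=lambda c: _rank_key(c, sign))
    n_elite = int(round(cfg.elite_fraction * cfg.population))
    next_pop = [Candidate(c.muts, c.fitness, c.born) for c in ranked[:n_elite]]
    n_immigrants = int(round(cfg.immigrant_fraction * cfg.population))
    for _ in range(min(n_immigrants, cfg.population - len(next_pop))):
        next_pop.append(_random_candidate(x_org, rng, cfg, born=generation))
    while len(next_pop) < cfg.population:
        if rng.random() < cfg.crossover_rate:
            pa = _tournament(pop, rng, cfg, sign)
            pb = _tournament(pop, rng, cfg, sign)
            specs = _crossover(pa, pb, rng, cfg, sign)
        else:
            specs = list(_tournament(pop, rng, cfg, sign).muts)
        if rng.random() < cfg.mutation_rate:
            specs = _mutate(specs, x_org, rng, cfg)
        next_pop.append(Candidate(MutationSet(specs), born=generation))
    for cand in next_pop:
        cache.fitness(cand)
    best = min(next_pop, key=lambda c: _rank_key(c, sign))
    entry = {
        "generation": generation,
        "best_fitness": float(best.fitness),          # signed quantity
        "best_oriented": float(sign * best.fitness),  # what the GA maximizes
        "mean_fitness": float(np.mean([c.fitness for c in next_pop])),
    }
    return next_pop, entry


def run_ga(
    x_org: ProteinSequence, cfg: GAConfig, scorer: MutantScorer
) -> RecommendationReport:
    """Full GA loop with fitness caching and a ranked recommendation list."""
    rng = np.random.default_rng(cfg.seed + 1)
    cache = _FitnessCache(x_org, scorer)
    sign = 1.0 if cfg.direction == "increase" else -1.0
    pop = initialize_population(x_org, cfg)
    for cand in pop:
        cache.fitness(cand)
    trace: list[dict] = []
    for gen in range(1, cfg.generations + 1):
        pop, entry = step_generation(pop, x_org, cfg, cache, rng, gen)
        trace.append(entry)

    all_cands = [
        Candidate(MutationSet.from_tokens(key), fit)
        for key, fit in cache.cache.items()
        if key  # exclude wild-type
    ]
    all_cands.sort(key=lambda c: _rank_key(c, sign))
    ranked = [
        {
            "tokens": list(c.key),
            "fitness": c.fitness,
            "n_edits": len(c.muts),
            "mixed_kinds": c.muts.has_mixed_kinds,
        }
        for c in all_cands[: cfg.top_n]
    ]
    return RecommendationReport(
        ranked=ranked,
        trace=trace,
        config=asdict(cfg),
        seed=cfg.seed,
        n_scorer_calls=cache.calls,
        n_unique_candidates=len(cache.cache),
    )


def exhaustive_single_site_scan(
    x_org: ProteinSequence,
    scorer: MutantScorer,
    direction: str = "increase",
    allowed_kinds: tuple[str, ...] = ("substitution", "deletion"),
) -> list[dict]:
    """Score every single-site edit (19L substitutions + L deletions).

    Exact oracle ranking under the documented tie-break: better oriented
    fitness, then fewer edits (trivially equal here), then token order.
    """
    if len(x_org) > 500:
        raise GAError("exhaustive scan is limited to length <= 500")
    from .synthetic import enumerate_single_edits

    sign = 1.0 if direction == "increase" else -1.0
    cache = _FitnessCache(x_org, scorer)
    cands = []
    for muts in enumerate_single_edits(x_org):
        if muts.specs[0].kind not in allowed_kinds:
            continue
        cand = Candidate(muts)
        cache.fitness(cand)
        cands.append(cand)
    cands.sort(key=lambda c: _rank_key(c, sign))
    return [
        {"tokens": list(c.key), "fitness": c.fitness} for c in cands
    ]
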