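"""Pattern quality control.

Three optimizers over an induced pattern set:

* precision filtering — rank every pattern by the precision of the
  predictions it makes on annotated data and iteratively drop those below
  a cutoff (iterated to a fixed point because removing a lower-order
  pattern can starve higher-order patterns downstream);
* per-pattern distance-threshold learning — an explicit ascending scan for
  lower-order patterns (accept a larger threshold only when training
  corrects strictly increase at no loss of precision, validated on
  held-out data), plus a genetic algorithm that assigns thresholds to all
  higher-order patterns jointly by maximizing training F-score;
* empirical-risk-minimization backward elimination — greedily remove the
  pattern whose removal most reduces f(P) = (wrong + missed events)
  + lambda * total pattern redundancy, where a pattern's redundancy is the
  fraction of its nodes that are non-essential.

All three operate on a candidate cache extracted once at the maximum
threshold and re-filtered per setting, which is exactly equivalent to
fresh extraction (see :func:`asmevent.event_engine.filter_candidates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asm_core import NodeMatchPolicy
from .corpus_io import Document
from .event_engine import (
    CandidateEvent,
    TaskConfig,
    extract_corpus,
    filter_candidates,
    gold_event_keys,
)
from .pattern_induction import EventPattern


@dataclass
class PatternStats:
    pattern_id: str
    n_total: int
    n_correct: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 100
    value_range: tuple[int, int] = (0, 6)
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_size: int = 2
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population size and generations must be >= 1")


@dataclass
class ERMConfig:
    lambda_reg: float = 3.0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass
class ThresholdAssignment:
    thresholds: dict[str, float] = field(default_factory=dict)

    def merged(self, other: "ThresholdAssignment") -> dict[str, float]:
        out = dict(self.thresholds)
        out.update(other.thresholds)
        return out


# --------------------------------------------------------------------------
# shared helpers


def _max_config(cfg: TaskConfig, t_max: float) -> TaskConfig:
    return TaskConfig(
        event_types=cfg.event_types,
        per_type_threshold={},
        weights=cfg.weights,
        default_threshold=t_max,
        allow_skip=cfg.allow_skip,
        max_rounds=cfg.max_rounds,
    )


def _gold_keys(docs: list[Document]) -> set[tuple]:
    out: set[tuple] = set()
    for d in docs:
        out |= gold_event_keys(d)
    return out


def _collect_valid(cands: list[CandidateEvent], thresholds, active=None) -> list[CandidateEvent]:
    return filter_candidates(cands, thresholds, active)


# --------------------------------------------------------------------------
# Eq. (1): precision-based filtering


def pattern_statistics(
    patterns: list[EventPattern],
    docs: list[Document],
    cfg: TaskConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
) -> dict[str, PatternStats]:
    """Per-pattern prediction counts from one end-to-end extraction.

    A deduplicated candidate counts once for every pattern that produced
    it; it is correct when it strictly equals a gold event.
    """
    gold = _gold_keys(docs)
    cands = extract_corpus(docs, patterns, cfg, policy, allow_skip)
    stats = {p.pattern_id: PatternStats(p.pattern_id, 0, 0) for p in patterns}
    for c in cands:
        correct = c.key() in gold
        for pid, _d in c.productions:
            st = stats[pid]
            st.n_total += 1
            if correct:
                st.n_correct += 1
    return stats


def pattern_precision(
    p: EventPattern,
    docs: list[Document],
    cfg: TaskConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
    support: list[EventPattern] = (),
) -> PatternStats:
    """Precision of one pattern's predictions; ``support`` supplies the
    lower-order patterns a higher-order ``p`` depends on."""
    stats = pattern_statistics([p, *support], docs, cfg, policy, allow_skip)
    return stats[p.pattern_id]


def precision_filter(
    patterns: list[EventPattern],
    docs: list[Document],
    cfg: TaskConfig,
    min_precision: float = 0.25,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
) -> list[EventPattern]:
    """Iteratively drop patterns whose prediction precision falls below the
    cutoff, re-running the end-to-end extraction each round until a fixed
    point (removals can starve dependent higher-order patterns)."""
    if not 0 <= min_precision <= 1:
        raise ValueError("min_precision must lie in [0, 1]")
    current = list(patterns)
    while True:
        stats = pattern_statistics(current, docs, cfg, policy, allow_skip)
        keep = [p for p in current if stats[p.pattern_id].precision >= min_precision]
        if len(keep) == len(current):
            return current
        current = keep


# --------------------------------------------------------------------------
# Algorithm 1: per-pattern threshold learning


def _single_pattern_curve(
    p: EventPattern,
    docs: list[Document],
    cfg: TaskConfig,
    t_max: float,
    policy: NodeMatchPolicy | None,
    allow_skip: bool | None,
) -> list[tuple[float, bool]]:
    """(distance, correct) for every prediction of ``p`` alone at t_max."""
    gold = _gold_keys(docs)
    cands = extract_corpus(
        docs, [p], _max_config(cfg, t_max), policy, allow_skip, prune_partials=False
    )
    return [(c.distance, c.key() in gold) for c in cands]


def _counts_at(curve: list[tuple[float, bool]], v: float) -> tuple[int, int]:
    eps = 1e-9
    total = sum(1 for d, _ in curve if d <= v + eps)
    correct = sum(1 for d, ok in curve if ok and d <= v + eps)
    return correct, total


def _prec(correct: int, total: int) -> float:
    return correct / total if total else 0.0


def learn_lower_thresholds(
    lower: list[EventPattern],
    train: list[Document],
    heldout: list[Document],
    cfg: TaskConfig,
    value_range: tuple[int, int] = (0, 12),
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
) -> ThresholdAssignment:
    """Explicit ascending scan per lower-order pattern.

    A candidate threshold replaces the current one only when training
    corrects strictly increase, training precision does not drop, and the
    held-out corrects and precision do not drop either.  Among equally good
    values the smallest is kept.  Matching runs once per pattern at the
    range maximum; the scan re-filters cached predictions.
    """
    lo, hi = value_range
    out: dict[str, float] = {}
    for p in lower:
        if p.is_higher_order:
            raise ValueError(f"{p.pattern_id} is higher-order")
        tr = _single_pattern_curve(p, train, cfg, hi, policy, allow_skip)
        hd = _single_pattern_curve(p, heldout, cfg, hi, policy, allow_skip)
        cur = lo
        cur_tc, cur_tt = _counts_at(tr, cur)
        cur_hc, cur_ht = _counts_at(hd, cur)
        for v in range(lo + 1, hi + 1):
            tc, tt = _counts_at(tr, v)
            hc, ht = _counts_at(hd, v)
            if (
                tc > cur_tc
                and _prec(tc, tt) >= _prec(cur_tc, cur_tt)
                and hc >= cur_hc
                and _prec(hc, ht) >= _prec(cur_hc, cur_ht)
            ):
                cur, cur_tc, cur_tt, cur_hc, cur_ht = v, tc, tt, hc, ht
        out[p.pattern_id] = float(cur)
    return ThresholdAssignment(out)


def ga_optimize_thresholds(
    patterns: list[EventPattern],
    lower_thresholds: ThresholdAssignment,
    train: list[Document],
    ga_cfg: GAConfig,
    task_cfg: TaskConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
) -> ThresholdAssignment:
    """Jointly assign integer thresholds to all higher-order patterns with
    an elitist genetic algorithm whose fitness is the strict F-score of the
    whole pattern set on the training data.  Lower-order thresholds stay
    fixed.  Reproducible given ``ga_cfg.seed``."""
    higher = sorted(
        (p for p in patterns if p.is_higher_order), key=lambda p: p.pattern_id
    )
    if not higher:
        return ThresholdAssignment({})
    lo, hi = ga_cfg.value_range
    t_max = float(
        max([hi, *lower_thresholds.thresholds.values()] or [hi])
    )
    cands = extract_corpus(
        train, patterns, _max_config(task_cfg, t_max), policy, allow_skip, prune_partials=False
    )
    gold = _gold_keys(train)
    fixed = dict(lower_thresholds.thresholds)
    for p in patterns:
        if not p.is_higher_order and p.pattern_id not in fixed:
            fixed[p.pattern_id] = float(p.threshold)
    ids = [p.pattern_id for p in higher]

    cache: dict[tuple[int, ...], float] = {}

    def fitness(genome: tuple[int, ...]) -> float:
        got = cache.get(genome)
        if got is not None:
            return got
        thr = dict(fixed)
        thr.update({pid: float(v) for pid, v in zip(ids, genome)})
        valid = filter_candidates(cands, thr)
        pred = {c.key() for c in valid}
        tp = len(pred & gold)
        fp = len(pred - gold)
        fn = len(gold - pred)
        r = tp / (tp + fn) if tp + fn else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        f = 2 * r * pr / (r + pr) if r + pr else 0.0
        cache[genome] = f
        return f

    rng = np.random.default_rng(ga_cfg.seed)
    n = len(ids)
    pop = rng.integers(lo, hi + 1, size=(ga_cfg.population_size, n))
    scores = np.array([fitness(tuple(g)) for g in pop])
    best_g, best_f = tuple(pop[int(scores.argmax())]), float(scores.max())
    for _gen in range(ga_cfg.generations):
        new = []
        elite_idx = np.argsort(-scores)[: ga_cfg.elitism]
        new.extend(pop[i].copy() for i in elite_idx)
        while len(new) < ga_cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=ga_cfg.tournament_size)
                winner = max(contenders, key=lambda i: scores[i])
                parents.append(pop[winner].copy())
            c1, c2 = parents
            if rng.random() < ga_cfg.crossover_rate:
                mask = rng.random(n) < 0.5
                c1[mask], c2[mask] = c2[mask].copy(), c1[mask].copy()
            for child in (c1, c2):
                mut = rng.random(n) < ga_cfg.mutation_rate
                child[mut] = rng.integers(lo, hi + 1, size=int(mut.sum()))
                new.append(child)
        pop = np.array(new[: ga_cfg.population_size])
        scores = np.array([fitness(tuple(g)) for g in pop])
        gi = int(scores.argmax())
        if scores[gi] > best_f:
            best_g, best_f = tuple(pop[gi]), float(scores[gi])
    return ThresholdAssignment({pid: float(v) for pid, v in zip(ids, best_g)})


# --------------------------------------------------------------------------
# Algorithm 2: ERM backward elimination


def pattern_redundancy(p: EventPattern) -> float:
    """Fraction of pattern nodes that are non-essential, in [0, 1)."""
    return (len(p.nodes) - len(p.essential_nodes)) / len(p.nodes)


class _ErmContext:
    """Cached-candidate evaluation of f(P') for subsets P' of the input."""

    def __init__(
        self,
        patterns: list[EventPattern],
        docs: list[Document],
        cfg: TaskConfig,
        erm_cfg: ERMConfig,
        policy: NodeMatchPolicy | None,
        allow_skip: bool | None,
    ) -> None:
        self.redundancy = {p.pattern_id: pattern_redundancy(p) for p in patterns}
        self.thresholds = {p.pattern_id: float(p.threshold) for p in patterns}
        t_max = max([0.0, *self.thresholds.values()])
        self.cands = extract_corpus(
            docs, patterns, _max_config(cfg, t_max), policy, allow_skip, prune_partials=False
        )
        self.gold = _gold_keys(docs)
        self.lam = erm_cfg.lambda_reg

    def objective(self, active: set[str]) -> float:
        valid = filter_candidates(self.cands, self.thresholds, active)
        pred = {c.key() for c in valid}
        e = len(pred - self.gold) + len(self.gold - pred)
        c_p = sum(self.redundancy[pid] for pid in active)
        return e + self.lam * c_p


def erm_objective(
    patterns: list[EventPattern],
    docs: list[Document],
    cfg: TaskConfig,
    erm_cfg: ERMConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
) -> float:
    """f(P) = (wrong + missed events) + lambda * total redundancy, with each
    pattern applied at its own fixed threshold."""
    ctx = _ErmContext(patterns, docs, cfg, erm_cfg, policy, allow_skip)
    return ctx.objective({p.pattern_id for p in patterns})


def erm_optimize(
    patterns: list[EventPattern],
    docs: list[Document],
    cfg: TaskConfig,
    erm_cfg: ERMConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
    trace: list[float] | None = None,
) -> list[EventPattern]:
    """Greedy backward elimination: repeatedly remove the pattern whose
    removal most reduces f(P); stop when no removal reduces it (maxGain
    <= 0).  Ties are broken by smallest pattern id.  ``trace``, if given,
    collects the strictly decreasing sequence of objective values."""
    ctx = _ErmContext(patterns, docs, cfg, erm_cfg, policy, allow_skip)
    active = {p.pattern_id for p in patterns}
    f_cur = ctx.objective(active)
    if trace is not None:
        trace.append(f_cur)
    while active:
        best_gain, best_pid = 0.0, None
        for pid in sorted(active):
            gain = f_cur - ctx.objective(active - {pid})
            if gain > best_gain:
                best_gain, best_pid = gain, pid
        if best_pid is None:
            break
        active.remove(best_pid)
        f_cur -= best_gain
        if trace is not None:
            trace.append(f_cur)
    return [p for p in patterns if p.pattern_id in active]
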