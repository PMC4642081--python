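"""Iterative bottom-up extraction of (possibly nested) events.

Patterns whose arguments are all entities (*lower-order*) are matched
first; every event they produce then becomes a potential argument for
*higher-order* patterns, whose sub-event-trigger nodes must land on the
trigger token of an already-extracted event of any type.  The loop runs to
a fixpoint (or a round cap).  Candidates are deduplicated by recursive
structural equality, each one remembering every (pattern, distance) pair
that produced it so that re-filtering a cached candidate set under a new
threshold vector is exactly equivalent to a fresh extraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .asm_core import DistanceWeights, Match, NodeMatchPolicy, find_matches
from .corpus_io import Document
from .pattern_induction import TRIGGER_ROLE, EventPattern

log = logging.getLogger(__name__)


@dataclass
class CandidateEvent:
    """An extracted event; argument targets are entity ids or other candidates."""

    doc_id: str
    sentence_index: int
    event_type: str
    trigger_tokens: frozenset[int]
    args: tuple[tuple[str, object], ...]  # (role, entity-id str | CandidateEvent)
    pattern_id: str
    distance: float
    #: every (pattern_id, distance) that produced this structural event
    productions: list[tuple[str, float]] = field(default_factory=list)

    @property
    def sub_refs(self) -> tuple["CandidateEvent", ...]:
        return tuple(t for _, t in self.args if isinstance(t, CandidateEvent))

    def key(self) -> tuple:
        """Recursive structural identity (type, trigger, role-labeled args)."""
        parts = []
        for role, target in self.args:
            if isinstance(target, CandidateEvent):
                parts.append((role, target.key()))
            else:
                parts.append((role, ("T", target)))
        return (
            self.doc_id,
            self.event_type,
            self.trigger_tokens,
            frozenset(parts),
        )


@dataclass
class TaskConfig:
    """Task-level parameters: event types, per-type thresholds, weights."""

    event_types: tuple[str, ...]
    per_type_threshold: dict[str, float] = field(default_factory=dict)
    weights: DistanceWeights = field(default_factory=DistanceWeights)
    default_threshold: float = 0.0
    allow_skip: bool = False
    max_rounds: int = 10

    def threshold_for(self, event_type: str) -> float:
        return self.per_type_threshold.get(event_type, self.default_threshold)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0


def parameter_vector(cfg: TaskConfig) -> list[tuple[str, float]]:
    """The ASM parameter vector: one threshold per event type followed by
    the active distance weights (w_s, w_l, w_d, plus w_n with skipping)."""
    params = [(f"t_{et}", cfg.threshold_for(et)) for et in cfg.event_types]
    w = cfg.weights
    params += [("w_s", w.w_s), ("w_l", w.w_l), ("w_d", w.w_d)]
    if cfg.allow_skip:
        params.append(("w_n", w.w_n))
    return params


# --------------------------------------------------------------------------
# extraction


def _entity_by_head(doc: Document, sent_i: int) -> dict[int, str]:
    return {
        ent.head_token: ent.id
        for ent in doc.entities.values()
        if ent.sentence_index == sent_i
    }


def _binding_nodes(p: EventPattern) -> tuple[list, list]:
    """Split non-trigger bindings into entity-argument and sub-event ones."""
    entity_args, sub_args = [], []
    for b in p.bindings:
        if b.role == TRIGGER_ROLE:
            continue
        (sub_args if b.sub_event_type else entity_args).append(b)
    return entity_args, sub_args


def _candidates_from_match(
    doc: Document,
    sent_i: int,
    p: EventPattern,
    m: Match,
    pool: list[CandidateEvent],
) -> list[CandidateEvent]:
    """Instantiate events from one graph match.

    Entity-bound argument nodes resolve to the entity mention headed by
    their image token; sub-event nodes resolve to every already-extracted
    event (of any type) whose trigger contains the image token, producing
    one candidate per combination.
    """
    pairs = m.mapping.as_dict
    heads = _entity_by_head(doc, sent_i)
    trigger = frozenset(
        pairs[b.node] for b in p.bindings if b.role == TRIGGER_ROLE
    )
    entity_args, sub_args = _binding_nodes(p)
    fixed: list[tuple[str, object]] = []
    for b in entity_args:
        ent = heads.get(pairs[b.node])
        if ent is None:
            return []
        fixed.append((b.role, ent))
    option_lists: list[list[tuple[str, object]]] = []
    for b in sub_args:
        image = pairs[b.node]
        opts = [
            (b.role, cand)
            for cand in pool
            if cand.sentence_index == sent_i and image in cand.trigger_tokens
        ]
        if not opts:
            return []
        option_lists.append(opts)
    out = []
    for combo in itertools.product(*option_lists):
        out.append(
            CandidateEvent(
                doc_id=doc.doc_id,
                sentence_index=sent_i,
                event_type=p.event_type,
                trigger_tokens=trigger,
                args=tuple(fixed) + tuple(combo),
                pattern_id=p.pattern_id,
                distance=m.total,
                productions=[(p.pattern_id, m.total)],
            )
        )
    return out


def extract_events(
    doc: Document,
    patterns: list[EventPattern],
    cfg: TaskConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
    prune_partials: bool = True,
    per_pattern_threshold: dict[str, float] | None = None,
) -> list[CandidateEvent]:
    """Bottom-up fixpoint extraction over one document.

    Round 0 matches lower-order patterns; later rounds re-match higher-order
    patterns against the growing candidate pool until no new structurally
    distinct event appears or ``cfg.max_rounds`` is hit (logged; partial
    output returned).

    ``prune_partials=False`` keeps partial (subsumed) events in the output;
    required when the result serves as a candidate cache for
    :func:`filter_candidates`, which applies the same pruning itself after
    validity filtering.
    """
    policy = policy or NodeMatchPolicy()
    if allow_skip is None:
        allow_skip = cfg.allow_skip
    lower = [p for p in patterns if not p.is_higher_order]
    higher = [p for p in patterns if p.is_higher_order]

    # graph matching happens once per (pattern, sentence)
    matches: dict[str, list[tuple[int, Match]]] = {}
    for p in lower + higher:
        if per_pattern_threshold is not None:
            t = per_pattern_threshold.get(p.pattern_id, cfg.threshold_for(p.event_type))
        else:
            t = cfg.threshold_for(p.event_type)
        hits = []
        for si, sent in enumerate(doc.sentences):
            for m in find_matches(p, sent, cfg.weights, t, policy, allow_skip):
                hits.append((si, m))
        matches[p.pattern_id] = hits

    by_key: dict[tuple, CandidateEvent] = {}

    def absorb(cand: CandidateEvent) -> bool:
        k = cand.key()
        cur = by_key.get(k)
        if cur is None:
            by_key[k] = cand
            return True
        for prod in cand.productions:
            if prod not in cur.productions:
                cur.productions.append(prod)
        if cand.distance < cur.distance:
            cur.distance, cur.pattern_id = cand.distance, cand.pattern_id
        return False

    for p in lower:
        for si, m in matches[p.pattern_id]:
            for cand in _candidates_from_match(doc, si, p, m, []):
                absorb(cand)

    rounds = 0
    while True:
        rounds += 1
        if rounds > cfg.max_rounds:
            log.warning("%s: extraction stopped after %d rounds", doc.doc_id, cfg.max_rounds)
            break
        pool = list(by_key.values())
        new = 0
        for p in higher:
            for si, m in matches[p.pattern_id]:
                for cand in _candidates_from_match(doc, si, p, m, pool):
                    if absorb(cand):
                        new += 1
        if new == 0:
            break
    out = list(by_key.values())
    if prune_partials:
        return _drop_subsumed(out)
    return sorted(
        out,
        key=lambda c: (c.doc_id, c.sentence_index, sorted(c.trigger_tokens), c.event_type, c.distance),
    )


def _arg_keys(c: CandidateEvent) -> frozenset:
    parts = []
    for role, target in c.args:
        if isinstance(target, CandidateEvent):
            parts.append((role, target.key()))
        else:
            parts.append((role, ("T", target)))
    return frozenset(parts)


def _drop_subsumed(cands: list[CandidateEvent]) -> list[CandidateEvent]:
    """Fold partial events into fuller ones.

    Individual-path patterns extract each argument of a multi-argument
    event separately; when a candidate's role-labeled argument set is a
    strict subset of another candidate with the same type and trigger, the
    partial one is dropped in favor of the joint event.
    """
    groups: dict[tuple, list[CandidateEvent]] = {}
    for c in cands:
        groups.setdefault(
            (c.doc_id, c.sentence_index, c.event_type, c.trigger_tokens), []
        ).append(c)
    kept: list[CandidateEvent] = []
    for group in groups.values():
        argsets = [(_arg_keys(c), c) for c in group]
        for ak, c in argsets:
            if any(ak < other for other, _ in argsets):
                continue
            kept.append(c)
    return sorted(
        kept,
        key=lambda c: (c.doc_id, c.sentence_index, sorted(c.trigger_tokens), c.event_type, c.distance),
    )


def filter_candidates(
    cands: list[CandidateEvent],
    thresholds: dict[str, float],
    active_patterns: set[str] | None = None,
) -> list[CandidateEvent]:
    """Re-filter cached candidates under a per-pattern threshold vector.

    A candidate is valid iff some production's pattern is active and its
    distance is within that pattern's threshold, and all sub-event
    arguments are themselves valid (recursively).  Given candidates that
    were generated exhaustively at the maximum threshold, this equals
    re-running :func:`extract_events` at the new thresholds.
    """
    eps = 1e-9
    memo: dict[int, bool] = {}

    def valid(c: CandidateEvent) -> bool:
        got = memo.get(id(c))
        if got is not None:
            return got
        ok = False
        for pid, d in c.productions:
            if pid not in thresholds:
                raise KeyError(f"unknown pattern id {pid!r} in candidate productions")
            if active_patterns is not None and pid not in active_patterns:
                continue
            if d <= thresholds[pid] + eps:
                ok = True
                break
        ok = ok and all(valid(s) for s in c.sub_refs)
        memo[id(c)] = ok
        return ok

    return _drop_subsumed([c for c in cands if valid(c)])


# --------------------------------------------------------------------------
# strict evaluation


def gold_event_keys(doc: Document) -> set[tuple]:
    """Structural keys of the document's gold events, mirroring
    :meth:`CandidateEvent.key` (entity targets by mention id, event targets
    recursively)."""
    keys: dict[str, tuple] = {}

    def key_of(eid: str) -> tuple:
        if eid in keys:
            return keys[eid]
        ev = doc.events[eid]
        parts = []
        for role, target in ev.args:
            if target.startswith("E"):
                parts.append((role, key_of(target)))
            else:
                parts.append((role, ("T", target)))
        k = (doc.doc_id, ev.type, ev.trigger_tokens, frozenset(parts))
        keys[eid] = k
        return k

    return {key_of(eid) for eid in doc.events}


def evaluate_strict(
    pred: list[CandidateEvent], docs: list[Document]
) -> EvalResult:
    """Strict recursive matching: an event is correct iff its type, trigger
    token set and role-labeled arguments (recursively) equal a gold event."""
    gold: set[tuple] = set()
    for doc in docs:
        gold |= gold_event_keys(doc)
    pred_keys = {c.key() for c in pred}
    tp = len(pred_keys & gold)
    return EvalResult(tp=tp, fp=len(pred_keys - gold), fn=len(gold - pred_keys))


def extract_corpus(
    docs: list[Document],
    patterns: list[EventPattern],
    cfg: TaskConfig,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool | None = None,
    prune_partials: bool = True,
    per_pattern_threshold: dict[str, float] | None = None,
) -> list[CandidateEvent]:
    out: list[CandidateEvent] = []
    for doc in docs:
        out.extend(
            extract_events(
                doc, patterns, cfg, policy, allow_skip, prune_partials, per_pattern_threshold
            )
        )
    return out
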