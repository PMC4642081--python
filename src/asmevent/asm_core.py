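"""Approximate subgraph matching (ASM).

A pattern graph G_r is approximately isomorphic to a subgraph of a sentence
graph G_s when an injective mapping f of its nodes exists whose weighted
subgraph distance

    subgraphDist = w_s*structDist + w_l*labelDist + w_d*directionalityDist
                   + w_n*nodeDist

does not exceed a threshold t.  structDist accumulates path-length
differences, labelDist counts edge-label differences, directionalityDist
counts edge-orientation differences, and nodeDist penalizes skipped
non-essential pattern nodes, normalized by the pattern size
(|skipped| / |V_r|).  When no node is skipped the extended distance equals
the original three-component distance.  Essential nodes (trigger,
sub-event trigger and argument nodes) can never be skipped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx

from .corpus_io import DependencyEdge, SentenceGraph, Token
from .pattern_induction import EventPattern

INF = math.inf


@dataclass(frozen=True)
class DistanceWeights:
    """Non-negative weights of the four distance components (equal by default)."""

    w_s: float = 1.0
    w_l: float = 1.0
    w_d: float = 1.0
    w_n: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_s, self.w_l, self.w_d, self.w_n) < 0:
            raise ValueError("distance weights must be non-negative")


@dataclass(frozen=True)
class NodeMatchPolicy:
    """Node equality criterion.

    ``P*+L`` (the default) requires identical relaxed POS tags and
    identical lemmas; ``P*+L+DSM`` additionally accepts a sentence lemma
    among the top-M distributionally most similar words of the pattern
    lemma.  ``EXACT`` compares surface+POS, ``L`` lemmas only, ``P``
    relaxed POS only.
    """

    criteria: str = "P*+L"
    dsm_model: object | None = None
    dsm_top_m: int = 3

    def __post_init__(self) -> None:
        if self.criteria not in ("EXACT", "L", "P", "P*+L", "P*+L+DSM"):
            raise ValueError(f"unknown matching criteria {self.criteria!r}")
        if self.criteria == "P*+L+DSM" and self.dsm_model is None:
            raise ValueError("DSM matching requested but no model provided")


@dataclass(frozen=True)
class Mapping:
    """Injective partial map pattern-node -> sentence-node plus skipped set."""

    pairs: tuple[tuple[int, int], ...]
    skipped: frozenset[int] = frozenset()

    @classmethod
    def of(cls, pairs: dict[int, int], skipped: set[int] | frozenset[int] = frozenset()) -> "Mapping":
        return cls(pairs=tuple(sorted(pairs.items())), skipped=frozenset(skipped))

    @property
    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def image(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.pairs)


@dataclass(frozen=True)
class Match:
    """A mapping with its per-component and total subgraph distance."""

    pattern_id: str
    mapping: Mapping
    struct_d: float
    label_d: float
    dir_d: float
    node_d: float
    total: float

    def sort_key(self) -> tuple:
        return (self.total, len(self.mapping.skipped), self.mapping.pairs)


class AlignmentError(Exception):
    """A pattern edge's endpoints have no connecting path in the sentence."""


def node_match(p: Token, s: Token, policy: NodeMatchPolicy) -> bool:
    """Decide whether a pattern token may map onto a sentence token."""
    if s.absorbed:
        return False
    if p.is_entity:
        if not s.is_entity:
            return False
        from .corpus_io import GENERIC_ENTITY

        return p.entity_type == s.entity_type or GENERIC_ENTITY in (
            p.entity_type,
            s.entity_type,
        )
    if s.is_entity:
        return False
    crit = policy.criteria
    if crit == "EXACT":
        return p.surface == s.surface and p.pos == s.pos
    if crit == "L":
        return p.lemma == s.lemma
    if crit == "P":
        return p.relaxed_pos == s.relaxed_pos
    if crit == "P*+L":
        return p.relaxed_pos == s.relaxed_pos and p.lemma == s.lemma
    # P*+L+DSM
    if p.relaxed_pos == s.relaxed_pos and p.lemma == s.lemma:
        return True
    if p.relaxed_pos != s.relaxed_pos:
        return False
    similars = policy.dsm_model.top_m_lemmas(p.lemma, p.pos, policy.dsm_top_m)  # type: ignore[union-attr]
    return s.lemma in similars


def edge_alignment(
    e: DependencyEdge, g: SentenceGraph, m: Mapping
) -> tuple[float, float, float]:
    """Align one pattern edge with the sentence path between its images.

    Both endpoints must be mapped.  Among all shortest undirected paths
    between the images, the one minimizing (label cost + direction cost) is
    used, ties broken by lexicographic node order; the structural cost is
    the path length minus one.  For a single-edge path the label and
    orientation are compared directly; for longer paths the pattern label
    must occur somewhere on the path (label cost) with consistent
    orientation along the traversal (direction cost).
    """
    pairs = m.as_dict
    if e.governor not in pairs or e.dependent not in pairs:
        raise AlignmentError(f"endpoint of {e} not mapped")
    u, v = pairs[e.governor], pairs[e.dependent]
    mg = g.undirected_multigraph()
    try:
        node_paths = list(nx.all_shortest_paths(mg, u, v))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        raise AlignmentError(f"images {u}, {v} disconnected")
    best: tuple | None = None
    for np in node_paths:
        hop_edges = [sorted(mg[a][b]) for a, b in zip(np, np[1:])]
        for combo in itertools.product(*hop_edges):
            if len(combo) == 1:
                se = combo[0]
                label_c = 0.0 if se.label == e.label else 1.0
                dir_c = 0.0 if (se.governor, se.dependent) == (u, v) else 1.0
            else:
                labels = [se.label for se in combo]
                label_c = 0.0 if e.label in labels else 1.0
                dir_c = 1.0
                for (a, b), se in zip(zip(np, np[1:]), combo):
                    if se.label == e.label and (se.governor, se.dependent) == (a, b):
                        dir_c = 0.0
                        break
            key = (label_c + dir_c, tuple(np), tuple(se.label for se in combo))
            cand = (key, (float(len(combo) - 1), label_c, dir_c))
            if best is None or cand[0] < best[0]:
                best = cand
    assert best is not None
    return best[1]


def subgraph_distance(
    p: EventPattern, g: SentenceGraph, m: Mapping, w: DistanceWeights
) -> Match:
    """Compute the four-component distance of a candidate mapping.

    Pattern edges with a skipped endpoint contribute nothing except through
    the skipped-node term; an unalignable edge yields an infinite total.
    """
    pairs = m.as_dict
    mapped = set(pairs)
    if set(pairs) | set(m.skipped) != set(p.nodes):
        raise ValueError("mapping does not cover the pattern node set")
    if not p.essential_nodes <= mapped:
        raise ValueError("essential pattern nodes may not be skipped")
    struct_d = label_d = dir_d = 0.0
    for e in p.edges:
        if e.governor in m.skipped or e.dependent in m.skipped:
            continue
        try:
            s, l, d = edge_alignment(e, g, m)
        except AlignmentError:
            return Match(p.pattern_id, m, INF, INF, INF, len(m.skipped) / len(p.nodes), INF)
        struct_d += s
        label_d += l
        dir_d += d
    node_d = len(m.skipped) / len(p.nodes)
    total = w.w_s * struct_d + w.w_l * label_d + w.w_d * dir_d + w.w_n * node_d
    return Match(p.pattern_id, m, struct_d, label_d, dir_d, node_d, total)


def _candidate_images(
    p: EventPattern, g: SentenceGraph, policy: NodeMatchPolicy
) -> dict[int, list[int]]:
    return {
        n: [i for i in sorted(g.tokens) if node_match(tok, g.tokens[i], policy)]
        for n, tok in p.nodes.items()
    }


def _group_minimal(matches: list[tuple[tuple, Match]]) -> list[Match]:
    best: dict[tuple, Match] = {}
    for key, m in matches:
        if key not in best or m.sort_key() < best[key].sort_key():
            best[key] = m
    return sorted(best.values(), key=lambda m: m.sort_key())


def find_matches(
    p: EventPattern,
    g: SentenceGraph,
    w: DistanceWeights,
    t: float,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool = False,
) -> list[Match]:
    """All approximate matches of the pattern with total distance <= t.

    For each distinct image of the essential nodes only the minimal-total
    match is returned (ties: fewest skipped nodes, then lexicographic
    image).  ``allow_skip=False`` forces a full injective mapping (the
    original ASM); with skipping enabled, non-essential nodes may be left
    unmapped at a penalty of ``w_n / |V_r|`` each.  The search is an
    exhaustive branch-and-bound over candidate images: partial component
    sums are non-negative and monotone, so pruning at ``> t`` is exact.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    policy = policy or NodeMatchPolicy()
    cands = _candidate_images(p, g, policy)
    essential = p.essential_nodes
    order = sorted(essential) + sorted(set(p.nodes) - essential)
    if any(not cands[n] for n in essential):
        return []
    n_nodes = len(p.nodes)
    skip_cost = w.w_n / n_nodes
    results: list[tuple[tuple, Match]] = []
    eps = 1e-9

    assigned: dict[int, int] = {}
    used: set[int] = set()
    skipped: set[int] = set()

    def incremental(n: int, s: int) -> float | None:
        """Distance added by edges between n and already-assigned nodes."""
        add = 0.0
        trial = dict(assigned)
        trial[n] = s
        mp = Mapping.of(trial)
        for e in p.edges:
            other = None
            if e.governor == n and e.dependent in assigned:
                other = e.dependent
            elif e.dependent == n and e.governor in assigned:
                other = e.governor
            if other is None:
                continue
            try:
                sc, lc, dc = edge_alignment(e, g, mp)
            except AlignmentError:
                return None
            add += w.w_s * sc + w.w_l * lc + w.w_d * dc
        return add

    def dfs(i: int, running: float) -> None:
        if i == len(order):
            m = subgraph_distance(p, g, Mapping.of(assigned, skipped), w)
            if m.total <= t + eps:
                key = tuple(sorted((n, s) for n, s in assigned.items() if n in essential))
                results.append((key, m))
            return
        n = order[i]
        for s in cands[n]:
            if s in used:
                continue
            add = incremental(n, s)
            if add is None or running + add > t + eps:
                continue
            assigned[n] = s
            used.add(s)
            dfs(i + 1, running + add)
            del assigned[n]
            used.remove(s)
        if allow_skip and n not in essential and running + skip_cost <= t + eps:
            skipped.add(n)
            dfs(i + 1, running + skip_cost)
            skipped.remove(n)

    dfs(0, 0.0)
    return _group_minimal(results)


def brute_force_matches(
    p: EventPattern,
    g: SentenceGraph,
    w: DistanceWeights,
    t: float,
    policy: NodeMatchPolicy | None = None,
    allow_skip: bool = False,
) -> list[Match]:
    """Exhaustive enumeration oracle with the same contract as
    :func:`find_matches`; guarded to patterns of at most 10 nodes."""
    if len(p.nodes) > 10:
        raise ValueError("brute-force oracle limited to patterns of <= 10 nodes")
    if t < 0:
        raise ValueError("threshold must be non-negative")
    policy = policy or NodeMatchPolicy()
    cands = _candidate_images(p, g, policy)
    essential = sorted(p.essential_nodes)
    non_essential = sorted(set(p.nodes) - p.essential_nodes)
    if any(not cands[n] for n in essential):
        return []
    skip_choices: list[tuple[int, ...]] = [()]
    if allow_skip:
        skip_choices = [
            combo
            for r in range(len(non_essential) + 1)
            for combo in itertools.combinations(non_essential, r)
        ]
    eps = 1e-9
    results: list[tuple[tuple, Match]] = []
    for skipped in skip_choices:
        mapped_nodes = [n for n in p.nodes if n not in skipped]
        for images in itertools.product(*[cands[n] for n in mapped_nodes]):
            if len(set(images)) != len(images):
                continue
            mp = Mapping.of(dict(zip(mapped_nodes, images)), set(skipped))
            m = subgraph_distance(p, g, mp, w)
            if m.total <= t + eps:
                pairs = mp.as_dict
                key = tuple(sorted((n, pairs[n]) for n in essential))
                results.append((key, m))
    return _group_minimal(results)


def match_to_json(m: Match) -> dict:
    """JSON-friendly form of a match (pattern id, image, components)."""
    return {
        "pattern_id": m.pattern_id,
        "image": {str(n): s for n, s in m.mapping.pairs},
        "skipped": sorted(m.mapping.skipped),
        "struct": m.struct_d,
        "label": m.label_d,
        "direction": m.dir_d,
        "node": m.node_d,
        "total": m.total,
    }
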