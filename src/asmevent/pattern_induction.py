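"""Induce dependency-graph event patterns from annotated sentences.

A pattern is the (undirected-)shortest dependency path, or union of such
paths, connecting an event's trigger token(s) to each of its arguments,
with lexical content retained on the nodes and role bindings recording
which nodes realize the trigger and the arguments.  An ``all_paths`` mode
additionally keeps longer acyclic paths up to a configurable slack above
the shortest length.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

import networkx as nx

from .corpus_io import DependencyEdge, Document, SentenceGraph, Token

log = logging.getLogger(__name__)

TRIGGER_ROLE = "Trigger"


@dataclass(frozen=True, order=True)
class RoleBinding:
    """Binds a pattern node to an event role.

    A non-empty ``sub_event_type`` marks the node as a sub-event trigger
    (the event filling this role is itself an event of that type); such
    nodes make the owning pattern *higher-order*.
    """

    node: int
    role: str
    sub_event_type: str = ""


@dataclass(frozen=True)
class Path:
    """An undirected traversal between two tokens, as original directed edges."""

    nodes: tuple[int, ...]
    edges: tuple[DependencyEdge, ...]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class EventPattern:
    """A pattern graph with event type, role bindings and distance threshold."""

    pattern_id: str
    event_type: str
    nodes: dict[int, Token]
    edges: tuple[DependencyEdge, ...]
    bindings: tuple[RoleBinding, ...]
    threshold: float = 0.0
    provenance: tuple = ()

    def __post_init__(self) -> None:
        for b in self.bindings:
            if b.node not in self.nodes:
                raise ValueError(f"binding {b} references unknown node")
        if len(self.nodes) > 1 and not self.is_connected():
            raise ValueError(f"pattern {self.pattern_id} is not connected")

    @property
    def essential_nodes(self) -> frozenset[int]:
        """Trigger, sub-event-trigger and argument nodes; never skippable."""
        return frozenset(b.node for b in self.bindings)

    @property
    def is_higher_order(self) -> bool:
        return any(b.sub_event_type for b in self.bindings)

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.governor, e.dependent) for e in self.edges)
        return nx.is_connected(g)

    def signature(self) -> tuple:
        """Content-based identity: type, edges, and node-indexed bindings."""
        return (
            self.event_type,
            frozenset(self.edges),
            frozenset(self.bindings),
            frozenset(
                (i, t.lemma, t.relaxed_pos, t.is_entity, t.entity_type)
                for i, t in self.nodes.items()
            ),
        )


# --------------------------------------------------------------------------
# path enumeration


def _expand_edge_paths(
    g: nx.MultiGraph, node_paths: list[list[int]]
) -> list[Path]:
    """Expand node paths into edge paths across all parallel edges per hop."""
    out: list[Path] = []
    for np in node_paths:
        hop_choices = []
        for u, v in zip(np, np[1:]):
            hop_choices.append(sorted(g[u][v]))  # keys are DependencyEdge
        for combo in itertools.product(*hop_choices):
            out.append(Path(nodes=tuple(np), edges=tuple(combo)))
    return sorted(set(out), key=lambda p: (p.nodes, p.edges))


def shortest_paths_undirected(g: SentenceGraph, a: int, b: int) -> list[Path]:
    """All minimum-length simple paths between ``a`` and ``b``, ignoring
    edge direction.  Parallel edges yield distinct paths.  Returns the empty
    list when the tokens are disconnected; a zero-length path when a == b.
    """
    if a == b:
        return [Path(nodes=(a,), edges=())]
    mg = g.undirected_multigraph()
    try:
        node_paths = list(nx.all_shortest_paths(mg, a, b))
    except nx.NetworkXNoPath:
        return []
    return _expand_edge_paths(mg, node_paths)


def all_acyclic_paths(g: SentenceGraph, a: int, b: int, max_len: int) -> list[Path]:
    """All simple (acyclic) paths of length <= ``max_len`` between the tokens."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if a == b:
        return [Path(nodes=(a,), edges=())]
    mg = g.undirected_multigraph()
    out: list[Path] = []
    for ep in nx.all_simple_edge_paths(mg, a, b, cutoff=max_len):
        nodes = [a] + [v for _, v, _ in ep]
        edges = tuple(key for _, _, key in ep)
        out.append(Path(nodes=tuple(nodes), edges=edges))
    return sorted(set(out), key=lambda p: (len(p.edges), p.nodes, p.edges))


# --------------------------------------------------------------------------
# induction


def _merge_paths(paths: list[Path]) -> tuple[set[int], set[DependencyEdge]]:
    nodes: set[int] = set()
    edges: set[DependencyEdge] = set()
    for p in paths:
        nodes.update(p.nodes)
        edges.update(p.edges)
    return nodes, edges


def _argument_endpoint(doc: Document, target: str) -> tuple[int, str]:
    """Resolve an argument target to (token index, sub-event type or '')."""
    if target.startswith("T"):
        return doc.entities[target].head_token, ""
    sub = doc.events[target]
    return min(sub.trigger_tokens), sub.type


def _paths_from_trigger(
    sent: SentenceGraph,
    trigger: frozenset[int],
    endpoint: int,
    mode: str,
    all_paths_slack: int,
) -> list[Path]:
    """Candidate paths from the (possibly multi-token) trigger to an argument.

    Shortest mode keeps all globally minimum-length paths over all trigger
    tokens; all_paths mode keeps every acyclic path up to that length plus
    the slack.
    """
    best: list[Path] = []
    best_len: int | None = None
    for t in sorted(trigger):
        for p in shortest_paths_undirected(sent, t, endpoint):
            if best_len is None or len(p) < best_len:
                best, best_len = [p], len(p)
            elif len(p) == best_len:
                best.append(p)
    if best_len is None:
        return []
    if mode == "shortest":
        return sorted(set(best), key=lambda p: (p.nodes, p.edges))
    if mode != "all_paths":
        raise ValueError(f"unknown induction mode {mode!r}")
    cutoff = max(best_len + all_paths_slack, 1)
    out: list[Path] = []
    for t in sorted(trigger):
        out.extend(all_acyclic_paths(sent, t, endpoint, cutoff))
    return sorted(set(out), key=lambda p: (len(p.edges), p.nodes, p.edges))


def induce_patterns(
    doc: Document,
    mode: str = "shortest",
    max_unions_per_event: int = 8,
    all_paths_slack: int = 2,
) -> list[EventPattern]:
    """Derive event patterns from every annotated event of the document.

    For each event: one *individual* pattern per (argument, path choice),
    plus, when the event has two or more arguments (which share the event
    trigger), *union* patterns over the cross-product of per-argument path
    choices (capped at ``max_unions_per_event``).  Multi-token triggers
    contribute the union of their pairwise shortest paths to every pattern.
    Sub-event arguments connect to the sub-event's trigger token.

    The document must already be entity-anonymized.
    """
    patterns: list[EventPattern] = []
    for eid in sorted(doc.events, key=lambda e: int(e[1:])):
        ev = doc.events[eid]
        sent = doc.sentences[ev.sentence_index]
        trigger = ev.trigger_tokens

        skeleton_nodes: set[int] = set(trigger)
        skeleton_edges: set[DependencyEdge] = set()
        if len(trigger) > 1:
            connected = True
            for t1, t2 in itertools.combinations(sorted(trigger), 2):
                pp = shortest_paths_undirected(sent, t1, t2)
                if not pp:
                    connected = False
                    break
                n, e = _merge_paths(pp)
                skeleton_nodes |= n
                skeleton_edges |= e
            if not connected:
                log.warning("%s: multi-token trigger disconnected, skipped", eid)
                continue

        arg_specs: list[tuple[str, int, str, list[Path]]] = []
        feasible = True
        for role, target in ev.args:
            endpoint, sub_type = _argument_endpoint(doc, target)
            paths = _paths_from_trigger(sent, trigger, endpoint, mode, all_paths_slack)
            if not paths:
                log.warning("%s: trigger and %s argument disconnected, skipped", eid, role)
                feasible = False
                break
            arg_specs.append((role, endpoint, sub_type, paths))
        if not feasible or not arg_specs:
            continue

        trig_bindings = tuple(
            RoleBinding(node=t, role=TRIGGER_ROLE) for t in sorted(trigger)
        )
        counter = itertools.count()

        def build(sel: list[tuple[str, int, str, Path]], kind: str) -> None:
            nodes = set(skeleton_nodes)
            edges = set(skeleton_edges)
            bindings = list(trig_bindings)
            for role, endpoint, sub_type, path in sel:
                nodes.update(path.nodes)
                edges.update(path.edges)
                bindings.append(
                    RoleBinding(node=endpoint, role=role, sub_event_type=sub_type)
                )
            patterns.append(
                EventPattern(
                    pattern_id=f"{doc.doc_id}.{eid}.{kind}{next(counter)}",
                    event_type=ev.type,
                    nodes={i: sent.tokens[i] for i in sorted(nodes)},
                    edges=tuple(sorted(edges)),
                    bindings=tuple(sorted(set(bindings))),
                    provenance=(doc.doc_id, sent.sentence_id, eid, mode),
                )
            )

        if len(arg_specs) >= 2:
            combos = itertools.product(
                *[[(r, ep, st, p) for p in paths] for r, ep, st, paths in arg_specs]
            )
            for sel in itertools.islice(combos, max_unions_per_event):
                build(list(sel), "u")
        for role, endpoint, sub_type, paths in arg_specs:
            for p in paths:
                build([(role, endpoint, sub_type, p)], "i")
    return patterns


# --------------------------------------------------------------------------
# deduplication


def _pattern_multigraph(p: EventPattern) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    roles: dict[int, set[tuple[str, str]]] = {}
    for b in p.bindings:
        roles.setdefault(b.node, set()).add((b.role, b.sub_event_type))
    for i, tok in p.nodes.items():
        g.add_node(
            i,
            content=(
                tok.lemma,
                tok.relaxed_pos,
                tok.is_entity,
                tok.entity_type,
                frozenset(roles.get(i, ())),
            ),
        )
    for e in p.edges:
        g.add_edge(e.governor, e.dependent, label=e.label)
    return g


def _iso_bucket(p: EventPattern) -> tuple:
    g = _pattern_multigraph(p)
    return (
        p.event_type,
        tuple(sorted(d["content"] for _, d in g.nodes(data=True))),
        tuple(sorted(d["label"] for _, _, d in g.edges(data=True))),
    )


def patterns_isomorphic(a: EventPattern, b: EventPattern) -> bool:
    """Exact isomorphism preserving lexical content (lemma + relaxed POS),
    entity typing, role bindings, and labeled edge directions."""
    if a.event_type != b.event_type:
        return False
    ga, gb = _pattern_multigraph(a), _pattern_multigraph(b)
    nm = nx.algorithms.isomorphism.categorical_node_match("content", None)
    em = nx.algorithms.isomorphism.categorical_multiedge_match("label", None)
    return nx.is_isomorphic(ga, gb, node_match=nm, edge_match=em)


def dedup_patterns(patterns: list[EventPattern]) -> list[EventPattern]:
    """Drop patterns exactly isomorphic to an earlier one of the same type.

    Input order is preserved; the earliest occurrence (provenance) of each
    isomorphism class is retained.
    """
    buckets: dict[tuple, list[EventPattern]] = {}
    kept: list[EventPattern] = []
    for p in patterns:
        key = _iso_bucket(p)
        dup = any(patterns_isomorphic(p, q) for q in buckets.get(key, ()))
        if not dup:
            buckets.setdefault(key, []).append(p)
            kept.append(p)
    return kept


# --------------------------------------------------------------------------
# pattern store serialization


def dump_patterns(patterns: list[EventPattern]) -> str:
    """Line-oriented pattern store; lossless for matchable content."""
    blocks: list[str] = []
    for p in patterns:
        lines = [f"pattern\t{p.pattern_id}\t{p.event_type}\t{p.threshold!r}"]
        if p.provenance:
            lines.append("provenance\t" + "\t".join(str(x) for x in p.provenance))
        for i in sorted(p.nodes):
            t = p.nodes[i]
            ent = t.entity_type if t.is_entity else "_"
            lines.append(f"node\t{i}\t{t.surface}\t{t.lemma}\t{t.pos}\t{ent}")
        for e in p.edges:
            gp = p.nodes[e.governor].pos
            dp = p.nodes[e.dependent].pos
            lines.append(
                f"edge\t{e.label}({p.nodes[e.governor].surface}-{e.governor}/{gp}, "
                f"{p.nodes[e.dependent].surface}-{e.dependent}/{dp})"
            )
        for b in p.bindings:
            lines.append(f"bind\t{b.node}\t{b.role}\t{b.sub_event_type or '_'}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def load_patterns(stream: str) -> list[EventPattern]:
    from .corpus_io import Token as Tok

    out: list[EventPattern] = []
    for block in stream.split("\n\n"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        header = lines[0].split("\t")
        if header[0] != "pattern":
            raise ValueError(f"malformed pattern block header: {lines[0]!r}")
        _, pid, etype, thr = header
        nodes: dict[int, Token] = {}
        edges: list[DependencyEdge] = []
        bindings: list[RoleBinding] = []
        provenance: tuple = ()
        for ln in lines[1:]:
            cols = ln.split("\t")
            if cols[0] == "node":
                _, i, surface, lemma, pos, ent = cols
                nodes[int(i)] = Tok(
                    index=int(i),
                    surface=surface,
                    lemma=lemma,
                    pos=pos,
                    is_entity=ent != "_",
                    entity_type="" if ent == "_" else ent,
                )
            elif cols[0] == "edge":
                m = re.match(r"^([\w:$|'<>.-]+)\((.*)-(\d+)/[^,]*,\s*(.*)-(\d+)/[^)]*\)$", cols[1])
                if not m:
                    raise ValueError(f"malformed edge line: {ln!r}")
                label, _gs, gov, _ds, dep = m.groups()
                edges.append(DependencyEdge(int(gov), int(dep), label))
            elif cols[0] == "bind":
                _, node, role, sub = cols
                bindings.append(
                    RoleBinding(int(node), role, "" if sub == "_" else sub)
                )
            elif cols[0] == "provenance":
                provenance = tuple(cols[1:])
            else:
                raise ValueError(f"malformed pattern line: {ln!r}")
        out.append(
            EventPattern(
                pattern_id=pid,
                event_type=etype,
                nodes=nodes,
                edges=tuple(edges),
                bindings=tuple(bindings),
                threshold=float(thr),
                provenance=provenance,
            )
        )
    return out
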