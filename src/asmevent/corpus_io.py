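"""Standoff-annotated documents and dependency graphs.

Reads the BioNLP shared-task standoff layout (``.txt`` raw text, ``.a1``
entity annotations, ``.a2`` trigger/event annotations) together with
pre-computed per-sentence dependency parses, and normalizes tokens for
pattern generalization (relaxed POS tags, entity anonymization).

Character offsets are 0-based half-open (standoff convention); token
indices are 1-based (CoNLL convention).
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx

log = logging.getLogger(__name__)

#: Generic entity string used when all entity types are collapsed.
GENERIC_ENTITY = "BIO_Entity"


def relaxed_pos(pos: str) -> str:
    """Collapse a Penn-Treebank tag to its relaxed base class.

    All noun tags (``NN``, ``NNS``, ``NNP``, ``NNPS``) map to ``NN`` and all
    verb tags (``VB``, ``VBD``, ``VBG``, ``VBN``, ``VBP``, ``VBZ``) map to
    ``VB``, so a plural noun can match a singular and conjugated verb forms
    can match each other.  Every other tag maps to itself.
    """
    if not pos:
        raise ValueError("empty POS tag")
    if pos.startswith("NN"):
        return "NN"
    if pos.startswith("VB"):
        return "VB"
    return pos


@dataclass
class Token:
    """A sentence token. ``index`` is the 1-based position in the sentence."""

    index: int
    surface: str
    lemma: str
    pos: str
    is_entity: bool = False
    entity_type: str = ""
    #: non-head token inside a multi-token entity span; excluded from path endpoints
    absorbed: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")

    @property
    def relaxed_pos(self) -> str:
        return relaxed_pos(self.pos)


@dataclass(frozen=True, order=True)
class DependencyEdge:
    """A labeled directed dependency, governor -> dependent (token indices)."""

    governor: int
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if self.governor == self.dependent:
            raise ValueError("self-loop dependency edge")


class SentenceGraph:
    """Tokens plus labeled directed dependency edges; may be disconnected."""

    def __init__(
        self,
        tokens: Iterable[Token],
        edges: Iterable[DependencyEdge] = (),
        sentence_id: str = "",
    ) -> None:
        self.sentence_id = sentence_id
        self.tokens: dict[int, Token] = {}
        for tok in tokens:
            if tok.index in self.tokens:
                raise ValueError(f"duplicate token index {tok.index}")
            self.tokens[tok.index] = tok
        self.edges: list[DependencyEdge] = []
        seen: set[DependencyEdge] = set()
        for e in edges:
            if e.governor not in self.tokens or e.dependent not in self.tokens:
                raise ValueError(f"edge {e} references unknown token")
            if e in seen:
                raise ValueError(f"duplicate dependency edge {e}")
            seen.add(e)
            self.edges.append(e)
        #: absolute character span of each token in the document text
        self.token_spans: dict[int, tuple[int, int]] = {}

    def __len__(self) -> int:
        return len(self.tokens)

    def undirected_multigraph(self) -> nx.MultiGraph:
        """Undirected multigraph view; parallel edges kept as distinct keys.

        Cached; callers must not mutate the edge list after first use.
        """
        cached = getattr(self, "_mg_cache", None)
        if cached is not None and len(cached.edges) == len(self.edges):
            return cached
        g = nx.MultiGraph()
        g.add_nodes_from(self.tokens)
        for e in self.edges:
            g.add_edge(e.governor, e.dependent, key=e)
        self._mg_cache = g
        return g

    def span(self) -> tuple[int, int]:
        if not self.token_spans:
            raise ValueError("token spans not aligned to text")
        starts = [s for s, _ in self.token_spans.values()]
        ends = [e for _, e in self.token_spans.values()]
        return min(starts), max(ends)


@dataclass
class EntityMention:
    """An ``.a1`` entity (T-number) with character offsets and head token."""

    id: str
    type: str
    char_start: int
    char_end: int
    sentence_index: int = -1
    head_token: int = -1
    tokens: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(f"{self.id}: empty or inverted character span")


@dataclass
class EventMention:
    """An ``.a2`` event (E-number): type, trigger tokens, role-labeled args.

    ``args`` targets are standoff ids: T-numbers (entities) or E-numbers
    (sub-events).
    """

    id: str
    type: str
    trigger_tokens: frozenset[int]
    args: tuple[tuple[str, str], ...]
    sentence_index: int = -1
    trigger_id: str = ""

    def __post_init__(self) -> None:
        if not self.trigger_tokens:
            raise ValueError(f"{self.id}: empty trigger token set")


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[SentenceGraph] = field(default_factory=list)
    entities: dict[str, EntityMention] = field(default_factory=dict)
    events: dict[str, EventMention] = field(default_factory=dict)
    #: trigger annotations from .a2: id -> (type, char_start, char_end)
    triggers: dict[str, tuple[str, int, int]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# dependency graph parsing

_EDGE_RE = re.compile(
    r"^\s*([\w:$|'<>.-]+)\(\s*(.*?)-(\d+)/([^\s,]+)\s*,\s*(.*?)-(\d+)/([^\s)]+)\s*\)\s*$"
)


def read_dependency_graph(rows: Iterable[str] | str, sentence_id: str = "") -> SentenceGraph:
    """Parse one sentence block into a :class:`SentenceGraph`.

    Two row dialects are accepted and may be mixed within a block:

    * tabular rows ``index  surface  lemma  pos  [governor  label]`` where a
      governor of ``0`` or ``_`` declares no incoming edge, and
    * textual edge rows ``label(gov-i/POS, dep-j/POS)`` referencing tokens
      declared by tabular rows.

    Both dialects produce identical graphs for the same edge set.
    """
    if isinstance(rows, str):
        rows = rows.splitlines()
    tokens: dict[int, Token] = {}
    pending_edges: list[tuple[DependencyEdge, str]] = []
    for raw in rows:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _EDGE_RE.match(line)
        if m:
            label, _gov_surf, gov, gov_pos, _dep_surf, dep, dep_pos = m.groups()
            edge = DependencyEdge(int(gov), int(dep), label)
            pending_edges.append((edge, f"{gov_pos}/{dep_pos}"))
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) not in (4, 6):
            raise ValueError(f"malformed dependency row: {raw!r}")
        idx = int(cols[0])
        tokens[idx] = Token(index=idx, surface=cols[1], lemma=cols[2], pos=cols[3])
        if len(cols) == 6 and cols[4] not in ("0", "_", ""):
            gov = int(cols[4])
            pending_edges.append((DependencyEdge(gov, idx, cols[5]), ""))
    edges = []
    for edge, _ in pending_edges:
        for end in (edge.governor, edge.dependent):
            if end not in tokens:
                raise ValueError(f"edge {edge} references undeclared token {end}")
        edges.append(edge)
    return SentenceGraph(tokens.values(), edges, sentence_id=sentence_id)


def _split_blocks(stream: Iterable[str] | str) -> list[list[str]]:
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    blocks: list[list[str]] = []
    cur: list[str] = []
    for ln in lines:
        if ln.strip():
            cur.append(ln)
        elif cur:
            blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)
    return blocks


def _align_tokens(doc_text: str, sentences: Sequence[SentenceGraph]) -> None:
    """Assign absolute character spans by locating surfaces left to right."""
    cursor = 0
    for sent in sentences:
        for idx in sorted(sent.tokens):
            surface = sent.tokens[idx].surface
            pos = doc_text.find(surface, cursor)
            if pos < 0:
                raise ValueError(
                    f"token {surface!r} (sentence {sent.sentence_id}) not found in text"
                )
            sent.token_spans[idx] = (pos, pos + len(surface))
            cursor = pos + len(surface)


# --------------------------------------------------------------------------
# standoff parsing


def _read_lines(stream: IO[str] | str | None) -> list[str]:
    if stream is None:
        return []
    text = stream if isinstance(stream, str) else stream.read()
    return [ln for ln in text.splitlines() if ln.strip()]


def _sentence_of_span(doc: Document, start: int, end: int) -> int:
    for i, sent in enumerate(doc.sentences):
        s0, s1 = sent.span()
        if start >= s0 and end <= s1:
            return i
    return -1


def _tokens_in_span(sent: SentenceGraph, start: int, end: int) -> tuple[int, ...]:
    out = [
        idx
        for idx, (t0, t1) in sent.token_spans.items()
        if t0 < end and t1 > start
    ]
    return tuple(sorted(out))


def _entity_head(sent: SentenceGraph, span_tokens: Sequence[int]) -> int:
    """Head = token whose governor lies outside the span; ties -> rightmost."""
    inside = set(span_tokens)
    governed_by = {e.dependent: e.governor for e in sent.edges}
    heads = [
        idx
        for idx in span_tokens
        if idx not in governed_by or governed_by[idx] not in inside
    ]
    if not heads:
        heads = list(span_tokens)
    return max(heads)


def read_standoff_document(
    txt: IO[str] | str,
    a1: IO[str] | str,
    a2: IO[str] | str | None,
    parses: IO[str] | str,
    doc_id: str = "doc",
) -> Document:
    """Assemble a :class:`Document` from standoff streams plus parses.

    Passing ``a2=None`` (test mode) yields a document with no events.
    Events whose trigger and arguments do not all lie in one sentence are
    dropped with a warning, matching the single-sentence scope of the
    extraction method.
    """
    text = txt if isinstance(txt, str) else txt.read()
    sentences = [
        read_dependency_graph(block, sentence_id=f"{doc_id}.s{i}")
        for i, block in enumerate(_split_blocks(parses))
    ]
    _align_tokens(text, sentences)
    doc = Document(doc_id=doc_id, text=text, sentences=sentences)

    for line in _read_lines(a1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed a1 line: {line!r}")
        tid = fields[0]
        etype, start, end = fields[1].split()
        start, end = int(start), int(end)
        if end > len(text):
            raise ValueError(f"{tid}: offset {end} beyond text length {len(text)}")
        ent = EntityMention(id=tid, type=etype, char_start=start, char_end=end)
        ent.sentence_index = _sentence_of_span(doc, start, end)
        if ent.sentence_index < 0:
            raise ValueError(f"{tid}: span outside all sentences")
        sent = doc.sentences[ent.sentence_index]
        ent.tokens = _tokens_in_span(sent, start, end)
        if not ent.tokens:
            raise ValueError(f"{tid}: no tokens overlap span {start}:{end}")
        ent.head_token = _entity_head(sent, ent.tokens)
        doc.entities[tid] = ent

    raw_events: dict[str, tuple[str, str, list[tuple[str, str]]]] = {}
    for line in _read_lines(a2):
        fields = line.split("\t")
        marker = fields[0]
        if marker.startswith("T"):
            etype, start, end = fields[1].split()
            start, end = int(start), int(end)
            if end > len(text):
                raise ValueError(f"{marker}: trigger offset beyond text")
            doc.triggers[marker] = (etype, start, end)
        elif marker.startswith("E"):
            spec = fields[1].split()
            etype, trig_id = spec[0].split(":")
            args = [tuple(a.split(":", 1)) for a in spec[1:]]
            raw_events[marker] = (etype, trig_id, args)  # type: ignore[arg-type]
        # M/A modification lines are out of scope and ignored

    _check_acyclic(raw_events)
    for eid in _topological_event_order(raw_events):
        etype, trig_id, args = raw_events[eid]
        if trig_id not in doc.triggers:
            raise ValueError(f"{eid}: unknown trigger {trig_id}")
        _, t0, t1 = doc.triggers[trig_id]
        sent_i = _sentence_of_span(doc, t0, t1)
        if sent_i < 0:
            raise ValueError(f"{eid}: trigger outside all sentences")
        trig_tokens = _tokens_in_span(doc.sentences[sent_i], t0, t1)
        ok = True
        for role, target in args:
            if target.startswith("T"):
                if target not in doc.entities:
                    raise ValueError(f"{eid}: dangling argument {target}")
                if doc.entities[target].sentence_index != sent_i:
                    ok = False
            elif target.startswith("E"):
                if target not in raw_events:
                    raise ValueError(f"{eid}: dangling argument {target}")
                if target in doc.events and doc.events[target].sentence_index != sent_i:
                    ok = False
                if target not in doc.events:
                    ok = False  # sub-event itself was dropped
            else:
                raise ValueError(f"{eid}: malformed argument target {target}")
        if not ok:
            log.warning("%s: dropping cross-sentence event %s", doc_id, eid)
            continue
        doc.events[eid] = EventMention(
            id=eid,
            type=etype,
            trigger_tokens=frozenset(trig_tokens),
            args=tuple(args),
            sentence_index=sent_i,
            trigger_id=trig_id,
        )
    return doc


def _check_acyclic(raw_events: dict[str, tuple[str, str, list[tuple[str, str]]]]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(raw_events)
    for eid, (_, _, args) in raw_events.items():
        for _, target in args:
            if target.startswith("E"):
                g.add_edge(eid, target)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cyclic event argument references")


def _topological_event_order(
    raw_events: dict[str, tuple[str, str, list[tuple[str, str]]]]
) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(raw_events)
    for eid, (_, _, args) in raw_events.items():
        for _, target in args:
            if target.startswith("E") and target in raw_events:
                g.add_edge(target, eid)  # sub-event first
    return list(nx.topological_sort(g))


def write_a2(doc: Document) -> str:
    """Serialize the document's events (triggers + E lines) as an .a2 stream.

    Round-trip contract: re-reading the output together with the original
    text/a1/parses reproduces the same events.
    """
    lines: list[str] = []
    used_triggers: set[str] = set()
    for ev in doc.events.values():
        if ev.trigger_id and ev.trigger_id in doc.triggers:
            used_triggers.add(ev.trigger_id)
        else:
            raise ValueError(f"{ev.id}: event has no trigger annotation")
        for _, target in ev.args:
            if target.startswith("T") and target not in doc.entities:
                raise ValueError(f"{ev.id}: unknown entity mention {target}")
            if target.startswith("E") and target not in doc.events:
                raise ValueError(f"{ev.id}: unknown event mention {target}")
    for tid in sorted(used_triggers, key=lambda t: int(t[1:])):
        etype, start, end = doc.triggers[tid]
        lines.append(f"{tid}\t{etype} {start} {end}\t{doc.text[start:end]}")
    order = _topological_event_order(
        {eid: (ev.type, ev.trigger_id, list(ev.args)) for eid, ev in doc.events.items()}
    )
    for eid in order:
        ev = doc.events[eid]
        args = " ".join(f"{role}:{target}" for role, target in ev.args)
        spec = f"{ev.type}:{ev.trigger_id}"
        lines.append(f"{eid}\t{spec} {args}".rstrip())
    return "\n".join(lines) + ("\n" if lines else "")


# --------------------------------------------------------------------------
# entity anonymization


def anonymize_entities(doc: Document, collapse_types: bool = False) -> Document:
    """Replace each entity's head token content with its generic type string.

    The head token's surface and lemma become the entity type (or
    ``BIO_Entity`` when ``collapse_types`` is set) and it is flagged as an
    entity; other tokens inside the span are flagged absorbed so they never
    serve as path endpoints.  Token counts and edge sets are unchanged.
    """
    out = copy.deepcopy(doc)
    heads_seen: dict[tuple[int, int], str] = {}
    for ent in out.entities.values():
        key = (ent.sentence_index, ent.head_token)
        if key in heads_seen:
            raise ValueError(
                f"entities {heads_seen[key]} and {ent.id} share head token {ent.head_token}"
            )
        heads_seen[key] = ent.id
        sent = out.sentences[ent.sentence_index]
        generic = GENERIC_ENTITY if collapse_types else ent.type
        head = sent.tokens[ent.head_token]
        head.surface = generic
        head.lemma = generic
        head.is_entity = True
        head.entity_type = generic
        for idx in ent.tokens:
            if idx != ent.head_token:
                sent.tokens[idx].absorbed = True
    return out
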