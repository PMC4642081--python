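"""Synthetic test inputs: a fully worked pattern-induction example and
randomized event corpora with planted events and controlled perturbations.

The worked example is a single annotated sentence whose dependency core
consists of three tokens — ``ligation-6/NN``, ``lead-20/VBP`` and
``phosphorylation-23/NN`` — connected by ``nsubj(lead-20, ligation-6)``,
``rcmod(ligation-6, lead-20)`` and ``prep_to(lead-20,
phosphorylation-23)``, carrying a Positive_regulation event whose Theme
and Cause are a Phosphorylation and a Binding sub-event.  Exactly five
distinct patterns are inducible from it: two path unions and three
individual paths.  Filler tokens hang off the core as leaves so they never
lie on any induced path.

The randomized corpora plant events in random dependency trees and emit
paired train/test documents.  Each test copy is perturbed through at most
one channel whose exact matching cost is known by construction:

========================  =======================================
channel                   minimal matching distance of the event
========================  =======================================
``none``                  0
``label_swap``            w_l  (one path edge label replaced)
``dir_flip``              w_d  (one path edge reversed)
``node_insert``           w_s  (one node splitting a path edge)
``modifier_insert``       w_n / |V_r| with node skipping enabled
                          (a train-only modifier sits on the
                          induced path); unmatchable without
========================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    Document,
    SentenceGraph,
    Token,
    anonymize_entities,
    read_standoff_document,
)
from .pattern_induction import DependencyEdge, EventPattern, RoleBinding

EVENT_TYPES = ("Gene_expression", "Binding", "Phosphorylation", "Localization", "Transcription")
REG_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")
EDGE_LABELS = ("dobj", "nsubj", "prep_of", "prep_in")
CHANNELS = ("none", "label_swap", "dir_flip", "node_insert", "modifier_insert")


def render_parse(tokens: list[Token], edges: list[DependencyEdge]) -> str:
    """One dependency block: 4-column token rows plus textual edge lines."""
    lines = [f"{t.index}\t{t.surface}\t{t.lemma}\t{t.pos}" for t in tokens]
    by_index = {t.index: t for t in tokens}
    for e in edges:
        g, d = by_index[e.governor], by_index[e.dependent]
        lines.append(f"{e.label}({g.surface}-{g.index}/{g.pos}, {d.surface}-{d.index}/{d.pos})")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# worked example


def _tok(i: int, surface: str, pos: str, lemma: str | None = None) -> Token:
    return Token(index=i, surface=surface, lemma=lemma or surface.lower(), pos=pos)


def worked_example_files() -> dict[str, str]:
    """Raw standoff streams (txt/a1/a2/parse) of the worked example."""
    rows = [
        (1, "The", "DT"), (2, "rapid", "JJ"), (3, "and", "CC"), (4, "efficient", "JJ"),
        (5, "CD40", "NN"), (6, "ligation", "NN"), (7, "observed", "VBN"), (8, "in", "IN"),
        (9, "these", "DT"), (10, "cells", "NNS"), (11, "would", "MD"), (12, "therefore", "RB"),
        (13, "be", "VB"), (14, "expected", "VBN"), (15, "to", "TO"), (16, "rapidly", "RB"),
        (17, "and", "CC"), (18, "efficiently", "RB"), (19, "also", "RB"), (20, "lead", "VBP"),
        (21, "directly", "RB"), (22, "to", "TO"), (23, "phosphorylation", "NN"),
        (24, "TRAF2", "NN"),
    ]
    lemmas = {10: "cell", 7: "observe", 14: "expect"}
    tokens = [_tok(i, s, p, lemmas.get(i)) for i, s, p in rows]
    edges = [
        DependencyEdge(20, 6, "nsubj"),
        DependencyEdge(6, 20, "rcmod"),
        DependencyEdge(20, 23, "prep_to"),
        DependencyEdge(6, 5, "nn"),
        DependencyEdge(23, 24, "prep_of"),
        DependencyEdge(6, 1, "det"),
        DependencyEdge(6, 2, "amod"),
        DependencyEdge(2, 3, "cc"),
        DependencyEdge(2, 4, "conj"),
        DependencyEdge(6, 7, "partmod"),
        DependencyEdge(7, 10, "prep_in"),
        DependencyEdge(10, 9, "det"),
        DependencyEdge(20, 11, "aux"),
        DependencyEdge(20, 12, "advmod"),
        DependencyEdge(20, 13, "aux"),
        DependencyEdge(20, 14, "advcl"),
        DependencyEdge(20, 16, "advmod"),
        DependencyEdge(16, 17, "cc"),
        DependencyEdge(16, 18, "conj"),
        DependencyEdge(20, 19, "advmod"),
        DependencyEdge(20, 21, "advmod"),
    ]
    text = " ".join(t.surface for t in tokens) + " ."

    def span(surface: str) -> tuple[int, int]:
        start = text.index(" " + surface + " ") + 1 if not text.startswith(surface) else 0
        return start, start + len(surface)

    spans = {t.index: span(t.surface) for t in tokens if t.index in (5, 6, 20, 23, 24)}
    a1 = "\n".join(
        [
            f"T1\tProtein {spans[5][0]} {spans[5][1]}\tCD40",
            f"T2\tProtein {spans[24][0]} {spans[24][1]}\tTRAF2",
        ]
    ) + "\n"
    a2 = "\n".join(
        [
            f"T3\tBinding {spans[6][0]} {spans[6][1]}\tligation",
            f"T4\tPhosphorylation {spans[23][0]} {spans[23][1]}\tphosphorylation",
            f"T5\tPositive_regulation {spans[20][0]} {spans[20][1]}\tlead",
            "E1\tBinding:T3 Theme:T1",
            "E2\tPhosphorylation:T4 Theme:T2",
            "E3\tPositive_regulation:T5 Theme:E2 Cause:E1",
        ]
    ) + "\n"
    return {
        "txt": text,
        "a1": a1,
        "a2": a2,
        "parse": render_parse(tokens, edges),
    }


def worked_example() -> tuple[Document, list[EventPattern]]:
    """The worked example document plus its five expected regulation
    patterns (two path unions and three individual paths)."""
    files = worked_example_files()
    doc = read_standoff_document(
        files["txt"], files["a1"], files["a2"], files["parse"], doc_id="worked"
    )
    core = {
        6: _tok(6, "ligation", "NN"),
        20: _tok(20, "lead", "VBP"),
        23: _tok(23, "phosphorylation", "NN"),
    }
    nsubj = DependencyEdge(20, 6, "nsubj")
    rcmod = DependencyEdge(6, 20, "rcmod")
    prep_to = DependencyEdge(20, 23, "prep_to")
    trig = RoleBinding(20, "Trigger")
    theme = RoleBinding(23, "Theme", "Phosphorylation")
    cause = RoleBinding(6, "Cause", "Binding")

    def pat(pid: str, edges: tuple, bindings: tuple) -> EventPattern:
        nodes = {i: core[i] for b in bindings for i in (b.node,)}
        for e in edges:
            nodes.setdefault(e.governor, core[e.governor])
            nodes.setdefault(e.dependent, core[e.dependent])
        return EventPattern(
            pattern_id=pid,
            event_type="Positive_regulation",
            nodes=nodes,
            edges=edges,
            bindings=tuple(sorted(bindings)),
        )

    expected = [
        pat("E1a", (nsubj, prep_to), (trig, theme, cause)),
        pat("E1b", (rcmod, prep_to), (trig, theme, cause)),
        pat("E1c", (prep_to,), (trig, theme)),
        pat("E1d", (nsubj,), (trig, cause)),
        pat("E1e", (rcmod,), (trig, cause)),
    ]
    return doc, expected


# --------------------------------------------------------------------------
# randomized event corpora


@dataclass
class CorpusSpec:
    """Study conditions of a synthetic event corpus.

    ``perturbation_rates`` maps channel name to probability; the remaining
    mass is unperturbed.  Channels are mutually exclusive per event so the
    recorded matching cost of each planted event is exact.
    """

    seed: int
    n_events: int = 12
    filler_range: tuple[int, int] = (2, 5)
    two_arg_rate: float = 0.25
    nesting_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)  # depth 1/2/3
    perturbation_rates: dict[str, float] = field(default_factory=dict)
    n_junk_patterns: int = 0

    def __post_init__(self) -> None:
        if not 0 <= sum(self.perturbation_rates.values()) <= 1:
            raise ValueError("perturbation rates must sum to at most 1")
        for ch in self.perturbation_rates:
            if ch not in CHANNELS or ch == "none":
                raise ValueError(f"unknown perturbation channel {ch!r}")
        if abs(sum(self.nesting_probs) - 1) > 1e-9:
            raise ValueError("nesting probabilities must sum to 1")


@dataclass
class PlantedEvent:
    """Bookkeeping for one planted top-level event in a test document."""

    scenario: int
    test_doc_id: str
    event_id: str
    channel: str
    pattern_nodes: int  # |V_r| of the induced pattern the cost refers to

    def cost(self, w, allow_skip: bool = True) -> float:
        """Minimal matching distance of the planted event by construction."""
        if self.channel == "none":
            return 0.0
        if self.channel == "label_swap":
            return w.w_l
        if self.channel == "dir_flip":
            return w.w_d
        if self.channel == "node_insert":
            return w.w_s
        if self.channel == "modifier_insert":
            return w.w_n / self.pattern_nodes if allow_skip else float("inf")
        raise ValueError(self.channel)


@dataclass
class CorpusBundle:
    train_docs: list[Document]
    test_docs: list[Document]
    planted: list[PlantedEvent]
    #: doc_id -> {"txt": ..., "a1": ..., "a2": ..., "parse": ...}
    files: dict[str, dict[str, str]]

    def anonymized(self) -> tuple[list[Document], list[Document]]:
        return (
            [anonymize_entities(d) for d in self.train_docs],
            [anonymize_entities(d) for d in self.test_docs],
        )


class _SentenceBuilder:
    def __init__(self) -> None:
        self.tokens: list[Token] = []
        self.edges: list[DependencyEdge] = []
        self.entities: list[tuple[str, int]] = []  # (type, token index)
        #: (type, trigger token, [(role, target)]) where target is an entity
        #: token index (int) or ("E", event ordinal) for a sub-event
        self.events: list[tuple[str, int, list[tuple[str, object]]]] = []

    def add(self, surface: str, pos: str, lemma: str | None = None) -> int:
        idx = len(self.tokens) + 1
        self.tokens.append(Token(index=idx, surface=surface, lemma=lemma or surface, pos=pos))
        return idx

    def link(self, gov: int, dep: int, label: str) -> None:
        self.edges.append(DependencyEdge(gov, dep, label))

    def render(self, doc_id: str, with_events: bool = True) -> dict[str, str]:
        text = " ".join(t.surface for t in self.tokens) + " ."
        spans: dict[int, tuple[int, int]] = {}
        cursor = 0
        for t in self.tokens:
            start = text.index(t.surface, cursor)
            spans[t.index] = (start, start + len(t.surface))
            cursor = start + len(t.surface)
        a1_lines = []
        ent_ids: dict[int, str] = {}
        for k, (etype, tok) in enumerate(self.entities, start=1):
            tid = f"T{k}"
            ent_ids[tok] = tid
            s, e = spans[tok]
            a1_lines.append(f"{tid}\t{etype} {s} {e}\t{text[s:e]}")
        a2_lines = []
        if with_events:
            t_next = len(self.entities) + 1
            ev_ids: dict[int, str] = {}
            for k, (etype, trig, _args) in enumerate(self.events, start=1):
                ev_ids[k - 1] = f"E{k}"
            for k, (etype, trig, args) in enumerate(self.events, start=1):
                tid = f"T{t_next}"
                t_next += 1
                s, e = spans[trig]
                a2_lines.append(f"{tid}\t{etype} {s} {e}\t{text[s:e]}")
                rendered = []
                for role, target in args:
                    if isinstance(target, int):  # entity token index
                        rendered.append(f"{role}:{ent_ids[target]}")
                    else:  # ("E", event ordinal)
                        rendered.append(f"{role}:{ev_ids[target[1]]}")
                a2_lines.append(f"E{k}\t{etype}:{tid} " + " ".join(rendered))
        return {
            "txt": text,
            "a1": "\n".join(a1_lines) + ("\n" if a1_lines else ""),
            "a2": "\n".join(a2_lines) + ("\n" if a2_lines else ""),
            "parse": render_parse(self.tokens, self.edges),
        }


def _build_doc(files: dict[str, str], doc_id: str) -> Document:
    return read_standoff_document(
        files["txt"], files["a1"], files["a2"], files["parse"], doc_id=doc_id
    )


def _add_fillers(sb: _SentenceBuilder, attach_to: int, n: int, tag: str) -> None:
    for j in range(n):
        f = sb.add(f"{tag}f{j}", "RB")
        sb.link(attach_to, f, "advmod")


def generate_event_corpus(spec: CorpusSpec) -> CorpusBundle:
    """Paired train/test documents with planted events of known cost.

    Every scenario contributes one training document (patterns are induced
    from it) and one test document carrying the same planted event,
    perturbed through at most one channel.  Nested scenarios plant a chain
    of events (innermost takes an entity Theme; each outer event takes the
    next inner event as Theme).  Junk scenarios plant a training-only event
    whose construction recurs unannotated in extra test documents, so its
    pattern fires only false positives.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    channels = list(spec.perturbation_rates)
    probs = [spec.perturbation_rates[c] for c in channels]
    channels.append("none")
    probs.append(1.0 - sum(probs))

    train_docs: list[Document] = []
    test_docs: list[Document] = []
    planted: list[PlantedEvent] = []
    files: dict[str, dict[str, str]] = {}

    for i in range(spec.n_events):
        depth = int(rng.choice((1, 2, 3), p=spec.nesting_probs))
        channel = "none"
        two_arg = False
        if depth == 1:
            channel = str(rng.choice(channels, p=probs))
            if channel == "none":
                two_arg = bool(rng.random() < spec.two_arg_rate)
        label = str(rng.choice(EDGE_LABELS))
        base_type = EVENT_TYPES[i % len(EVENT_TYPES)]
        n_fill = int(rng.integers(spec.filler_range[0], spec.filler_range[1] + 1))

        def build(side: str) -> _SentenceBuilder:
            sb = _SentenceBuilder()
            trig = sb.add(f"trig{i}", "VBZ", lemma=f"trig{i}")
            ent = sb.add(f"PROTA{i}", "NN")
            sb.entities.append(("Protein", ent))
            args: list[tuple[str, object]] = [("Theme", ent)]
            if two_arg:
                ent2 = sb.add(f"PROTB{i}", "NN")
                sb.entities.append(("Protein", ent2))
                cause_label = "nsubj" if label != "nsubj" else "dobj"
                sb.link(trig, ent2, cause_label)
                args.append(("Cause", ent2))
            if channel == "modifier_insert" and side == "train":
                mid = sb.add(f"mod{i}", "NN")
                sb.link(trig, mid, label)
                sb.link(mid, ent, "prep_of")
            elif channel == "label_swap" and side == "test":
                swapped = EDGE_LABELS[(EDGE_LABELS.index(label) + 1) % len(EDGE_LABELS)]
                sb.link(trig, ent, swapped)
            elif channel == "dir_flip" and side == "test":
                sb.link(ent, trig, label)
            elif channel == "node_insert" and side == "test":
                mid = sb.add(f"ins{i}", "NN")
                sb.link(trig, mid, label)
                sb.link(mid, ent, "dep")
            else:
                sb.link(trig, ent, label)
            sb.events.append((base_type, trig, args))
            prev = 0  # ordinal of the innermost event
            top_trig = trig
            for lvl in range(1, depth):
                t2 = sb.add(f"trig{i}_{lvl}", "VBZ", lemma=f"trig{i}_{lvl}")
                sb.link(t2, top_trig, "xcomp")
                sb.events.append(
                    (REG_TYPES[(i + lvl) % len(REG_TYPES)], t2, [("Theme", ("E", prev))])
                )
                prev += 1
                top_trig = t2
            _add_fillers(sb, top_trig, n_fill, f"s{i}{side[0]}")
            return sb

        train_id, test_id = f"train{i:03d}", f"test{i:03d}"
        files[train_id] = build("train").render(train_id)
        files[test_id] = build("test").render(test_id)
        train_docs.append(_build_doc(files[train_id], train_id))
        test_docs.append(_build_doc(files[test_id], test_id))
        # |V_r| of the induced lowest-level pattern: trigger + entity (+ cause
        # entity) (+ train-side modifier on the path)
        n_nodes = 2 + (1 if two_arg else 0) + (1 if channel == "modifier_insert" else 0)
        planted.append(
            PlantedEvent(
                scenario=i,
                test_doc_id=test_id,
                event_id=f"E{depth}",
                channel=channel,
                pattern_nodes=n_nodes,
            )
        )

    for j in range(spec.n_junk_patterns):
        sb = _SentenceBuilder()
        trig = sb.add(f"junktrig{j}", "NN")
        ent = sb.add(f"JPROT{j}", "NN")
        sb.entities.append(("Protein", ent))
        sb.link(trig, ent, "prep_of")
        sb.events.append(("Transcription", trig, [("Theme", ent)]))
        jid = f"junktrain{j:03d}"
        files[jid] = sb.render(jid)
        train_docs.append(_build_doc(files[jid], jid))
        for k in range(3):  # unannotated recurrences: false positives only
            sb2 = _SentenceBuilder()
            t2 = sb2.add(f"junktrig{j}", "NN")
            e2 = sb2.add(f"JPROT{j}x{k}", "NN")
            sb2.entities.append(("Protein", e2))
            sb2.link(t2, e2, "prep_of")
            kid = f"junktest{j:03d}_{k}"
            files[kid] = sb2.render(kid, with_events=False)
            test_docs.append(_build_doc(files[kid], kid))

    return CorpusBundle(train_docs, test_docs, planted, files)


# --------------------------------------------------------------------------
# DSM toy corpora


@dataclass
class DsmCorpusSpec:
    """Words grouped into classes that share a context distribution.

    Designated ``antonym_pairs`` form two-word classes with *identical*
    (noise-free) context counts, reproducing the failure mode where words
    of opposite meaning are distributionally indistinguishable.
    """

    seed: int
    n_classes: int = 3
    words_per_class: int = 3
    contexts_per_class: int = 8
    base_count: int = 6
    count_noise: int = 1
    antonym_pairs: tuple[tuple[str, str], ...] = ()


def generate_dsm_corpus(spec: DsmCorpusSpec) -> list[SentenceGraph]:
    """Two-token parsed sentences realizing word/context co-occurrences.

    Words of the same class draw near-identical counts over the class's
    contexts; classes use disjoint context sets.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    sentences: list[SentenceGraph] = []
    labels = ("amod", "dobj", "prep_of", "nsubj")
    sid = 0

    def emit(head: str, word: str, label: str, count: int) -> None:
        nonlocal sid
        for _ in range(count):
            toks = [
                Token(index=1, surface=head, lemma=head, pos="NN"),
                Token(index=2, surface=word, lemma=word, pos="NN"),
            ]
            sentences.append(
                SentenceGraph(toks, [DependencyEdge(1, 2, label)], sentence_id=f"dsm{sid}")
            )
            sid += 1

    for k in range(spec.n_classes):
        contexts = [
            (f"h{k}_{c}", labels[c % len(labels)]) for c in range(spec.contexts_per_class)
        ]
        for j in range(spec.words_per_class):
            word = f"w{k}_{j}"
            for head, label in contexts:
                noise = int(rng.integers(0, spec.count_noise + 1)) if spec.count_noise else 0
                emit(head, word, label, spec.base_count + noise)
    for a_idx, (w1, w2) in enumerate(spec.antonym_pairs):
        contexts = [
            (f"anth{a_idx}_{c}", labels[c % len(labels)])
            for c in range(spec.contexts_per_class)
        ]
        for word in (w1, w2):
            for head, label in contexts:
                emit(head, word, label, spec.base_count)
    return sentences
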