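"""Shared fixtures and builders for the test suite.

All inputs are generated programmatically: the worked single-sentence
example, randomized dependency graphs/patterns for oracle comparisons,
and small hand-built standoff documents.
"""

from __future__ import annotations

import numpy as np
import pytest

from asmevent.corpus_io import (
    Document,
    SentenceGraph,
    Token,
    anonymize_entities,
    read_standoff_document,
)
from asmevent.pattern_induction import DependencyEdge, EventPattern, RoleBinding
from asmevent.synthetic_fixtures import render_parse, worked_example

LEMMAS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")
POS_TAGS = ("NN", "VBZ", "JJ")
LABELS = ("nsubj", "dobj", "amod", "prep_of")


def random_sentence_graph(rng: np.random.Generator, n: int) -> SentenceGraph:
    """Random labeled tree over a small vocabulary plus a few extra edges."""
    toks = [
        Token(
            index=i + 1,
            surface=f"w{i}",
            lemma=str(rng.choice(LEMMAS)),
            pos=str(rng.choice(POS_TAGS)),
        )
        for i in range(n)
    ]
    edges: list[DependencyEdge] = []
    seen: set[tuple] = set()
    for i in range(2, n + 1):
        gov = int(rng.integers(1, i))
        lab = str(rng.choice(LABELS))
        seen.add((gov, i, lab))
        edges.append(DependencyEdge(gov, i, lab))
    for _ in range(int(rng.integers(0, 3))):
        a, b = (int(x) for x in rng.choice(np.arange(1, n + 1), 2, replace=False))
        lab = str(rng.choice(LABELS))
        if (a, b, lab) not in seen:
            seen.add((a, b, lab))
            edges.append(DependencyEdge(a, b, lab))
    return SentenceGraph(toks, edges)


def random_pattern(rng: np.random.Generator, n: int) -> EventPattern:
    """Random connected pattern (tree-based) with 1-2 essential nodes."""
    g = random_sentence_graph(rng, n)
    ess = sorted(
        int(x) for x in rng.choice(np.arange(1, n + 1), size=min(2, n), replace=False)
    )
    bindings = [RoleBinding(ess[0], "Trigger")]
    if len(ess) > 1:
        bindings.append(RoleBinding(ess[1], "Theme"))
    return EventPattern(
        pattern_id=f"rand{rng.integers(1 << 30)}",
        event_type="X",
        nodes=g.tokens,
        edges=tuple(g.edges),
        bindings=tuple(bindings),
    )


def make_doc(
    doc_id: str,
    tokens: list[tuple[str, str]],
    edges: list[tuple[int, int, str]],
    entities: list[tuple[str, int]] = (),
    events: list[tuple[str, int, list[tuple[str, str]]]] = (),
) -> Document:
    """Build a one-sentence standoff document from compact descriptions.

    ``tokens`` are (surface, POS) 1-indexed in order; ``entities`` are
    (type, token); ``events`` are (type, trigger token, [(role, target)])
    with targets ``"T<k>"`` (k-th entity, 1-based) or ``"E<k>"`` (k-th
    event).
    """
    toks = [
        Token(index=i + 1, surface=s, lemma=s, pos=p) for i, (s, p) in enumerate(tokens)
    ]
    deps = [DependencyEdge(g, d, l) for g, d, l in edges]
    text = " ".join(t.surface for t in toks) + " ."
    spans = {}
    cursor = 0
    for t in toks:
        start = text.index(t.surface, cursor)
        spans[t.index] = (start, start + len(t.surface))
        cursor = start + len(t.surface)
    a1_lines = []
    for k, (etype, tok) in enumerate(entities, start=1):
        s, e = spans[tok]
        a1_lines.append(f"T{k}\t{etype} {s} {e}\t{text[s:e]}")
    a2_lines = []
    t_next = len(entities) + 1
    for k, (etype, trig, args) in enumerate(events, start=1):
        s, e = spans[trig]
        a2_lines.append(f"T{t_next}\t{etype} {s} {e}\t{text[s:e]}")
        rendered = " ".join(f"{role}:{target}" for role, target in args)
        a2_lines.append(f"E{k}\t{etype}:T{t_next} {rendered}".rstrip())
        t_next += 1
    return read_standoff_document(
        text,
        "\n".join(a1_lines) + ("\n" if a1_lines else ""),
        "\n".join(a2_lines) + ("\n" if a2_lines else ""),
        render_parse(toks, deps),
        doc_id=doc_id,
    )


@pytest.fixture(scope="session")
def worked():
    """(document, expected patterns) of the worked induction example."""
    return worked_example()


@pytest.fixture(scope="session")
def worked_anonymized(worked):
    doc, expected = worked
    return anonymize_entities(doc), expected
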