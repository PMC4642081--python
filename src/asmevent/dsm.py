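"""Distributional similarity model over dependency contexts.

Each word (lemma plus POS) is represented by a sparse vector of its
first-level dependency contexts: for an edge ``amod(toxicity, lethal)``
the dependent ``lethal`` receives the feature ``toxicity→amod`` and the
governor ``toxicity`` receives ``lethal←amod``.  Feature values are
pointwise mutual information in ratio form,

    mi(w, c) = (F_c(w) / N) / ((F(w)/N) * (F(c)/N)),

discounted against low-frequency bias by Lin's factor

    F_c(w)/(F_c(w)+1) * min(F(w), F(c)) / (min(F(w), F(c))+1),

and squashed into [0, 1) via lambda*mi / (1 + lambda*mi) so that very
large ratios cannot dominate the cosine similarity between words.
Contexts seen at most ``min_context_freq`` times in the corpus are
dropped.  A ``log`` form of the mutual information (floored at zero) is
available as an option.
"""

from __future__ import annotations

import copy
import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .corpus_io import SentenceGraph
from .pattern_induction import TRIGGER_ROLE, EventPattern, dedup_patterns

WordKey = tuple[str, str]  # (lemma, POS)


def feature_of(partner_lemma: str, label: str, partner_is_governor: bool) -> str:
    """Canonical serialization of a dependency context feature."""
    arrow = "→" if partner_is_governor else "←"
    return f"{partner_lemma}{arrow}{label}"


@dataclass
class MIVector:
    word: WordKey
    features: dict[str, float] = field(default_factory=dict)

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.features.values()))


@dataclass
class DSMModel:
    vectors: dict[WordKey, MIVector]
    lambda_scale: float = 0.01
    min_context_freq: int = 5

    def cosine(self, a: WordKey, b: WordKey) -> float:
        va, vb = self.vectors.get(a), self.vectors.get(b)
        if va is None or vb is None:
            return 0.0
        return cosine_similarity(va, vb)

    def top_m_similar(self, w: WordKey, m: int) -> list[tuple[WordKey, float]]:
        return top_m_similar(self, w, m)

    def top_m_lemmas(self, lemma: str, pos: str, m: int) -> set[str]:
        """Lemmas of the top-M most similar words, for node matching."""
        key: WordKey = (lemma, pos)
        if key not in self.vectors:
            from .corpus_io import relaxed_pos

            fallback = [
                k for k in self.vectors if k[0] == lemma and relaxed_pos(k[1]) == relaxed_pos(pos)
            ]
            if not fallback:
                return set()
            key = sorted(fallback)[0]
        return {k[0] for k, _ in top_m_similar(self, key, m)}


def build_model(
    corpus: Iterable[SentenceGraph],
    lambda_scale: float = 0.01,
    min_context_freq: int = 5,
    mi_form: str = "ratio",
    context_depth: int = 1,
) -> DSMModel:
    """Count word/context co-occurrences over a parsed corpus and build the
    scaled-PMI vectors.  ``context_depth`` > 1 additionally walks contexts
    along chains of that many dependency edges."""
    if mi_form not in ("ratio", "log"):
        raise ValueError(f"unknown mi_form {mi_form!r}")
    pair_freq: Counter[tuple[WordKey, str]] = Counter()
    sentences = list(corpus)
    if not sentences:
        raise ValueError("empty corpus")
    for sent in sentences:
        adj: dict[int, list[tuple[int, str, bool]]] = defaultdict(list)
        for e in sent.edges:
            adj[e.dependent].append((e.governor, e.label, True))
            adj[e.governor].append((e.dependent, e.label, False))
        for idx, tok in sent.tokens.items():
            w: WordKey = (tok.lemma, tok.pos)
            seen = {idx}
            frontier = [(idx, "")]
            for _ in range(context_depth):
                nxt = []
                for node, prefix in frontier:
                    for partner, label, is_gov in adj[node]:
                        if partner in seen:
                            continue
                        feat = prefix + feature_of(
                            sent.tokens[partner].lemma, label, is_gov
                        )
                        pair_freq[(w, feat)] += 1
                        nxt.append((partner, feat + "|"))
                frontier = nxt
    word_freq: Counter[WordKey] = Counter()
    ctx_freq: Counter[str] = Counter()
    for (w, c), n in pair_freq.items():
        word_freq[w] += n
        ctx_freq[c] += n
    total = sum(pair_freq.values())
    vectors: dict[WordKey, MIVector] = {}
    for (w, c), n in pair_freq.items():
        if ctx_freq[c] <= min_context_freq:
            continue
        fw, fc = word_freq[w], ctx_freq[c]
        ratio = (n / total) / ((fw / total) * (fc / total))
        mi = ratio if mi_form == "ratio" else max(0.0, math.log(ratio))
        mi *= (n / (n + 1)) * (min(fw, fc) / (min(fw, fc) + 1))
        scaled = lambda_scale * mi / (1 + lambda_scale * mi)
        if scaled > 0:
            vectors.setdefault(w, MIVector(word=w)).features[c] = scaled
    return DSMModel(
        vectors=vectors, lambda_scale=lambda_scale, min_context_freq=min_context_freq
    )


def cosine_similarity(a: MIVector, b: MIVector) -> float:
    """Cosine of two sparse non-negative vectors; 0 for a zero vector."""
    na, nb = a.norm(), b.norm()
    if na == 0 or nb == 0:
        return 0.0
    small, big = (a.features, b.features) if len(a.features) <= len(b.features) else (b.features, a.features)
    dot = sum(v * big.get(k, 0.0) for k, v in small.items())
    return dot / (na * nb)


def top_m_similar(model: DSMModel, w: WordKey, m: int) -> list[tuple[WordKey, float]]:
    """The ``m`` most similar words to ``w`` (excluding ``w``), ranked by
    cosine descending with ties broken lexicographically; deterministic.
    Unknown words yield the empty list."""
    if w not in model.vectors or m <= 0:
        return []
    ref = model.vectors[w]
    scored = [
        (other, sim)
        for other, vec in model.vectors.items()
        if other != w and (sim := cosine_similarity(ref, vec)) > 0
    ]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored[:m]


def expand_patterns(
    patterns: list[EventPattern],
    model: DSMModel,
    m: int,
    trigger_only: bool = False,
) -> list[EventPattern]:
    """Generative DSM integration: emit one copy of a pattern per
    (substitutable node, top-M similar word), substituting a single token
    lemma each time.  Originals are retained and the result deduplicated.
    ``trigger_only`` restricts substitution to trigger-bound nodes."""
    if m < 0:
        raise ValueError("m must be >= 0")
    out = list(patterns)
    for p in patterns:
        trig_nodes = {b.node for b in p.bindings if b.role == TRIGGER_ROLE}
        for i in sorted(p.nodes):
            tok = p.nodes[i]
            if tok.is_entity:
                continue
            if trigger_only and i not in trig_nodes:
                continue
            for (lemma, pos), _sim in model.top_m_similar((tok.lemma, tok.pos), m):
                if lemma == tok.lemma:
                    continue
                new_nodes = dict(p.nodes)
                sub = copy.copy(tok)
                sub.lemma = lemma
                sub.surface = lemma
                sub.pos = pos
                new_nodes[i] = sub
                out.append(
                    EventPattern(
                        pattern_id=f"{p.pattern_id}~{i}:{lemma}",
                        event_type=p.event_type,
                        nodes=new_nodes,
                        edges=p.edges,
                        bindings=p.bindings,
                        threshold=p.threshold,
                        provenance=p.provenance + ("dsm",),
                    )
                )
    return dedup_patterns(out)


def dump_model(model: DSMModel) -> str:
    """Sorted JSON-lines dump (word, feature, value) for diffable tests."""
    lines = []
    for w in sorted(model.vectors):
        vec = model.vectors[w]
        for feat in sorted(vec.features):
            lines.append(
                json.dumps(
                    {"lemma": w[0], "pos": w[1], "feature": feat, "value": vec.features[feat]},
                    ensure_ascii=False,
                )
            )
    header = json.dumps(
        {"lambda_scale": model.lambda_scale, "min_context_freq": model.min_context_freq}
    )
    return "\n".join([header] + lines) + "\n"


def load_model(stream: str) -> DSMModel:
    lines = [ln for ln in stream.splitlines() if ln.strip()]
    meta = json.loads(lines[0])
    vectors: dict[WordKey, MIVector] = {}
    for ln in lines[1:]:
        rec = json.loads(ln)
        key: WordKey = (rec["lemma"], rec["pos"])
        vectors.setdefault(key, MIVector(word=key)).features[rec["feature"]] = rec["value"]
    return DSMModel(
        vectors=vectors,
        lambda_scale=meta["lambda_scale"],
        min_context_freq=meta["min_context_freq"],
    )
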