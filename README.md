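# asmevent — approximate subgraph matching for biomedical event extraction

Biomedical events — statements like *"CD40 ligation leads to phosphorylation
of TRAF2"* — have a trigger word, a type (Binding, Phosphorylation,
Positive_regulation, …) and role-labeled arguments that may themselves be
events, giving nested structures. `asmevent` extracts such events from
dependency-parsed text by **instance-based graph matching**: it learns, from
annotated training sentences, the dependency subgraphs that connect a
trigger to its arguments, then finds approximate occurrences of those
subgraphs in new sentences.

The package is aimed at text-mining researchers working with BioNLP
shared-task–style standoff corpora (`.txt` / `.a1` / `.a2` plus per-sentence
dependency parses) and at anyone who needs a transparent, pattern-based
alternative to end-to-end classifiers for relation and event extraction.

## The model

A pattern graph *G_r* = (*V_r*, *E_r*) matches a subgraph of a sentence
graph *G_s* under an injective mapping *f* when its **subgraph distance**
stays within a per-pattern threshold *t*:

```
subgraphDist_f(G_r, G_s) = w_s·structDist + w_l·labelDist + w_d·directionalityDist + w_n·nodeDist
```

* `structDist` — extra path length between the images of a pattern edge's
  endpoints;
* `labelDist` — dependency-label mismatches;
* `directionalityDist` — edge-orientation mismatches;
* `nodeDist` — |skipped non-essential nodes| / |V_r|, the penalty for
  leaving lexical context nodes of the pattern unmapped. Essential nodes
  (trigger, sub-event triggers, arguments) can never be skipped. With no
  skips the distance reduces to the original three-component form.

Nodes match under the `P*+L` criterion: identical lemmas and identical
*relaxed* POS tags (all noun tags collapse to `NN`, all verb tags to `VB`);
optionally a distributional-similarity thesaurus (scaled, discounted PMI
over dependency contexts) widens lexical matching to a word's top-*M*
neighbours.

Around this core the package provides:

* **pattern induction** — shortest-path (or bounded all-paths) subgraphs
  from each annotated event, both per-argument paths and their unions, with
  entity anonymization and isomorphism-based deduplication;
* **bottom-up extraction** — entity-argument patterns first, their events
  then feeding higher-order patterns, iterated to a fixpoint, with strict
  recursive evaluation;
* **pattern-set optimization** — per-pattern precision filtering, explicit
  threshold learning for lower-order patterns, a genetic algorithm for
  higher-order thresholds, and empirical-risk-minimization backward
  elimination balancing prediction errors against pattern redundancy
  (fraction of non-essential nodes), `f(P) = E(P, G) + λ·C_P`;
* **synthetic corpora** — generators that plant events in random trees with
  perturbations of known matching cost, so every component is testable
  without external data.

## Worked example

A single annotated sentence whose core dependencies are
`nsubj(lead-20, ligation-6)`, `rcmod(ligation-6, lead-20)` and
`prep_to(lead-20, phosphorylation-23)` carries a Positive_regulation event
whose Cause is a Binding event (trigger *ligation*) and whose Theme is a
Phosphorylation event (trigger *phosphorylation*):

```python
from asmevent import (
    worked_example, anonymize_entities, induce_patterns, dedup_patterns,
    extract_events, evaluate_strict, TaskConfig,
)

doc, _ = worked_example()
adoc = anonymize_entities(doc)
patterns = dedup_patterns(induce_patterns(adoc))
for p in patterns:
    if p.event_type == "Positive_regulation":
        print(p.pattern_id, [e.label for e in p.edges])

events = extract_events(adoc, patterns, TaskConfig(event_types=()))
result = evaluate_strict(events, [adoc])
print(f"tp={result.tp} fp={result.fp} fn={result.fn} F={result.f_score:.2f}")
```

prints five distinct regulation patterns — two path unions and three
individual paths (there are *two* same-length paths between *lead* and
*ligation*, one per parallel edge, so both union and both Cause-path
variants appear) — and a perfect self-extraction:

```
worked.E3.u0 ['rcmod', 'prep_to']
worked.E3.u1 ['nsubj', 'prep_to']
worked.E3.i2 ['prep_to']
worked.E3.i3 ['rcmod']
worked.E3.i4 ['nsubj']
tp=3 fp=0 fn=0 F=1.00
```

The three extracted events are the Binding, the Phosphorylation and the
Positive_regulation nesting both.

## Command line

```bash
asmevent simulate --out corpus --seed 4 --n-events 8      # synthetic standoff corpus
asmevent induce --train corpus/train --out patterns.txt
asmevent extract --patterns patterns.txt --config cfg.yaml --in corpus/test --out pred
asmevent eval --pred pred --gold corpus/test              # prints tp/fp/fn/R/P/F
asmevent dsm-build --corpus corpus/train --out dsm.jsonl
asmevent learn-thresholds --patterns patterns.txt --config cfg.yaml \
    --train corpus/train --heldout corpus/test --out tuned.txt --seed 0
asmevent optimize --patterns tuned.txt --config cfg.yaml --train corpus/train \
    --mode erm --lambda 3 --out final.txt
```

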