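# Methods

This note documents the models and procedures implemented in `asmevent`,
the choices made where the design was genuinely open, and what the
synthetic evaluation does and does not establish.

## Input model

Documents follow the standoff convention: raw text, `.a1` entity
annotations, `.a2` trigger/event annotations, all referencing 0-based
half-open character offsets; token indices are 1-based within a sentence.
Dependency parses are consumed pre-computed, one block per sentence, in
either a tabular 6-column form (`index surface lemma pos governor label`)
or a textual edge form `label(gov-i/POS, dep-j/POS)`; both parse to the
same multigraph. Sentence graphs are labeled directed multigraphs: two
tokens may be connected by several dependencies (e.g. `nsubj` one way and
`rcmod` the other), and each parallel edge counts as a distinct path.
Token spans are recovered by scanning the text left to right for each
surface form, which is exact for the whitespace-tokenized inputs this
package produces and consumes.

Events spanning more than one sentence are dropped with a warning: the
extraction model is strictly sentence-scoped.

Entity anonymization replaces the **head token** of each entity mention —
the token inside the span whose governor lies outside it, ties broken by
the rightmost such token (the convention had to be fixed; parses are
near-trees so the rule is almost always unique) — with the generic type
string (`Protein`, …; optionally the single class `BIO_Entity`). Non-head
tokens of a multi-token mention are flagged *absorbed* and excluded from
path endpoints and from matching.

## Pattern induction

For each annotated event the trigger token(s) and each argument endpoint
(entity head, or the sub-event's trigger token) are connected by
shortest paths in the *undirected* view of the sentence multigraph. All
equally short paths are kept. Patterns come in two kinds:

* one **individual** pattern per (argument, path choice) — higher recall;
* **union** patterns joining one path choice per argument when the event
  has two or more arguments sharing the trigger — higher precision. When
  several arguments have several path choices, unions enumerate the
  cross-product, capped at 8 per event (configurable); enumeration rather
  than a single canonical union is what yields both union variants in the
  worked example.

Multi-token triggers contribute the union of their pairwise shortest paths
to every pattern of the event. `all_paths` mode additionally keeps every
acyclic path up to the shortest length plus a slack *K* (default 2);
unbounded "all lengths" is exponential, and the slack cap keeps the
documented superset relationship with shortest-path induction while
bounding pattern growth.

Patterns record lemma and relaxed POS as matchable content (surfaces kept
for diagnostics), the role bindings (trigger, Theme/Cause/…; a binding
with a sub-event type marks a sub-event trigger node and makes the pattern
*higher-order*), and the essential-node set = all bound nodes.
Deduplication removes exact isomorphs within an event type — node content,
role bindings, edge labels and directions all preserved by some bijection —
keeping the earliest provenance; candidate pairs are pre-bucketed by a
content signature before running the (multigraph) isomorphism test.

## Matching

`P*+L` node matching requires identical lemmas and relaxed POS (noun tags
collapse to `NN`, verb tags to `VB`). Entity-bound pattern nodes match only
entity tokens of a compatible generic type (`BIO_Entity` is compatible with
everything). The DSM variant additionally accepts a sentence lemma among
the top-*M* distributional neighbours of the pattern lemma, POS class
unchanged.

Per pattern edge, the images of its endpoints are aligned along a shortest
undirected path in the sentence: among all shortest paths the one
minimizing (label cost + direction cost) is chosen, ties broken by
lexicographic node order. A single-edge path compares label and
orientation directly; for longer paths the pattern label must occur
somewhere on the path, oriented consistently with the traversal. The
authoritative component formulas live in earlier work on the matcher; this
concretization reproduces every behavior documented for the distance
(single-edge mismatch costs, path-length accumulation) and is isolated in
one function so an alternative rule (e.g. per-hop label counting) is a
one-point change.

The search for mappings is exhaustive over candidate images with
branch-and-bound pruning: components are non-negative and monotone in the
partial assignment, so pruning above the threshold is exact; the unit
tests and the acceptance script verify literal equality with a brute-force
enumerator on hundreds of random pattern/sentence pairs. Non-essential
nodes may be skipped (when enabled) at a cost of `w_n / |V_r|` each; edges
touching a skipped node contribute nothing else. Per distinct image of the
essential nodes only the minimal-distance match is reported (ties: fewest
skips, then lexicographic image), making outputs deterministic.

All four weights default to 1 (the equal-weights constraint); thresholds
and weights are exposed per task, one threshold per event type plus the
active weights — 16 parameters for a 13-type task, 43 for a 40-type task.

## Extraction and evaluation

Extraction is bottom-up: patterns whose arguments are all entities run
first; each extracted event becomes a potential argument for higher-order
patterns, whose sub-event-trigger nodes must land on the trigger token of
an already-extracted event of *any* type (sub-event typing is
unconstrained; the produced event records the actual type matched). When
several events share a trigger token, one candidate per combination is
produced. The loop runs until no structurally new candidate appears,
capped at 10 rounds (the unconstrained-type fixpoint cannot be proven
terminating in general; the cap plus a warning makes termination certain).

Candidates are deduplicated by recursive structural equality, each keeping
every (pattern, distance) pair that produced it. Re-filtering a candidate
set extracted once at the maximum threshold under a new threshold vector —
a candidate is valid iff some producing pattern passes, and all sub-event
arguments are recursively valid — is exactly equivalent to re-running
extraction, which is what makes threshold search loops affordable; the
equivalence is itself a tested property (100 random vectors vs 100 fresh
extractions).

Individual-path patterns of a multi-argument event extract each argument
separately. Such *partial* events (argument set a strict subset of a
same-trigger, same-type candidate) are folded into the fuller event at
output time; candidate caches keep them so the filtering equivalence holds
at every threshold vector. Evaluation is strict: an event is correct iff
type, trigger token set, and role-labeled arguments (recursively) all
match; precision/recall/F default to 0 on empty denominators, so a
never-firing pattern ranks at precision 0.

## Pattern-set optimization

**Precision filtering** ranks each pattern by the precision of the
candidates it produced over an annotated corpus and drops those below a
cutoff (default ¼), iterated to a fixed point because removing a
lower-order pattern can starve the higher-order patterns downstream.

**Threshold learning.** Lower-order patterns are scanned explicitly over
an integer range (default [0, 12]): a larger threshold is accepted only
when training corrects strictly increase, training precision does not
drop, and held-out corrects and precision do not drop (the held-out
criterion is stated only loosely in the source design; "no decrease on
either count" is the strictest reading and is what is implemented). Among
equally good values the smallest is kept — a strictness bias. Higher-order
patterns are tuned jointly by an elitist genetic algorithm (population
100, 100 generations, integer genes in [0, 6] by default) whose fitness is
the strict F-score of the whole set with lower-order thresholds frozen.
GA internals are standard choices — tournament selection of size 2,
uniform crossover at rate 0.9, per-gene uniform-resample mutation at rate
0.1, elitism of 1 — all configurable and seeded (numpy `default_rng`),
making runs bit-reproducible. Fitness evaluations are cached by genome and
computed by re-filtering the single candidate cache.

**ERM backward elimination** minimizes `f(P) = (N_wrong + N_missed) +
λ·Σ_p redundancy(p)` where redundancy is the fraction of non-essential
nodes. Each iteration removes the pattern whose removal yields the largest
positive reduction (ties: smallest pattern id); the loop stops at
`maxGain ≤ 0`, so the objective sequence is strictly decreasing and the
procedure terminates. λ defaults to 3 (6 is the other value used in the
source experiments).

## Distributional similarity model

Words are keyed by lemma+POS. Features are first-level dependency
contexts, `head→label` on the dependent side and `dependent←label` on the
governor side (a depth option chains contexts). Feature values are
pointwise mutual information in **ratio form** (no logarithm): the
documented scaling `λ·mi/(1+λ·mi)` with λ = 0.01 only discriminates on
large unbounded ratios, which log-PMI does not produce, so the ratio form
is the default and a `log` switch (negative values floored at 0) is
provided. The value is discounted by Lin's factor
`F_c(w)/(F_c(w)+1) · min(F(w),F(c))/(min+1)` before scaling, and contexts
with corpus frequency ≤ 5 are dropped. Similarity is the cosine of the
sparse vectors; top-*M* queries exclude the word itself and any
zero-cosine word, with ties broken lexicographically. The generative
integration copies a pattern once per (substitutable node, neighbour)
with a single lemma substitution, originals retained, result deduplicated.

Antonyms occur in near-identical contexts and are therefore ranked as
nearest neighbours — the model's characteristic failure mode, reproduced
deliberately by the synthetic corpus's identical-context antonym pairs.

## Synthetic data

The generators define the evaluation conditions:

* `worked_example()` — the single-sentence induction example; only the
  three core tokens and their three labeled edges are structurally
  meaningful, so filler tokens attach as leaves and can never lie on an
  induced path.
* `generate_event_corpus(spec)` — paired train/test documents (default 12
  scenarios; nesting depth 1/2/3 with probability 0.6/0.25/0.15; 25% of
  flat scenarios take a second, Cause argument; 2–5 leaf fillers per
  sentence). Each test event is perturbed through at most one channel
  with an exact, recorded matching cost: edge-label swap (`w_l`),
  direction flip (`w_d`), intermediate-node insertion (`w_s`), or a
  train-side modifier on the path (`w_n/|V_r|` with skipping, unmatchable
  without). Mutual exclusion per event is what makes the recorded cost
  exact, and generator/matcher agreement on these costs is itself a test.
  Optional junk scenarios plant a training-only event whose construction
  recurs unannotated in extra test documents, giving a pattern that fires
  only false positives. Trigger lemmas are unique per scenario so patterns
  cannot cross-fire and every recovery observation is attributable.
* `generate_dsm_corpus(spec)` — two-token sentences realizing word/context
  counts; words of a class share a context distribution up to small count
  noise, designated antonym pairs share it exactly.

All generation is driven by a mandatory seed through numpy `default_rng`;
same seed, byte-identical corpora.

**What passing these tests shows — and does not.** The synthetic corpora
have noiseless annotations, single-governor trees plus controlled
perturbations, unique trigger lemmas and one entity type; real parses have
attachment errors, shared triggers, overlapping mentions and far richer
lexical variation. The suite therefore validates the *mechanics* —
induction, distance, search, nesting, threshold semantics, optimization
behavior — not the F-scores attainable on shared-task corpora, which
require the external annotated data.

## Numerical and degenerate-input conventions

Distances are floats with an absolute tolerance of 1e-9 at threshold
comparisons (thresholds are meant inclusively); an unalignable edge yields
an infinite distance sentinel. Zero-length paths exist only for identical
endpoints; disconnected trigger/argument pairs skip the pattern with a
warning rather than failing the document. Empty candidate sets, empty
pattern stores and empty corpora evaluate to zeros rather than errors,
except `build_model`, which rejects an empty corpus outright. The
brute-force matcher is guarded to patterns of ≤ 10 nodes. Problem sizes
throughout the suite (≤ 10 scenarios per corpus, ≤ 8-node patterns,
500 oracle pairs, a 3^5 exhaustive GA grid) were chosen so each component
is exercised across its behavioral regimes while any single check remains
enumerable by its oracle.
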