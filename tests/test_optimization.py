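"""Pattern quality control: precision filter, threshold learning, GA, ERM."""

import itertools

import pytest

from asmevent.corpus_io import anonymize_entities
from asmevent.event_engine import TaskConfig, evaluate_strict, extract_corpus
from asmevent.optimization import (
    ERMConfig,
    GAConfig,
    ThresholdAssignment,
    erm_objective,
    erm_optimize,
    ga_optimize_thresholds,
    learn_lower_thresholds,
    pattern_precision,
    pattern_redundancy,
    precision_filter,
)
from asmevent.pattern_induction import dedup_patterns, induce_patterns
from asmevent.synthetic_fixtures import CorpusSpec, generate_event_corpus

from conftest import make_doc


def induce_all(docs):
    return dedup_patterns([p for d in docs for p in induce_patterns(d)])


def transcription_docs():
    """'expression of TNF mRNA' trains a pattern that also fires on the
    unannotated 'level of TNF mRNA' phrasing: one TP, one FP."""
    train = make_doc(
        "tr",
        [("expression", "NN"), ("TNF", "NN"), ("mRNA", "NN")],
        [(1, 3, "prep_of"), (3, 2, "nn")],
        entities=[("Protein", 2)],
        events=[("Transcription", 1, [("Theme", "T1")])],
    )
    # same dependency context, no gold Transcription event
    fp_doc = make_doc(
        "lv",
        [("expression", "NN"), ("TNF2", "NN"), ("mRNA", "NN")],
        [(1, 3, "prep_of"), (3, 2, "nn")],
        entities=[("Protein", 2)],
    )
    return anonymize_entities(train), anonymize_entities(fp_doc)


class TestPatternPrecision:
    def test_counts(self):
        train, fp_doc = transcription_docs()
        (pat,) = induce_all([train])
        cfg = TaskConfig(event_types=("Transcription",))
        stats = pattern_precision(pat, [train, fp_doc], cfg)
        assert (stats.n_total, stats.n_correct) == (2, 1)
        assert stats.precision == 0.5

    def test_never_firing_pattern_has_zero_precision(self):
        train, _ = transcription_docs()
        (pat,) = induce_all([train])
        empty = make_doc("e", [("unrelated", "NN")], [])
        stats = pattern_precision(pat, [anonymize_entities(empty)], TaskConfig(event_types=()))
        assert stats.n_total == 0 and stats.precision == 0.0


class TestPrecisionFilter:
    def test_perfect_patterns_unchanged(self):
        spec = CorpusSpec(seed=31, n_events=5, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0)
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        cfg = TaskConfig(event_types=())
        assert precision_filter(pats, test, cfg) == pats

    def test_junk_pattern_removed_first_round(self):
        spec = CorpusSpec(
            seed=33, n_events=4, n_junk_patterns=2, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0
        )
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        kept = precision_filter(pats, test, TaskConfig(event_types=()))
        assert any("junktrain" in p.pattern_id for p in pats)
        assert not any("junktrain" in p.pattern_id for p in kept)
        assert all("junktrain" not in p.pattern_id for p in kept)

    def test_starved_higher_order_pattern_removed_in_later_round(self):
        """Dropping a lower-order pattern removes the higher-order pattern
        that depended on its events (the down-stream effect of iteration)."""
        # train: chain regulation(trigH) -> expression(trigL) -> PROT
        train = make_doc(
            "tr",
            [("induces", "VBZ"), ("junkexpr", "VBZ"), ("PROT", "NN")],
            [(1, 2, "xcomp"), (2, 3, "dobj")],
            entities=[("Protein", 3)],
            events=[
                ("Gene_expression", 2, [("Theme", "T1")]),
                ("Positive_regulation", 1, [("Theme", "E1")]),
            ],
        )
        # test: same construction twice unannotated, once annotated only at
        # the lower level -> lower pattern precision 1/3, higher fires only
        # where lower fired
        def test_doc(did, annotated):
            return make_doc(
                did,
                [("induces", "VBZ"), ("junkexpr", "VBZ"), ("PROTX", "NN")],
                [(1, 2, "xcomp"), (2, 3, "dobj")],
                entities=[("Protein", 3)],
                events=(
                    [("Gene_expression", 2, [("Theme", "T1")])] if annotated else []
                ),
            )

        docs = [
            anonymize_entities(test_doc("t1", False)),
            anonymize_entities(test_doc("t2", False)),
            anonymize_entities(test_doc("t3", False)),
            anonymize_entities(test_doc("t4", False)),
        ]
        pats = induce_all([anonymize_entities(train)])
        assert len(pats) == 2
        kept = precision_filter(pats, docs, TaskConfig(event_types=()), min_precision=0.25)
        assert kept == []  # lower removed for 0 precision, higher starved


class TestLearnLowerThresholds:
    def test_exact_only_pattern_stays_at_zero(self):
        spec = CorpusSpec(seed=41, n_events=3, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0)
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        cfg = TaskConfig(event_types=())
        ta = learn_lower_thresholds(pats, test, test, cfg, (0, 12))
        assert set(ta.thresholds.values()) == {0.0}

    def test_label_perturbation_learns_higher_threshold(self):
        """A 1-unit label difference hides one extra true event and no
        false ones: the scan must raise the threshold to at least w_l."""
        spec = CorpusSpec(
            seed=43,
            n_events=6,
            nesting_probs=(1.0, 0, 0),
            two_arg_rate=0.0,
            perturbation_rates={"label_swap": 1.0},
        )
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        cfg = TaskConfig(event_types=())
        ta = learn_lower_thresholds(pats, test, test, cfg, (0, 12))
        assert all(v >= 1.0 for v in ta.thresholds.values())

    def test_collapsed_range_returns_minimum(self):
        spec = CorpusSpec(seed=41, n_events=2, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0)
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        ta = learn_lower_thresholds(pats, test, test, TaskConfig(event_types=()), (0, 0))
        assert set(ta.thresholds.values()) <= {0.0}

    def test_never_reduces_corrects_or_precision_vs_zero(self):
        spec = CorpusSpec(
            seed=47,
            n_events=8,
            nesting_probs=(1.0, 0, 0),
            two_arg_rate=0.0,
            perturbation_rates={"label_swap": 0.4, "dir_flip": 0.3},
        )
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        cfg = TaskConfig(event_types=())
        ta = learn_lower_thresholds(pats, test, test, cfg, (0, 12))
        from asmevent.optimization import _counts_at, _prec, _single_pattern_curve

        for p in pats:
            curve = _single_pattern_curve(p, test, cfg, 12.0, None, None)
            c0, t0 = _counts_at(curve, 0.0)
            cv, tv = _counts_at(curve, ta.thresholds[p.pattern_id])
            assert cv >= c0
            assert _prec(cv, tv) >= _prec(c0, t0)


def ga_fixture():
    """Five higher-order patterns whose jointly optimal thresholds are the
    unique vector (0, 1, 0, 1, 0).

    For every scenario the chain 'regulation -> expression -> PROT' is
    annotated in one test document.  A second document repeats the
    construction with the regulation edge label changed (distance 1 for the
    higher pattern); for even scenarios that occurrence is NOT annotated
    (threshold 1 would add a false positive), for odd scenarios it IS
    (threshold 1 adds a true positive).
    """
    train, test = [], []
    for i in range(5):
        train.append(
            make_doc(
                f"tr{i}",
                [(f"reg{i}", "VBZ"), (f"expr{i}", "VBZ"), ("PROT", "NN")],
                [(1, 2, "xcomp"), (2, 3, "dobj")],
                entities=[("Protein", 3)],
                events=[
                    ("Gene_expression", 2, [("Theme", "T1")]),
                    ("Regulation", 1, [("Theme", "E1")]),
                ],
            )
        )
        test.append(
            make_doc(
                f"te{i}c",
                [(f"reg{i}", "VBZ"), (f"expr{i}", "VBZ"), ("PROTX", "NN")],
                [(1, 2, "xcomp"), (2, 3, "dobj")],
                entities=[("Protein", 3)],
                events=[
                    ("Gene_expression", 2, [("Theme", "T1")]),
                    ("Regulation", 1, [("Theme", "E1")]),
                ],
            )
        )
        swapped_events = [("Gene_expression", 2, [("Theme", "T1")])]
        if i % 2 == 1:
            swapped_events.append(("Regulation", 1, [("Theme", "E1")]))
        test.append(
            make_doc(
                f"te{i}s",
                [(f"reg{i}", "VBZ"), (f"expr{i}", "VBZ"), ("PROTY", "NN")],
                [(1, 2, "advcl"), (2, 3, "dobj")],
                entities=[("Protein", 3)],
                events=swapped_events,
            )
        )
    train = [anonymize_entities(d) for d in train]
    test = [anonymize_entities(d) for d in test]
    pats = induce_all(train)
    lower = ThresholdAssignment(
        {p.pattern_id: 0.0 for p in pats if not p.is_higher_order}
    )
    return pats, lower, test


class TestGA:
    def test_no_higher_order_patterns_empty_assignment(self):
        spec = CorpusSpec(seed=41, n_events=2, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0)
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        out = ga_optimize_thresholds(
            pats, ThresholdAssignment({p.pattern_id: 0.0 for p in pats}), test,
            GAConfig(seed=0, population_size=4, generations=2), TaskConfig(event_types=()),
        )
        assert out.thresholds == {}

    def test_collapsed_range_returns_that_point(self):
        pats, lower, test = ga_fixture()
        out = ga_optimize_thresholds(
            pats, lower, test,
            GAConfig(value_range=(2, 2), seed=0, population_size=6, generations=3),
            TaskConfig(event_types=()),
        )
        assert set(out.thresholds.values()) == {2.0}

    def test_seeded_runs_are_identical(self):
        pats, lower, test = ga_fixture()
        cfg = GAConfig(value_range=(0, 3), seed=11, population_size=12, generations=6)
        a = ga_optimize_thresholds(pats, lower, test, cfg, TaskConfig(event_types=()))
        b = ga_optimize_thresholds(pats, lower, test, cfg, TaskConfig(event_types=()))
        assert a.thresholds == b.thresholds

    def test_finds_global_optimum_of_designed_fixture(self):
        pats, lower, test = ga_fixture()
        task = TaskConfig(event_types=())
        ga_cfg = GAConfig(value_range=(0, 2), seed=3, population_size=30, generations=25)
        out = ga_optimize_thresholds(pats, lower, test, ga_cfg, task)
        higher_ids = sorted(p.pattern_id for p in pats if p.is_higher_order)
        assert len(higher_ids) == 5

        def fitness(vec):
            merged = dict(lower.thresholds)
            merged.update(dict(zip(higher_ids, map(float, vec))))
            pred = extract_corpus(test, pats, task, per_pattern_threshold=merged)
            return evaluate_strict(pred, test).f_score

        # exhaustive search over the full grid
        best = max(
            itertools.product(range(3), repeat=5), key=lambda v: (fitness(v), v)
        )
        got = tuple(int(out.thresholds[pid]) for pid in higher_ids)
        assert fitness(got) == pytest.approx(fitness(best))
        # the designed optimum alternates 0/1 by scenario parity
        assert fitness(best) == pytest.approx(fitness((0, 1, 0, 1, 0)))
        assert fitness((0, 1, 0, 1, 0)) > fitness((0, 0, 0, 0, 0))
        assert fitness((0, 1, 0, 1, 0)) > fitness((1, 1, 1, 1, 1))


class TestRedundancyAndErm:
    def test_redundancy_values(self, worked_anonymized):
        adoc, expected = worked_anonymized
        # Table-style union pattern: 3 nodes, all bound -> 0
        assert pattern_redundancy(expected[0]) == 0.0

    def test_redundancy_fraction(self):
        train = make_doc(
            "tr",
            [("induces", "VBZ"), ("binding", "NN"), ("activity", "NN"), ("PROT", "NN")],
            [(1, 3, "dobj"), (3, 2, "nn"), (2, 4, "prep_of")],
            entities=[("Protein", 4)],
            events=[("Binding", 2, [("Theme", "T1")])],
        )
        (pat,) = induce_all([anonymize_entities(train)])
        assert pattern_redundancy(pat) == pytest.approx(0.0)  # 2-node path
        # compact 2-node entity+trigger pattern has redundancy 0
        compact = make_doc(
            "c",
            [("activities", "NNS"), ("PROT", "NN")],
            [(1, 2, "nn")],
            entities=[("Protein", 2)],
            events=[("Positive_regulation", 1, [("Theme", "T1")])],
        )
        (cp,) = induce_all([anonymize_entities(compact)])
        assert pattern_redundancy(cp) == 0.0

    @staticmethod
    def verbose_compact_fixture():
        """A verbose 3-node pattern and a compact 2-node pattern that
        predict the same events once node skipping is allowed."""
        verbose_train = make_doc(
            "v",
            [("expr0", "VBZ"), ("modifier", "NN"), ("PROT", "NN")],
            [(1, 2, "dobj"), (2, 3, "prep_of")],
            entities=[("Protein", 3)],
            events=[("Gene_expression", 1, [("Theme", "T1")])],
        )
        compact_train = make_doc(
            "c",
            [("expr0", "VBZ"), ("PROT", "NN")],
            [(1, 2, "dobj")],
            entities=[("Protein", 2)],
            events=[("Gene_expression", 1, [("Theme", "T1")])],
        )
        test = make_doc(
            "t",
            [("expr0", "VBZ"), ("PROTX", "NN")],
            [(1, 2, "dobj")],
            entities=[("Protein", 2)],
            events=[("Gene_expression", 1, [("Theme", "T1")])],
        )
        pats = induce_all([anonymize_entities(verbose_train), anonymize_entities(compact_train)])
        for p in pats:
            p.threshold = 0.5  # enough for the w_n/3 skip of the verbose pattern
        return pats, [anonymize_entities(test)]

    def test_erm_objective_perfect_extraction_all_essential(self):
        pats, test = self.verbose_compact_fixture()
        compact = [p for p in pats if len(p.nodes) == 2]
        cfg = TaskConfig(event_types=(), allow_skip=True)
        f = erm_objective(compact, test, cfg, ERMConfig(lambda_reg=3.0))
        assert f == 0.0  # no errors, no redundancy

    def test_erm_objective_arithmetic(self):
        pats, test = self.verbose_compact_fixture()
        cfg = TaskConfig(event_types=(), allow_skip=True)
        lam = 3.0
        f = erm_objective(pats, test, cfg, ERMConfig(lambda_reg=lam))
        c_p = sum(pattern_redundancy(p) for p in pats)
        assert c_p == pytest.approx(1 / 3)
        assert f == pytest.approx(0.0 + lam * c_p)  # E = 0, only redundancy

    def test_erm_objective_counts_missed_events(self):
        _, test = self.verbose_compact_fixture()
        cfg = TaskConfig(event_types=())
        f = erm_objective([], test, cfg, ERMConfig(lambda_reg=3.0))
        assert f == 1.0  # the one gold event is missed

    def test_erm_removes_redundant_verbose_pattern(self):
        pats, test = self.verbose_compact_fixture()
        cfg = TaskConfig(event_types=(), allow_skip=True)
        trace: list = []
        kept = erm_optimize(pats, test, cfg, ERMConfig(lambda_reg=3.0), trace=trace)
        assert [len(p.nodes) for p in kept] == [2]  # verbose one eliminated
        assert trace == sorted(trace, reverse=True)
        assert len(set(trace)) == len(trace)  # strictly decreasing

    def test_lambda_zero_keeps_what_large_lambda_removes(self):
        pats0, test = self.verbose_compact_fixture()
        cfg = TaskConfig(event_types=(), allow_skip=True)
        kept0 = erm_optimize(pats0, test, cfg, ERMConfig(lambda_reg=0.0))
        patsL, _ = self.verbose_compact_fixture()
        keptL = erm_optimize(patsL, test, cfg, ERMConfig(lambda_reg=6.0))
        assert len(kept0) == 2 and len(keptL) == 1

    def test_all_necessary_patterns_returned_unchanged(self):
        spec = CorpusSpec(seed=51, n_events=4, nesting_probs=(1.0, 0, 0), two_arg_rate=0.0)
        bundle = generate_event_corpus(spec)
        train, test = bundle.anonymized()
        pats = induce_all(train)
        kept = erm_optimize(pats, test, TaskConfig(event_types=()), ERMConfig(lambda_reg=3.0))
        assert {p.pattern_id for p in kept} == {p.pattern_id for p in pats}
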