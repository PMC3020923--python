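"""Breadth/Depth metric family and IR baselines."""

import numpy as np
import pytest

from ontobench.mapping import CorpusStatistics
from ontobench.metrics import (
    ConfusionCounts,
    breadth1,
    breadth2,
    breadth3_depth3,
    concept_confusion,
    depth,
    evaluate,
    ir_metrics,
    pair_confusion,
)
from tests.conftest import make_ontology


def _stats(freq, prob=None, cooc=None, typed=None):
    return CorpusStatistics(
        concept_freq=freq,
        cooccurrence=cooc or {},
        relation_prob=prob or {},
        typed_weight=typed,
    )


class TestIRMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=5, fp=0, fn=0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(tp=1, fp=1, fn=3), (0.5, 0.25, 1 / 3)),
            (ConfusionCounts(tp=0, fp=2, fn=2), (0.0, 0.0, 0.0)),
        ],
    )
    def test_formulas(self, counts, expected):
        m = ir_metrics(counts)
        assert (m.precision, m.recall, m.f_measure) == pytest.approx(expected)

    def test_undefined_denominators_are_none(self):
        m = ir_metrics(ConfusionCounts(tp=0, fp=0, fn=3))
        assert m.precision is None and m.f_measure is None
        assert m.recall == 0.0

    def test_confusion_against_stats(self):
        stats = _stats({"a": 0.6, "b": 0.4}, cooc={("a", "b"): 1, ("b", "a"): 1})
        X = make_ontology(concepts=["a", "x"], relations=[("a", "r", "x")])
        cc = concept_confusion(X, stats)
        assert (cc.tp, cc.fp, cc.fn) == (1, 1, 1)
        pc = pair_confusion(X, stats)
        assert (pc.tp, pc.fp, pc.fn) == (0, 1, 2)


class TestBreadth:
    def test_full_coverage_is_one(self):
        stats = _stats({"a": 0.2, "b": 0.8})
        assert breadth1(make_ontology(concepts=["a", "b"]), stats) == pytest.approx(1.0)

    def test_partial_coverage(self):
        stats = _stats({"a": 0.2, "b": 0.8})
        assert breadth1(make_ontology(concepts=["a"]), stats) == pytest.approx(0.2)

    def test_unobserved_concepts_contribute_zero(self):
        stats = _stats({"a": 1.0})
        X = make_ontology(concepts=["a", "ghost1", "ghost2"])
        assert breadth1(X, stats) == pytest.approx(1.0)

    def test_breadth2_single_pair(self):
        stats = _stats({"a": 0.5, "b": 0.5}, prob={("a", "b"): 0.4, ("b", "a"): 1.0})
        X = make_ontology(concepts=["a", "b"], relations=[("a", "r", "b")])
        assert breadth2(X, stats) == pytest.approx(0.5 * 0.4)

    def test_breadth2_conservation_when_all_pairs_covered(self):
        # every observed concept has co-occurrences and X covers every pair:
        # sum_i f_i sum_j p_ij = sum_i f_i = 1
        rng = np.random.default_rng(11)
        ids = [f"c{i}" for i in range(6)]
        f = rng.dirichlet(np.ones(6))
        prob = {}
        for i, cid in enumerate(ids):
            row = rng.dirichlet(np.ones(5))
            for w, other in zip(row, [o for o in ids if o != cid]):
                prob[(cid, other)] = float(w)
        stats = _stats(dict(zip(ids, map(float, f))), prob=prob)
        X = make_ontology(
            concepts=ids,
            relations=[(i, "r", j) for (i, j) in prob],
        )
        assert breadth2(X, stats) == pytest.approx(1.0)

    def test_breadth_oracle_random_subontologies(self):
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(20)]
        f = dict(zip(ids, map(float, rng.dirichlet(np.ones(20)))))
        stats = _stats(f)
        for _ in range(50):
            chosen = list(rng.choice(ids, size=7, replace=False))
            X = make_ontology(concepts=chosen)
            assert breadth1(X, stats) == pytest.approx(sum(f[c] for c in chosen))


class TestDepth:
    def test_depth_is_breadth_per_constituent(self):
        X = make_ontology(concepts=[f"c{i}" for i in range(4)])
        report = depth(1, 0.5, X)
        assert report.depth == pytest.approx(0.125)
        assert report.size_used == 4

    def test_zero_breadth_zero_depth(self):
        X = make_ontology(concepts=["a"])
        assert depth(1, 0.0, X).depth == 0.0

    def test_empty_ontology_errors(self):
        with pytest.raises(ValueError, match="empty"):
            depth(1, 0.0, make_ontology())

    def test_level2_uses_pair_count_not_relation_count(self):
        X = make_ontology(
            concepts=["a", "b"],
            relations=[("a", "is-a", "b"), ("a", "part-of", "b")],
        )
        report = depth(2, 0.4, X)
        assert report.size_used == 1  # one ordered pair despite two predicates
        assert depth(3, 0.4, X).size_used == 2


class TestBreadth3:
    def _typed_stats(self):
        return _stats(
            {"a": 0.5, "b": 0.5},
            prob={("a", "b"): 0.6, ("b", "a"): 1.0},
            typed={("a", "is-a", "b"): 0.5, ("a", "part-of", "b"): 0.5},
        )

    def test_single_predicate_reduces_to_breadth2(self):
        stats = _stats(
            {"a": 0.5, "b": 0.5},
            prob={("a", "b"): 0.6},
            typed={("a", "is-a", "b"): 1.0},
        )
        X = make_ontology(concepts=["a", "b"], relations=[("a", "is-a", "b")])
        report = breadth3_depth3(X, stats)
        assert report.breadth == pytest.approx(breadth2(X, stats))
        assert report.depth * X.n_relations == pytest.approx(
            depth(2, breadth2(X, stats), X).depth * X.n_pairs
        )

    def test_holding_one_of_two_equal_predicates_halves_mass(self):
        stats = self._typed_stats()
        X = make_ontology(concepts=["a", "b"], relations=[("a", "is-a", "b")])
        assert breadth3_depth3(X, stats).breadth == pytest.approx(0.5 * 0.6 * 0.5)

    def test_missing_typed_weight_contributes_zero(self):
        stats = self._typed_stats()
        X = make_ontology(concepts=["a", "b"], relations=[("a", "mystery", "b")])
        assert breadth3_depth3(X, stats).breadth == 0.0

    def test_brute_force_triple_sum_oracle(self):
        rng = np.random.default_rng(3)
        ids = ["a", "b", "c"]
        f = dict(zip(ids, map(float, rng.dirichlet(np.ones(3)))))
        prob, typed, relations = {}, {}, []
        predicates = ["is-a", "part-of"]
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                prob[(i, j)] = float(rng.random())
                w = rng.dirichlet(np.ones(2))
                for k, pred in enumerate(predicates):
                    typed[(i, pred, j)] = float(w[k])
                    if rng.random() < 0.6:
                        relations.append((i, pred, j))
        stats = _stats(f, prob=prob, typed=typed)
        X = make_ontology(concepts=ids, relations=relations)
        expected = sum(
            f[i] * prob[(i, j)] * typed[(i, k, j)] for (i, k, j) in set(relations)
        )
        assert breadth3_depth3(X, stats).breadth == pytest.approx(expected)


class TestMetricBehaviour:
    def test_adding_concepts_never_decreases_breadth(self):
        rng = np.random.default_rng(17)
        ids = [f"c{i}" for i in range(10)]
        stats = _stats(dict(zip(ids, map(float, rng.dirichlet(np.ones(10))))))
        base = list(ids[:3])
        b_prev = breadth1(make_ontology(concepts=base), stats)
        for extra in ids[3:]:
            base.append(extra)
            b_next = breadth1(make_ontology(concepts=base), stats)
            assert b_next >= b_prev
            b_prev = b_next

    def test_zero_frequency_padding_strictly_lowers_depth(self):
        stats = _stats({"a": 0.7, "b": 0.3})
        lean = make_ontology(concepts=["a", "b"])
        padded = make_ontology(concepts=["a", "b", "ghost"])
        r_lean = evaluate(lean, stats, 1)
        r_padded = evaluate(padded, stats, 1)
        assert r_padded.breadth == r_lean.breadth
        assert r_padded.depth < r_lean.depth

    def test_breadth_bounded_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            n = int(rng.integers(2, 12))
            ids = [f"c{i}" for i in range(n)]
            stats = _stats(dict(zip(ids, map(float, rng.dirichlet(np.ones(n))))))
            size = int(rng.integers(1, n + 1))
            X = make_ontology(concepts=list(rng.choice(ids, size=size, replace=False)))
            report = evaluate(X, stats, 1)
            assert 0.0 <= report.breadth <= 1.0
            assert report.depth >= 0.0

    def test_equal_precision_recall_different_depth(self):
        # same-size ontologies with identical confusion counts but
        # different depth: breadth/depth see usage mass, IR sees sets
        stats = _stats({"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1})
        x1 = make_ontology("x1", concepts=["a", "b"])
        x2 = make_ontology("x2", concepts=["c", "d"])
        ir1 = ir_metrics(concept_confusion(x1, stats))
        ir2 = ir_metrics(concept_confusion(x2, stats))
        assert ir1 == ir2
        assert evaluate(x1, stats, 1).depth != evaluate(x2, stats, 1).depth
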