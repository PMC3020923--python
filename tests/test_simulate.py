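"""Synthetic-fixture generator: determinism, limits, parameter recovery."""

import math

import numpy as np
import pytest

from ontobench.corpus import analyze, build_contexts
from ontobench.fittest import complete_ontology, fittest_of_size, loss_metrics
from ontobench.mapping import (
    CorpusStatistics,
    estimate_frequencies,
    estimate_relation_probs,
    match_concepts,
)
from ontobench.metrics import evaluate
from ontobench.simulate import (
    GeneratorSpec,
    generate_concept_corpus,
    generate_ontology_family,
    generate_substitution_corpus,
    zipf_weights,
)
from ontobench.substitution import substitution_probs


def _estimate(cc, unit="document"):
    docs = [analyze(d, cc.tagger) for d in cc.documents]
    mentions = match_concepts(docs, cc.ontology, unit=unit)
    freq = estimate_frequencies(mentions)
    cooc, prob = estimate_relation_probs(mentions)
    return mentions, freq, cooc, prob


class TestConceptCorpus:
    def test_same_seed_byte_identical(self):
        spec = GeneratorSpec(seed=5, n_concepts=8, n_documents=50)
        a = generate_concept_corpus(spec)
        b = generate_concept_corpus(spec)
        assert [d.text for d in a.documents] == [d.text for d in b.documents]
        assert a.truth.concept_freq == b.truth.concept_freq

    def test_different_seed_differs(self):
        a = generate_concept_corpus(GeneratorSpec(seed=1, n_concepts=8, n_documents=50))
        b = generate_concept_corpus(GeneratorSpec(seed=2, n_concepts=8, n_documents=50))
        assert [d.text for d in a.documents] != [d.text for d in b.documents]

    def test_document_count_matches_spec(self):
        cc = generate_concept_corpus(GeneratorSpec(seed=0, n_concepts=5, n_documents=77))
        assert len(cc.documents) == 77

    def test_zipf_zero_is_uniform(self):
        w = zipf_weights(50, 0.0)
        assert np.allclose(w, 1 / 50)
        # empirical check on a mentions-only corpus
        spec = GeneratorSpec(
            seed=3, n_concepts=10, zipf_s=0.0, n_documents=2000,
            mention_doc_fraction=1.0, mentions_per_doc=(1, 1),
        )
        _, freq, _, _ = _estimate(generate_concept_corpus(spec))
        se = math.sqrt(0.1 * 0.9 / 2000)
        for f in freq.values():
            assert abs(f - 0.1) < 3 * se

    def test_infeasible_joint_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            GeneratorSpec(seed=0, n_concepts=5, cooccurrence_joint=np.ones((3, 3)))

    def test_ground_truth_rows_stochastic(self):
        cc = generate_concept_corpus(GeneratorSpec(seed=9, n_concepts=12, n_documents=10))
        rows = {}
        for (i, _j), p in cc.truth.relation_prob.items():
            rows[i] = rows.get(i, 0.0) + p
        for total in rows.values():
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_mention_counts_recovered_exactly(self):
        # tiny corpus: dictionary matcher must find every planted mention
        cc = generate_concept_corpus(GeneratorSpec(seed=4, n_concepts=6, n_documents=30))
        mentions, _, _, _ = _estimate(cc)
        expected = 0
        for doc in cc.documents:
            expected += sum(
                1 for tok in doc.text.split() if tok in cc.concept_lexicon
            )
        assert len(mentions) == expected


class TestParameterRecovery:
    def test_frequency_and_relation_recovery(self):
        spec = GeneratorSpec(seed=12, n_concepts=20, n_documents=5000)
        cc = generate_concept_corpus(spec)
        _, freq, cooc, prob = _estimate(cc)
        n_docs = spec.n_documents

        total_mentions = sum(
            len([t for t in d.text.split() if t in cc.concept_lexicon])
            for d in cc.documents
        )
        for cid, f_true in cc.truth.concept_freq.items():
            se = math.sqrt(max(f_true * (1 - f_true), 1e-12) / total_mentions)
            assert abs(freq.get(cid, 0.0) - f_true) <= 3 * se + 1e-9

        row_counts = {}
        for (i, _j), n in cooc.items():
            row_counts[i] = row_counts.get(i, 0) + n
        z_scores = []
        for (i, j), p_true in cc.truth.relation_prob.items():
            n_row = row_counts.get(i, 0)
            if n_row < 30:
                continue  # too few co-occurrence events for a stable check
            se = math.sqrt(p_true * (1 - p_true) / n_row)
            z_scores.append(abs(prob.get((i, j), 0.0) - p_true) / se)
        # hundreds of simultaneous estimates: allow the statistically
        # expected handful of >3 s.e. excursions, none far out
        expected_beyond = 0.0027 * len(z_scores)
        quota = int(expected_beyond + 3.0 * expected_beyond ** 0.5) + 1
        assert sum(z > 3.0 for z in z_scores) <= quota
        assert max(z_scores) <= 4.5


class TestSubstitutionCorpus:
    def test_dominant_synonym_takes_all_synonym_mass(self):
        spec = GeneratorSpec(
            seed=6,
            substitution_spec={
                ("pain", "NOUN"): {("pain", "NOUN"): 0.5, ("ache", "NOUN"): 0.5,
                                   ("zilch", "NOUN"): 0.0},
            },
            sentences_per_headword=300,
        )
        sc = generate_substitution_corpus(spec)
        docs = [analyze(d, sc.tagger) for d in sc.documents]
        table = substitution_probs(build_contexts(docs, k=2), sc.thesaurus)
        head = ("pain", "NOUN")
        assert table.probs[(head, ("zilch", "NOUN"))] == 0.0
        assert table.probs[(head, ("ache", "NOUN"))] == pytest.approx(0.5, abs=0.1)

    def test_unseen_headword_has_zero_row(self):
        spec = GeneratorSpec(
            seed=7,
            substitution_spec={
                ("pang", "NOUN"): {("pang", "NOUN"): 0.0, ("throe", "NOUN"): 1.0},
            },
            sentences_per_headword=100,
        )
        sc = generate_substitution_corpus(spec)
        docs = [analyze(d, sc.tagger) for d in sc.documents]
        table = substitution_probs(build_contexts(docs, k=2), sc.thesaurus)
        assert table.probs[(("pang", "NOUN"), ("throe", "NOUN"))] == 0.0
        assert table.headword_counts[("pang", "NOUN")] == 0

    def test_planted_mixture_recovered(self):
        rates = {("x", "NOUN"): 0.6, ("y", "NOUN"): 0.3, ("z", "NOUN"): 0.1}
        spec = GeneratorSpec(
            seed=8,
            substitution_spec={
                ("w", "NOUN"): {("w", "NOUN"): 0.4, ("x", "NOUN"): 0.36,
                                ("y", "NOUN"): 0.18, ("z", "NOUN"): 0.06},
            },
            sentences_per_headword=4000,
        )
        sc = generate_substitution_corpus(spec)
        docs = [analyze(d, sc.tagger) for d in sc.documents]
        table = substitution_probs(build_contexts(docs, k=2), sc.thesaurus)
        head = ("w", "NOUN")
        n = spec.sentences_per_headword
        for syn, planted in (("x", 0.36), ("y", 0.18), ("z", 0.06)):
            est = table.probs[(head, (syn, "NOUN"))]
            se = math.sqrt(planted * (1 - planted) / n)
            assert abs(est - planted) <= 3 * se
        # ranking follows the planted ordering
        row = table.row(head)
        assert max(row, key=row.get) == ("x", "NOUN")

    def test_rate_sum_validation(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorSpec(
                substitution_spec={("w", "NOUN"): {("x", "NOUN"): 0.5}}
            )


class TestOntologyFamily:
    @pytest.fixture
    def stats_and_complete(self):
        cc = generate_concept_corpus(
            GeneratorSpec(seed=21, n_concepts=15, n_documents=1500)
        )
        _, freq, cooc, prob = _estimate(cc)
        stats = CorpusStatistics(
            concept_freq=freq, cooccurrence=cooc, relation_prob=prob
        )
        return stats, complete_ontology(stats)

    def test_top_beats_random_beats_bottom(self, stats_and_complete):
        stats, complete = stats_and_complete
        family = generate_ontology_family(complete, size=5, seed=2)
        depths = {
            name: evaluate(onto, stats, 1).depth for name, onto in family.items()
        }
        assert depths["top"] >= depths["random"] >= depths["bottom"]

    def test_superset_breadth_no_smaller(self, stats_and_complete):
        stats, complete = stats_and_complete
        small = generate_ontology_family(complete, size=4, seed=2)["top"]
        large = generate_ontology_family(complete, size=9, seed=2)["top"]
        assert evaluate(large, stats, 1).breadth >= evaluate(small, stats, 1).breadth

    def test_bottom_has_maximal_relative_depth_loss(self, stats_and_complete):
        stats, complete = stats_and_complete
        size = 5
        family = generate_ontology_family(complete, size=size, seed=2)
        fittest = fittest_of_size(complete, budget=size, level=1)
        losses = {
            name: loss_metrics(
                evaluate(onto, stats, 1).depth, fittest.depth
            ).relative_depth_loss
            for name, onto in family.items()
        }
        assert losses["bottom"] == max(losses.values())
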