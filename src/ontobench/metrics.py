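"""Breadth/Depth metric family and information-retrieval baselines.

Given corpus statistics (concept frequencies ``f_i`` and relation
probabilities ``p_ij``), an ontology ``X`` is scored at three granularity
levels:

* ``Breadth^1 = sum_{i in C_X ∩ C_T} f_i`` — probability mass of corpus
  concept usage the ontology covers; in [0, 1].
* ``Breadth^2 = sum_{(i,j) in pairs(X) ∩ pairs(T)} f_i * p_ij`` — mass of
  concept–relation usage covered; in [0, 1] because each row of ``p``
  sums to at most 1.
* ``Breadth^3 = sum_{(i,k,j) in R_X ∩ R_T} f_i * p_ij * pi_k|ij`` — as
  Breadth^2 but resolving individual predicate types via their relative
  textual prevalence ``pi_k|ij``.

``Depth`` divides each Breadth by the matching ontology size (|C_X|,
number of relation-bearing ordered pairs, |R_X| respectively): coverage
per constituent, the parsimony counterpart to coverage.  Concepts or
relations present in the ontology but unseen in the corpus contribute
zero mass — they are improbable, not false.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from ontobench.mapping import CorpusStatistics
from ontobench.ontology import Ontology

__all__ = [
    "ConfusionCounts", "IRMetrics", "MetricReport", "concept_confusion",
    "pair_confusion", "ir_metrics", "breadth1", "breadth2", "depth",
    "breadth3_depth3", "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Cross-tabulation of ontology membership against corpus observation."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class IRMetrics:
    """Precision/recall/F; a value is None when its denominator is zero."""

    precision: float | None
    recall: float | None
    f_measure: float | None


@dataclass(frozen=True)
class MetricReport:
    level: int
    breadth: float
    depth: float
    size_used: int

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError(f"level must be 1, 2 or 3, got {self.level}")
        if not 0.0 <= self.breadth <= 1.0 + 1e-12:
            raise ValueError(f"breadth {self.breadth} outside [0, 1]")


def concept_confusion(X: Ontology, stats: CorpusStatistics) -> ConfusionCounts:
    """tp = concepts of X observed in the corpus, fn = observed concepts X
    misses, fp = concepts of X never observed."""
    observed = set(stats.concept_freq)
    mine = set(X.concepts)
    tp = len(mine & observed)
    return ConfusionCounts(tp=tp, fp=len(mine - observed), fn=len(observed - mine))


def pair_confusion(X: Ontology, stats: CorpusStatistics) -> ConfusionCounts:
    """As :func:`concept_confusion`, over ordered relation-bearing pairs."""
    observed = set(stats.cooccurrence)
    mine = set(X.pair_set())
    tp = len(mine & observed)
    return ConfusionCounts(tp=tp, fp=len(mine - observed), fn=len(observed - mine))


def ir_metrics(counts: ConfusionCounts) -> IRMetrics:
    """Precision, recall and F-measure; F = 0 when P = R = 0, None when a
    denominator vanishes (never silently coerced to 0)."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if precision is None or recall is None:
        f = None
    elif precision + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return IRMetrics(precision=precision, recall=recall, f_measure=f)


def breadth1(X: Ontology, stats: CorpusStatistics) -> float:
    """Concept-level coverage: sum of f_i over concepts of X observed in T."""
    total = math.fsum(stats.concept_freq.get(cid, 0.0) for cid in X.concepts)
    return min(total, 1.0)  # guard float accumulation at the upper bound


def breadth2(X: Ontology, stats: CorpusStatistics) -> float:
    """Concept+relation coverage: sum of f_i * p_ij over relation-bearing
    ordered pairs of X that co-occur in T."""
    f = stats.concept_freq
    p = stats.relation_prob
    total = math.fsum(
        f.get(i, 0.0) * p.get((i, j), 0.0) for (i, j) in X.pair_set()
    )
    return min(total, 1.0)


def depth(level: int, breadth: float, X: Ontology) -> MetricReport:
    """Depth at the given level: Breadth divided by |C_X| (level 1), by the
    relation-bearing pair count (level 2) or by |R_X| (level 3)."""
    if level == 1:
        size = X.n_concepts
    elif level == 2:
        size = X.n_pairs
    elif level == 3:
        size = X.n_relations
    else:
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    if size == 0:
        raise ValueError(f"empty ontology: level-{level} size is 0")
    return MetricReport(level=level, breadth=breadth, depth=breadth / size, size_used=size)


def breadth3_depth3(X: Ontology, stats: CorpusStatistics) -> MetricReport:
    """Typed-relation coverage and parsimony.

    Each typed relation (i, k, j) of X covered by the corpus contributes
    ``f_i * p_ij * pi_k|ij``; pairs lacking a typed weight contribute 0.
    Depth^3 divides by |R_X|, so cataloguing many predicates for the same
    pair dilutes rather than inflates the score.
    """
    if stats.typed_weight is None:
        raise ValueError("statistics carry no typed-relation weights")
    f = stats.concept_freq
    p = stats.relation_prob
    pi = stats.typed_weight
    total = 0.0
    for rel in X.relations:
        pair_mass = f.get(rel.source, 0.0) * p.get((rel.source, rel.target), 0.0)
        if pair_mass == 0.0:
            continue
        total += pair_mass * pi.get((rel.source, rel.predicate, rel.target), 0.0)
    return depth(3, total, X)


def evaluate(X: Ontology, stats: CorpusStatistics, level: int) -> MetricReport:
    """Breadth + Depth report for ``X`` against ``stats`` at ``level``."""
    if level == 1:
        return depth(1, breadth1(X, stats), X)
    if level == 2:
        return depth(2, breadth2(X, stats), X)
    if level == 3:
        return breadth3_depth3(X, stats)
    raise ValueError(f"level must be 1, 2 or 3, got {level}")
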