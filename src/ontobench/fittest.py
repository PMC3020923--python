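"""Complete ontology, fittest-of-fixed-size selection, and Depth Loss.

The *complete ontology* of a corpus contains every concept and every
co-occurring concept pair observed in it, with their estimated usage
probabilities.  The *fittest ontology of size k* is the k-member subset of
the complete ontology maximizing Depth.  Because Depth is an additive sum
of non-negative per-item masses divided by the fixed budget, picking the k
items with the largest masses is the exact optimum — no search needed.

Comparing an arbitrary ontology's Depth to the same-size fittest Depth
yields *Depth Loss* (the absolute shortfall), *Relative Depth* (their
ratio, in [0, 1]) and *Relative Depth Loss* (1 - Relative Depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ontobench.mapping import CorpusStatistics
from ontobench.ontology import Concept, Ontology, Relation

logger = logging.getLogger(__name__)

__all__ = [
    "CompleteOntology", "FittestSelection", "FittestResult",
    "complete_ontology", "fittest_of_size", "loss_metrics",
]

_TOL = 1e-12


@dataclass
class CompleteOntology:
    """Every concept and co-occurring pair observed in a corpus, with
    their probabilities."""

    concept_freq: dict[str, float]
    pair_prob: dict[tuple[str, str], float]
    label: str = ""

    @property
    def n_concepts(self) -> int:
        return len(self.concept_freq)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_prob)

    def to_ontology(self) -> Ontology:
        onto = Ontology(name=self.label or "complete")
        for cid in sorted(self.concept_freq):
            onto.add_concept(Concept(id=cid, preferred_name=cid))
        for i, j in sorted(self.pair_prob):
            onto.add_relation(Relation(source=i, predicate="related-to", target=j))
        return onto


@dataclass
class FittestSelection:
    """The depth-maximizing subset of the complete ontology at a budget."""

    level: int
    budget: int
    items: tuple  # concept ids (level 1) or ordered pairs (level 2)
    breadth: float
    depth: float


@dataclass(frozen=True)
class FittestResult:
    """Loss metrics of a test ontology against the same-size fittest one."""

    depth_fittest: float
    depth_x: float
    depth_loss: float
    relative_depth: float
    relative_depth_loss: float


def complete_ontology(stats: CorpusStatistics) -> CompleteOntology:
    """All observed concepts and co-occurring pairs with probabilities."""
    if not stats.concept_freq:
        raise ValueError("empty corpus statistics")
    return CompleteOntology(
        concept_freq=dict(stats.concept_freq),
        pair_prob={
            pair: stats.relation_prob[pair]
            for pair in stats.cooccurrence
            if stats.relation_prob.get(pair, 0.0) > 0.0
        },
        label=stats.label,
    )


def fittest_of_size(
    complete: CompleteOntology, budget: int, level: int = 1
) -> FittestSelection:
    """Select the ``budget`` items of largest corpus mass.

    Level 1 ranks concepts by ``f_i``; level 2 ranks ordered pairs by
    ``f_i * p_ij`` (their member concepts come along implicitly).  Ties
    break on identifier so results are bit-for-bit reproducible.  Budgets
    beyond the available items clamp with a warning.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if level == 1:
        weighted = [(f, cid) for cid, f in complete.concept_freq.items()]
    elif level == 2:
        weighted = [
            (complete.concept_freq.get(i, 0.0) * p, (i, j))
            for (i, j), p in complete.pair_prob.items()
        ]
    else:
        raise ValueError("fittest selection is defined for levels 1 and 2")
    if budget > len(weighted):
        logger.warning(
            "budget %d exceeds available items (%d); clamped", budget, len(weighted)
        )
        budget = len(weighted)
    if budget == 0:
        raise ValueError("complete ontology has no items at this level")
    weighted.sort(key=lambda wi: (-wi[0], wi[1]))
    chosen = weighted[:budget]
    breadth = sum(w for w, _ in chosen)
    return FittestSelection(
        level=level,
        budget=budget,
        items=tuple(item for _, item in chosen),
        breadth=breadth,
        depth=breadth / budget,
    )


def loss_metrics(depth_x: float, fittest_depth: float) -> FittestResult:
    """Depth Loss and its normalized forms.

    ``depth_loss = fittest_depth - depth_x``;
    ``relative_depth = depth_x / fittest_depth`` (in [0, 1]);
    ``relative_depth_loss = 1 - relative_depth``.
    A test ontology deeper than the fittest of its own size violates the
    optimality of the selection and raises.
    """
    if fittest_depth <= 0.0:
        raise ValueError("fittest depth must be positive")
    if depth_x > fittest_depth * (1.0 + 1e-9) + _TOL:
        raise ValueError(
            f"depth {depth_x} exceeds fittest depth {fittest_depth}: "
            "optimality violated"
        )
    depth_x = min(depth_x, fittest_depth)
    relative_depth = depth_x / fittest_depth
    return FittestResult(
        depth_fittest=fittest_depth,
        depth_x=depth_x,
        depth_loss=fittest_depth - depth_x,
        relative_depth=relative_depth,
        relative_depth_loss=1.0 - relative_depth,
    )
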