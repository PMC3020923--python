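"""Concept recognition in text and estimation of corpus usage statistics.

Concept mentions are found by longest-match dictionary lookup over
lemmatized token spans (a lightweight substitute for full-blown biomedical
concept-mapping engines).  From the mentions the module estimates

* concept frequencies ``f_i`` — normalized mention shares, sum to 1;
* co-occurrence counts ``n_ij`` — number of text units (documents or
  sentences) containing both concepts;
* relation probabilities ``p_ij = n_ij / sum_j' n_ij'`` — the probability
  that a mention of ``i`` is accompanied by ``j`` in the same unit, with
  ``p_ij = 0`` for concepts unobserved or never co-occurring;
* optionally typed-relation weights ``pi_k|ij`` — the relative frequency
  of the k-th predicate among all mentions of relations between i and j.

A smoothed variant keeps every row a proper distribution by routing
residual mass to a pseudo-concept sink, so that unobserved concepts are
punished smoothly rather than zeroed.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, Sequence

from ontobench.corpus import Document, default_normalize
from ontobench.ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "Mention", "CorpusStatistics", "SmoothingParams", "match_concepts",
    "estimate_frequencies", "estimate_relation_probs", "smooth_relation_probs",
    "estimate_typed_weights", "save_statistics", "load_statistics",
    "NULL_CONCEPT_ID",
]

NULL_CONCEPT_ID = "__NULL__"

Pair = tuple[str, str]


@dataclass(frozen=True)
class Mention:
    unit_id: Hashable
    concept_id: str
    surface: str = ""


@dataclass
class CorpusStatistics:
    """Concept and relation usage probabilities estimated from a corpus."""

    concept_freq: dict[str, float]
    cooccurrence: dict[Pair, int] = field(default_factory=dict)
    relation_prob: dict[Pair, float] = field(default_factory=dict)
    typed_weight: dict[tuple[str, str, str], float] | None = None
    unit: str = "document"
    label: str = ""

    def validate(self, tol: float = 1e-9) -> None:
        total = sum(self.concept_freq.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"concept frequencies sum to {total}, not 1")
        rows: dict[str, float] = defaultdict(float)
        for (i, _j), p in self.relation_prob.items():
            if not 0.0 <= p <= 1.0 + tol:
                raise ValueError(f"probability out of range: {p}")
            rows[i] += p
        for i, s in rows.items():
            if s > tol and abs(s - 1.0) > tol:
                raise ValueError(f"relation probabilities of {i!r} sum to {s}")


@dataclass(frozen=True)
class SmoothingParams:
    """Additive smoothing constants; requires 0 <= alpha < beta < 1."""

    alpha: float = 0.0
    beta: float = 0.01
    null_concept_id: str = NULL_CONCEPT_ID

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < self.beta < 1.0):
            raise ValueError(
                f"smoothing requires 0 <= alpha < beta < 1, "
                f"got alpha={self.alpha}, beta={self.beta}"
            )


# ---------------------------------------------------------------------------
# Dictionary matching
# ---------------------------------------------------------------------------


def _build_phrase_index(
    ontology_or_lexicon, lemmatize: Callable[[str], str] | None
) -> dict[tuple[str, ...], str]:
    """Map lemma-token tuples to concept ids; ties go to the lexicographically
    smallest concept id so matching is deterministic."""
    if isinstance(ontology_or_lexicon, Ontology):
        items = [
            (name, cid)
            for cid, concept in ontology_or_lexicon.concepts.items()
            for name in concept.names()
        ]
    else:  # mapping phrase -> concept id
        items = [(name, cid) for name, cid in ontology_or_lexicon.items()]
    index: dict[tuple[str, ...], str] = {}
    for name, cid in items:
        if lemmatize is None:
            key = tuple(default_normalize(name).split())
        else:
            key = tuple(lemmatize(w) for w in name.lower().split())
        if not key:
            continue
        if key in index:
            index[key] = min(index[key], cid)
        else:
            index[key] = cid
    return index


def match_concepts(
    corpus: Iterable[Document],
    ontology_or_lexicon,
    unit: str = "document",
    lemmatize: Callable[[str], str] | None = None,
) -> list[Mention]:
    """Recognize concept mentions by longest-match dictionary lookup.

    Matching is case-insensitive and operates on token base forms; at each
    position the longest matching span wins and overlapping candidates
    resolve to the leftmost-longest.  Mentions never span sentence
    boundaries.  ``unit`` decides the co-occurrence unit recorded with each
    mention: the whole document or the single sentence.
    """
    if unit not in ("document", "sentence"):
        raise ValueError(f"unknown unit {unit!r}")
    index = _build_phrase_index(ontology_or_lexicon, lemmatize)
    if not index:
        return []
    max_len = max(len(k) for k in index)
    mentions: list[Mention] = []
    for doc in corpus:
        if not doc.analyzed:
            raise ValueError(f"document {doc.doc_id!r} not analyzed")
        for s_idx, sent in enumerate(doc.sentences):
            bases = [tok.base_form.lower() for tok in sent]
            unit_id = doc.doc_id if unit == "document" else (doc.doc_id, s_idx)
            pos = 0
            while pos < len(bases):
                matched = None
                for span in range(min(max_len, len(bases) - pos), 0, -1):
                    cid = index.get(tuple(bases[pos : pos + span]))
                    if cid is not None:
                        matched = (cid, span)
                        break
                if matched is not None:
                    cid, span = matched
                    surface = " ".join(tok.surface for tok in sent[pos : pos + span])
                    mentions.append(Mention(unit_id=unit_id, concept_id=cid, surface=surface))
                    pos += span
                else:
                    pos += 1
    return mentions


# ---------------------------------------------------------------------------
# Statistics estimation
# ---------------------------------------------------------------------------


def estimate_frequencies(mentions: Sequence[Mention]) -> dict[str, float]:
    """Normalized concept frequencies: f_i = mentions(i) / total mentions."""
    if not mentions:
        raise ValueError("cannot estimate frequencies from an empty mention list")
    counts = Counter(m.concept_id for m in mentions)
    total = sum(counts.values())
    return {cid: n / total for cid, n in counts.items()}


def estimate_relation_probs(
    mentions: Sequence[Mention],
) -> tuple[dict[Pair, int], dict[Pair, float]]:
    """Unit-level co-occurrence counts and row-normalized probabilities.

    ``n_ij`` counts units containing both i and j (each unit contributes at
    most once per pair, however many times the concepts are mentioned);
    counts are kept for both orders so ``n_ij == n_ji``.  Rows with no
    co-occurrences get no entries — their probabilities are 0.
    """
    units: dict[Hashable, set[str]] = defaultdict(set)
    for m in mentions:
        units[m.unit_id].add(m.concept_id)
    cooc: dict[Pair, int] = defaultdict(int)
    for members in units.values():
        ordered = sorted(members)
        for a_idx in range(len(ordered)):
            for b_idx in range(a_idx + 1, len(ordered)):
                i, j = ordered[a_idx], ordered[b_idx]
                cooc[(i, j)] += 1
                cooc[(j, i)] += 1
    row_totals: dict[str, int] = defaultdict(int)
    for (i, _j), n in cooc.items():
        row_totals[i] += n
    probs = {(i, j): n / row_totals[i] for (i, j), n in cooc.items()}
    return dict(cooc), probs


def smooth_relation_probs(
    cooccurrence: Mapping[Pair, int],
    params: SmoothingParams,
    concepts: Iterable[str] | None = None,
) -> dict[Pair, float]:
    """Additive smoothing with a pseudo-concept sink.

    Every concept row becomes a proper distribution over real targets plus
    the sink ``params.null_concept_id``: real targets get pseudo-count
    alpha, the sink gets ``alpha * N * (1 - beta) / beta`` so that a row
    with no observations places mass ``1 - beta`` (close to 1 for small
    beta) on the sink, while well-observed rows leave it only a sliver.
    With ``alpha = 0`` the unsmoothed probabilities are recovered exactly
    and observed rows carry no sink mass; fully unobserved rows then place
    all mass on the sink.
    """
    if params.null_concept_id in (concepts or ()):
        raise ValueError("null_concept_id collides with a concept id")
    universe = set(concepts) if concepts is not None else set()
    for i, j in cooccurrence:
        universe.add(i)
        universe.add(j)
    universe.discard(params.null_concept_id)
    alpha, beta = params.alpha, params.beta
    n_targets = max(len(universe) - 1, 1)
    sink_count = alpha * n_targets * (1.0 - beta) / beta

    rows: dict[str, dict[str, int]] = defaultdict(dict)
    for (i, j), n in cooccurrence.items():
        rows[i][j] = n

    probs: dict[Pair, float] = {}
    for i in sorted(universe):
        observed = rows.get(i, {})
        row_total = sum(observed.values())
        denom = row_total + alpha * n_targets + sink_count
        if denom == 0.0:  # alpha == 0 and i unobserved: all mass on the sink
            probs[(i, params.null_concept_id)] = 1.0
            continue
        if alpha > 0.0:
            for j in sorted(universe):
                if j == i:
                    continue
                probs[(i, j)] = (observed.get(j, 0) + alpha) / denom
        else:
            for j, n in sorted(observed.items()):
                probs[(i, j)] = n / denom
        probs[(i, params.null_concept_id)] = sink_count / denom
    return probs


def estimate_typed_weights(
    triple_counts: Mapping[tuple[str, str, str], int],
) -> dict[tuple[str, str, str], float]:
    """Relative frequency pi_k|ij of predicate k among mentions of relations
    between i and j.  Triples are (source, predicate, target); pairs with no
    counted triples are simply absent."""
    pair_totals: dict[Pair, int] = defaultdict(int)
    for (i, _k, j), n in triple_counts.items():
        pair_totals[(i, j)] += n
    return {
        (i, k, j): n / pair_totals[(i, j)]
        for (i, k, j), n in triple_counts.items()
        if pair_totals[(i, j)] > 0
    }


# ---------------------------------------------------------------------------
# Statistics I/O (TSV)
# ---------------------------------------------------------------------------


def save_statistics(stats: CorpusStatistics, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "concept_freq.tsv", "w", encoding="utf-8") as fh:
        fh.write("concept_id\tf\n")
        for cid in sorted(stats.concept_freq):
            fh.write(f"{cid}\t{stats.concept_freq[cid]:.17g}\n")
    with open(directory / "relations.tsv", "w", encoding="utf-8") as fh:
        fh.write("source_id\ttarget_id\tn\tp\n")
        for i, j in sorted(set(stats.cooccurrence) | set(stats.relation_prob)):
            n = stats.cooccurrence.get((i, j), 0)
            p = stats.relation_prob.get((i, j), 0.0)
            fh.write(f"{i}\t{j}\t{n}\t{p:.17g}\n")
    if stats.typed_weight:
        with open(directory / "typed_weights.tsv", "w", encoding="utf-8") as fh:
            fh.write("source_id\tpredicate\ttarget_id\tpi\n")
            for i, k, j in sorted(stats.typed_weight):
                fh.write(f"{i}\t{k}\t{j}\t{stats.typed_weight[(i, k, j)]:.17g}\n")


def load_statistics(directory: str | Path, unit: str = "document") -> CorpusStatistics:
    directory = Path(directory)
    concept_freq: dict[str, float] = {}
    with open(directory / "concept_freq.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            cid, f = line.rstrip("\n").split("\t")
            concept_freq[cid] = float(f)
    cooc: dict[Pair, int] = {}
    prob: dict[Pair, float] = {}
    rel_path = directory / "relations.tsv"
    if rel_path.exists():
        with open(rel_path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                i, j, n, p = line.rstrip("\n").split("\t")
                if int(n):
                    cooc[(i, j)] = int(n)
                prob[(i, j)] = float(p)
    typed: dict[tuple[str, str, str], float] | None = None
    typed_path = directory / "typed_weights.tsv"
    if typed_path.exists():
        typed = {}
        with open(typed_path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                i, k, j, pi = line.rstrip("\n").split("\t")
                typed[(i, k, j)] = float(pi)
    return CorpusStatistics(
        concept_freq=concept_freq,
        cooccurrence=cooc,
        relation_prob=prob,
        typed_weight=typed,
        unit=unit,
        label=directory.name,
    )
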