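"""Synthetic corpora, ontologies and thesauri with known ground truth.

Real benchmarking corpora (millions of abstracts) and licensed
terminologies are large; every estimator in this package is instead
exercised against generated fixtures whose true parameters are planted and
emitted alongside:

* concept mentions drawn from a Zipf frequency law (the frequency skew
  characteristic of real terminologies), with synonym surface forms mixed
  in so dictionary matching is exercised;
* unit-level co-occurrences drawn from a planted symmetric joint weight
  matrix, whose row-normalization is the true relation-probability matrix;
* templated sentences placing thesaurus headwords and synonyms into shared
  four-word contexts at planted substitution rates.

Documents are deliberately schematic — template sentences, not English
syntax.  The same seed always yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ontobench.corpus import Document, LexiconTagger
from ontobench.fittest import CompleteOntology
from ontobench.ontology import Concept, Ontology, Relation
from ontobench.substitution import SubstitutionTable, ThesaurusEntry

__all__ = [
    "GeneratorSpec", "GroundTruth", "ConceptCorpus", "SubstitutionCorpus",
    "zipf_weights", "generate_concept_corpus", "generate_substitution_corpus",
    "generate_ontology_family",
]

Word = tuple[str, str]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic study conditions.

    ``cooccurrence_joint`` plants the symmetric co-occurrence structure: a
    non-negative symmetric matrix (zero diagonal) whose normalized entries
    are the probabilities that a co-occurrence unit carries each unordered
    concept pair.  Row-normalizing it gives the true ``p_ij``.  When None,
    a seeded random symmetric matrix is drawn.  ``mention_doc_fraction`` of
    documents carry repeated mentions of a single Zipf-drawn concept (these
    shape the frequency law without touching co-occurrence counts); the
    rest carry exactly one planted concept pair.
    """

    seed: int = 0
    n_concepts: int = 50
    zipf_s: float = 1.0
    n_documents: int = 5000
    mentions_per_doc: tuple[int, int] = (1, 3)  # uniform-inclusive range
    mention_doc_fraction: float = 0.5
    cooccurrence_joint: np.ndarray | None = None
    cooccurrence_density: float = 0.3
    synonym_rate: float = 0.3
    substitution_spec: dict[Word, dict[Word, float]] | None = None
    sentences_per_headword: int = 2000
    n_context_frames: int = 8
    n_hapax_fillers: int = 5

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValueError("need at least 2 concepts")
        if not 0.0 <= self.mention_doc_fraction <= 1.0:
            raise ValueError("mention_doc_fraction must be in [0, 1]")
        if self.cooccurrence_joint is not None:
            q = np.asarray(self.cooccurrence_joint, dtype=float)
            if q.shape != (self.n_concepts, self.n_concepts):
                raise ValueError(
                    f"cooccurrence_joint shape {q.shape} does not match "
                    f"n_concepts={self.n_concepts}"
                )
            if (q < 0).any() or not np.allclose(q, q.T):
                raise ValueError("cooccurrence_joint must be symmetric non-negative")
        if self.substitution_spec is not None:
            for head, rates in self.substitution_spec.items():
                total = sum(rates.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"substitution rates for {head} sum to {total}, not 1"
                    )
                if any(r < 0 for r in rates.values()):
                    raise ValueError("substitution rates must be non-negative")


@dataclass
class GroundTruth:
    """Exact expected values of the estimators on the generated corpus."""

    concept_freq: dict[str, float]
    relation_prob: dict[tuple[str, str], float]
    joint: np.ndarray
    concept_ids: list[str]


@dataclass
class ConceptCorpus:
    documents: list[Document]
    ontology: Ontology
    tagger: LexiconTagger
    concept_lexicon: dict[str, str]  # surface phrase -> concept id
    truth: GroundTruth
    spec: GeneratorSpec


@dataclass
class SubstitutionCorpus:
    documents: list[Document]
    tagger: LexiconTagger
    thesaurus: list[ThesaurusEntry]
    truth: SubstitutionTable
    spec: GeneratorSpec


def zipf_weights(n: int, s: float) -> np.ndarray:
    """Normalized Zipf weights w_r ∝ (r+1)^-s; s = 0 gives uniform."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


def _concept_id(i: int) -> str:
    return f"C{i:04d}"


def _concept_token(i: int) -> str:
    return f"disease{i}"


def _synonym_token(i: int) -> str:
    return f"malady{i}"


def _default_joint(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_concepts
    q = np.zeros((n, n))
    upper = np.triu_indices(n, k=1)
    mask = rng.random(len(upper[0])) < spec.cooccurrence_density
    vals = rng.random(len(upper[0])) * mask
    q[upper] = vals
    q = q + q.T
    if q.sum() == 0:  # pathological draw: plant one pair
        q[0, 1] = q[1, 0] = 1.0
    return q


def generate_concept_corpus(spec: GeneratorSpec) -> ConceptCorpus:
    """Generate a corpus with planted concept frequencies and co-occurrences.

    Each document is either a *mention document* (one Zipf-drawn concept
    mentioned 1+ times, no co-occurrence) or a *pair document* (exactly one
    concept pair drawn from the planted joint).  The emitted ground truth
    gives the exact expected values of the frequency and relation-probability
    estimators under these conditions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_concepts
    ids = [_concept_id(i) for i in range(n)]
    zipf = zipf_weights(n, spec.zipf_s)

    joint = (
        np.asarray(spec.cooccurrence_joint, dtype=float)
        if spec.cooccurrence_joint is not None
        else _default_joint(spec, rng)
    )
    joint = joint / joint.sum()  # distribution over ordered pairs (symmetric)
    pair_marginal = joint.sum(axis=1)  # P(pair contains i)

    lo, hi = spec.mentions_per_doc
    mean_mentions = (lo + hi) / 2.0
    c = 1.0 - spec.mention_doc_fraction  # fraction of pair documents

    # exact expected mention shares: a mention document contributes
    # mean_mentions Zipf-drawn mentions; a pair document contributes one
    # mention of each member, i.e. 2 * P(pair contains i) in expectation
    weights = (1.0 - c) * mean_mentions * zipf + c * 2.0 * pair_marginal
    f_true = weights / weights.sum()
    row_sums = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_true = np.where(row_sums > 0, joint / row_sums, 0.0)

    # flatten upper triangle for pair sampling
    iu, ju = np.triu_indices(n, k=1)
    pair_probs = 2.0 * joint[iu, ju]  # unordered-pair distribution
    pair_probs = pair_probs / pair_probs.sum()

    lexicon: dict[str, tuple[str, str]] = {"the": ("the", "OTHER"), "with": ("with", "OTHER")}
    concept_lexicon: dict[str, str] = {}
    for i, cid in enumerate(ids):
        for tok in (_concept_token(i), _synonym_token(i)):
            lexicon[tok] = (tok, "NOUN")
        concept_lexicon[_concept_token(i)] = cid
        concept_lexicon[_synonym_token(i)] = cid

    def render(i: int) -> str:
        if rng.random() < spec.synonym_rate:
            return _synonym_token(i)
        return _concept_token(i)

    documents: list[Document] = []
    for d in range(spec.n_documents):
        sentences: list[str] = []
        if rng.random() < spec.mention_doc_fraction:
            concept = rng.choice(n, p=zipf)
            m = int(rng.integers(lo, hi + 1))
            for _ in range(m):
                sentences.append(f"the {render(concept)} .")
        else:
            k = rng.choice(len(pair_probs), p=pair_probs)
            a, b = int(iu[k]), int(ju[k])
            sentences.append(f"the {render(a)} with {render(b)} .")
        documents.append(Document(doc_id=f"doc{d:06d}", text=" ".join(sentences)))

    ontology = Ontology(name="complete-truth")
    for i, cid in enumerate(ids):
        ontology.add_concept(
            Concept(
                id=cid,
                preferred_name=_concept_token(i),
                synonyms=(_synonym_token(i),),
                semantic_type="Disease or Syndrome",
            )
        )
    for a in range(n):
        for b in range(n):
            if a != b and joint[a, b] > 0:
                ontology.add_relation(
                    Relation(source=ids[a], predicate="related-to", target=ids[b])
                )

    truth = GroundTruth(
        concept_freq={cid: float(f_true[i]) for i, cid in enumerate(ids)},
        relation_prob={
            (ids[a], ids[b]): float(p_true[a, b])
            for a in range(n)
            for b in range(n)
            if a != b and p_true[a, b] > 0
        },
        joint=joint,
        concept_ids=ids,
    )
    return ConceptCorpus(
        documents=documents,
        ontology=ontology,
        tagger=LexiconTagger(lexicon),
        concept_lexicon=concept_lexicon,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Substitution corpus
# ---------------------------------------------------------------------------


def _default_substitution_spec() -> dict[Word, dict[Word, float]]:
    return {
        ("headache", "NOUN"): {
            ("headache", "NOUN"): 0.5,
            ("migraine", "NOUN"): 0.3,
            ("neuralgia", "NOUN"): 0.15,
            ("mess", "NOUN"): 0.05,
        },
        ("futile", "ADJ"): {
            ("futile", "ADJ"): 0.4,
            ("vain", "ADJ"): 0.35,
            ("fruitless", "ADJ"): 0.25,
        },
    }


def generate_substitution_corpus(spec: GeneratorSpec) -> SubstitutionCorpus:
    """Generate templated sentences realizing planted substitution rates.

    For each headword, every sentence draws one candidate (the headword or
    a synonym) at the planted rates and embeds it in one of a fixed pool of
    shared four-content-word frames, so that all candidates share context
    profiles and the conditional estimator recovers the planted rates.
    One-word hapax sentences are mixed in to exercise rare-word binning and
    empty-context boundaries without disturbing the frames.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sub_spec = spec.substitution_spec or _default_substitution_spec()

    lexicon: dict[str, tuple[str, str]] = {}
    frames: list[tuple[str, str, str, str]] = []
    for fi in range(spec.n_context_frames):
        frame = (
            f"ctxnoun{fi}", f"ctxverb{fi}", f"ctxadj{fi}", f"ctxnoun{fi}b",
        )
        lexicon[frame[0]] = (frame[0], "NOUN")
        lexicon[frame[1]] = (frame[1], "VERB")
        lexicon[frame[2]] = (frame[2], "ADJ")
        lexicon[frame[3]] = (frame[3], "NOUN")
        frames.append(frame)
    for hi in range(spec.n_hapax_fillers):
        lexicon[f"hapax{hi}"] = (f"hapax{hi}", "NOUN")

    thesaurus: list[ThesaurusEntry] = []
    truth = SubstitutionTable(label="planted")
    sentences: list[str] = []
    for head, rates in sub_spec.items():
        candidates = sorted(rates, key=lambda w: (w != head, w))
        for base, pos in candidates:
            lexicon[base] = (base, pos)
        synonyms = tuple(c for c in candidates if c != head)
        thesaurus.append(ThesaurusEntry(headword=head, synonyms=synonyms))
        head_rate = rates.get(head, 0.0)
        truth.self_mass[head] = head_rate
        for syn in synonyms:
            truth.probs[(head, syn)] = rates[syn]
        probs = np.array([rates[c] for c in candidates])
        draws = rng.choice(len(candidates), size=spec.sentences_per_headword, p=probs)
        n_head = 0
        for draw in draws:
            word = candidates[draw][0]
            if candidates[draw] == head:
                n_head += 1
            f = frames[int(rng.integers(len(frames)))]
            sentences.append(f"{f[0]} {f[1]} {word} {f[2]} {f[3]} .")
        truth.headword_counts[head] = n_head
    for hi in range(spec.n_hapax_fillers):
        sentences.append(f"hapax{hi} .")

    order = rng.permutation(len(sentences))
    documents = [
        Document(doc_id=f"s{si:06d}", text=sentences[order[si]])
        for si in range(len(sentences))
    ]
    return SubstitutionCorpus(
        documents=documents,
        tagger=LexiconTagger(lexicon),
        thesaurus=thesaurus,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Graded ontology families
# ---------------------------------------------------------------------------


def generate_ontology_family(
    complete: CompleteOntology, size: int, seed: int = 0
) -> dict[str, Ontology]:
    """Same-size concept sub-ontologies of graded coverage.

    ``top`` takes the ``size`` most frequent concepts, ``bottom`` the least
    frequent, ``random`` a seeded uniform sample — so Depth orderings
    (top >= random >= bottom) are predictable from the ground truth.
    """
    ids = sorted(complete.concept_freq, key=lambda c: (-complete.concept_freq[c], c))
    if not 1 <= size <= len(ids):
        raise ValueError(f"size must be in [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    picks = {
        "top": ids[:size],
        "bottom": ids[-size:],
        "random": [ids[k] for k in sorted(rng.choice(len(ids), size=size, replace=False))],
    }
    family = {}
    for name, chosen in picks.items():
        onto = Ontology(name=name)
        for cid in sorted(chosen):
            onto.add_concept(Concept(id=cid, preferred_name=cid))
        for i, j in sorted(complete.pair_prob):
            if i in onto.concepts and j in onto.concepts:
                onto.add_relation(Relation(source=i, predicate="related-to", target=j))
        family[name] = onto
    return family
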