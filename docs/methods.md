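# Methods

This note records the statistical model behind `ontobench`, the parameter
choices that matter, what the synthetic fixtures do and do not emulate,
and the places where the design was genuinely open.

## Model

An ontology is scored against a corpus through two estimated parameter
families:

* **Concept frequencies** f_i: the share of all recognized concept
  mentions belonging to concept i, Σ_i f_i = 1. Mentions are found by
  longest-match dictionary lookup over lemmatized token spans within a
  sentence (ties to the leftmost span). This matcher is deliberately
  lightweight; a full concept-mapping engine with candidate scoring and
  word-sense disambiguation would slot in behind the same mention
  interface.
* **Relation probabilities** p_ij = n_ij / Σ_j′ n_ij′, where n_ij is the
  number of co-occurrence units containing both i and j. The unit defaults
  to the whole document (appropriate for abstract-sized documents) and can
  be switched to the sentence. Repeated mentions inside one unit count
  once — unit-level events are robust to mention-count inflation within a
  document. A concept never observed, or observed but never co-occurring,
  has p_ij = 0 for all j: its row simply carries no mass, which is exactly
  how such concepts are punished in Breadth²/Depth². n_ij is kept for both
  orders (n_ij = n_ji); rows are normalized per source concept, so p is
  generally asymmetric.

Breadth at level 1/2/3 sums f_i, f_i·p_ij, or f_i·p_ij·π_k|ij over the
ontology's members observed in the corpus; Depth divides by |C_X|, |ℜ_X|
(ordered pairs with ≥ 1 relation) or |R_X|. The level-2 denominator
deliberately ignores predicate multiplicity: an ontology cataloguing five
predicates for one pair is no "larger", at level 2, than one cataloguing
a single predicate. At level 3 the typed weights π_k|ij (relative textual
prevalence of each predicate between i and j, Σ_k π_k|ij = 1) resolve
individual predicates, and the |R_X| denominator makes predicate padding
dilutive. Typed weights are estimated from externally supplied
(source, predicate, target) mention counts; extracting typed relations
from raw text is out of scope.

The weighting f_i·p_ij at level 2 makes Breadth² a proper sub-probability:
Σ_i f_i Σ_j p_ij ≤ Σ_i f_i = 1, with equality when every observed concept
has co-occurrences and the ontology covers every observed pair. Both
breadth sums use compensated summation and are clamped at 1.0 against
float accumulation.

## Smoothing

The zero policy above makes p degenerate for unobserved concepts. The
optional smoothed estimator keeps every row a proper distribution by
adding a pseudo-concept sink ∅ (id `__NULL__`):

    p_ij = (n_ij + α) / D_i,    p_i∅ = E / D_i,
    D_i  = Σ_j n_ij + αN + E,   E = αN(1 − β)/β,

with N the number of candidate targets and 0 ≤ α < β < 1. The form is
fixed by its required limits rather than derived from a reference: rows
sum to one with the sink included; a fully unobserved row places mass
1 − β (≈ 1 for small β) on the sink with every real probability ≈ 0; a
well-observed row leaves only a sliver on the sink; and α = 0 recovers
the unsmoothed estimator exactly, with all mass on the sink for
unobserved rows. Defaults α = 0 (no smoothing) and β = 0.01.

## Substitution probabilities

For a thesaurus entry with headword w and synonyms s_1…s_M:

    p(s | w) = Σ_c P(c | w) · P(s | c)

* Contexts c are canonical keys over the k = 2 nearest content words
  (NOUN/VERB/ADJ/ADV) on each side of an occurrence, within the sentence,
  truncated at boundaries, order ignored. Candidate context words are the
  nearest *content* words, not the nearest tokens filtered afterwards —
  the reading that yields fuller windows from sparse prose.
* Words whose corpus-wide base-form frequency is ≤ 1 (`--rare-threshold`)
  are replaced inside windows by part-of-speech pseudo-words
  (`rare-noun`, …), densifying otherwise unique contexts.
* P(c | w) = n(w, c)/n(w); P(s | c) is s's share of context-c occurrences
  normalized over the candidate set {w} ∪ synonyms(w). The headword
  belongs to the candidate set: otherwise a single-synonym entry would
  score probability 1 whenever any context is shared. Consequently
  self-mass + Σ synonym masses = 1 for any headword with context support,
  a conservation law the tests enforce at 1e-9. Normalizing over the
  whole vocabulary instead is available behind a flag
  (`whole_vocabulary=True`) but breaks this conservation and is not the
  default. Candidates must match the headword's part of speech; cross-POS
  synonyms are dropped with a warning.
* Headwords absent from the corpus get all-zero rows (the level-1 zero
  policy carried over).

Cross-corpus comparison uses base-2 Jensen–Shannon divergence on the
candidate simplex (zero rows excluded): symmetric, finite on disjoint
support, equal to 1 there.

## Fittest ontology and loss

The complete ontology of a corpus is every observed concept with f_i and
every co-occurring ordered pair with p_ij. The fittest ontology of budget
k maximizes Depth subject to |selection| = k. Because Depth is
Σ(item masses)/k with non-negative masses and a fixed denominator, the
exact optimum is the top-k items by mass (f_i at level 1, f_i·p_ij at
level 2); ties break on identifier so selections are bit-for-bit
reproducible. Exhaustive subset enumeration on small instances confirms
optimality in the tests. The level-2 budget counts ordered pairs,
matching the Depth² denominator. The level-1 budget counts concepts;
whether a concept- or relation-count budget is the more faithful control
is left to the caller, and the loss identities are budget-agnostic
either way. Depth Loss, Relative Depth and Relative Depth Loss follow
from Depth_X and the fittest Depth; a test ontology deeper than the
same-size fittest one is an internal-consistency error, not a result.

## Tagging and lemmatization

No statistical tagger is bundled. The tagger contract is any callable
text → sentences of (surface, base form, coarse POS in {NOUN, VERB, ADJ,
ADV, OTHER}); unknown tags map to OTHER. Two implementations ship:

* `RuleTagger` — deterministic rule-based English tagging and
  lemmatization (closed-class word list, suffix heuristics, small
  irregular tables). It is approximate by construction; its role is
  dictionary matching and context building on plain prose, and its errors
  are systematic rather than random, so corpus comparisons remain
  meaningful.
* `LexiconTagger` — exact tagging from an explicit word → (lemma, POS)
  lexicon, used by the synthetic fixtures and appropriate for any
  controlled vocabulary.

Hyphenated items are kept as single tokens; multiword expressions are
handled at the matching layer, not the token layer.

## Synthetic fixtures

`simulate` plants the quantities the estimators are supposed to recover:

* Concept frequencies follow a Zipf law with exponent `zipf_s` (default
  1.0, the skew typical of terminology usage; 0 gives uniform).
* Co-occurrence structure is a symmetric non-negative joint matrix over
  concept pairs (seeded random by default, density 0.3); each *pair
  document* realizes exactly one pair drawn from it, so unit-level counts
  are unbiased draws and the true p is the row-normalized joint. *Mention
  documents* (default half the corpus, 1–3 mentions of a single concept)
  shape the frequency law without touching co-occurrence. The emitted
  ground truth is the exact expectation of each estimator under this
  mixture.
* Substitution corpora place one candidate (headword or synonym, drawn at
  the planted rates) into one of 8 shared four-content-word frames per
  sentence, so all candidates share context profiles and the conditional
  estimator's expectation equals the planted rate. One-word hapax
  sentences exercise rare binning and empty-context boundaries.
* Concept surfaces alternate between a preferred token and a synonym
  token (rate 0.3) to exercise alias resolution.

Fixed seed ⇒ byte-identical corpora (single integer-seeded PCG64
generator). What the fixtures do **not** emulate: English syntax,
polysemy, discontinuous or overlapping mentions, tagger noise, and
document-length heterogeneity. Passing recovery tests therefore
demonstrates estimator correctness under the stated sampling model, not
robustness to real-world text noise.

Recovery tests check each planted parameter against its estimate within
3 standard errors. For the relation-probability matrix this means
hundreds of simultaneous checks, where an unbiased estimator is
*expected* to produce the occasional ~3.2σ excursion; those tests
therefore allow the binomially expected number of >3σ excursions (mean +
3·√mean of Binomial(n, 0.0027), in practice 1–3) and cap all deviations
at 4.5σ. Small parameter sets (frequencies, substitution rates) are
checked strictly at 3σ.

## Numerical and edge-case choices

* Probability conservation tolerances: 1e-9 throughout.
* Empty corpus, empty ontology, zero-size denominators: errors, never
  silent zeros. Undefined precision/recall (zero denominator) is reported
  as `None`, never coerced to 0; F = 0 when P = R = 0.
* Duplicate relation triples collapse; relations with unknown endpoints
  are rejected at load time with the offending line named.
* Overlap analysis establishes concept identity by case-folded,
  lemmatized exact match over preferred names and synonyms, with
  union-find closure so shared aliases merge identities transitively — a
  deterministic stand-in for curated cross-terminology mappings. Relation
  overlap is directed by default; an undirected mode is provided since
  either convention is defensible for Venn comparisons.
* Budgets exceeding the available items clamp with a warning; fittest
  tie-breaks are lexicographic on identifier.

## Known limitations

* The dictionary matcher has no word-sense disambiguation; ambiguous
  surface forms resolve to the lexicographically smallest concept id.
* Co-occurrence is a crude proxy for asserted semantic relations;
  documents mentioning two concepts need not relate them.
* The rule lemmatizer over- and under-stems in predictable ways
  (suffix-rule artifacts); use a lexicon tagger when gold morphology is
  available.
* No level-3 fittest optimization is offered: with typed weights the
  objective is still additive, but the practically interesting budgets at
  that level (per-predicate catalogues) have no established convention.
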