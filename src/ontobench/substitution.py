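"""Synonym substitution probabilities from shared distributional contexts.

For a thesaurus headword ``w`` with synonyms ``s_1 .. s_M``, the
substitution probability of each synonym is obtained by conditioning on the
contexts in which the headword occurs:

    p(s | w) = sum_c  P(c | w) * P(s | c)

where ``P(c | w)`` is the share of the headword's occurrences carrying
context ``c``, and ``P(s | c)`` is how often ``s`` (as opposed to the other
candidates) appears with that context, normalized over the candidate set
``{w} ∪ synonyms(w)``.  The headword itself belongs to the candidate set,
so for any headword with context support the self-mass plus all synonym
masses sum to 1.  Headwords absent from the corpus get all-zero rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ontobench.corpus import ContextIndex, POS_TAGS

logger = logging.getLogger(__name__)

__all__ = [
    "ThesaurusEntry", "SubstitutionTable", "load_thesaurus", "save_table",
    "substitution_probs", "rank_synonyms", "compare_corpora",
    "js_divergence",
]

Word = tuple[str, str]  # (base_form, pos)


@dataclass(frozen=True)
class ThesaurusEntry:
    """A headword and its substitutable synonyms, all POS-typed."""

    headword: Word
    synonyms: tuple[Word, ...]

    def __post_init__(self) -> None:
        if self.headword in self.synonyms:
            raise ValueError(f"headword {self.headword} listed among its own synonyms")


@dataclass
class SubstitutionTable:
    """Per-headword substitution probabilities over its synonym list."""

    probs: dict[tuple[Word, Word], float] = field(default_factory=dict)
    self_mass: dict[Word, float] = field(default_factory=dict)
    headword_counts: dict[Word, int] = field(default_factory=dict)
    label: str = ""

    def row(self, headword: Word) -> dict[Word, float]:
        return {
            syn: p for (h, syn), p in self.probs.items() if h == headword
        }

    def headwords(self) -> list[Word]:
        return sorted(self.headword_counts)


def load_thesaurus(path: str | Path) -> list[ThesaurusEntry]:
    """Read a TSV thesaurus: headword, pos, pipe-separated synonyms.

    All synonyms inherit the headword's POS (the interchange format is
    single-POS per row; cross-POS synonymy is expressed as separate rows).
    """
    entries: list[ThesaurusEntry] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["headword", "pos"]:
            raise ValueError(f"{path}: expected columns headword, pos, synonyms")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            head, pos, syn_cell = cells[0], cells[1], cells[2]
            if pos not in POS_TAGS:
                raise ValueError(f"{path}:{lineno}: unknown pos {pos!r}")
            synonyms = tuple((s, pos) for s in syn_cell.split("|") if s)
            entries.append(ThesaurusEntry(headword=(head, pos), synonyms=synonyms))
    return entries


def save_table(table: SubstitutionTable, path: str | Path) -> None:
    """Write a substitution table as TSV: headword, pos, synonym, probability,
    headword_count (self-mass rows use the headword as its own synonym)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("headword\tpos\tsynonym\tprobability\theadword_count\n")
        for head in table.headwords():
            count = table.headword_counts.get(head, 0)
            rows = [(head[0], table.self_mass.get(head, 0.0))]
            rows += sorted((s[0], p) for s, p in table.row(head).items())
            for syn, p in rows:
                fh.write(f"{head[0]}\t{head[1]}\t{syn}\t{p:.17g}\t{count}\n")


def substitution_probs(
    contexts: ContextIndex,
    thesaurus: Iterable[ThesaurusEntry],
    whole_vocabulary: bool = False,
) -> SubstitutionTable:
    """Estimate substitution probabilities for every thesaurus entry.

    ``whole_vocabulary=True`` normalizes ``P(s | c)`` over every word seen
    with context ``c`` instead of the entry's candidate set (exposed as an
    alternative reading; the candidate-set default is what the package's
    conservation properties assume).
    """
    table = SubstitutionTable()
    for entry in thesaurus:
        head = entry.headword
        candidates = [head]
        for syn in entry.synonyms:
            if syn[1] != head[1]:
                logger.warning(
                    "dropping cross-POS synonym %r of headword %r", syn, head
                )
                continue
            candidates.append(syn)
        if len(candidates) == 1:
            logger.warning("thesaurus entry %r has no usable synonyms; skipped", head)
            continue
        head_contexts = contexts.word_context_counts.get(head)
        n_head = sum(head_contexts.values()) if head_contexts else 0
        table.headword_counts[head] = contexts.word_counts.get(head, 0)
        if not n_head:
            for syn in candidates[1:]:
                table.probs[(head, syn)] = 0.0
            table.self_mass[head] = 0.0
            continue
        masses = {cand: 0.0 for cand in candidates}
        for ckey, n_wc in head_contexts.items():
            p_c_given_w = n_wc / n_head
            words_in_c = contexts.context_word_counts[ckey]
            if whole_vocabulary:
                denom = sum(words_in_c.values())
            else:
                denom = sum(words_in_c.get(cand, 0) for cand in candidates)
            if denom == 0:
                continue
            for cand in candidates:
                masses[cand] += p_c_given_w * words_in_c.get(cand, 0) / denom
        table.self_mass[head] = masses[head]
        for syn in candidates[1:]:
            table.probs[(head, syn)] = masses[syn]
    return table


def rank_synonyms(table: SubstitutionTable, headword: Word) -> list[Word]:
    """Synonyms of ``headword`` in descending probability, zero rows empty,
    ties broken lexicographically."""
    if headword not in table.headword_counts:
        raise KeyError(f"headword {headword!r} not in table")
    row = table.row(headword)
    ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return [syn for syn, p in ranked if p > 0.0]


# ---------------------------------------------------------------------------
# Cross-corpus comparison
# ---------------------------------------------------------------------------


def _entropy2(dist: Sequence[float]) -> float:
    return -sum(p * math.log2(p) for p in dist if p > 0.0)


def js_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Base-2 Jensen–Shannon divergence of two distributions on the same
    support (in [0, 1]; 1 for disjoint support)."""
    m = [(a + b) / 2.0 for a, b in zip(p, q)]
    return _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2.0


def compare_corpora(
    tables: Mapping[str, SubstitutionTable],
) -> list[tuple[Word, float]]:
    """Rank headwords by how unlike their substitution behavior is across
    corpora.

    For each headword present with nonzero mass in >= 2 tables, the
    distributions over the candidate simplex (self-mass + synonyms) are
    compared pairwise by base-2 Jensen–Shannon divergence; all-zero rows
    are excluded from the comparison.  Returns (headword, mean pairwise
    divergence) sorted most-divergent first; headwords supported nowhere
    are omitted.
    """
    if len(tables) < 2:
        raise ValueError("compare_corpora needs at least two tables")
    heads: set[Word] = set()
    for table in tables.values():
        heads.update(table.headword_counts)
    results: list[tuple[Word, float]] = []
    for head in sorted(heads):
        dists = []
        for table in tables.values():
            if head not in table.headword_counts:
                continue
            row = table.row(head)
            support = sorted(row)
            vec = [table.self_mass.get(head, 0.0)] + [row[s] for s in support]
            total = sum(vec)
            if total <= 0.0:
                continue
            dists.append((support, [v / total for v in vec]))
        if len(dists) < 2:
            continue
        # align supports pairwise (tables may list different synonyms)
        divs = []
        for (sup_a, vec_a), (sup_b, vec_b) in combinations(dists, 2):
            union = sorted(set(sup_a) | set(sup_b))
            a_map = dict(zip(sup_a, vec_a[1:]))
            b_map = dict(zip(sup_b, vec_b[1:]))
            pa = [vec_a[0]] + [a_map.get(s, 0.0) for s in union]
            pb = [vec_b[0]] + [b_map.get(s, 0.0) for s in union]
            divs.append(js_divergence(pa, pb))
        results.append((head, sum(divs) / len(divs)))
    results.sort(key=lambda kv: (-kv[1], kv[0]))
    return results
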