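"""Corpus ingestion, tagging/lemmatization and context-window construction.

The co-occurrence and substitution estimators downstream need, for every
content word in a corpus, a small unordered context: up to ``k`` content
words (nouns, verbs, adjectives, adverbs) on each side within the same
sentence, with corpus-unique words binned into part-of-speech pseudo-words
(``rare-noun``, ``rare-verb``, ...) so that sparse contexts can still be
compared.  Tagging and lemmatization are a pluggable contract: any callable
that maps raw text to sentences of (surface, base_form, pos) triples works;
a rule-based English tagger ships as the default and a dictionary-backed
``LexiconTagger`` serves controlled/synthetic corpora.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Token", "Document", "ContextWindow", "ContextIndex", "CorpusFormatError",
    "read_corpus", "analyze", "build_contexts", "RuleTagger", "LexiconTagger",
    "default_normalize", "CONTENT_POS", "rare_pseudo_word",
]

CONTENT_POS = ("NOUN", "VERB", "ADJ", "ADV")
POS_TAGS = CONTENT_POS + ("OTHER",)

_RARE = {
    "NOUN": "rare-noun",
    "VERB": "rare-verb",
    "ADJ": "rare-adjective",
    "ADV": "rare-adverb",
}


def rare_pseudo_word(pos: str) -> str:
    """The pseudo-word replacing corpus-unique words of part of speech ``pos``."""
    return _RARE[pos]


class CorpusFormatError(ValueError):
    """Raised when a corpus file cannot be parsed."""


@dataclass(frozen=True)
class Token:
    surface: str
    base_form: str
    pos: str  # NOUN | VERB | ADJ | ADV | OTHER

    def __post_init__(self) -> None:
        if not self.base_form:
            raise ValueError("token with empty base_form")
        if self.pos not in POS_TAGS:
            object.__setattr__(self, "pos", "OTHER")


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[list[Token]] | None = None

    @property
    def analyzed(self) -> bool:
        return self.sentences is not None


# ---------------------------------------------------------------------------
# Corpus readers
# ---------------------------------------------------------------------------


def read_corpus(path: str | Path, format: str | None = None) -> list[Document]:
    """Read a corpus: a directory of UTF-8 ``.txt`` files (one document per
    file, doc_id = file stem) or a JSON-lines file of ``{"doc_id", "text"}``
    records.  Empty documents are dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("textdir" if path.is_dir() else "jsonl")
    if fmt == "textdir":
        docs = [
            Document(doc_id=p.stem, text=p.read_text(encoding="utf-8"))
            for p in sorted(path.glob("*.txt"))
        ]
    elif fmt == "jsonl":
        docs = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc.msg}") from exc
                if "doc_id" not in record or "text" not in record:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: record needs doc_id and text"
                    )
                docs.append(Document(doc_id=str(record["doc_id"]), text=record["text"]))
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")

    seen: set[str] = set()
    kept: list[Document] = []
    for doc in docs:
        if doc.doc_id in seen:
            raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        if not doc.text.strip():
            logger.warning("dropping empty document %r", doc.doc_id)
            continue
        kept.append(doc)
    return kept


# ---------------------------------------------------------------------------
# Tagger contract + implementations
# ---------------------------------------------------------------------------

Tagger = Callable[[str], list[list[tuple[str, str, str]]]]

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[A-Za-z][A-Za-z0-9'\-]*|\d+")

# Closed-class words tagged OTHER by the rule tagger.
_FUNCTION_WORDS = frozenset(
    """a an the and or but nor so yet of in on at by for with to from into onto
    over under about as if than then that this these those it its he she they
    them his her their we you i me my your our us is are was were be been being
    am do does did done have has had having will would shall should can could
    may might must not no nor there here when where while which who whom whose
    what why how because although though unless until before after between
    during through up down out off again once very too also just only both each
    few more most other some such own same s t don now against all any""".split()
)

_IRREGULAR_NOUNS = {
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "people": "person", "geese": "goose",
}
_IRREGULAR_VERBS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "am": "be", "been": "be",
    "has": "have", "had": "have", "did": "do", "done": "do", "went": "go",
    "gone": "go", "ran": "run", "saw": "see", "seen": "see", "slept": "sleep",
    "took": "take", "taken": "take", "gave": "give", "given": "give",
    "made": "make", "said": "say", "found": "find", "came": "come",
    "got": "get", "knew": "know", "known": "know", "wrote": "write",
    "written": "write", "ate": "eat", "eaten": "eat", "drew": "draw",
    "drawn": "draw", "felt": "feel", "kept": "keep", "left": "leave",
    "told": "tell", "thought": "think", "brought": "bring",
}
_ADV_EXCEPTIONS = frozenset({"family", "only", "early", "likely"})
_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ic", "ish", "less", "ant", "ent")

# Small open-class lexicons: words the suffix rules would otherwise mistag.
_COMMON_VERBS = frozenset(
    """sleep run eat walk talk speak see go make take give know think feel
    come find get keep leave tell bring write draw open spread extend widen
    sprawl stretch develop increase prolong enlarge degrade impair demean
    depress grow treat cause affect occur improve reduce use show need want
    help work play live move turn start stop begin end read call ask answer
    believe remember appear remain happen""".split()
)
_COMMON_ADJECTIVES = frozenset(
    """big red small large good bad new old young high low long short great
    little own other futile vain chronic viral acute severe mild common rare
    frequent clinical medical black white blue green strong weak full empty
    deep wide narrow hot cold warm dark light""".split()
)
_COMMON_ADVERBS = frozenset(
    """fast well never always often soon here there today yesterday tomorrow
    beforehand almost perhaps maybe together away back forward still already
    yet""".split()
)


def _strip_es(word: str) -> str:
    # "churches" -> "church" but "headaches" -> "headache": keep the final
    # e when a vowel precedes the ch/sh cluster (approximate, like all
    # suffix rules here)
    if word.endswith(("ches", "shes")) and word[-5] in "aeiou":
        return word[:-1]
    return word[:-2]


def _lemmatize_noun(word: str) -> str:
    if word in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "sses", "xes", "zes")):
        return _strip_es(word)
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    return word


def _lemmatize_verb(word: str) -> str:
    if word in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "sses", "xes", "zes")):
        return _strip_es(word)
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    if word.endswith("ying") and len(word) > 5:
        return word[:-4] + "y"
    if word.endswith("ing") and len(word) > 5:
        stem = word[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        elif stem.endswith(("at", "iv", "os", "ut", "ir")):
            stem += "e"
        return stem
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ed") and len(word) > 4:
        stem = word[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        elif stem.endswith(("at", "iv", "os", "ut", "ir")):
            stem += "e"
        return stem
    return word


class RuleTagger:
    """Deterministic rule-based English sentence splitter / tagger / lemmatizer.

    Coarse and intentionally simple: closed-class words are OTHER, ``-ly``
    words are adverbs, a fixed suffix list marks adjectives, ``-ing``/``-ed``
    forms are verbs, everything else is a noun.  It is the replaceable
    default behind the tagger contract, adequate for dictionary matching and
    context building on plain prose.
    """

    def __call__(self, text: str) -> list[list[tuple[str, str, str]]]:
        sentences = []
        for raw in _SENT_SPLIT.split(text):
            tokens = []
            for match in _TOKEN.finditer(raw):
                surface = match.group(0)
                word = surface.lower()
                pos, base = self.tag_word(word)
                tokens.append((surface, base, pos))
            if tokens:
                sentences.append(tokens)
        return sentences

    @staticmethod
    def tag_word(word: str) -> tuple[str, str]:
        if word in _FUNCTION_WORDS or word.isdigit():
            return "OTHER", word
        if word in _IRREGULAR_VERBS:
            return "VERB", _IRREGULAR_VERBS[word]
        if word in _COMMON_ADVERBS:
            return "ADV", word
        if word in _COMMON_ADJECTIVES:
            return "ADJ", word
        if word in _COMMON_VERBS or _lemmatize_verb(word) in _COMMON_VERBS:
            return "VERB", _lemmatize_verb(word)
        if word.endswith("ly") and word not in _ADV_EXCEPTIONS and len(word) > 3:
            return "ADV", word
        if word.endswith(_ADJ_SUFFIXES) and len(word) > 4:
            return "ADJ", word
        if word.endswith(("ing", "ed")) and len(word) > 4:
            return "VERB", _lemmatize_verb(word)
        return "NOUN", _lemmatize_noun(word)

    def lemma(self, word: str) -> str:
        return self.tag_word(word.lower())[1]


class LexiconTagger:
    """Tagger backed by an explicit word -> (base_form, pos) lexicon.

    Used for synthetic corpora where gold lemmas/tags are known, and for
    any corpus with a controlled vocabulary.  Unknown words fall back to a
    default POS with identity lemma.
    """

    def __init__(
        self,
        lexicon: Mapping[str, tuple[str, str]],
        default_pos: str = "OTHER",
    ) -> None:
        self.lexicon = {w.lower(): (b, p) for w, (b, p) in lexicon.items()}
        self.default_pos = default_pos

    def __call__(self, text: str) -> list[list[tuple[str, str, str]]]:
        sentences = []
        for raw in _SENT_SPLIT.split(text):
            tokens = []
            for match in _TOKEN.finditer(raw):
                surface = match.group(0)
                base, pos = self.lexicon.get(
                    surface.lower(), (surface.lower(), self.default_pos)
                )
                tokens.append((surface, base, pos))
            if tokens:
                sentences.append(tokens)
        return sentences

    def lemma(self, word: str) -> str:
        return self.lexicon.get(word.lower(), (word.lower(), None))[0]


_DEFAULT_TAGGER = RuleTagger()


def default_normalize(text: str) -> str:
    """Case-fold and lemmatize a (possibly multiword) name to a canonical key."""
    words = [m.group(0).lower() for m in _TOKEN.finditer(text)]
    return " ".join(_DEFAULT_TAGGER.lemma(w) for w in words)


def analyze(doc: Document, tagger: Tagger | None = None) -> Document:
    """Run ``tagger`` over ``doc.text``; returns the document with sentences
    of :class:`Token`.  Unknown tags map to OTHER, empty sentences drop."""
    tagger = tagger or _DEFAULT_TAGGER
    try:
        raw_sentences = tagger(doc.text)
    except Exception as exc:  # pragma: no cover - contract failure path
        raise RuntimeError(f"tagger failed on document {doc.doc_id!r}: {exc}") from exc
    doc.sentences = [
        [Token(surface=s, base_form=b, pos=p) for (s, b, p) in sent]
        for sent in raw_sentences
        if sent
    ]
    return doc


# ---------------------------------------------------------------------------
# Context windows
# ---------------------------------------------------------------------------

_KEY_SEP = "\x1f"


@dataclass(frozen=True)
class ContextWindow:
    """Unordered multiset of up to 2k (base_form, pos) content-word items."""

    k: int
    items: tuple[tuple[str, str], ...]

    @property
    def key(self) -> str:
        """Canonical order-invariant context key (bit-stable across runs)."""
        return _KEY_SEP.join(f"{b}/{p}" for b, p in sorted(self.items))


@dataclass
class Occurrence:
    doc_id: str
    sentence_index: int
    token_index: int
    word: tuple[str, str]  # (base_form, pos)
    window: ContextWindow


class ContextIndex:
    """Aggregated context statistics for a corpus.

    ``word_context_counts[(base, pos)][key]`` — windows of that word with
    that canonical context; ``context_word_counts[key][(base, pos)]`` — how
    often each word appeared with that context; ``word_counts`` — total
    windows per word (= content-word occurrence count).
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self.word_context_counts: dict[tuple[str, str], Counter] = {}
        self.context_word_counts: dict[str, Counter] = {}
        self.word_counts: Counter = Counter()
        self.occurrences: list[Occurrence] = []

    def add(self, occ: Occurrence) -> None:
        key = occ.window.key
        self.word_context_counts.setdefault(occ.word, Counter())[key] += 1
        self.context_word_counts.setdefault(key, Counter())[occ.word] += 1
        self.word_counts[occ.word] += 1
        self.occurrences.append(occ)


def build_contexts(
    corpus: Iterable[Document],
    k: int = 2,
    rare_threshold: int = 1,
    keep_occurrences: bool = True,
) -> ContextIndex:
    """Build the context index over analyzed documents.

    For every content-word occurrence, the window holds the ``k`` nearest
    content words on each side within the sentence (truncated at sentence
    boundaries, never padded).  Words whose corpus-wide base-form frequency
    is <= ``rare_threshold`` are replaced inside windows by their
    part-of-speech pseudo-word.  Rare binning depends only on corpus-wide
    counts, so rebuilding on the same corpus is deterministic.
    """
    docs = list(corpus)
    for doc in docs:
        if not doc.analyzed:
            raise ValueError(f"document {doc.doc_id!r} not analyzed")

    base_counts: Counter = Counter()
    for doc in docs:
        for sent in doc.sentences:
            for tok in sent:
                base_counts[tok.base_form] += 1

    def window_item(tok: Token) -> tuple[str, str]:
        if base_counts[tok.base_form] <= rare_threshold:
            return (rare_pseudo_word(tok.pos), tok.pos)
        return (tok.base_form, tok.pos)

    index = ContextIndex(k=k)
    for doc in docs:
        for s_idx, sent in enumerate(doc.sentences):
            content = [
                (t_idx, tok) for t_idx, tok in enumerate(sent) if tok.pos in CONTENT_POS
            ]
            for c_idx, (t_idx, tok) in enumerate(content):
                before = content[max(0, c_idx - k) : c_idx]
                after = content[c_idx + 1 : c_idx + 1 + k]
                items = tuple(window_item(t) for _, t in before + after)
                occ = Occurrence(
                    doc_id=doc.doc_id,
                    sentence_index=s_idx,
                    token_index=t_idx,
                    word=(tok.base_form, tok.pos),
                    window=ContextWindow(k=k, items=items),
                )
                index.add(occ)
    if not keep_occurrences:
        index.occurrences = []
    return index
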