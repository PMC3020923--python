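"""Ontologies as concept + relation tables, with I/O and overlap analysis.

An ontology here is the lightweight structure common to controlled medical
terminologies and thesauri: a set of named concepts (each with aliases and
an optional semantic type) and a set of directed, predicate-labelled
relations between them.  Two relation counts matter throughout the package:
``|R_X|``, the number of relation triples, and the number of ordered
(source, target) pairs carrying at least one relation — equal for
predicate-poor ontologies, ``|R_X|`` larger for predicate-rich ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Concept", "Relation", "Ontology", "OntologyFormatError",
    "OntologyIntegrityError", "load_ontology", "save_ontology", "pair_set",
    "NameMatcher", "concept_overlap", "relation_overlap",
]

DEFAULT_PREDICATE = "related-to"


class OntologyFormatError(ValueError):
    """Raised when an ontology file cannot be parsed."""


class OntologyIntegrityError(ValueError):
    """Raised when ontology invariants are violated (e.g. dangling relation)."""


@dataclass(frozen=True)
class Concept:
    """A named entity of the ontology with its textual aliases."""

    id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    semantic_type: str | None = None

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise OntologyIntegrityError(f"concept {self.id!r}: empty preferred_name")
        # dedupe synonyms case-insensitively, preserving first spelling
        seen: dict[str, str] = {}
        for s in self.synonyms:
            seen.setdefault(s.casefold(), s)
        object.__setattr__(self, "synonyms", tuple(seen.values()))

    def names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


@dataclass(frozen=True)
class Relation:
    """A directed, typed link between two concepts (by id)."""

    source: str
    predicate: str
    target: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


class Ontology:
    """A set of :class:`Concept` plus a set of :class:`Relation`.

    Duplicate (source, predicate, target) triples collapse; relations whose
    endpoints are unknown are rejected at insertion time.
    """

    def __init__(
        self,
        name: str = "",
        concepts: Iterable[Concept] = (),
        relations: Iterable[Relation] = (),
    ) -> None:
        self.name = name
        self._concepts: dict[str, Concept] = {}
        self._relations: set[Relation] = set()
        for c in concepts:
            self.add_concept(c)
        for r in relations:
            self.add_relation(r)

    # -- construction ----------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.id in self._concepts:
            raise OntologyIntegrityError(f"duplicate concept id {concept.id!r}")
        self._concepts[concept.id] = concept

    def add_relation(self, relation: Relation) -> None:
        for endpoint in (relation.source, relation.target):
            if endpoint not in self._concepts:
                raise OntologyIntegrityError(
                    f"relation {relation} references unknown concept {endpoint!r}"
                )
        self._relations.add(relation)

    # -- access ----------------------------------------------------------

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._concepts

    @property
    def relations(self) -> frozenset[Relation]:
        return frozenset(self._relations)

    def __len__(self) -> int:
        return len(self._concepts)

    @property
    def n_concepts(self) -> int:
        return len(self._concepts)

    @property
    def n_relations(self) -> int:
        """|R_X|: total relation triples."""
        return len(self._relations)

    @property
    def n_pairs(self) -> int:
        """Number of ordered pairs with >= 1 relation."""
        return len(self.pair_set())

    def pair_set(self) -> frozenset[tuple[str, str]]:
        """Ordered (source, target) pairs having at least one relation."""
        return frozenset(r.pair for r in self._relations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.name == other.name
            and self._concepts == other._concepts
            and self._relations == other._relations
        )

    def __repr__(self) -> str:
        return (
            f"Ontology(name={self.name!r}, |C|={self.n_concepts}, "
            f"|R|={self.n_relations}, |pairs|={self.n_pairs})"
        )


def pair_set(ontology: Ontology) -> frozenset[tuple[str, str]]:
    """Ordered concept-id pairs of ``ontology`` with at least one relation."""
    return ontology.pair_set()


# ---------------------------------------------------------------------------
# I/O: TSV directory, JSON mirror, OBO 1.2 flat file (read-only)
# ---------------------------------------------------------------------------

_CONCEPT_COLUMNS = ["id", "preferred_name", "synonyms", "semantic_type"]
_RELATION_COLUMNS = ["source_id", "predicate", "target_id"]


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tsv"
    if path.suffix == ".json":
        return "json"
    if path.suffix == ".obo":
        return "obo"
    raise OntologyFormatError(f"cannot infer ontology format from {path}")


def load_ontology(path: str | Path, format: str | None = None) -> Ontology:
    """Load an ontology from ``path``.

    Formats: ``tsv`` (a directory holding ``concepts.tsv`` + ``relations.tsv``),
    ``json`` (one object mirroring the TSV schema) and ``obo`` (OBO 1.2 flat
    file; ``is_a`` and ``relationship:`` lines become relations, obsolete
    terms are skipped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _load_tsv(path)
    if fmt == "json":
        return _load_json(path)
    if fmt == "obo":
        return _load_obo(path)
    raise OntologyFormatError(f"unknown ontology format {fmt!r}")


def _split_synonyms(cell: str) -> tuple[str, ...]:
    return tuple(s for s in cell.split("|") if s) if cell else ()


def _load_tsv(directory: Path) -> Ontology:
    cpath = directory / "concepts.tsv"
    rpath = directory / "relations.tsv"
    onto = Ontology(name=directory.name)
    for lineno, row in _read_tsv(cpath, _CONCEPT_COLUMNS):
        try:
            onto.add_concept(
                Concept(
                    id=row["id"],
                    preferred_name=row["preferred_name"],
                    synonyms=_split_synonyms(row.get("synonyms", "")),
                    semantic_type=row.get("semantic_type") or None,
                )
            )
        except OntologyIntegrityError as exc:
            raise OntologyIntegrityError(f"{cpath}:{lineno}: {exc}") from exc
    if rpath.exists():
        for lineno, row in _read_tsv(rpath, _RELATION_COLUMNS):
            try:
                onto.add_relation(
                    Relation(
                        source=row["source_id"],
                        predicate=row.get("predicate") or DEFAULT_PREDICATE,
                        target=row["target_id"],
                    )
                )
            except OntologyIntegrityError as exc:
                raise OntologyIntegrityError(f"{rpath}:{lineno}: {exc}") from exc
    return onto


def _read_tsv(path: Path, required: Sequence[str]):
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in required[:2] if c not in header]
        if missing:
            raise OntologyFormatError(f"{path}:1: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) > len(header):
                raise OntologyFormatError(
                    f"{path}:{lineno}: {len(cells)} fields for {len(header)} columns"
                )
            cells += [""] * (len(header) - len(cells))
            yield lineno, dict(zip(header, cells))


def _load_json(path: Path) -> Ontology:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise OntologyFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    onto = Ontology(name=payload.get("name", path.stem))
    for entry in payload.get("concepts", []):
        onto.add_concept(
            Concept(
                id=entry["id"],
                preferred_name=entry["preferred_name"],
                synonyms=tuple(entry.get("synonyms", ())),
                semantic_type=entry.get("semantic_type"),
            )
        )
    for entry in payload.get("relations", []):
        onto.add_relation(
            Relation(
                source=entry["source_id"],
                predicate=entry.get("predicate", DEFAULT_PREDICATE),
                target=entry["target_id"],
            )
        )
    return onto


def _load_obo(path: Path) -> Ontology:
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    onto = Ontology(name=graph.graph.get("ontology", path.stem))
    for node, data in graph.nodes(data=True):
        synonyms = []
        for syn in data.get("synonym", ()):
            # OBO synonym lines look like: "text" SCOPE [xrefs]
            if syn.startswith('"') and '"' in syn[1:]:
                synonyms.append(syn[1 : syn.index('"', 1)])
        onto.add_concept(
            Concept(
                id=node,
                preferred_name=data.get("name", node),
                synonyms=tuple(synonyms),
                semantic_type=data.get("namespace"),
            )
        )
    # obonet stores edges child -> parent keyed by predicate
    for source, target, predicate in graph.edges(keys=True):
        onto.add_relation(Relation(source=source, predicate=predicate, target=target))
    return onto


def save_ontology(ontology: Ontology, path: str | Path, format: str = "tsv") -> None:
    """Write ``ontology`` in canonical order (ids sorted) for stable round-trips."""
    path = Path(path)
    concepts = sorted(ontology.concepts.values(), key=lambda c: c.id)
    relations = sorted(
        ontology.relations, key=lambda r: (r.source, r.predicate, r.target)
    )
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "concepts.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(_CONCEPT_COLUMNS) + "\n")
            for c in concepts:
                fh.write(
                    "\t".join(
                        [c.id, c.preferred_name, "|".join(c.synonyms), c.semantic_type or ""]
                    )
                    + "\n"
                )
        with open(path / "relations.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(_RELATION_COLUMNS) + "\n")
            for r in relations:
                fh.write("\t".join([r.source, r.predicate, r.target]) + "\n")
    elif format == "json":
        payload = {
            "name": ontology.name,
            "concepts": [
                {
                    "id": c.id,
                    "preferred_name": c.preferred_name,
                    "synonyms": list(c.synonyms),
                    "semantic_type": c.semantic_type,
                }
                for c in concepts
            ],
            "relations": [
                {"source_id": r.source, "predicate": r.predicate, "target_id": r.target}
                for r in relations
            ],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise OntologyFormatError(f"cannot save format {format!r}")


# ---------------------------------------------------------------------------
# Cross-ontology identity and overlap (Venn-style region counts)
# ---------------------------------------------------------------------------


class NameMatcher:
    """Establishes concept identity across ontologies by normalized names.

    Two concepts are the same entity iff any of their case-folded,
    lemmatized names (preferred name or synonym) coincide.  This is a
    deterministic stand-in for curated cross-terminology mappings.
    """

    def __init__(self, normalize: Callable[[str], str] | None = None) -> None:
        if normalize is None:
            from ontobench.corpus import default_normalize

            normalize = default_normalize
        self.normalize = normalize

    def keys(self, concept: Concept) -> frozenset[str]:
        return frozenset(self.normalize(n) for n in concept.names())


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[object, object] = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_concepts(
    ontologies: Sequence[Ontology], matcher: NameMatcher
) -> list[dict[str, object]]:
    """Map each ontology's concept ids to cross-ontology cluster labels."""
    uf = _UnionFind()
    per_onto: list[dict[str, frozenset[str]]] = []
    for idx, onto in enumerate(ontologies):
        keymap = {}
        for cid, concept in onto.concepts.items():
            node = (idx, cid)
            keys = matcher.keys(concept)
            keymap[cid] = keys
            uf.find(node)
            for key in keys:
                uf.union(("key", key), node)
        per_onto.append(keymap)
    return [
        {cid: uf.find((idx, cid)) for cid in onto.concepts}
        for idx, onto in enumerate(ontologies)
    ]


def _region_counts(sets: Sequence[set]) -> dict[tuple[str, ...], int]:
    names = [f"S{i}" for i in range(len(sets))]
    universe = set().union(*sets) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for element in universe:
        members = tuple(n for n, s in zip(names, sets) if element in s)
        regions[members] = regions.get(members, 0) + 1
    return regions


def _label_regions(
    regions: dict[tuple[str, ...], int], labels: Sequence[str]
) -> dict[tuple[str, ...], int]:
    mapping = {f"S{i}": lab for i, lab in enumerate(labels)}
    return {
        tuple(mapping[m] for m in members): count for members, count in regions.items()
    }


def concept_overlap(
    ontologies: Sequence[Ontology], matcher: NameMatcher | None = None
) -> dict[tuple[str, ...], int]:
    """Venn region counts of shared concepts across 2 or 3 ontologies.

    Returns a mapping from the tuple of ontology names forming a region
    (e.g. ``("A",)`` for A-only, ``("A", "B")`` for the A∩B-only region) to
    the number of distinct concept identities in that region.  Counts
    partition the union exactly.
    """
    if not 2 <= len(ontologies) <= 3:
        raise ValueError("concept_overlap expects 2 or 3 ontologies")
    matcher = matcher or NameMatcher()
    clusters = _cluster_concepts(ontologies, matcher)
    sets = [set(c.values()) for c in clusters]
    labels = [o.name or f"ontology{i}" for i, o in enumerate(ontologies)]
    return _label_regions(_region_counts(sets), labels)


def relation_overlap(
    ontologies: Sequence[Ontology],
    matcher: NameMatcher | None = None,
    directed: bool = True,
) -> dict[tuple[str, ...], int]:
    """Venn region counts over ordered concept pairs carrying a relation.

    Pairs are mapped through the cross-ontology concept identity first.
    With ``directed=False`` the pair (a, b) is identified with (b, a).
    """
    if not 2 <= len(ontologies) <= 3:
        raise ValueError("relation_overlap expects 2 or 3 ontologies")
    matcher = matcher or NameMatcher()
    clusters = _cluster_concepts(ontologies, matcher)
    sets = []
    for onto, cluster in zip(ontologies, clusters):
        pairs = set()
        for s, t in onto.pair_set():
            key = (cluster[s], cluster[t])
            if not directed:
                key = tuple(sorted(key, key=repr))
            pairs.add(key)
        sets.append(pairs)
    labels = [o.name or f"ontology{i}" for i, o in enumerate(ontologies)]
    return _label_regions(_region_counts(sets), labels)
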