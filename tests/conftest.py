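import pytest

from ontobench.ontology import Concept, Ontology, Relation


def make_ontology(name="X", concepts=(), relations=()):
    """Build an ontology from plain ids and (source, predicate, target) triples."""
    onto = Ontology(name=name)
    for cid in concepts:
        onto.add_concept(Concept(id=cid, preferred_name=cid))
    for src, pred, tgt in relations:
        onto.add_relation(Relation(source=src, predicate=pred, target=tgt))
    return onto


@pytest.fixture
def abc_ontology():
    return make_ontology(
        "abc",
        concepts=["a", "b", "c"],
        relations=[("a", "is-a", "b"), ("a", "part-of", "b"), ("b", "is-a", "c")],
    )
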