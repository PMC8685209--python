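import random

import numpy as np
import pytest

from ppsim.corpus import AnnotationRecord, ProfileSet, Stratum
from ppsim.ontology import Ontology


def make_ontology(edges, extra_terms=()):
    """Build an Ontology from (child, parent) tuples."""
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    for t in extra_terms:
        parents.setdefault(t, set())
    return Ontology({t: frozenset(ps) for t, ps in parents.items()})


def random_dag(rng: random.Random, n_terms: int, max_parents: int = 2):
    """Random rooted DAG: term i attaches to 1..max_parents earlier terms."""
    names = [f"N{i:03d}" for i in range(n_terms)]
    parents = {names[0]: frozenset()}
    for i in range(1, n_terms):
        k = rng.randint(1, min(max_parents, i))
        parents[names[i]] = frozenset(rng.sample(names[:i], k))
    return Ontology(parents)


def random_profiles(rng: random.Random, ont: Ontology, n_profiles: int, max_terms: int = 5):
    terms = sorted(ont.terms)
    return [
        set(rng.sample(terms, rng.randint(1, min(max_terms, len(terms)))))
        for _ in range(n_profiles)
    ]


def profile_set(profiles, diagnoses, stratum=Stratum.ALL, kept=None):
    """Assemble a ProfileSet directly, for tests that bypass annotation tables."""
    if kept is None:
        kept = sum(len(p) for p in profiles.values())
    return ProfileSet(
        profiles={v: frozenset(ts) for v, ts in profiles.items()},
        diagnosis=dict(diagnoses),
        stratum=stratum,
        kept_annotation_count=kept,
    )


@pytest.fixture
def chain_ont():
    # C -> B -> A, root A
    return make_ontology([("C", "B"), ("B", "A")])


@pytest.fixture
def diamond_ont():
    # D -> {B, C}, B -> A, C -> A
    return make_ontology([("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")])


@pytest.fixture
def seven_term_ont():
    # R with two branches: X -> {t1, t2}, Y -> {t3, t4}
    return make_ontology(
        [("t1", "X"), ("t2", "X"), ("t3", "Y"), ("t4", "Y"), ("X", "R"), ("Y", "R")]
    )


@pytest.fixture
def records_mixed():
    """One plain, one negated, one uncertain, one dual-flagged mention."""
    return [
        AnnotationRecord("v1", "t1", False, False),
        AnnotationRecord("v1", "t2", True, False),
        AnnotationRecord("v2", "t3", False, True),
        AnnotationRecord("v2", "t4", True, True),
    ]


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return random.Random(20211206)


@pytest.fixture
def nprng():
    return np.random.default_rng(20211206)
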