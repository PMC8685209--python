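"""Term DAG loading and ancestor-closure queries.

Phenotype terms live in a rooted directed acyclic graph under ``is_a``
subsumption (the shape of the Human Phenotype Ontology and its relatives).
Semantic similarity needs fast reflexive-transitive ancestor closures, so the
:class:`Ontology` object precomputes nothing but memoises closures on demand.

Two input formats are supported:

* a minimal OBO 1.2 subset (``[Term]`` stanzas; ``id``, ``name``, ``is_a``,
  ``is_obsolete`` lines) parsed with :mod:`obonet` — obsolete terms are
  excluded and only ``is_a`` edges are honoured;
* a headered TSV edge list with columns ``child`` and ``parent``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Ontology", "OntologyError", "load_ontology"]


class OntologyError(ValueError):
    """Raised for structurally invalid term graphs or unknown terms."""


@dataclass
class Ontology:
    """A rooted DAG of terms with ``is_a`` parent edges.

    Parameters
    ----------
    parents
        Mapping term -> set of direct parents. Every term must appear as a
        key; the root has an empty parent set.

    Notes
    -----
    Ancestor closures are reflexive: a term is its own ancestor. This is the
    standard convention for corpus-based Resnik similarity, and makes
    ``resnik(t, t) == ic(t)`` hold.
    """

    parents: dict[str, frozenset[str]]
    root: str = field(init=False)
    _closure: dict[str, frozenset[str]] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = {t: frozenset(ps) for t, ps in self.parents.items()}
        self._validate()

    def _validate(self) -> None:
        terms = set(self.parents)
        if not terms:
            raise OntologyError("ontology has no terms")
        for t, ps in self.parents.items():
            dangling = ps - terms
            if dangling:
                raise OntologyError(
                    f"term {t!r} references undefined parent(s): {sorted(dangling)}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"cycle detected involving term {cycle[0][0]!r}")
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        self.root = roots[0]
        # acyclicity + single root + no dangling parents ==> every term
        # reaches the root by following parent edges

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def _require(self, term: str) -> None:
        if term not in self.parents:
            raise OntologyError(f"unknown term: {term!r}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive ancestor closure of ``term`` (includes root)."""
        self._require(term)
        cached = self._closure.get(term)
        if cached is not None:
            return cached
        closure = {term}
        for p in self.parents[term]:
            closure |= self.ancestors(p)
        result = frozenset(closure)
        self._closure[term] = result
        return result

    def common_ancestors(self, a: str, b: str) -> frozenset[str]:
        """Shared ancestors of ``a`` and ``b``; never empty (root is shared)."""
        return self.ancestors(a) & self.ancestors(b)

    def descendants(self, term: str) -> frozenset[str]:
        """All terms whose ancestor closure contains ``term`` (includes term)."""
        self._require(term)
        return frozenset(t for t in self.parents if term in self.ancestors(t))


def _load_edgelist(path: Path) -> Ontology:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child", "parent"):
        if col not in df.columns:
            raise OntologyError(f"edge list {path} is missing column {col!r}")
    parents: dict[str, set[str]] = {}
    for child, parent in zip(df["child"], df["parent"]):
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return Ontology({t: frozenset(ps) for t, ps in parents.items()})


def _load_obo(path: Path) -> Ontology:
    # obonet drops obsolete stanzas and stores child->parent is_a edges
    graph = obonet.read_obo(path, ignore_obsolete=True)
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    ignored = 0
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            ignored += 1
            continue
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    if ignored:
        logger.warning("ignored %d non-is_a relationship edge(s) in %s", ignored, path)
    return Ontology({t: frozenset(ps) for t, ps in parents.items()})


def load_ontology(source: str | Path, format: str | None = None) -> Ontology:
    """Load a validated :class:`Ontology` from an OBO file or TSV edge list.

    Parameters
    ----------
    source
        Path to the ontology file.
    format
        ``"obo"`` or ``"edgelist"``; inferred from the extension
        (``.obo`` -> obo, anything else -> edgelist) when omitted.

    Raises
    ------
    OntologyError
        On cycles (naming a cycle member), multiple roots (listing them),
        or dangling parent references.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "obo" if path.suffix.lower() == ".obo" else "edgelist"
    if format == "obo":
        return _load_obo(path)
    if format == "edgelist":
        return _load_edgelist(path)
    raise ValueError(f"unknown ontology format: {format!r}")
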