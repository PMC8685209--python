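"""Synthetic ontology-annotated cohorts with controllable context structure.

Real critical-care cohorts with text-derived phenotype profiles are access
restricted, so pipeline behaviour is studied on generated ones. Each
diagnosis owns a *signature*: a handful of terms sampled from one subtree of
a random ontology, so same-diagnosis profiles are ontologically close and a
depth-sensitive measure (Resnik MICA) can separate diagnoses. Visits draw a
diagnosis, emit signature terms with a per-term probability plus Poisson
background terms, and then add negated and uncertain mentions at controlled
per-visit rates.

Two negation regimes bracket the competing hypotheses about what negated
mentions carry:

* ``noise`` — negated terms are uniform draws, pure clutter; removing them
  should help diagnosis ranking;
* ``signal`` — negated terms come from the signatures of a fixed set of
  *differential* diagnoses of the visit's true diagnosis (conditions being
  ruled out); they then correlate with the diagnosis and removing them
  should not help.

Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import AnnotationRecord
from .ontology import Ontology

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_ontology",
    "generate_cohort",
    "scenario",
    "SCENARIO_NAMES",
]

N_DIFFERENTIALS = 2  # ruled-out diagnoses per diagnosis in signal mode


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Rates are per visit: ``signature_rate`` is the chance each signature term
    is mentioned affirmed; ``background_rate``, ``neg_rate`` and ``unc_rate``
    are Poisson means for background / negated / uncertain mention counts;
    ``dual_rate`` is the chance a negated mention is also flagged uncertain.
    """

    n_visits: int = 300
    n_diagnoses: int = 30
    ontology_terms: int = 500
    branching: int = 3
    signature_size: int = 8
    signature_rate: float = 0.5
    background_rate: float = 15.0
    neg_rate: float = 8.0
    unc_rate: float = 3.0
    dual_rate: float = 0.04
    neg_mode: str = "noise"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_visits < 1:
            problems.append("n_visits must be positive")
        if self.n_diagnoses < 1:
            problems.append("n_diagnoses must be positive")
        if self.ontology_terms < 2:
            problems.append("ontology_terms must be >= 2")
        if self.branching < 1:
            problems.append("branching must be positive")
        if not 1 <= self.signature_size <= self.ontology_terms:
            problems.append("signature_size must be in [1, ontology_terms]")
        for name in ("signature_rate", "dual_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be a probability in [0, 1]")
        for name in ("background_rate", "neg_rate", "unc_rate"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        if self.neg_mode not in ("noise", "signal"):
            problems.append("neg_mode must be 'noise' or 'signal'")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


@dataclass
class SyntheticCohort:
    """A generated ontology, annotation list and diagnosis mapping."""

    ontology: Ontology
    annotations: list[AnnotationRecord]
    diagnoses: dict[str, str]
    truth: CohortSpec
    signatures: dict[str, frozenset[str]]

    def write(self, out_dir: str | Path) -> None:
        """Write ontology.tsv, annotations.tsv, diagnoses.tsv and spec.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "ontology.tsv", "w") as fh:
            fh.write("child\tparent\n")
            for child in sorted(self.ontology.terms):
                for parent in sorted(self.ontology.parents[child]):
                    fh.write(f"{child}\t{parent}\n")
        with open(out / "annotations.tsv", "w") as fh:
            fh.write("visit_id\tterm\tnegated\tuncertain\n")
            for r in self.annotations:
                fh.write(
                    f"{r.visit_id}\t{r.term}\t{int(r.negated)}\t{int(r.uncertain)}\n"
                )
        with open(out / "diagnoses.tsv", "w") as fh:
            fh.write("visit_id\tdiagnosis\n")
            for v in sorted(self.diagnoses):
                fh.write(f"{v}\t{self.diagnoses[v]}\n")
        (out / "spec.json").write_text(self.truth.to_json())


def _term_name(i: int) -> str:
    return f"T:{i:07d}"


def generate_ontology(terms: int, branching: int, seed: int) -> Ontology:
    """Random rooted tree over ``terms`` terms.

    Each non-root term attaches to a uniformly chosen earlier term, preferring
    parents that still have fewer than ``branching`` children (falling back to
    any earlier term once all are saturated). Deterministic under ``seed``.
    """
    if terms < 2:
        raise ValueError("an ontology needs at least 2 terms (root plus one child)")
    rng = np.random.default_rng(seed)
    child_count = np.zeros(terms, dtype=int)
    parents: dict[str, frozenset[str]] = {_term_name(0): frozenset()}
    for i in range(1, terms):
        open_slots = np.flatnonzero(child_count[:i] < branching)
        pool = open_slots if open_slots.size else np.arange(i)
        parent = int(rng.choice(pool))
        child_count[parent] += 1
        parents[_term_name(i)] = frozenset({_term_name(parent)})
    return Ontology(parents)


def _subtree_sample(
    ont: Ontology, size: int, rng: np.random.Generator
) -> frozenset[str]:
    """Sample ``size`` terms from one random subtree large enough to hold them."""
    terms = sorted(ont.terms)
    candidates = [t for t in terms if t != ont.root and len(ont.descendants(t)) >= size]
    if not candidates:
        candidates = [ont.root]
    anchor = candidates[int(rng.integers(len(candidates)))]
    pool = sorted(ont.descendants(anchor))
    picked = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
    return frozenset(pool[i] for i in sorted(picked))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort under ``spec`` (see module docstring)."""
    spec.validate()
    ont = generate_ontology(spec.ontology_terms, spec.branching, spec.seed)
    rng = np.random.default_rng([spec.seed, 7919])

    dx_labels = [f"DX{d:03d}" for d in range(spec.n_diagnoses)]
    signatures = {
        d: _subtree_sample(ont, spec.signature_size, rng) for d in dx_labels
    }
    # fixed ruled-out differentials per diagnosis (signal mode)
    differentials: dict[str, list[str]] = {}
    for d in dx_labels:
        others = [x for x in dx_labels if x != d]
        if others:
            k = min(N_DIFFERENTIALS, len(others))
            picked = rng.choice(len(others), size=k, replace=False)
            differentials[d] = [others[i] for i in sorted(picked)]
        else:
            differentials[d] = []

    all_terms = sorted(t for t in ont.terms if t != ont.root)
    visit_ids = [f"V{v:05d}" for v in range(spec.n_visits)]
    diagnoses: dict[str, str] = {}
    annotations: list[AnnotationRecord] = []

    def context_pool(d: str) -> list[str]:
        if spec.neg_mode == "signal" and differentials[d]:
            pool = sorted({t for x in differentials[d] for t in signatures[x]})
            if pool:
                return pool
        return all_terms

    for v in visit_ids:
        d = dx_labels[int(rng.integers(spec.n_diagnoses))]
        diagnoses[v] = d
        for t in sorted(signatures[d]):
            if rng.random() < spec.signature_rate:
                annotations.append(AnnotationRecord(v, t, False, False))
        for _ in range(rng.poisson(spec.background_rate)):
            t = all_terms[int(rng.integers(len(all_terms)))]
            annotations.append(AnnotationRecord(v, t, False, False))
        pool = context_pool(d)
        for _ in range(rng.poisson(spec.neg_rate)):
            t = pool[int(rng.integers(len(pool)))]
            dual = rng.random() < spec.dual_rate
            annotations.append(AnnotationRecord(v, t, True, dual))
        for _ in range(rng.poisson(spec.unc_rate)):
            t = pool[int(rng.integers(len(pool)))]
            annotations.append(AnnotationRecord(v, t, False, True))

    return SyntheticCohort(
        ontology=ont,
        annotations=annotations,
        diagnoses=diagnoses,
        truth=spec,
        signatures=signatures,
    )


_SCENARIOS = {
    # negated/uncertain mentions are clutter; filtering should help
    "noise-negation": CohortSpec(neg_mode="noise", seed=20210),
    # negated/uncertain mentions are ruled-out differentials; filtering
    # discards diagnosis-linked information
    "signal-negation": CohortSpec(neg_mode="signal", seed=20211),
    # diagnosis carries no phenotype signal at all
    "null": CohortSpec(signature_rate=0.0, neg_mode="noise", seed=20212),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario(name: str, seed: int | None = None) -> CohortSpec:
    """A documented preset :class:`CohortSpec`.

    Presets share cohort size (300 visits, 30 diagnoses, 500-term ontology)
    and the per-visit mention rates; they differ only in negation mode and
    signature informativeness. ``seed`` overrides the preset seed, for
    replicate studies.
    """
    if name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(_SCENARIOS)}"
        )
    spec = _SCENARIOS[name]
    if seed is not None:
        spec = dataclasses.replace(spec, seed=int(seed))
    return spec
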