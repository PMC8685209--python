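"""Corpus information content, Resnik pairwise and Best-Match-Average
groupwise semantic similarity.

The information content (IC) of a term is the negative natural log of the
probability of observing the term — directly or through any of its
descendants — in the annotation corpus of one stratum:

    ic(t) = -ln( n(t) / N )

where ``n(t)`` counts profiles containing ``t`` or a descendant of ``t`` and
``N`` is the number of non-empty profiles. Pairwise similarity is Resnik's
measure, the IC of the most informative common ancestor (MICA); groupwise
similarity is the Best Match Average: for each term of either set take the
best Resnik match in the other set, and average all best-match values.

Because the IC is corpus-based, it must be recomputed for every stratum; the
:class:`ICTable` carries its stratum tag and :func:`all_pairs` refuses a
profile-set/IC-table stratum mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import ProfileSet, Stratum
from .ontology import Ontology

__all__ = ["ICTable", "SimilarityMatrix", "compute_ic", "resnik", "bma", "all_pairs"]

LOG_BASE = "e"  # natural log; the base only rescales scores


@dataclass
class ICTable:
    """Term -> information content (nats) for one stratum's corpus.

    Terms never observed in the corpus (zero propagated count) are absent
    from the table and contribute IC 0 wherever they are consulted.
    """

    ic: dict[str, float]
    corpus_profile_count: int
    stratum: Stratum

    def __getitem__(self, term: str) -> float:
        return self.ic.get(term, 0.0)


@dataclass
class SimilarityMatrix:
    """Symmetric visit-by-visit groupwise similarity scores for one stratum."""

    visits: list[str]
    scores: np.ndarray
    stratum: Stratum

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.visits)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over the visit order")

    def value(self, a: str, b: str) -> float:
        i, j = self.visits.index(a), self.visits.index(b)
        return float(self.scores[i, j])

    def to_tsv(self, path: str | Path) -> None:
        """Serialise unordered pairs (``visit_a < visit_b``) as long-form TSV
        with a JSON metadata sidecar."""
        path = Path(path)
        order = np.argsort(self.visits)
        with open(path, "w") as fh:
            fh.write("visit_a\tvisit_b\tscore\n")
            for ii in range(len(order)):
                for jj in range(ii + 1, len(order)):
                    i, j = order[ii], order[jj]
                    fh.write(
                        f"{self.visits[i]}\t{self.visits[j]}\t"
                        f"{self.scores[i, j]:.10g}\n"
                    )
        meta = {
            "stratum": self.stratum.value,
            "log_base": LOG_BASE,
            "n_visits": len(self.visits),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, stratum: Stratum | None = None) -> "SimilarityMatrix":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"visit_a": str, "visit_b": str})
        if stratum is None:
            meta_path = path.with_suffix(path.suffix + ".meta.json")
            if meta_path.exists():
                stratum = Stratum.from_label(json.loads(meta_path.read_text())["stratum"])
            else:
                stratum = Stratum.ALL
        visits = sorted(set(df["visit_a"]) | set(df["visit_b"]))
        idx = {v: i for i, v in enumerate(visits)}
        scores = np.zeros((len(visits), len(visits)))
        for a, b, s in zip(df["visit_a"], df["visit_b"], df["score"]):
            scores[idx[a], idx[b]] = scores[idx[b], idx[a]] = s
        return cls(visits=visits, scores=scores, stratum=Stratum.from_label(stratum))


def compute_ic(ps: ProfileSet, ont: Ontology) -> ICTable:
    """Propagated corpus IC for one stratum.

    A profile containing term ``t`` contributes one count to ``t`` and to
    every ancestor of ``t`` (presence-based: mention multiplicity within a
    profile is not used). ``N`` is the number of profiles with at least one
    term; profiles emptied by the stratum filter do not shrink the corpus.
    """
    nonempty = [terms for terms in ps.profiles.values() if terms]
    if not nonempty:
        raise ValueError(
            f"cannot compute information content: all {len(ps)} profiles in "
            f"stratum {ps.stratum.value} are empty"
        )
    n_total = len(nonempty)
    counts: dict[str, int] = {}
    for terms in nonempty:
        closure: set[str] = set()
        for t in terms:
            closure |= ont.ancestors(t)
        for a in closure:
            counts[a] = counts.get(a, 0) + 1
    ic = {t: -math.log(n / n_total) for t, n in counts.items()}
    return ICTable(ic=ic, corpus_profile_count=n_total, stratum=ps.stratum)


def resnik(a: str, b: str, ict: ICTable, ont: Ontology) -> float:
    """IC of the most informative common ancestor of ``a`` and ``b``.

    Ancestors absent from the IC table contribute 0, so two terms whose only
    shared ancestor is the (ubiquitous) root score 0.
    """
    return max(ict[c] for c in ont.common_ancestors(a, b))


def bma(
    a: Iterable[str], b: Iterable[str], ict: ICTable, ont: Ontology
) -> float:
    """Best Match Average groupwise similarity between two term sets.

    Averages, over the |A| + |B| terms of both sets, each term's best Resnik
    match in the opposite set. Symmetric by construction; 0 if either set is
    empty (the convention for profiles emptied by context filtering).
    """
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    bests = [max(resnik(x, y, ict, ont) for y in b) for x in a]
    bests += [max(resnik(x, y, ict, ont) for x in a) for y in b]
    return float(sum(bests) / len(bests))


def _term_pair_resnik(
    terms: list[str], ict: ICTable, ont: Ontology
) -> np.ndarray:
    """Dense Resnik matrix over ``terms`` (the distinct annotated terms)."""
    ancestors = sorted({a for t in terms for a in ont.ancestors(t)})
    anc_idx = {a: i for i, a in enumerate(ancestors)}
    icv = np.array([ict[a] for a in ancestors])
    A = np.zeros((len(terms), len(ancestors)), dtype=bool)
    for i, t in enumerate(terms):
        for a in ont.ancestors(t):
            A[i, anc_idx[a]] = True
    R = np.zeros((len(terms), len(terms)))
    W = A * icv
    for i in range(len(terms)):
        shared = W * A[i]
        R[i] = shared.max(axis=1) if shared.size else 0.0
    return R


def all_pairs(ps: ProfileSet, ict: ICTable, ont: Ontology) -> SimilarityMatrix:
    """All-vs-all BMA similarity matrix over the cohort of one stratum.

    The IC table must have been computed from the same stratum's corpus;
    a stratum mismatch is a hard error because reusing another stratum's IC
    silently changes every score.
    """
    if ict.stratum is not ps.stratum:
        raise ValueError(
            f"stratum mismatch: profiles are {ps.stratum.value!r} but the IC "
            f"table was computed for {ict.stratum.value!r}"
        )
    visits = ps.visits
    n = len(visits)
    terms = sorted({t for v in visits for t in ps.profiles[v]})
    tidx = {t: i for i, t in enumerate(terms)}
    profile_idx = [np.array([tidx[t] for t in sorted(ps.profiles[v])], dtype=int) for v in visits]
    sizes = np.array([len(p) for p in profile_idx])

    if not terms:
        return SimilarityMatrix(visits=visits, scores=np.zeros((n, n)), stratum=ps.stratum)

    R = _term_pair_resnik(terms, ict, ont)

    # best[j, t] = best Resnik match of term t within profile j
    best = np.zeros((n, len(terms)))
    for j, idx in enumerate(profile_idx):
        if idx.size:
            best[j] = R[:, idx].max(axis=1)

    # directional best-match sums: S[i, j] = sum_{t in profile i} best[j, t]
    P = np.zeros((n, len(terms)))
    for i, idx in enumerate(profile_idx):
        P[i, idx] = 1.0
    S = P @ best.T

    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (S + S.T) / denom
    scores[(sizes[:, None] == 0) | (sizes[None, :] == 0)] = 0.0
    return SimilarityMatrix(visits=visits, scores=scores, stratum=ps.stratum)
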