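"""Ranking-based evaluation of shared-diagnosis prediction.

Every unordered visit pair is labelled true when the two visits share a
primary diagnosis. The pooled (global) similarity ranking yields an AUC with
a 95% Hanley–McNeil confidence interval; per-visit (local) rankings yield
Mean Reciprocal Rank and Top-k Accuracy; and a Mann–Whitney U test on the
best-true-match ranks compares a filtered stratum's rankings against the
baseline's (significance read at the 0.01 cutoff).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .corpus import ProfileSet, Stratum
from .similarity import SimilarityMatrix

__all__ = [
    "PairLabel",
    "LocalRanking",
    "EvaluationReport",
    "label_pairs",
    "global_auc",
    "auc_midrank",
    "rank_shift_from_ranks",
    "hanley_mcneil_ci",
    "local_rankings",
    "mrr",
    "top_k_accuracy",
    "implied_case_difference",
    "rank_shift_test",
    "evaluate_stratum",
]

SIGNIFICANCE_CUTOFF = 0.01


class PairLabel(NamedTuple):
    visit_a: str
    visit_b: str
    shared: bool


@dataclass
class LocalRanking:
    """All other visits ranked by similarity to one focal visit.

    ``ordered`` holds ``(visit_id, score, shared)`` sorted by score
    descending; ties are broken by ascending visit id so rankings are
    bit-reproducible.
    """

    focal: str
    ordered: list[tuple[str, float, bool]]

    def first_true_rank(self) -> int | None:
        """1-based rank of the best same-diagnosis match, or None."""
        for rank, (_, _, shared) in enumerate(self.ordered, start=1):
            if shared:
                return rank
        return None

    def true_ranks(self) -> list[int]:
        return [r for r, (_, _, s) in enumerate(self.ordered, start=1) if s]


@dataclass
class EvaluationReport:
    """One stratum's row of the results table."""

    stratum: Stratum
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    mrr: float
    a_at_10: float
    n_evaluable: int
    rank_shift_p: float | None = None
    k: int = 10
    significant: bool | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if not (self.auc_ci_low <= self.auc <= self.auc_ci_high):
            raise ValueError("AUC must lie inside its confidence interval")
        if self.rank_shift_p is not None:
            self.significant = self.rank_shift_p < SIGNIFICANCE_CUTOFF

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum.value,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "mrr": self.mrr,
            "a_at_10": self.a_at_10,
            "n_evaluable": self.n_evaluable,
            "rank_shift_p": self.rank_shift_p,
            "k": self.k,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def tsv_row(self) -> str:
        p = "" if self.rank_shift_p is None else f"{self.rank_shift_p:.4g}"
        return (
            f"{self.stratum.value}\t{self.auc:.4f}\t{self.auc_ci_low:.4f}\t"
            f"{self.auc_ci_high:.4f}\t{self.mrr:.3f}\t{self.a_at_10:.3f}\t"
            f"{p}\t{self.n_evaluable}"
        )

    TSV_HEADER = "stratum\tauc\tci_low\tci_high\tmrr\ta_at_10\tp_value\tn_evaluable"


def label_pairs(ps: ProfileSet) -> list[PairLabel]:
    """One shared-diagnosis label per unordered pair of distinct visits."""
    visits = ps.visits
    return [
        PairLabel(a, b, ps.diagnosis[a] == ps.diagnosis[b])
        for i, a in enumerate(visits)
        for b in visits[i + 1 :]
    ]


def auc_midrank(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` against boolean ``truth``, with midranks."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    ranks = stats.rankdata(scores)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both true and false entries")
    u = ranks[truth].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def hanley_mcneil_ci(auc: float, n1: int, n0: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley–McNeil standard-error confidence interval for an AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def global_auc(
    m: SimilarityMatrix, labels: Sequence[PairLabel]
) -> tuple[float, float, float]:
    """AUC of the pooled pair ranking, with a 95% Hanley–McNeil interval.

    Ties are handled by midranks, so a fully tied score list gives 0.5.
    Requires at least one true and one false pair.
    """
    idx = {v: i for i, v in enumerate(m.visits)}
    scores = np.array([m.scores[idx[l.visit_a], idx[l.visit_b]] for l in labels])
    truth = np.array([l.shared for l in labels], dtype=bool)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0:
        raise ValueError("cannot compute AUC: no shared-diagnosis (true) pairs")
    if n0 == 0:
        raise ValueError("cannot compute AUC: no non-shared (false) pairs")
    auc = auc_midrank(scores, truth)
    lo, hi = hanley_mcneil_ci(auc, n1, n0)
    return auc, lo, hi


def local_rankings(m: SimilarityMatrix, ps: ProfileSet) -> list[LocalRanking]:
    """One descending-score ranking per focal visit over all other visits."""
    idx = {v: i for i, v in enumerate(m.visits)}
    out = []
    for focal in ps.visits:
        i = idx[focal]
        rows = [
            (other, float(m.scores[i, idx[other]]), ps.diagnosis[focal] == ps.diagnosis[other])
            for other in ps.visits
            if other != focal
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        out.append(LocalRanking(focal=focal, ordered=rows))
    return out


def _evaluable(rankings: Sequence[LocalRanking]) -> list[tuple[LocalRanking, int]]:
    pairs = []
    for r in rankings:
        ftr = r.first_true_rank()
        if ftr is not None:
            pairs.append((r, ftr))
    return pairs


def mrr(rankings: Sequence[LocalRanking]) -> tuple[float, int]:
    """Mean reciprocal rank of the best true match, over evaluable visits.

    A focal visit with no same-diagnosis partner anywhere in the cohort is
    excluded; the count of included visits is returned alongside.
    """
    ev = _evaluable(rankings)
    if not ev:
        return 0.0, 0
    return float(np.mean([1.0 / ftr for _, ftr in ev])), len(ev)


def top_k_accuracy(rankings: Sequence[LocalRanking], k: int = 10) -> float:
    """Fraction of evaluable focal visits with a true match at rank <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ev = _evaluable(rankings)
    if not ev:
        return 0.0
    return float(np.mean([ftr <= k for _, ftr in ev]))


def implied_case_difference(acc_a: float, acc_b: float, n: int) -> int:
    """Number of additional top-k successes implied by two accuracies at n."""
    return round((acc_b - acc_a) * n)


def rank_shift_test(
    rankings_x: Sequence[LocalRanking],
    rankings_base: Sequence[LocalRanking],
    mode: str = "best",
) -> float:
    """Two-sided Mann–Whitney U p-value comparing true-match ranks.

    ``mode="best"`` (default) compares, per evaluable focal visit, the rank
    of its best same-diagnosis match; ``mode="pooled"`` pools the ranks of
    every same-diagnosis match instead. Tie correction is applied; samples
    small enough for the exact null distribution use it.
    """
    if mode == "best":
        xs = [ftr for _, ftr in _evaluable(rankings_x)]
        bs = [ftr for _, ftr in _evaluable(rankings_base)]
    elif mode == "pooled":
        xs = [r for lr in rankings_x for r in lr.true_ranks()]
        bs = [r for lr in rankings_base for r in lr.true_ranks()]
    else:
        raise ValueError(f"unknown rank-shift mode {mode!r}; use 'best' or 'pooled'")
    return rank_shift_from_ranks(xs, bs)


def rank_shift_from_ranks(xs: Sequence[int], bs: Sequence[int]) -> float:
    """Two-sided, tie-corrected Mann-Whitney U p-value on two rank samples."""
    if len(xs) < 2 or len(bs) < 2:
        raise ValueError(
            f"rank-shift test needs >= 2 evaluable visits per side "
            f"(got {len(xs)} and {len(bs)})"
        )
    if list(xs) == list(bs):
        return 1.0
    res = stats.mannwhitneyu(xs, bs, alternative="two-sided", method="auto")
    return float(res.pvalue)


def evaluate_stratum(
    m: SimilarityMatrix,
    ps: ProfileSet,
    baseline_rankings: Sequence[LocalRanking] | None = None,
    k: int = 10,
    mwu_mode: str = "best",
) -> EvaluationReport:
    """Assemble one stratum's full report.

    ``rank_shift_p`` is omitted when no baseline rankings are supplied (the
    baseline stratum's own row).
    """
    labels = label_pairs(ps)
    auc, lo, hi = global_auc(m, labels)
    rankings = local_rankings(m, ps)
    mrr_val, n_eval = mrr(rankings)
    acc = top_k_accuracy(rankings, k=k)
    p = None
    if baseline_rankings is not None:
        p = rank_shift_test(rankings, baseline_rankings, mode=mwu_mode)
    return EvaluationReport(
        stratum=ps.stratum,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        mrr=mrr_val,
        a_at_10=acc,
        n_evaluable=n_eval,
        rank_shift_p=p,
        k=k,
    )
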