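"""Replicate studies over synthetic cohorts.

Two study designs support calibration and effect-recovery checks:

* :func:`filtering_effect_replicates` — regenerate a scenario across a fixed
  seed list and, per replicate, compare the negation-filtered stratum against
  the unfiltered baseline (AUC, MRR, per-replicate and pooled rank-shift
  Mann-Whitney tests);
* :func:`null_label_shuffle_study` — fix one cohort's similarity matrices and
  permute the diagnosis labels repeatedly, giving the no-signal reference
  distribution of the AUC and of the rank-shift p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import Stratum, build_profiles
from .evaluation import (
    auc_midrank,
    global_auc,
    label_pairs,
    local_rankings,
    mrr,
    rank_shift_from_ranks,
    rank_shift_test,
)
from .similarity import all_pairs, compute_ic
from .synthetic import SyntheticCohort, generate_cohort, scenario

__all__ = [
    "FilteringEffectResult",
    "filtering_effect_replicates",
    "null_label_shuffle_study",
]


@dataclass
class FilteringEffectResult:
    """Per-replicate metrics of a filtered-vs-baseline comparison."""

    scenario: str
    seeds: list[int]
    auc_base: np.ndarray
    auc_filtered: np.ndarray
    mrr_base: np.ndarray
    mrr_filtered: np.ndarray
    p_per_replicate: np.ndarray
    pooled_p: float

    @property
    def auc_improvement_fraction(self) -> float:
        return float(np.mean(self.auc_filtered > self.auc_base))

    @property
    def mean_auc_effect(self) -> float:
        return float(np.mean(self.auc_filtered - self.auc_base))


def _stratum_metrics(cohort: SyntheticCohort, stratum: Stratum):
    ps = build_profiles(cohort.annotations, cohort.diagnoses, cohort.ontology, stratum)
    ict = compute_ic(ps, cohort.ontology)
    m = all_pairs(ps, ict, cohort.ontology)
    auc = global_auc(m, label_pairs(ps))[0]
    rankings = local_rankings(m, ps)
    return auc, rankings


def filtering_effect_replicates(
    scenario_name: str,
    seeds: Sequence[int],
    baseline: Stratum = Stratum.ALL,
    filtered: Stratum = Stratum.NO_NEG,
) -> FilteringEffectResult:
    """Regenerate ``scenario_name`` for every seed and compare two strata.

    The pooled rank-shift test concatenates each side's best-true-match
    ranks across all replicates before the Mann-Whitney comparison.
    """
    auc_b, auc_f, mrr_b, mrr_f, p_rep = [], [], [], [], []
    pooled_b: list[int] = []
    pooled_f: list[int] = []
    for seed in seeds:
        cohort = generate_cohort(scenario(scenario_name, seed=seed))
        ab, rank_b = _stratum_metrics(cohort, baseline)
        af, rank_f = _stratum_metrics(cohort, filtered)
        auc_b.append(ab)
        auc_f.append(af)
        mrr_b.append(mrr(rank_b)[0])
        mrr_f.append(mrr(rank_f)[0])
        p_rep.append(rank_shift_test(rank_f, rank_b))
        pooled_b.extend(r.first_true_rank() for r in rank_b if r.first_true_rank())
        pooled_f.extend(r.first_true_rank() for r in rank_f if r.first_true_rank())
    return FilteringEffectResult(
        scenario=scenario_name,
        seeds=list(seeds),
        auc_base=np.array(auc_b),
        auc_filtered=np.array(auc_f),
        mrr_base=np.array(mrr_b),
        mrr_filtered=np.array(mrr_f),
        p_per_replicate=np.array(p_rep),
        pooled_p=rank_shift_from_ranks(pooled_f, pooled_b),
    )


def null_label_shuffle_study(
    cohort: SyntheticCohort,
    n_shuffles: int = 200,
    seed: int = 0,
    baseline: Stratum = Stratum.ALL,
    filtered: Stratum = Stratum.NO_NEG,
) -> dict[str, np.ndarray]:
    """Label-permutation reference distribution on one fixed cohort.

    The similarity matrices and local orderings are computed once (they do
    not depend on labels); each shuffle permutes the diagnosis labels over
    visits, then recomputes the baseline global AUC and the rank-shift
    p-value between the filtered and baseline local rankings.

    Returns arrays ``auc`` (length ``n_shuffles``) and ``p`` (rank-shift
    p-values).
    """
    per_stratum = {}
    for s in (baseline, filtered):
        ps = build_profiles(cohort.annotations, cohort.diagnoses, cohort.ontology, s)
        ict = compute_ic(ps, cohort.ontology)
        m = all_pairs(ps, ict, cohort.ontology)
        rankings = local_rankings(m, ps)
        per_stratum[s] = (ps, m, rankings)

    ps_b, m_b, rank_b = per_stratum[baseline]
    visits = ps_b.visits
    n = len(visits)
    vidx = {v: i for i, v in enumerate(visits)}
    iu, ju = np.triu_indices(n, k=1)
    pair_scores = m_b.scores[iu, ju]

    # orderings are label-free; precompute the index matrix per stratum
    order_idx = {}
    for s, (_, _, rankings) in per_stratum.items():
        by_focal = {r.focal: r for r in rankings}
        order_idx[s] = np.array(
            [[vidx[v] for v, _, _ in by_focal[f].ordered] for f in visits]
        )

    rng = np.random.default_rng(seed)
    labels = np.array([ps_b.diagnosis[v] for v in visits])
    codes = np.unique(labels, return_inverse=True)[1]

    aucs = np.empty(n_shuffles)
    pvals = np.empty(n_shuffles)
    for rep in range(n_shuffles):
        shuffled = codes[rng.permutation(n)]
        truth = shuffled[iu] == shuffled[ju]
        aucs[rep] = auc_midrank(pair_scores, truth)
        ranks = {}
        for s in (baseline, filtered):
            shared = shuffled[order_idx[s]] == shuffled[:, None]
            has_match = shared.any(axis=1)
            first = shared.argmax(axis=1) + 1
            ranks[s] = first[has_match]
        pvals[rep] = rank_shift_from_ranks(
            list(ranks[filtered]), list(ranks[baseline])
        )
    return {"auc": aucs, "p": pvals}
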