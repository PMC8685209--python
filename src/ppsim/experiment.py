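"""End-to-end stratified similarity experiment.

:class:`SimilarityExperiment` is the model object: it is built from an
annotation table, a diagnosis mapping and an ontology, and ``fit()`` runs
the whole pipeline for each requested stratum — filter annotations, build
profiles, recompute the information content on *that stratum's* corpus,
compute the all-pairs Best-Match-Average matrix, and evaluate global and
local rankings against the baseline stratum. The returned
:class:`ExperimentResults` carries per-stratum reports, annotation counts
and a ``summary()`` table.

All randomness lives in the synthetic generator; given fixed inputs the
experiment is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import corpus as _corpus
from . import evaluation as _eval
from . import similarity as _sim
from .corpus import AnnotationRecord, ProfileSet, Stratum
from .evaluation import EvaluationReport, LocalRanking
from .ontology import Ontology, load_ontology
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SimilarityExperiment", "ExperimentResults", "run_experiment"]

DEFAULT_STRATA = (Stratum.ALL, Stratum.NO_NEG, Stratum.NO_UNC, Stratum.NO_NEG_NO_UNC)


@dataclass
class RunConfig:
    """File-based configuration of one experiment run."""

    ontology: str
    annotations: str
    diagnoses: str
    out_dir: str = "results"
    strata: Sequence[Stratum] = DEFAULT_STRATA
    baseline: Stratum = Stratum.ALL
    k: int = 10
    mwu_mode: str = "best"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.strata = tuple(Stratum.from_label(s) for s in self.strata)
        self.baseline = Stratum.from_label(self.baseline)
        if self.baseline not in self.strata:
            raise ValueError(
                f"baseline stratum {self.baseline.value!r} must be among the "
                f"requested strata {[s.value for s in self.strata]}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


@dataclass
class ExperimentResults:
    """Fitted results: one evaluation report per stratum, plus provenance."""

    reports: dict[Stratum, EvaluationReport]
    counts: dict[str, int]
    kept_counts: dict[Stratum, int]
    matrices: dict[Stratum, SimilarityMatrix]
    profile_sets: dict[Stratum, ProfileSet]
    baseline: Stratum
    k: int = 10

    def summary(self) -> str:
        """Results-table text: one row per stratum, baseline p-value blank."""
        lines = [
            f"Shared-diagnosis ranking over {len(next(iter(self.profile_sets.values())))} "
            f"visits (baseline: {self.baseline.value})",
            "",
            f"{'stratum':<15}{'kept':>8}{'AUC':>9}{'95% CI':>19}"
            f"{'MRR':>8}{'A@%d' % self.k:>8}{'p-value':>12}",
        ]
        for s, r in self.reports.items():
            p = "-" if r.rank_shift_p is None else f"{r.rank_shift_p:.3g}"
            ci = f"({r.auc_ci_low:.4f}-{r.auc_ci_high:.4f})"
            lines.append(
                f"{s.value:<15}{self.kept_counts[s]:>8}{r.auc:>9.4f}{ci:>19}"
                f"{r.mrr:>8.3f}{r.a_at_10:>8.3f}{p:>12}"
            )
        return "\n".join(lines)

    def counts_tsv(self) -> str:
        c = self.counts
        lines = ["metric\tcount"]
        lines += [f"{k}\t{v}" for k, v in c.items()]
        lines += [f"kept_{s.value}\t{n}" for s, n in self.kept_counts.items()]
        return "\n".join(lines) + "\n"

    def results_tsv(self) -> str:
        lines = [EvaluationReport.TSV_HEADER]
        lines += [r.tsv_row() for r in self.reports.values()]
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "counts.tsv").write_text(self.counts_tsv())
        (out / "results.tsv").write_text(self.results_tsv())
        for s, m in self.matrices.items():
            m.to_tsv(out / f"matrix_{s.value}.tsv")
        for s, r in self.reports.items():
            r.to_json(out / f"report_{s.value}.json")


class SimilarityExperiment:
    """Context-stratified phenotype-profile similarity experiment.

    Parameters
    ----------
    annotations
        Concept mentions with negation/uncertainty flags.
    diagnoses
        Visit id -> primary-diagnosis label.
    ontology
        The term DAG the annotations refer to.
    strata, baseline, k, mwu_mode
        Which context strata to run, which one anchors the rank-shift test,
        the top-k cutoff, and the Mann-Whitney sample construction
        (``"best"`` or ``"pooled"``).
    """

    def __init__(
        self,
        annotations: Sequence[AnnotationRecord],
        diagnoses: Mapping[str, str],
        ontology: Ontology,
        strata: Sequence[Stratum] = DEFAULT_STRATA,
        baseline: Stratum = Stratum.ALL,
        k: int = 10,
        mwu_mode: str = "best",
    ) -> None:
        self.annotations = list(annotations)
        self.diagnoses = dict(diagnoses)
        self.ontology = ontology
        self.strata = tuple(Stratum.from_label(s) for s in strata)
        self.baseline = Stratum.from_label(baseline)
        if self.baseline not in self.strata:
            raise ValueError("baseline must be among the requested strata")
        self.k = k
        self.mwu_mode = mwu_mode

    @classmethod
    def from_files(
        cls,
        ontology: str | Path,
        annotations: str | Path,
        diagnoses: str | Path,
        **kwargs,
    ) -> "SimilarityExperiment":
        ont = load_ontology(ontology)
        ann = _corpus.read_annotations(annotations)
        dx = _corpus.read_diagnoses(diagnoses)
        return cls(ann, dx, ont, **kwargs)

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "SimilarityExperiment":
        return cls.from_files(
            cfg.ontology,
            cfg.annotations,
            cfg.diagnoses,
            strata=cfg.strata,
            baseline=cfg.baseline,
            k=cfg.k,
            mwu_mode=cfg.mwu_mode,
        )

    def _run_stratum(self, stratum: Stratum) -> tuple[ProfileSet, SimilarityMatrix]:
        logger.info("stratum %s: building profiles", stratum.value)
        ps = _corpus.build_profiles(
            self.annotations, self.diagnoses, self.ontology, stratum
        )
        # IC must come from this stratum's own corpus, never be reused
        ict = _sim.compute_ic(ps, self.ontology)
        logger.info(
            "stratum %s: %d kept annotations, %d terms in IC table",
            stratum.value, ps.kept_annotation_count, len(ict.ic),
        )
        return ps, _sim.all_pairs(ps, ict, self.ontology)

    def fit(self) -> ExperimentResults:
        """Run every stratum and evaluate against the baseline rankings."""
        counts = _corpus.count_annotations(self.annotations)
        logger.info("annotation counts: %s", counts)

        order = [self.baseline] + [s for s in self.strata if s is not self.baseline]
        profile_sets: dict[Stratum, ProfileSet] = {}
        matrices: dict[Stratum, SimilarityMatrix] = {}
        baseline_rankings: list[LocalRanking] | None = None
        reports: dict[Stratum, EvaluationReport] = {}

        for stratum in order:
            ps, m = self._run_stratum(stratum)
            profile_sets[stratum] = ps
            matrices[stratum] = m
            reports[stratum] = _eval.evaluate_stratum(
                m,
                ps,
                baseline_rankings=None if stratum is self.baseline else baseline_rankings,
                k=self.k,
                mwu_mode=self.mwu_mode,
            )
            if stratum is self.baseline:
                baseline_rankings = _eval.local_rankings(m, ps)

        ordered_reports = {s: reports[s] for s in self.strata}
        return ExperimentResults(
            reports=ordered_reports,
            counts=counts,
            kept_counts={s: profile_sets[s].kept_annotation_count for s in self.strata},
            matrices={s: matrices[s] for s in self.strata},
            profile_sets={s: profile_sets[s] for s in self.strata},
            baseline=self.baseline,
            k=self.k,
        )


def run_experiment(cfg: RunConfig) -> ExperimentResults:
    """Load inputs per ``cfg``, fit the experiment, and write all outputs."""
    logging.basicConfig(level=cfg.log_level)
    try:
        model = SimilarityExperiment.from_config(cfg)
    except Exception as e:
        raise RuntimeError(f"experiment aborted while loading inputs: {e}") from e
    results = model.fit()
    results.save(cfg.out_dir)
    return results
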