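# Methods

## Problem and pipeline

`ppsim` measures how context disambiguation — the removal of negated and
uncertain concept mentions — affects ontology-based similarity of patient
visit phenotype profiles, and the use of that similarity to rank visits by
shared primary diagnosis. The pipeline, per stratum:

1. filter the annotation list (`all`, `no-neg`, `no-unc`, `no-neg-no-unc`);
2. collapse surviving mentions into per-visit term **sets** (profiles);
3. compute corpus information content **on that stratum's corpus**;
4. compute the all-vs-all Best-Match-Average Resnik similarity matrix;
5. evaluate global AUC, local MRR / A@10, and the Mann–Whitney rank-shift
   test against the `all` baseline.

## Model conventions

**Profiles are sets.** Duplicate mentions of a term in one visit collapse;
mention multiplicity does not enter the similarity. Each mention is filtered
independently, so a term mentioned both plainly and negated in one visit
survives negation filtering through its plain mention.

**Empty profiles are retained.** A visit whose profile is emptied by
filtering stays in the cohort with similarity 0 to every other visit, so all
four strata rank the same visits and their metrics are comparable. Such
profiles do not count toward the IC corpus size N (an empty profile carries
no annotations and is not evidence about term frequency).

**Information content.** `IC(t) = −ln(n(t)/N)` with presence-based,
ancestor-propagated counting: a profile containing `t` contributes one count
to `t` and every ancestor. Natural log; the base only rescales all scores
and cancels in every rank-based metric. Terms never observed in a corpus
are absent from its IC table and contribute IC 0 wherever consulted (this
can only happen for fixture edge cases or cross-stratum queries; every term
actually annotated in the corpus is observed by construction). Ancestor
closure is reflexive, so `resnik(t, t) = IC(t)` and `BMA(A, A)` equals the
mean IC of `A`.

**Per-stratum IC is enforced.** Reusing the baseline's IC table for a
filtered stratum is the easiest silent bug in this design; `ICTable`
carries a stratum tag and the matrix builder refuses a mismatch.

**Rankings and ties.** Local rankings sort by score descending with ties
broken by ascending visit id, making every ranking bit-reproducible. Global
AUC uses midranks (Mann–Whitney with tie correction), so an all-tied score
list scores 0.5. The AUC interval is the Hanley–McNeil normal
approximation at 95%; it is a standard choice, not the only one, and is
labelled as this package's convention.

**Rank-shift test.** Default sample construction takes, per evaluable focal
visit, the rank of its *best* same-diagnosis match; a `pooled` mode using
all same-diagnosis ranks is available (`--mwu-mode pooled`). Two-sided,
tie-corrected; scipy's exact null is used automatically for small untied
samples. Visits with no same-diagnosis partner in the cohort are excluded
from MRR/A@10/rank-shift samples and reported via `n_evaluable`.

**Unordered pairs.** BMA is symmetric, so the global ranking uses each
unordered pair once and excludes self-pairs.

## Synthetic cohorts

Real critical-care text corpora with phenotype annotations are
access-restricted, so the generator emulates their statistical shape:

- a random rooted ontology tree (500 terms, branching cap 3 in the presets);
- each diagnosis owns a **signature** of 8 terms drawn from one subtree, so
  same-diagnosis profiles are ontologically clustered — a depth-sensitive
  MICA measure cannot separate diagnoses whose signatures are uniform over
  the ontology, since their common ancestors collapse to the root;
- each visit draws a diagnosis uniformly, emits each signature term affirmed
  with probability 0.5, plus Poisson(15) uniform background terms;
- negated mentions arrive at Poisson(8) per visit and uncertain at
  Poisson(3), with a negated mention also flagged uncertain with
  probability 0.04 — these per-visit rates mirror the published annotation
  table of the cohort this design emulates (≈44 mentions per visit, ≈8
  negated, ≈3 uncertain, dual fraction ≈0.04);
- `noise` mode draws context-flagged terms uniformly (pure clutter);
  `signal` mode draws them from the signatures of two fixed *differential*
  diagnoses per diagnosis (conditions being ruled out), making them
  diagnosis-informative.

Presets use 300 visits and 30 diagnoses. The visit count is a deliberately
desk-scale cohort; the diagnosis count and signature parameters were chosen
once so that the baseline (`all`) operating point falls in the regime the
methodology typically reports on real data (AUC ≈ 0.74, MRR ≈ 0.34,
A@10 ≈ 0.73 here) — with many fewer diagnoses, every visit has dozens of
same-diagnosis partners and A@10 saturates near 1.0, leaving no headroom to
observe filtering effects. Generation is byte-reproducible from the spec's
seed.

What the generator does **not** model: real clinical language, annotation
error from concept recognition, repeated patients across visits (a stated
bias of visit-level sampling on real data), heavy-tailed per-visit mention
counts, and ICD-style diagnosis hierarchies. Passing tests on these cohorts
demonstrates that the pipeline recovers a planted effect in the direction
and significance expected — not that any particular effect size transfers
to a given clinical dataset.

## Replicate studies

- **Filtering effect** (`filtering_effect_replicates`): regenerate a
  scenario over a seed list (tests use 50 replicates; the acceptance script
  30) and compare `no-neg` vs `all` per replicate; the pooled rank-shift
  test concatenates best-true-match ranks across replicates. Under the
  noise preset filtering improves AUC in essentially every replicate; under
  the signal preset the mean AUC effect is negative.
- **Null calibration** (`null_label_shuffle_study`): one cohort with
  signature probability 0 (diagnosis carries no signal), similarity
  matrices fixed, diagnosis labels permuted 200 times. Matrices and local
  orderings are label-free, so they are computed once and only the labels
  move; mean AUC sits at 0.5 within Monte-Carlo error and the rank-shift
  test stays non-significant at 0.01 in ≥95% of shuffles.

## Degenerate inputs and errors

Cyclic ontologies, multiple roots, and dangling parent references are hard
errors at load; unknown terms and unlabelled visits are hard errors at
profile construction; AUC requires at least one true and one false pair;
the rank-shift test requires two evaluable visits per side; an all-empty
stratum has no corpus and refuses to produce an IC table.

## Known limitations

- The dense all-pairs matrix is quadratic in cohort size; it is intended
  for cohorts up to a few thousand visits.
- Only `is_a` subsumption is used; other ontology relations are ignored
  with a warning.
- Alternative pairwise measures (Lin, Jiang–Conrath, Wang) and
  context-weighted similarity combining affirmed/negated/uncertain scores
  are out of scope.
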