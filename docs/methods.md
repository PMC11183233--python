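# Methods

## The curation problem and the role model

A gene-expression *series* is a study with samples described by free-text
characteristic lines (`tissue: liver`, `treatment: vehicle`, …).  A
*design call* (annotation) partitions a subset of samples into a control
group and a perturbation group and names the perturbation (its type —
drug, disease or gene manipulation — its name, and the cell type).  One
series may contain several designs (e.g. separate dose arms sharing a
control group).

The pipeline assigns one role per stage of a waterfall data flow:
annotator → result checker → prompt optimizer (a negative-feedback loop
over the annotator's prompt) → corpus-scale annotation by the surviving
*optimal annotator* → quality controller.  Roles exchange structured
payloads and must answer in a fixed JSON schema; free-form answers get
one re-prompt retry and are then recorded as unparseable failures rather
than exceptions, so a single bad response never aborts a corpus run.

## Quality-control criteria

An annotation passes QC only if all three criteria hold:

1. **Alignment.**  For every normalized characteristic key that is
   neither in the sex/age ignore class nor the designated perturbation
   key, the *set* of values observed in the control group equals the set
   observed in the perturbation group.  Sets rather than multisets:
   replicate counts legitimately differ between groups.  Sex and age are
   expressly ignored (the ignore class ships with configurable synonym
   lists: {sex, gender}, {age, age (years), …}).
2. **Uniformity.**  Samples of the same type are consolidated: no
   unassigned sample may share the full non-ignored characteristic
   profile of an assigned sample, and neither group may mix two distinct
   perturbation-key values.  The mixing rule is unconditional — a mixed
   group can always be split into homogeneous groups, so mixing is never
   accepted.
3. **Perturbation assignment.**  The perturbation type is a valid enum
   value, the perturbation name is non-empty and occurs
   (case-insensitive substring, optional synonym table, deliberately no
   fuzzy matching) in the perturbation-group sample metadata, and the
   direction is right: the control group's perturbation-key value must
   not carry the perturbation name.

The *perturbation key* is the characteristic encoding the intervention
itself.  Synthetic corpora label it; otherwise the engine takes the
first key whose name or perturbation-group values mention the
perturbation name, then the unique key whose control and perturbation
value sets are disjoint, and otherwise evaluates criterion 1 over all
non-ignored keys with criterion 3 falling back to free-text search.
Annotations referencing unknown sample ids are a hard Fail.

The same judgement can be delegated to an LLM channel.  The offline mock
implementation returns the rule verdict flipped with a configured
Bernoulli disagreement probability (drawn from a stable hash of seed,
annotation reference and QC round, so verdicts are order-invariant),
which lets the consistency machinery be tested at any target level.
Consensus across channels/rounds: two agreeing verdicts decide; a
disagreement triggers exactly one re-annotation round, whose two
verdicts decide, with a third QC draw and majority rule if they disagree
again.

## Metrics

QCC is the fraction of annotations whose two QC channels agree on final
status (status only, not per-criterion flags).  APR is the fraction of
annotations passing; DPR the fraction of datasets with ≥ 1 passing
annotation.  Undefined proportions (empty denominators) raise rather
than reporting 0.  The manual-vs-automatic cross-tabulation counts
{Excellent, Moderate} ↔ Success and Error ↔ Fail as the two agreement
cells — an Error/Fail cell means the controller correctly caught a bad
grouping.

## Mock backend and prompt optimization

The mock annotator is rule-based, not a language model: it scans
normalized characteristics for the first non-ignored key that varies and
contains a control-like value (vehicle, wild type, healthy, …), assigns
those samples to the control group, and infers the perturbation type
from the key name.  Prompt "optimization" is made measurable by gating
rule classes on the template: version 0 is dose-blind (all perturbed
samples merged into one group); the optimizer appends the directive
sentence matching the dominant discrepancy field and bumps the version,
which activates per-value (dose-aware) grouping.  The optimizer edits
instruction text only, never the system text.  Its only sources of wrong
answers are the explicit error plan (group swaps, name variants) — so
tests always know ground truth.  Training iterates annotate → check →
optimize with a default budget of 5 revisions and target discrepancy
rate 0; the discrepancy rate is total discrepancies over gold design
calls.

Gold matching pairs each annotation with the gold record maximizing
Jaccard similarity of the combined sample-id set (ties: perturbation-name
equality, then gold order).  A control/perturbation swap is one
conceptual error and yields a single grouping discrepancy; direction
correctness is separately the job of QC criterion 3.

A live OpenAI-compatible backend exists behind the same contract
(bounded retries, pinned temperature 0) but nothing in the pipeline or
tests requires it.

## Synthetic corpora

The generator emulates drug/gene/disease perturbation studies: 2–4
samples per group by default, one perturbation key plus tissue, cell
line, age and sex characteristics, templated title/summary/design text
mentioning the perturbation.  Error classes are injected per series at
configured rates with bookkeeping labels: `confounder` (tissue differs
between groups), `multiple_disturbances` (a second agent varies with the
primary one), `swap` and `name_inconsistency` (annotator-level edits),
and `age_difference`, which is deliberately benign — it encodes the
sex/age ignore rule as a testable property.  Every rule-QC failure on a
generated corpus must map to an injected non-benign label; clean corpora
produce zero failures.

What the generator does **not** emulate: real GEO prose style and
vocabulary drift, missing or contradictory characteristics, platform
heterogeneity, and genuine language-model failure modes beyond the
labelled classes.  Passing tests therefore demonstrate the correctness
of the QC engine, metrics, and workflow machinery under known ground
truth — not annotation accuracy on real free text.

## Signatures and connectivity

Differential expression is one standardized procedure for both
platforms: counts are library-size normalized to CPM and log2(x+1)
transformed (microarray intensities are taken as already log-scale), and
each gene receives a Welch t statistic (perturbation minus control;
≥ 2 replicates per group required; genes with zero variance in both
groups are dropped).  Connectivity between two signatures is Spearman
correlation over the union of each signature's 250 strongest-|t| genes
restricted to shared genes (≥ 10 required); significance is a two-sided
gene-label permutation test (default 10,000 draws, mandatory seed), and
library screens apply Benjamini–Hochberg across targets and sort by
correlation.  Spearman rather than Pearson because rank correlation is
robust to the scale differences between microarray and RNA-seq
statistics.  Perfect rank agreement/reversal is reported as exactly ±1.

Numerical note: when top-gene selection is active the permutation null
is conservative (the selected gene set is coupled to the observed
values), a known property of connectivity-style scores; the null
calibration check therefore runs in the exchangeable regime with
selection disabled (`n_top` covering all genes), where permutation
p-values are exactly uniform.

## Problem sizes and numerical choices

Verification runs use corpora of 200–2,000 series for QC and calibration
properties, 300 series for injection recovery, 500 random small series
(≤ 6 samples, ≤ 4 keys) against the brute-force criterion checker, 500
replicates for null-p uniformity (499 permutations each) and 300 seeded
replicates for planted-pair sign recovery at 1-sd effects over 200
genes.  QC-consistency calibration is judged against two-sided binomial
99% bounds at n = 2,000.  All randomness is integer-seeded through
`numpy.random.default_rng` and stable hashes; nothing depends on Python
hash ordering, so runs are byte-reproducible across platforms.

## Known limitations

- Criterion 1 compares value sets group-wise; per-sample pairwise
  matching (an alternative reading of "characteristics match") would be
  stricter on heterogeneous groups.
- The re-annotation round with a deterministic annotator reproduces the
  round-1 annotation; only the QC draws differ.  With a live backend the
  second round can genuinely revise the design call.
- The ATC-style corpus harvesting, hosted databases and live-model cost
  accounting that a production deployment would add are out of scope;
  the package stops at the run report and connectivity tables.
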