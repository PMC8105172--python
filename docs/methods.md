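# Methods

This note records the evaluation model implemented by `idrbench`, the
conventions and numerical choices it fixes, what the synthetic generator
does and does not emulate, and the design decisions that were genuinely
open.

## Reference model

A benchmark target is a protein sequence with interval annotations
(1-based, inclusive) in up to three classes: experimentally verified
disorder, binding regions, and residues observed in experimental
structures.  Intervals within one class are silently merged to a sorted,
non-overlapping canonical form; this never changes residue membership.
Conflicts *across* classes are resolved by a single precedence rule:
disorder always overwrites structure.  Three references follow:

- **disprot** — positives are disorder residues, everything else negative.
  The negative set is therefore optimistic: unannotated residues are not
  known to be ordered, merely not annotated.
- **disprot_pdb** — negatives are restricted to residues actually observed
  in a structure (and not disorder-annotated); everything else is masked
  and excluded from all counting.  This trades coverage for label
  confidence.  No attempt is made to filter disorder annotations that fall
  inside resolved structures; the precedence rule handles the overlap.
- **binding** — positives are binding residues; targets without binding
  annotations stay in the reference as all-negative entries, because a
  binding predictor must be penalized for calling binding where none is
  annotated.

Targets present in the sequence collection but carrying no annotation are
retained (all-negative, or all-masked under `disprot_pdb`).  Every build
asserts the partition invariant |positive| + |negative| + |masked| =
length.

## Prediction conventions

Scores are rounded half-up on the decimal representation to 3 decimals,
giving 1001 representable values; rounding is idempotent.  Classification
is non-strict: `score ≥ threshold` is positive.  The threshold is resolved
in priority order: inferred from submitted binary states as the minimum
score among state-positive residues across the whole set (with the
inconsistency count logged when the ≥ rule does not reproduce the
submitted states — ties at the threshold score with differing states are
reported, not guessed at); otherwise the method's declared threshold;
otherwise 0.5.  When scores are absent, states are used as scores
verbatim; when states are absent they are derived at the resolved
threshold.

One deliberate exception: the Conservation baseline is specified with a
strict rule (score > 0.4 is disordered), so its emitted states use the
strict rule while its stored threshold remains 0.4.  At the evaluation
level this matters only for residues scoring exactly 0.400.

## Metrics

All metrics follow the standard confusion-matrix definitions.  The
degenerate cases are absorbed by conventions rather than NaNs: F-beta
(0.5, 1, 2) and any rate with a zero denominator are set to 0, and MCC is
set to 0 whenever any of the four marginals (reference positives/negatives,
predicted positives/negatives) is empty.  The MCC convention matters
particularly under the target strategy, where fully disordered targets (no
reference negatives) and all-one-class predictions are common and pull the
mean MCC down by construction.  Each `MetricSet` records which conventions
fired.

Curves are evaluated on the fixed grid {0.000, …, 1.000} with step 0.001;
since scores live on the same grid after rounding, the grid scan is
exhaustive — grid F_max provably equals the brute-force maximum of F1 over
all distinct score thresholds (and the tests check this on random
fixtures).  F_max ties resolve to the lowest threshold, which maximizes
recall at equal F1 and makes reports deterministic.  AUC is the
trapezoidal area over the ROC points augmented with (0,0) and (1,1), so
degenerate score distributions still integrate to a defined area; tied
scores produce diagonal segments whose area equals the ½·P(tie) correction
of the rank statistic.

Two aggregation strategies: *dataset* concatenates all unmasked residues
(equivalently, sums per-target confusion matrices — asserted exactly);
*target* computes each metric per target and takes the unweighted mean
("mean value" is read as unweighted; no length weighting).  Under the
target strategy the curve columns are per-threshold means and AUC is
integrated over the averaged ROC points (a macro-average).  Whether AUC
should be computed on the grid or on all distinct scores is
underdetermined; the grid is used, and the monotone-transform invariance
test bounds the discrepancy at zero for grid-valued scores.

## Bootstrap and significance

Uncertainty is estimated by resampling residues — concatenated (label,
score) pairs — with replacement 1000 times.  Because residues are
exchangeable, the resample is drawn as a multinomial over the joint
label × score-bin histogram (2 × 1001 cells), which is distribution-exact
and orders of magnitude faster than index resampling.  The confidence
interval is `replicate mean ± t(0.975, n_boot−1) × replicate standard
deviation` (the replicate standard deviation *is* the bootstrap standard
error, so it is not divided by √n_boot); alpha is 0.05.  Replicates where
a convention fires are counted and flagged.  CI width empirically scales
as 1/√k under k-fold dataset duplication, which the tests verify.

Method pairs are compared with a two-tailed paired t-test.  Pairing is
over bootstrap replicates by replicate index (each method is resampled
with the same seed); pairing over per-target values is available by
passing per-target vectors to the same function.  Zero-variance
differences are degenerate: p = 1 for equal means, 0-limit (logged)
otherwise.

## Baselines

- **Random** — i.i.d. uniform scores, threshold 0.5.  Expected AUC 0.5.
- **Shuffled** — a global permutation of the unmasked reference labels,
  emitted as binary scores.  Dataset-level prevalence is preserved exactly;
  per-target composition is not.  Masked positions sit outside the
  permutation pool and receive score 0, which is inert because masked
  residues never enter any metric.
- **Conservation** — per-position Jensen–Shannon divergence (base-2
  logarithms, 0·log 0 ≡ 0, clamped to [0, 1]) between the target's
  homolog-derived frequency profile and the BLOSUM62 marginal amino-acid
  frequencies (shipped with the package, overridable).  The literal rule —
  JSD > 0.4 means disordered — is implemented as specified, although the
  biological rationale (IDRs are less conserved) suggests the opposite
  direction; an `invert` flag emits 1 − JSD for users who want the other
  reading.  The package does not guess which direction a given assessment
  actually ran.
- **Structure complement** — residues outside all observed-structure
  intervals score 1.0, inside 0.0; a target with no structure record is
  entirely "disordered".  Variants based on the target's own structures,
  close homologs (≥30% identity), remote homologs (20–30%) or predicted
  domains differ only in the provenance of the coverage intervals supplied;
  homology searches themselves are out of scope and consumed as files.

## Fully-disordered-protein challenge

A target is an annotated IDP when ≥ 95% of its residues (over the full
length) are disorder-annotated, and a predicted IDP when the fraction of
state-positive residues at the method's resolved threshold reaches the
same cut-off.  "At least" is used on both sides; the threshold is
configurable since nearby values are known not to change rankings much.
Methods are ranked by protein-level F1, ties broken by method name.
The published confusion table for this challenge (34 methods × TN/FP/FN/TP
plus six metric columns, 646 targets, 45 annotated IDPs) ships with the
package as an exact test vector for the metric conventions.

## Synthetic data

The generator emulates the *structure* of the benchmark inputs, not their
biology.  Defaults mirror the real benchmark's composition: 646 targets,
exactly 40 fully disordered (≥95%), 232 with a binding region placed
strictly inside a disorder region, disorder intervals of at least 10
residues (the curation minimum).  Target lengths are log-normal (median
250, σ = 0.6, clipped to [30, 2500]) — a scale choice, not a fit to any
database.  Non-IDP targets aim for 25% disordered residues, placed by
rejection sampling with a hard attempt cap; an infeasible density raises
rather than silently under-filling, and ground truth is recorded by
recounting the emitted intervals, never by trusting the request.  Ordered
runs are covered by structure intervals with probability 0.8, bleeding a
few residues into adjacent disorder with probability 0.3 to exercise the
precedence rule.

Sequences are uniform over the 20 amino acids, and synthetic predictor
scores are class-conditional (Beta or point-mass distributions), i.e.
i.i.d. given the label.  Real predictors make spatially correlated errors
and real disorder has compositional bias, so passing calibration tests
here demonstrates correctness of the *evaluation machinery*, not expected
performance of any real method on real data.  The noisy-predictor AUC
oracle P(S⁺ > S⁻) + ½P(S⁺ = S⁻) is computed by exact summation over the
rounded-score grid and checked against the measured AUC at ~10⁵ residues
(agreement within 0.01).  Profile generation mixes the background with a
per-position point mass at weight equal to the contrast parameter, so the
Conservation baseline's signal is tunable from none (contrast 0) to
near-perfect separation.

## Problem sizes and runtime

The test suite and the acceptance script are sized for a laptop-class
single core: calibration checks use a ~1.1 × 10⁵-residue synthetic
benchmark (200 targets), the brute-force F_max oracle runs on 100 fixtures
of up to 10³ residues, bootstraps use the full 1000 replicates (the
multinomial trick makes them cheap), and the protein-level challenge uses
the full 646-target composition.  The complete suite runs in a few
seconds.

## Known limitations

- The artifact consumes precomputed interval/profile files; it does not
  run homology searches, map structures onto sequences, or curate
  annotations.  Partial structure mappings are assumed already expressed
  in target coordinates.
- The target-strategy AUC is a macro-average over per-target ROC points;
  other definitions (mean of per-target AUCs) would differ for
  heterogeneous targets.
- The Conservation baseline's direction ambiguity is exposed, not
  resolved.
- `--threads` parallelizes per-method evaluation only; per-target work is
  independent by contract but executed vectorized rather than threaded.
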