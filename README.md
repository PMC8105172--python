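# idrbench

An assessment toolkit for residue-level predictors of protein intrinsic
disorder and of disordered binding regions.

Intrinsically disordered proteins and regions (IDPs/IDRs) lack a stable
three-dimensional fold; predictors assign each residue of a protein a score
in [0, 1] (and often a binary state) for being disordered.  Benchmarking
such predictors fairly is mostly a bookkeeping problem — how positive and
negative residues are defined, what is excluded, how thresholds are chosen,
and how uncertainty is estimated — and this package implements that
bookkeeping as a reusable library plus CLI, for assessors running a
community benchmark and for method developers who want to evaluate exactly
the way the community challenges do.

## What it computes

**Reference sets.**  From per-target interval annotations (1-based,
inclusive) of *disorder*, *binding* and *structure-observed* residues,
three residue-level references are built:

- `disprot` — disorder-annotated residues are positive, all others negative;
- `disprot_pdb` — positives as above (disorder always overwrites
  structure), negatives only where an experimental structure was observed,
  and residues covered by neither are **masked**: excluded from every count;
- `binding` — binding-annotated residues are positive; targets with no
  binding annotation are kept as all-negative entries.

**Metrics.**  Predicted states come from `score ≥ threshold`, where the
threshold is inferred from the submitted states (minimum score among
state-positive residues), or declared by the method, or 0.5.  Scores are
rounded half-up to 3 decimals, and curves are evaluated on the full
threshold grid {0.000, 0.001, …, 1.000}.  The headline statistics are

- *F_max* = max over thresholds of F1 = 2·TP / (2·TP + FP + FN),
- AUC of the ROC curve (trapezoidal, endpoints (0,0) and (1,1) appended),
- MCC, balanced accuracy, precision/recall/specificity, F0.5, F2,

with explicit conventions: any metric with a zero denominator is 0, and
MCC is 0 whenever any confusion-matrix marginal is empty.  Metrics are
computed under a *dataset* strategy (all residues concatenated) and a
*target* strategy (unweighted mean of per-target values).  Uncertainty
comes from a residue-level bootstrap (1000 resamples, Student-t 95%
intervals) and methods are compared with two-tailed paired t-tests.

**Baselines.**  Random (uniform scores, threshold 0.5), Shuffled dataset
(global label permutation — preserves dataset prevalence, not per-target
composition), Conservation (base-2 Jensen–Shannon divergence between a
target's homolog-derived residue-frequency profile and the BLOSUM62
background frequencies, positive when > 0.4), and structure-complement
baselines (whatever lacks an observed structure is called disordered).

**Challenges.**  Disorder and binding challenges rank methods by F_max;
the fully-disordered-protein (IDP) challenge calls a protein disordered
when ≥ 95% of its residues are annotated (or predicted) disordered and
ranks methods by protein-level F1.

**Synthetic fixtures.**  `idrbench.synthetic` generates complete inputs —
sequences, annotations, frequency profiles, and noisy predictors with an
analytically known expected AUC — so the whole pipeline runs and is tested
without any external download.

## Worked example

```python
import numpy as np
from idrbench.references import TargetSequence, IntervalAnnotation, build_reference
from idrbench.predictions import PredictionEntry, PredictionSet, resolve_threshold
from idrbench.metrics import curves, evaluate_at_threshold, bootstrap_metric

targets = [TargetSequence("P1", "MKVAYHLQERTGDSAWPNCI" * 5)]
anns = [IntervalAnnotation("P1", "disorder", [(1, 30), (71, 100)]),
        IntervalAnnotation("P1", "structure_observed", [(37, 68)])]
ref = build_reference(targets, anns, "disprot_pdb")

rng = np.random.default_rng(0)
truth = ref.entries["P1"].labels == 1
scores = np.where(truth, rng.beta(4, 2, 100), rng.beta(2, 4, 100))
pset = PredictionSet("demo", declared_threshold=0.5)
pset.entries["P1"] = PredictionEntry("P1", scores.round(3))
resolve_threshold(pset)

cm, mset = evaluate_at_threshold(ref, pset, "dataset")
cs = curves(ref, pset, "dataset")
boot = bootstrap_metric(ref, pset, "f1", seed=0)
print(f"confusion: tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn} masked={cm.masked}")
print(f"F1={mset.f1:.3f}  MCC={mset.mcc:.3f}  BAC={mset.bac:.3f}")
print(f"F_max={cs.f_max:.3f} at threshold {cs.f_max_threshold:.3f}; AUC={cs.auc:.3f}")
print(f"bootstrap F1 95% CI: [{boot.ci_low:.3f}, {boot.ci_high:.3f}]")
```

prints

```
confusion: tp=47 fp=6 fn=13 tn=26 masked=8
F1=0.832  MCC=0.574  BAC=0.798
F_max=0.872 at threshold 0.361; AUC=0.892
bootstrap F1 95% CI: [0.754, 0.907]
```

Of the 100 residues, 60 are disorder-positive, 32 structure-negative and 8
(positions 31–36 and 69–70, covered by neither annotation) are masked and
play no role in any number.  The noisy demo predictor recovers most
positives at its 0.5 threshold (F1 = 0.832); scanning all thresholds finds
a better operating point at 0.361 (F_max = 0.872), and the residue-level
bootstrap brackets the F1 estimate.

The same flow is available from the shell:

```bash
idrbench fixtures --outdir fix --n-targets 50 --seed 4
idrbench build-ref --fasta fix/targets.fasta --annotations fix/annotations.tsv \
    --mode disprot_pdb --out ref.txt
idrbench baseline --kind random --fasta fix/targets.fasta --seed 9 --out random.caid
idrbench evaluate --fasta fix/targets.fasta --annotations fix/annotations.tsv \
    --mode disprot --predictions fix/synthetic-predictor.caid \
    --predictions random.caid --out report/
idrbench idp --fasta fix/targets.fasta --annotations fix/annotations.tsv \
    --predictions fix/synthetic-predictor.caid --out idp.tsv
```

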