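# gbmsig

Pathway-constrained discovery and survival validation of multigene
prognostic signatures from tumour expression data, with glioblastoma
(GBM) progression as the motivating setting.

## The problem

After surgery plus adjuvant chemoradiation, GBM patients progress at very
different speeds. A gene-expression signature that separates rapid from
slow progressors — and keeps its prognostic value on patients it was never
fitted on — is useful both for stratifying patients and for nominating
resistance-related target genes. `gbmsig` implements the full discovery
procedure as a reproducible pipeline:

1. **Variance filter** — keep genes with unscaled median absolute deviation
   MAD ≥ 0.5 on the log2 matrix.
2. **Batch check** — guided principal component analysis (gPCA): the ratio
   δ of the batch-guided to unguided leading singular variance, with a
   permutation p-value.
3. **Pathway restriction** — candidate genes are limited to gene sets that
   are over-represented among the high-variance genes (exact hypergeometric
   upper-tail test, Benjamini–Hochberg correction) and belong to a curated
   allowlist of resistance-relevant categories.
4. **Progression classes** — patients with uncensored progression-free
   survival (PFS) inside an eligibility window are split at the Q1/Q3
   quartiles: class 1 (rapid, PFS ≤ Q1), class 2 (slow, PFS > Q3), class 3
   (intermediate) held out.
5. **Modified SVM-RFE** — recursive feature elimination with a linear
   soft-margin SVM (cost C = 10): features are ranked by w² and the
   lowest-ranked 10% dropped per recursion, while a stratified 5-fold
   cross-validated error rate is recorded at every level (the elimination
   is re-run inside each training fold, so the estimate is not biased by
   selection). The signature is the level with minimal CV error, ties going
   to the fewer genes.
6. **Prognostic index** — per-gene Cox proportional-hazards coefficients
   β_g are fitted on the held-out class 3; each sample gets
   PI = Σ_g β_g · x_g, and the median PI splits samples into low- and
   high-risk groups.
7. **Validation** — Kaplan–Meier curves with Greenwood/log(−log) intervals
   and Brookmeyer–Crowley median CIs, the log-rank test, two-group Cox
   hazard ratios (HR = exp β), per-subtype strata, a frozen-β transfer to
   an external cohort, and a univariate-plus-multivariate Cox model
   (risk group, age, MGMT methylation) testing the signature's
   independence.

Because the original tumour cohorts cannot be redistributed, the package
ships a first-class synthetic-cohort generator
(`gbmsig.simulate`) that plants a known signature: expression shifts an
exponential proportional-hazards model through a linear predictor
η = Σ β_true·z, with calibrated uniform right-censoring, optional batch
shifts, and a GMT collection whose "resistance" sets concentrate the
planted genes. Every stage of the pipeline is tested against it.

## Worked example

```python
from gbmsig.pipeline import PipelineConfig, SimulationSettings, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationSettings(
        n_samples=300, n_genes=600, n_signature_genes=20,
        effect_size=3.0, censoring_rate=0.2),
    out_dir="demo_run", seed=7)
manifest = run_pipeline(cfg)
```

On this cohort (20 planted genes whose joint standardized log-hazard shift
is 3) the run prints, via the manifest:

```
high-variance genes : 359
batch-effect p      : 0.85
candidate pool      : 109
classes (rapid/slow/intermediate): 41 41 82
signature size      : 50
CV error at optimum : 0.39
held-out PFS        : median low 111 vs high 63 days, log-rank p=0.00056, HR=2.22
```

Read: no batch effect is detected (p = 0.85); the pathway filter reduces
600 genes to 109 candidates; SVM-RFE's minimal-error level keeps 50 genes
(survival-derived classes are noisy, so the two classes are only partially
separable — CV error 0.39); yet the prognostic index built from those genes
on the held-out intermediate patients splits them into risk groups whose
median PFS differs by nearly a factor of two, with a log-rank p of 5.6×10⁻⁴
and a hazard ratio of 2.2 for the high-risk group. All outputs (trace,
signature, risk tables, KM summaries, multivariate report, manifest) are
plain TSV/JSON files under `demo_run/`.

The same stages are available as shell commands
(`gbmsig simulate | filter | enrich | select | score | survive | report |
pipeline`).

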