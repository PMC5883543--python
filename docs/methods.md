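# Methods

## Synthetic cohort model

The generator (`gbmsig.simulate`) produces the data-generating structure
the analysis assumes, not a facsimile of any real cohort.

**Expression.** Gene g of sample i is x_gi = μ_g + σ_g z_gi with
μ_g ~ U(5, 10) (log2 microarray scale), σ_g ~ U(0.3, 1.5) and
z_gi ~ N(0, 1), i.i.d. across genes. Planted signature genes draw
σ_g ~ U(0.9, 1.5), so their unscaled MAD (≈ 0.674 σ) clears the default
0.5 filter: prognostic genes are discoverable downstream of a variance
filter, as they must be in the real procedure.

**Survival.** The linear predictor is η_i = Σ_g β_g z_gi over the
signature genes (standardized expression, so β is scale-free). PFS is
exponential with hazard h₀·exp(η); overall survival adds an independent
second exponential stage with the same η, guaranteeing OS > PFS. The
default baseline hazard h₀ = 1/300 events/day puts the η = 0 median
time-to-progression near 200 days, the scale of GBM PFS. When `beta_true`
is not supplied, each of the k signature genes gets β = effect_size/√k, so
`effect_size` is the SD of η — the standardized hazard shift of the whole
signature. (The two-class generator `simulate_two_class` instead applies
`effect_size` per gene as a between-class mean shift in within-class SD
units; its conditions are stated per gene wherever it is used.)

**Censoring.** C ~ U(0, c) independently per endpoint, with c calibrated
by bisection so that the expected censored fraction E[min(t, c)/c] over
the drawn event times equals the target rate. Simple, monotone and
bit-reproducible.

**Batches.** Batch labels are assigned round-robin over the η ranking, so
batch and planted signal are unconfounded by construction; an optional
additive shift of `batch_shift` per-gene SDs separates the extreme
batches.

**Gene sets.** The planted genes are spread round-robin over the first
⌊n_gene_sets/2⌋ "resistance" sets. Resistance-set filler genes are drawn
from the high-variance half of the genome and background-set members from
all genes — i.e. resistance pathways are variance-coherent, which is what
makes them genuinely over-represented among the genes passing the MAD
filter. Without this coherence the enrichment stage would have nothing to
find, because in this generator variance and set membership would be
independent by construction.

**What the generator does not emulate:** probe-level artefacts and RMA
normalization, gene–gene correlation beyond the shared hazard link,
non-proportional hazards, informative censoring, subtype-specific effect
sizes, and platform differences beyond location/scale (the transfer step
absorbs only those via per-gene z-scaling). Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
performance on real tumour cohorts.

## Preprocessing

MAD is unscaled (no 1.4826 consistency factor) with an inclusive ≥ 0.5
cutoff on log2 data. Quartiles for the progression classes use linear
interpolation (NumPy default, R type 7); the convention is configurable.
Class boundaries: class 1 is PFS ≤ Q1 (inclusive, since the rapid class's
upper limit equals Q1), class 2 is PFS > Q3, class 3 the remainder.
Eligibility defaults to uncensored PFS within [6, 720] days. Q1 = Q3
raises a stratification error rather than emitting empty classes.

gPCA: with Y the samples × genes matrix centered per gene and A the
batch-indicator matrix, δ = ‖Y v₁g‖²/‖Y v₁u‖², where v₁u is the first
right singular vector of Y and v₁g that of AᵀY. Significance is by batch-
label permutation, p = (1 + #{δ_perm ≥ δ}) / (n_perm + 1); the default
999 permutations give 0.001 resolution. Only a test is provided — no
batch correction, matching a workflow that checks and proceeds.

## Pathway restriction

The curated web-service step is replaced by a local exact test: per set,
p = P(X ≥ overlap) for X hypergeometric over the declared background,
sets intersected with the background first, BH correction across sets.
The default selection policy takes sets with q ≤ 0.05 that also appear in
a caller-supplied allowlist of category names — a reproducible stand-in
for manual curation (the pipeline's simulate mode allowlists the planted
resistance sets). The candidate pool is the union of the chosen sets'
members intersected with the high-variance genes, sorted for determinism.

## Modified SVM-RFE

Linear soft-margin SVM, C = 10, feature ranking by w² (a class-mean-
weighted "R-SVM" criterion w·Δmean is available via config), ties broken
by lexicographic feature id. Each recursion drops
ceil(0.10 · n_surviving) features, at least one, never the last one; the
schedule is configurable down to one-at-a-time.

The embedded error estimate is the method's centrepiece and the design
choice that matters most. Cross-validating the surviving subset directly
is optimistically biased, because the subset was chosen using the very
samples being held out; at 300 features × 80 samples this "fixed-subset"
scheme reaches 0% CV error on pure noise. The default scheme therefore
re-runs the entire elimination path inside each training fold (5
stratified folds, drawn once per run from a derived seed) and scores the
held-out fold at every level; under a pure-noise null the minimal error
over all levels then stays near chance (measured ≥ 0.375 over 20 seeded
cohorts of 80 samples × 300 genes). The fixed-subset scheme is kept
behind `RFEConfig(cv_scheme="fixed_subset")` for comparison.

The signature is the level with minimal CV error; ties resolve to the
fewest genes. This parsimony rule means that when planted genes are
individually strong (≥ 2 SD per-gene shifts), the selected subset is a
small all-signal core (3–8 genes, precision ≈ 1) rather than the full
planted set — the error curve reaches its minimum long before all planted
genes are needed. Recovering a planted set *in full* requires genes that
are individually weak but jointly discriminative, and even then the
minimum-error level only approximately tracks the planted size.

## Prognostic model and survival analysis

Per-gene β come from univariate Cox proportional-hazards fits (partial
likelihood, Efron tie handling, Wald inference) on the held-out class-3
patients; a joint multivariable fit over the signature is available
behind a flag. Univariate per-gene fits are the default because the
published per-gene coefficient table is captioned as univariate. Only
Efron tie handling is provided.

PI = Σ β_g x_g on the raw (log2) expression; an optional post-hoc
z-standardization of the PI vector changes neither ranks nor the median
split. Risk groups: PI < threshold → low, PI ≥ threshold → high, with the
median as default threshold and an explicit-threshold escape hatch that
must leave both groups non-empty. Transfer to an external cohort applies
the frozen β's, optionally after per-gene z-scaling of the external
matrix (location/scale harmonization across platforms); it never refits.

Kaplan–Meier curves use the product-limit estimator with Greenwood
variance and pointwise 95% intervals on the log(−log) scale; the median
is the smallest time with Ŝ ≤ 0.5 (∞ if never reached) and its CI comes
from inverting the confidence band (Brookmeyer–Crowley style), open ends
reported as ∞. The log-rank test is the two-group (O−E)²/V form with
hypergeometric variance; events precede censorings at tied times. The
two-group hazard ratio is a binary-covariate Cox fit with low risk as
reference. Subtype-stratified analyses run KM + log-rank per stratum,
skip (with a report) strata lacking both risk groups or any event, and
leave p-values unadjusted across strata. The independence analysis fits
three univariate Cox models and one joint model on complete cases — risk
group (low reference), age (continuous), MGMT status (methylated
reference) — and reports n, events, HR and Wald p per variable per model;
near-perfectly collinear designs are rejected with a numeric error.

## Pipeline, seeds and determinism

A single global seed fans out to per-stage sub-seeds via BLAKE2b hashing
of stage names (all below 2³¹), so stages are independently reproducible
and a rerun with the same config produces byte-identical outputs and
manifest. The manifest records the config hash, per-stage statistics, and
a held-out audit: the identities of the samples used by feature selection,
checked to be disjoint from class 3. Stage failures abort with the stage
name; earlier outputs are retained.

## Problem sizes used by the test suite

Tests run on simulated cohorts of 80–600 samples and 40–600 genes, 99–199
gPCA permutations, 200-replicate null calibrations, and 20-seed sweeps
for recovery and null behavior of the RFE — sizes chosen so the whole
suite exercises every stage end to end in a few minutes on one core while
keeping binomial/KS noise well inside the asserted tolerances.

## Known limitations

- Exponential (constant-baseline) survival only; a Weibull shape is a
  natural config extension.
- No penalized Cox, time-varying covariates, competing risks, or
  proportional-hazards diagnostics.
- The enrichment stand-in tests over-representation only; no topology or
  redundancy between sets is modelled.
- Cross-platform transfer is approximated by per-gene z-scaling; real
  probe-to-gene harmonization is out of scope.
- The parsimony of the minimal-error selection rule (above) is inherent:
  the method optimizes discriminative error, not recovery of a planted
  gene list.
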