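# Methods

This note documents the statistical models, parameter defaults, numerical
choices, and limitations of `hervtriage`. It describes what the code
computes; every empirical number quoted here is produced by the test suite
or the acceptance script.

## Region selection

Coordinates are 0-based half-open throughout (BED-native); VCF positions
are converted at the I/O boundary. A cancer predisposition gene (CPG)
enters the analysis when |log2 fold change| > 1 **and** adjusted
p < 0.05, both strict, with duplicates collapsed to the first record. An
element is selected when its gap distance to a gene body — for intervals
[a,b) and [c,d), max(0, c−b, a−d) — is at most the radius (default
20,000 bp, measured from the gene body; an element straddling the
boundary is selected if any base is within radius). Nearest-gene ties
break to the lexicographically smallest symbol, so annotation is
deterministic. Positional classification has precedence exonic >
intronic > flank; flank labels are strand-aware (5′ of the gene is
upstream). Region merging joins intervals sharing at least one base;
bookended intervals stay separate. Merging is idempotent and preserves
the union of covered bases (property-tested against a per-position
oracle).

## Cohort handling

Variant identity is (chrom, pos, ref, alt); rsIDs are annotations only,
since multiallelic splitting leaves several records with one rsID.
Splitting produces one biallelic record per ALT; a sample's code counts
copies of that ALT, other ALTs count as reference, and half-calls (0/.)
are treated as missing. Symbolic alleles are skipped with a warning.
Cohort merge takes the union of variant keys; a variant unseen in one
cohort's file is coded homozygous reference there when
`missing_to_ref` is on (the convention needed when cases and controls
are joint-called separately and absence cannot be distinguished from
reference), and missing otherwise; explicit `./.` is preserved in both
modes. Cohorts disagreeing on REF at a shared position abort the merge
by design — such records indicate inconsistent normalization upstream.

Allele frequencies are unfolded alternate-allele frequencies over
non-missing genotypes: Σg / (2·n_nonmissing). No minor-allele folding is
applied, so reported "MAF" values may exceed 0.5.

The train/validation split allocates round(0.6·n_s) of each stratum to
training with round-half-up (138 samples → 83 training, 55 validation).
Among `n_trials` seeded shuffles the trial minimizing the balance score
is kept — the maximum absolute deviation of the per-stratum training
fraction from 0.6, optionally extended over secondary attribute columns
(e.g. sex) whose balance the randomization should also respect. With
strata alone the score is constant across trials (the allocation is
deterministic); the multi-trial search matters exactly when secondary
columns are supplied. This balance metric was an open design choice; the
maximum deviation was chosen over a chi-square statistic because it is
monotone, interpretable, and sufficient for the per-stratum guarantee
|training fraction − 0.6| ≤ 1/n_s.

## Supervised admixture estimation

Genotypes at M ancestry-informative markers (AIMs) are modelled as
g_m ~ Binomial(2, f_m), f_m = Σ_k q_k p_km, with p_km fixed reference-
population alternate-allele frequencies (clamped to (0,1)) and q on the
K-simplex. The maximum-likelihood q is found by EM:

    q_k ← (1/2M′) Σ_m [ g_m q_k p_km / f_m + (2−g_m) q_k (1−p_km) / (1−f_m) ]

over the M′ non-missing markers, initialized uniform, iterated until the
log-likelihood gain falls below `tol` (default 1e-6, max 2000
iterations). The likelihood is non-decreasing every iteration (asserted
in tests), and the EM fixed point matches an independent derivative-free
maximizer and a simplex grid search on small instances. A panel with
identical frequencies in all populations makes the likelihood flat in q;
the uniform vector is returned with an unidentifiability warning.
Permuting panel populations permutes q identically.

This supervised estimator replaces MCMC-based clustering deliberately:
with reference frequencies fixed, the likelihood is well-identified, the
computation is deterministic and fast, and burn-in/replication settings
become moot. The categorical rules are applied in order: EUR if
q_EUR > 0.90; AFR if q_AFR ≥ 0.70; EAS if q_EAS ≥ 0.70; HIS if
Native-American ancestry q_NAT ≥ 0.10 and strictly exceeds both q_AFR
and q_EAS; otherwise AMR. For regression covariates the q-vector is used
continuously with EUR dropped as baseline (avoiding collinearity with
the intercept); the NAT component doubles as the continuous
Hispanic-ancestry covariate.

**Estimation accuracy at study scale.** With K = 4 and M = 85 the
per-component error of the exact MLE is bounded below by the information
in 85 binomial observations. Under the default panel (Balding–Nichols
divergence 0.15, 85 markers selected from a 179-candidate pool) the mean
per-component error at n = 500 is ≈ 0.068 — and even a maximally
informative panel (frequencies at the 0.01/0.99 bounds) cannot do better
than ≈ 0.03–0.04 for admixed individuals. The recovery property test
asserts the oracle-derived bound 0.08; tighter accuracy requires more
markers, not a better optimizer.

## Association and confounding

Per-variant fits are additive logistic regressions (dosage 0/1/2)
computed by iteratively reweighted least squares (Newton–Raphson),
converged when the score norm < 1e-8 or the step < 1e-10, with
two-sided Wald p-values 2Φ(−|β/se|). The unadjusted model is intercept +
dosage; the adjusted model adds sex and the three ancestry covariates.
Samples missing the genotype are dropped per variant (complete-case).
Monomorphic variants are returned flagged with undefined effects.
Complete or quasi-complete separation — a coefficient drifting past 15
on the logit scale, or non-convergence — yields a flagged result with
p set to missing rather than a spurious estimate; a Firth-type penalty
was considered and deliberately not made the default, to mirror the
behaviour of standard GWAS logistic fits. Rank-deficient designs raise
an error naming the collinear columns. No MAF or MAC filter is applied
before association.

The IRLS implementation is cross-checked in tests against an independent
Newton optimizer (agreement to 1e-6 in coefficients and standard
errors), against the 2×2 closed form exp(β̂) = ad/bc, and for
calibration: the type-I error over 1000 null variants is within 2
binomial standard errors of the nominal 0.05.

Confounding per variant is |OR_adj − OR_unadj| / OR_unadj, flagged when
strictly above 0.10 (scale-consistent; the boundary case is handled
robustly against floating-point noise). The significance threshold is
α / n_variants; the study-level threshold can also be supplied directly,
since the effective test count in a published analysis is not always
recoverable from α and the nominal variant count. The odds ratio is not
collapsible, so a modest OR shift under adjustment can occur even
without classical confounding; the 10% flag should be read as
"covariate-sensitive", not as a causal statement.

## Triage cascade

Exclusion codes are computed independently per rule and unioned, so the
cascade is order-independent. A variant is *confirmed* when its
adjusted-model p is below threshold in training **and** validation for
the same sample type; variants significant only after adjustment carry
an `adjusted_only` flag.

The qualitative published rules ("inconsistent distribution", "large
variations") needed quantitative defaults; these were fixed by requiring
that the bundled 27-variant frequency table reproduce its known
exclusion pattern, and are configurable:

- **† (split inconsistency):** |MAF_train − MAF_valid| > 0.10 (strict),
  or a train/valid ratio outside [0.5, 2] when both are positive.
- **‡ (crossed pattern):** the only significant cells pair one sample
  type in training with the other in validation, with no same-type
  confirmation.
- **◊ (database discrepancy):** an external frequency is reported,
  |internal − external| > 0.10, and the fold change exceeds 2 in either
  direction (external 0 counts as infinite fold). Tri-allelic variants
  are never excluded by this rule — their split records make external
  comparisons ambiguous — and are flagged inconclusive instead. On the
  bundled table these defaults flag exactly 8 of 27 variants
  (regression-tested).

The rare screen extracts variants with case MAF ≥ 0.10 (a cohort of 74
gives ≈ 81.8% power to detect a 10-point frequency difference under the
normal approximation implemented in `power_detectable_difference`),
calls them *rare* when every available control frequency is ≤ 0.01
(absent external = 0), and *rare_enriched* when the case frequency also
reaches 10× the external frequency (or the external is absent/zero).
The classification is monotone in case frequency. Somatic candidates are
blood→tumor frequency gains ≥ 0.02, the smallest shift worth reporting
at these sample sizes; linkage clusters form by single linkage at
genotype-r² ≥ 0.8, with r² the squared Pearson correlation of dosage
vectors over pairwise-complete samples (undefined and flagged for
constant vectors).

## Poly(A)-tail analysis

Runs are strict homopolymers of the tail base on the element's sense
strand; minus-strand elements are handled by reverse complementing, and
results are strand-invariant by construction (tested). The measured run
must contain the annotated tail anchor, so A-runs elsewhere in the
element never count. The "before" length is the maximal run containing
the anchor; the variant allele is applied (SNVs only — indels are
rejected explicitly, since run accounting across length changes is a
different problem); the "after" length is recomputed on the edited
sequence. A spacer-merging substitution therefore yields
after = left_run + right_run + 1, e.g. 29 + 7 + 1 = 37 and
25 + 10 + 1 = 36 for the two canonical fixtures. Run lengths equal an
exhaustive scan of every homopolymer in the edited string
(property-tested).

## Synthetic-data generator

The generator emulates the study conditions; defaults are chosen once:

- **Reference panel:** K = 4 populations (EUR, AFR, EAS, NAT — proxies
  for the classical reference panels), M = 85 AIMs selected as the most
  informative (largest cross-population spread) of a 179-candidate pool,
  matching how AIM panels are assembled by selection. Frequencies follow
  a Balding–Nichols construction — a shared ancestral frequency
  perturbed per population by a single divergence parameter F (default
  0.15; F = 0 gives identical populations, F = 1 near-fixed differences)
  — clamped to [0.01, 0.99] to avoid degenerate likelihoods.
- **Admixture:** each individual draws a dominant population and a
  Beta(2, 6) admixed fraction (mean 0.25), reflecting cohorts dominated
  by near-pure individuals with an admixed minority; a symmetric
  Dirichlet model is available as a config option.
- **Cohorts:** 138 cases and 2015 controls at full scale (tests and the
  acceptance script use scaled-down sizes, typically 200/400, chosen so
  every planted feature is comfortably powered). Sex is Bernoulli(0.5)
  by default with a separate case-cohort imbalance knob. Case status is
  Bernoulli on a logit scale: baseline −1, planted per-allele log-odds
  effects, a sex term (0.5) and an ancestry term (1.5) that create
  genuine confounding; individuals are sampled retrospectively until
  both quotas fill, preserving planted odds ratios. Published effect
  sizes for the study's hits are not available, so planted defaults
  (log-OR 1.0–1.5 common hits; case MAF 0.12 vs control 0.002 rare;
  +0.05 tumor shift somatic) are testability choices, not estimates.
- **Tumor samples:** copies of case blood genotypes with designated
  variants resampled at a shifted frequency. Linked pairs copy a source
  column with a 3% redraw at the source's own frequency, keeping allele
  frequencies intact while giving r² ≈ 0.9.
- **Alu sequences:** one record per element — two ~130 bp monomers, an
  A₅ linker, and a poly(A) tail drawn from 21–26 bp (the genomic
  average range); every second element carries a planted spacer variant
  A^a X A^b with recorded before/after truth.

What the generator does **not** emulate: read-level noise and coverage
variation (genotypes are drawn, not called), genotyping error, linkage
structure beyond the planted pairs, indels, and locus dropout. Passing
tests therefore demonstrate the statistical machinery on clean
genotypes, not robustness to upstream calling artifacts.

## Pipeline and determinism

All randomness flows from explicit seeds through `numpy` generators with
fixed spawn keys per stage, so identical configs give byte-identical
outputs; the manifest records SHA-256 hashes of every file and the
end-to-end rerun test asserts hash equality. Stage counts (regions,
variants tested, exclusions by code, rare/somatic candidates) are logged
and conserved: every variant is accounted for by exactly one status.
Unicode †/‡/◊ codes are mirrored in an ASCII column
(dagger/ddagger/diamond) for toolchain safety.

## Known limitations

- Ancestry adjustment is global per individual; locally varying ancestry
  along the genome can still confound individual loci.
- The supervised estimator is only as good as the reference panel; with
  85 AIMs the per-component uncertainty is several percentage points
  (see above), which propagates into covariates.
- The exclusion thresholds (†/◊) are reverse-engineered defaults for
  qualitative published rules and should be revisited per application.
- Separation-flagged variants (common for rare alleles in small strata)
  carry no p-value by design; a Firth-penalized fit would be the natural
  extension.
- The power calculation is a one-sample normal approximation; exact
  binomial power differs slightly in small samples.
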