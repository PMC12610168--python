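# Methods

## The association model

Expression of gene *g* in sample *s* is modeled as an additive linear
function of allele dosage with age as a covariate:

e_gs = μ_g + β·d_vs + γ·age_s + ε_gs,  d ∈ {0, 1, 2}

Dosages enter raw (unstandardized), so β is the change in normalized
expression per copy of the ALT allele. The engine residualizes the
expression matrix and the dosage matrix off the covariate design
(QR-based projection) and computes every pair's statistics from the
residual correlation r: t = r·√(df/(1−r²)), β = ⟨e*,g*⟩/⟨g*,g*⟩,
se = √(SSE/df/⟨g*,g*⟩), explained variance t²/(t²+df), two-sided
Student-t p-value, and a 95% CI at t₀.₉₇₅(df). By Frisch–Waugh–Lovell
these equal per-pair OLS of expression on dosage + covariates exactly;
the test suite asserts agreement with statsmodels OLS to 1e−8 on a
75 × 500 × 2,000 panel. Degrees of freedom are n − 3 with the default
intercept + age design (n − q − 1 in general).

Missing genotype calls are allowed: a SNP with missing calls is
re-fit on its complete samples only (pairwise deletion), with df
reduced accordingly. This is a package choice — hard-call pipelines
rarely document missingness handling — and is the only point where
per-pair sample sets differ.

Numerical choices: residual correlations are never clamped; p-values
that underflow double precision are reported at the smallest positive
subnormal rather than 0; a SNP with zero residual variance yields a
flagged (all-NaN) record that still counts as a test but is never
emitted; a constant expression row yields β = 0, p = 1.

## cis/trans classification and multiple testing

A pair is cis iff the SNP is on the gene's chromosome and within
100 kb of the gene *body* (start..end), boundary inclusive; distance
is 0 inside the gene, else bp to the nearer edge (−1 recorded for
cross-chromosome pairs, where distance is undefined). The anchor is
the gene body, not the TSS, reading "within ±100 kb of the gene" as
gene proximity.

cis and trans are analyzed separately. The thresholds p < 0.02 (cis)
and p < 1e−6 (trans) are *emission* thresholds, not significance
claims: BH FDR is computed per class against the total number of
tests in that class (the matrix-eQTL convention), so q-values are
unaffected by how many records were materialized. Significance is
FDR ≤ 0.05. The conservation identity
n_cis_tests + n_trans_tests = n_SNPs × n_genes holds on every run and
is asserted in tests. Gene-wise reduction keeps each gene's lowest-FDR
significant cis record, with deterministic tie-breaks (p, then
position, then snp_id).

## Hotspots and the permutation null

Per-SNP regulated-gene counts use *distinct* genes with significant
records. Cis hotspots are SNPs with ≥ 7 genes (inclusive). Trans
hotspot candidates must *strictly* exceed the 99th percentile
(linear-interpolation convention) of the per-SNP count distribution —
"more than" the cutoff count.

The permutation null permutes the sample labels of the expression
matrix, one shared permutation per iteration applied to every gene
jointly. This preserves genotype LD and the inter-gene correlation
structure — exactly the features that inflate per-SNP counts under the
null — while breaking genotype–expression linkage. Implementation is
Freedman–Lane style: residualized expression is permuted and
re-projected off the covariates. Each iteration rescans only the
candidate SNPs against all genes with the trans pipeline (same
emission threshold; BH against the trans-pair count restricted to the
candidates), and the observed statistic is computed with the same
restricted construction so observed and permuted counts are
exchangeable. The estimator perm_p = (1 + r)/(B + 1) never returns 0;
its values lie on the grid {(k+1)/(B+1)}, so at the production default
B = 100,000 the smallest reportable value is ≈ 1e−5. Hotspot q-values
are plain BH across the candidate list (m = number of candidates);
significance is q < 0.05. (A π₀-adjusted q-value estimator would give
smaller q at the same p; plain BH is used here and documented.) A
trans hotspot with at least one cis record at FDR ≤ 0.05 is flagged
as a shared cis+trans hub.

Test- and demo-scale runs use B = 1,000–2,000; B only changes the
resolution of perm_p, not the statistic.

## Preprocessing

Order of genotype QC: MAF filter → LD pruning → near-gene restriction
(nothing forces this order statistically; pruning on the fullest
marker set is the package's documented choice).

- MAF = min(f, 1−f) with f = Σd/(2·n_nonmissing); the filter keeps
  strictly MAF > 0.01, and monomorphic SNPs are always dropped.
- LD pruning is PLINK-style `indep-pairwise` on dosage r² (Pearson on
  0/1/2 codes, pairwise-complete over missing calls): within a sliding
  window of 50 SNPs every pair with r² ≥ 0.2 loses its
  later-positioned member, advancing 5 SNPs at a time; passes repeat
  (finishing with single-SNP stride) until no retained within-window
  pair reaches the threshold — a postcondition verified by brute force
  in tests. Window/step are conventional defaults, exposed in config.
- Near-gene restriction keeps SNPs within 100 kb (inclusive, same
  window as the cis definition by default) of any expressed gene.
- Expression filtering removes genes with total counts < 200 or zero
  counts in ≥ 70 samples; for cohorts of size n ≠ 75 the zero limit
  rescales to ⌈70/75·n⌉.
- Normalization is a variance-stabilizing stand-in, not DESeq2's VST:
  median-of-ratios size factors (genes with any zero excluded from the
  median) followed by log2(count/sf + 1). It preserves the two
  properties the scan needs — approximate variance stabilization and
  library-size invariance. Exact invariance under rescaling one
  sample is impossible for any method whose reference depends on all
  samples: scaling one of m samples by c shifts the geometric-mean
  reference by c^(1/m), moving all normalized values by one common
  constant; tests assert exactly this behavior.
- The variant-context labeler is positional only (genic/exonic/
  intronic/upstream/downstream/intergenic, strand-aware flanks); it is
  a stub standing where transcript-resolution effect prediction would
  sit in a production pipeline.

## Enrichment

Right-sided hypergeometric p = P(X ≥ k) for an overlap of k query
genes with a K-gene term in an N-gene background (all genes surviving
the expression filter unless a custom universe is supplied); terms are
intersected with the background first. Bonferroni and BH are both
reported. Term grouping follows the kappa-score idea at the
conventional 0.4 threshold: Cohen's kappa between two terms' binary
membership vectors over the background, an edge where κ ≥ 0.4, and
clusters = connected components with ≥ 2 terms (singletons stay
unclustered). Connected components are the simplest reproducible
reading of iterative leading-group merging; the two coincide except
on chains of marginal similarity. κ is returned as NaN when chance
agreement is exactly 1 (both terms empty or both the whole
background). The right-sided test (rather than two-sided or mid-p) is
the package's documented choice.

## The synthetic cohort

The generator emulates the statistical structure the analysis
assumes, at desk scale:

- **Genome** — a few chromosomes with non-overlapping gene bodies
  (2–20 kb) and uniform SNP positions; by default one SNP is
  guaranteed inside every gene so each gene is cis-testable.
- **Genotypes** — Hardy–Weinberg draws with per-block allele frequency
  uniform in [maf_low, maf_high] (defaults 0.1–0.5). LD is a
  block-founder copy: consecutive SNPs share a founder genotype, each
  sample redrawn from HWE with probability `flip_noise` (default 0.1)
  — the simplest mechanism that makes pruning meaningful; a coalescent
  haplotype model is out of scope. Columns that come out monomorphic
  are redrawn, since a zero-variance dosage cannot be tested; at
  n = 75 a hard guarantee that every empirical MAF clears the 0.01
  filter is otherwise impossible without distorting HWE.
- **Covariates** — age ~ N(14.3, 8.8²) months truncated at 1 month
  (a realistic fattening-cattle age profile); the age effect on
  expression defaults to 0 — no consensus magnitude exists — and is
  configurable.
- **Planted effects** — a fraction of genes receives a cis effect from
  a SNP within the window; each hotspot spec entry (n_targets, beta)
  plants a trans master regulator with distant targets; optionally the
  first hub also carries a cis effect (a shared cis+trans hub). Effect
  sizes are fixed magnitudes in latent-SD units with random sign —
  fixed rather than drawn, so recovery tests have a well-defined
  truth. Cis effects may use `het_peak` mode (β·1[d=1], expression
  highest in heterozygotes) to emulate non-additive patterns; the scan
  still analyzes them additively, as the additive model dictates.
- **Expression** — latent_gs = baseline_g + Σ effects + γ·age + N(0,
  noise_sd²), and a count layer: negative-binomial with mean
  lib_s·softmax_g(latent) (library sizes uniform 0.5–1.5 M, dispersion
  0.1). Scan-level tests consume the latent matrix directly,
  decoupling association error from normalization error; pipeline
  tests consume counts. Note the unit change: latent effects are in
  natural-log SD units while the normalization outputs log2, so a
  planted β appears as β/ln 2 in normalized units.

What the generator does *not* emulate: relatedness/kinship among
animals (the linear model ignores it, and so does the generator),
population stratification, realistic LD decay, sex chromosomes, and
GC/length biases in counts. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to confounding present in real cohorts.

## Problem sizes and determinism

Test and demo panels use 40–75 samples, 15–500 genes, 90–2,000 SNPs
and B = 200–2,000 permutations — sizes chosen so the full suite runs
in well under a minute while every statistical check retains power.
All randomness flows through numpy `SeedSequence` children of a single
integer seed; identical seeds give byte-identical output files.

## Known limitations

- FDR within the emitted-record list assumes emitted p-values are the
  smallest in their class, which holds by construction of the emission
  threshold.
- The hotspot permutation vets candidates selected on the observed
  data (selection and testing share the data), as in the original
  design; the permutation p is valid for the count statistic given the
  candidate set, not for the selection step.
- Connected-component kappa clustering can chain otherwise dissimilar
  terms through intermediates.
- The VST stand-in under-stabilizes very low counts relative to a
  full mean-variance-fit transform.
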