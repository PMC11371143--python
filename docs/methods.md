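# Methods

## The design and the model

The pipeline targets a three-taxon domestication series of tetraploid wheat
— wild emmer (ancestral), emmer (primary domesticate), durum wheat
(secondary domesticate) — with 10/10/12 genotypes respectively, each grown
under two nitrogen (N) regimes (high, starvation) with two biological
replicates: 128 RNA-seq samples. Normalized log-scale expression Y of one
gene is modelled as

    Y_ijkl = μ + S_i + G_j(i) + N_k + (S×N)_ik + (G×N)_jk(i) + ε_l(ijk)

with the taxon effect S, genotype-nested-in-taxon effect G, nitrogen effect
N and both interactions all random and the intercept fixed. Because the
lines are inbred, between-genotype variance stands in for additive genetic
variance; hence

    H² = (V_S + V_G) / V_A,
    V_A = V_S + V_G + V_N + V_{S×N}/n + V_{G×N}/n + V_ε/n,

with n = 2 nitrogen levels: interaction and residual variances are averaged
over the environments a genotype mean is taken across. The S×N share used
by the scan's rescue rule is V_{S×N} divided by the plain sum of all six
components (a share of total variance, without the /n weights).

Expression Q_ST for a taxon pair at one N level comes from the reduced model
`Y = S + G(S) + ε` fitted to that condition's samples, as
`Q_ST = V_S/(V_S + V_G)` — the between- to within-taxon variance ratio.
This is deliberately the ratio used by the scan, not the classical
`V_B/(V_B + 2V_W)`; with inbred lines the two differ by the factor-of-two
convention only, and thresholds in the scan are calibrated to this form.

## Estimation

Each gene is fitted independently by REML. The marginal covariance is
`V = Σ_k σ²_k K_k + σ²_ε I`, where K_k is the boolean same-level kernel of
factor k; the design is shared by all genes so kernels are computed once.
The REML objective and its analytic gradient (via `P = V⁻¹ −
V⁻¹1(1'V⁻¹1)⁻¹1'V⁻¹`) are minimized with L-BFGS-B under box constraints
σ² ≥ 0, so negative components are clamped by construction (`fit_status =
"clamped"` when an estimate sits on the bound). A Haseman–Elston-style
method-of-moments regression — least squares of centered response
cross-products on the kernels — supplies starting values and the fallback
when the optimizer fails. The response is rescaled to unit variance before
optimization and the estimates rescaled back. A constant response yields
all-zero components and H² = 0; an incomplete design (an empty taxon × N
cell) yields `fit_status = "failed"` rather than an exception.

Identifiability caveat, stated because it shapes every downstream
interpretation: components carried by 2–3 factor levels (taxon, nitrogen,
taxon × nitrogen) have ~1–2 degrees of freedom per gene. Their per-gene
estimates are χ²-distributed with medians well below the parameter (median
χ²₁ = 0.455), an attenuation no estimator can remove. Per-gene Q_ST (two
taxon levels) inherits this: with V_S = 1, V_G = 3 the median Q_ST across
genes sits near 0.06–0.13, not at the parameter ratio 0.25. This matches
the small median Q_ST values seen in real data of this design and is why
the scan uses the *tail* of the Q_ST distribution rather than its location.
Components with many levels (genotype: 20–32 levels; genotype × N;
residual) are recovered with < 15% median bias in simulations.

## Population-genetic estimators

Hard-genotype estimators with closed forms are used throughout (the
genotype-likelihood/SFS machinery used upstream of the original dataset is
out of scope; this substitution is deterministic and testable against
brute-force oracles):

- π: per site with m ≥ 2 non-missing allele copies and ALT frequency p̂,
  the unbiased mean pairwise difference `2p̂(1−p̂)·m/(m−1)`, summed over
  sites and divided by the total surveyed length L. L is a required input
  (`total_sites`): per-site diversity is meaningless without it, and it is
  not derivable from a SNP-only VCF. The pipeline's simulated default is
  the summed gene-interval length.
- Watterson θ: `S/(a_n · L)` with `a_n = Σ_{i<n} 1/i`, n = allele copies.
- F_ST: per-site Hudson/Bhatia components `A = (p₁−p₂)² − p₁(1−p₁)/(n₁−1)
  − p₂(1−p₂)/(n₂−1)` and `B = p₁(1−p₂) + p₂(1−p₁)`; the per-gene weighted
  estimate is `ΣA/ΣB` over the gene's usable sites — a ratio of sums, which
  is consistent under weak differentiation where the mean of per-site
  ratios is not. Negative per-gene values are reported as-is and only
  excluded at the scan stage (F_ST < 0.01 is dropped there anyway). Sites
  with fewer than 2 allele copies in either population are skipped and
  logged.
- Genotype coding: ALT-allele dosage 0/1/2, heterozygotes = 1; missing = −1.
  VCF positions are 1-based; gene intervals 0-based half-open (BED
  convention; GFF3 converted on read); a site at position p belongs to
  gene [start, end) iff start < p ≤ end, and may belong to several
  overlapping genes. Strand is carried but ignored.
- Structure PCA: allele-sharing distance `mean(|d_i − d_j|)/2` over shared
  non-missing sites, then classical MDS (double-centering +
  eigendecomposition), deterministic up to axis sign.

## The scan

Thresholds default to: CPM filter ≥ 1 in ≥ 10 samples per taxon (union over
taxa); H² ≥ 0.7 OR S×N share ≥ 0.2; the 95% linear-interpolation quantile
(ties inclusive) of each comparison's Q_ST distribution over prefiltered
genes; F_ST ≥ 0.01; padj < 0.001; 500-kb thinning; 50% missingness; 1% MAF.
OR ("rescue") prefilter semantics are the default because the S×N rule
exists to retain N-responsive genes the H² rule would drop; `prefilter_logic:
and` is available. Comparisons with fewer than 20 defined Q_ST values are
skipped with a warning.

One structural consequence worth knowing: because the 5% tail is a quantile
of the *prefiltered* distribution, the flagged set is not monotone in the
prefilter thresholds — tightening H² removes genes from the distribution,
which can lower the tail cutoff and admit different genes. Monotonicity
holds stage-wise (prefiltered set in h2_min/sxn_min/logic; flagged set in
tail_q and fst_min), and that is what the tests assert.

## Normalization

The default transform is log2(CPM + 1): non-negative (required by CV_A),
variance-flattening, and strictly monotone per sample. Model-based
variance-stabilizing or TMM/voom normalizations are not reimplemented; the
transform is a config hook (`ln_cpm1` also ships) so alternatives can be
substituted. Ratio statistics (H², Q_ST, S×N share, CV_A) are invariant to
the log base and to global rescaling; absolute variance components are on
the squared-log2 scale.

## The synthetic-data generator

`SimConfig` defaults reproduce the study layout (10/10/12 genotypes, 2 N
levels, 2 replicates). Counts are negative binomial with mean exp(η) and
variance m + φm² (φ = 0 degenerates to Poisson; default φ = 0.1, a typical
biological-replicate dispersion), where η follows the random-effects model
with per-gene components; defaults (V_S = 0.1, V_G = 0.3, V_N = 0.05,
V_{S×N} = 0.05, V_{G×N} = 0.05, V_ε = 0.1 on the natural-log scale, baseline
mean 200 counts) give moderately heritable, moderately N-responsive
expression. Genotypes follow the Balding–Nichols model — per-taxon allele
frequencies Beta-distributed around a uniform(0.05, 0.95) ancestral
frequency with divergence F_t per taxon (defaults 0.1/0.1/0.2, durum most
diverged, matching the real series) — chosen because F is exactly the
target of the Hudson-type estimator, giving an analytic recovery check.
All draws come from a seeded numpy PCG64 generator; expression and genotype
streams use spawned child seeds so the two are independently reproducible.

What the generator does not emulate — and what passing tests therefore do
not establish about real data: no co-expression between genes (effects are
drawn independently per gene), no linkage between SNPs, no
selection-induced coupling of Q_ST and F_ST, no library-size or batch
structure beyond what NB sampling induces, and no genotype-likelihood
uncertainty. Recovery tests validate the estimators, not the biology.

## Problem sizes and numerical choices

Simulation-based tests use 150–500 genes and up to 5,000 SNPs with the full
128-sample design — enough for stable medians of the recovery targets while
keeping the whole suite in the low minutes on one core. The Mann–Whitney
implementation enumerates all C(n+m, n) labelings exactly (valid under
ties) for n + m ≤ 12 and otherwise uses the normal approximation with
midrank tie correction and continuity correction. Degenerate inputs are
defined explicitly: CV_A is undefined (NaN, excluded from group means) when
the mean genotype mean is 0; Q_ST is undefined when V_S + V_G = 0 or a
taxon has one genotype; Welch tests on two constant equal groups give
p = 1, constant unequal groups p = 0; genes without usable SNPs have
undefined F_ST and cannot be classified by the scan.

## Known limitations

Per-gene variance components for few-level factors are strongly attenuated
(see above); the built-in DE test is a stand-in for count-model pipelines
and is best used together with externally produced DEG lists via the
intersection operator; π/θ/F_ST assume called hard genotypes; the loss
composition `1−(1−L_pd)(1−L_sd)` is exact only when no flip (diversity
gain) occurs in either stage.
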