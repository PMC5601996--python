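# Methods

## Scope and model

`circaqtl` implements the statistical chain of a cellular circadian-QTL
study: bioluminescence recordings from synchronized cell lines yield
per-line clock traits (period T, phase φ, amplitude A); traits are
cleaned of technical confounders; cleaned traits are tested for
association with genome-wide genotypes; candidate variants are
cross-checked against behavioral chronotype extremes and by RNAi
perturbation statistics; and timecourse rhythmicity plus protein decay
round out the molecular follow-up. Because the original cohort is not
distributable, a first-class synthetic-data module generates every input
with the statistical structure the analysis assumes; all quantitative
claims in the test suite are therefore claims about data of that class.

## Trait extraction

The oscillation model is

    y(t) = c + d·exp(−t/τ_b) + A·exp(−λt)·cos(2π(t−φ)/T) + ε

with a constant plus decaying culture baseline and an exponentially
damped cosine. For fixed (T, λ, τ_b) the model is linear in
(c, d, a, b); the fitter therefore scans a deterministic period grid
(0.25 h steps across the bounds, default 20–30 h) crossed with a small
damping grid (0–0.08 h⁻¹), solves each start in closed form, and refines
the best start with bounded trust-region least squares (tolerances
1e-10). This replaces wavelet-based period estimation with a transparent
parametric fit; equivalence is claimed only at the level of recovering
(T, φ, A) from traces of the simulated class — on those, the median
period error at SNR 10 is below 0.1 h (measured by the acceptance
suite).

Phase convention: φ is the time of the first maximum of the *cosine
term* after t = 0, in [0, T). The peak of the damped product leads the
cosine peak by (T/2π)·atan(λT/2π) ≈ 0.3 h at λ = 0.02, T = 24 — inside
the tolerances used anywhere phase is compared — and this convention
makes the fit exactly covariant under time-shifts. A fit is flagged
non-converged when the input is constant or the fitted amplitude is
below 1.5 residual standard deviations; such replicates are excluded
from (and counted in) the per-line aggregation.

`detrend_trace` (centered running mean, truncated at the edges) is
provided for exploratory baseline removal, but the recommended
`analyze_trace` path fits the baseline jointly: the running mean
attenuates the oscillation by a period-dependent factor 1−sinc(πW/T) and
its truncated edge windows bias the fitted period, which the joint fit
avoids.

## Phenotype normalization

Three steps: (1) arithmetic mean over technical replicates within each
biological replicate (covariates must be constant within the averaged
group); (2) per trait, a linear mixed model value ~ passage + date with
a random intercept per cell line, fitted by REML, from which the least
significant covariate (passage by a z test on its coefficient, date by a
joint Wald χ² on its dummy block) is dropped and the model refitted
until every retained covariate has p < α = 0.05 (ties broken by
covariate name; degenerate covariates dropped with a warning before
fitting); (3) residuals averaged per line. The response is standardized
and the passage covariate centered/scaled internally — an affine
reparameterization that leaves Wald tests and original-scale residuals
unchanged — because REML optimization on raw trait scales (e.g. counts
near 100) is ill-conditioned.

Residuals are observed minus the **fixed-effect** prediction only; the
random line intercept is deliberately retained because the line-level
signal *is* the phenotype carried into the GWAS. Consequence: planted
genotype effects attenuate by <10% on average when confounders are
independent of genotype (verified by the acceptance suite), and
residualizing twice retains nothing and changes values only by a
constant.

## GWAS

Variant QC applies, in order, MAF ≥ 0.05, Hardy–Weinberg exact
conditional test p ≥ 1e-6 (full enumeration of same-parity heterozygote
counts given the allele counts, summing configurations no more probable
than the observed one), call rate ≥ 0.975, and imputation info ≥ 0.4;
the retained set is order-independent, only the reported first-failing
reason depends on the order. Association is the Spearman correlation
(average ranks for the ubiquitous dosage ties) with two-sided p from
t = ρ√((n−2)/(1−ρ²)) on n−2 df; missing dosages use pairwise-complete
deletion and SNPs monomorphic after deletion return NA with a reason.
The t approximation is mildly anti-conservative at tied small samples —
the measured null tail fraction at p < 0.01 is ~0.0107 and the QQ λ is
unbiased (mean 1.004 over seeds).

Gene assignment links a SNP to every gene whose TSS (BED 0-based
half-open; start for +, end−1 for −) lies within 100 kb, boundary
inclusive; coordinates are converted in one place. Trait-pair overlap
uses the upper hypergeometric tail of the shared-SNP count — one defined
choice among several the source material leaves open.

## Chronotype enrichment

For extreme-chronotype cohorts sharing the GWAS variant panel, each
SNP's statistic is |f_larks − f_owls| of the ALT allele
(f = Σdosage / 2·n_called). The profile reports, for each threshold in
{1e-3, 1e-4, 1e-5, 1e-6}, the Δf distribution over SNPs with GWAS
p < τ: Tukey five-number summaries, means, counts and a kernel-density
export. Empty sets are recorded with n = 0. The tag-SNP variant selects
greedily in ascending-p order, founding a new block unless dosage r²
with an existing tag reaches 0.8 (the LD-block construction of the
original genotyping pipeline is not recoverable; greedy r² tagging is
deterministic and oracle-checkable).

A caveat the design surfaced: the per-threshold means are computed on
**nested** SNP sets and are therefore strongly positively correlated, so
trend tests across the four means (e.g. Mann–Kendall) are miscalibrated
— the one-sided false-trend rate under an independent chronotype is
~20%, not 5%, and the standard two-sided test cannot reach significance
with four points at all. The discriminating null check is the planted
contrast itself: P(mean Δf at 1e-5 > mean at 1e-3) is ~0.55–0.60 under
the null versus ~1.0 when the chronotype shares the causal loci.

## RNAi / RSA

Hairpin measurements are Z-scored per trait over the entire screen
(sample SD). For each gene with k hairpins at ascending ranks
r_1 < … < r_k among N hairpins (ranked most-negative-first for
"decrease", most-positive-first for "increase"; ties broken by hairpin
id), the RSA score is min over j of the hypergeometric upper tail
P(≥ j of the k hairpins in the top r_j positions). Every gene receives a
score in both directions, so a gene with discordant hairpins appears in
both distributions. No activity cutoff is applied before scoring.
Genelist-vs-background comparisons use two-sample KS and Kruskal–Wallis
on log₁₀ scores per direction; the background is the whole screen with
the genelist *included* (the genome-wide reference), which biases the
null KS p upward only when the genelist is a substantial fraction of the
screen (≈+0.10 at 10%, negligible at genome scale). The combined display
pools decrease-direction log-scores with sign-inverted
increase-direction log-scores; a seeded size-matched background
subsample (default 50 per direction) is exported for scatter parity.

## Rhythmicity and decay

Cosinor regression fixes the period at 24 h (the data class is generated
under 24 h cycles): OLS of the (log-transformed, upstream) series on
[1, sin, cos], amplitude √(a²+b²), acrophase the hour of the fitted
maximum in [0, 24), and p from the F test of (a,b) = (0,0) on (2, n−3)
df — the specific test statistic is this package's declared choice.
Zero-residual fits are flagged `perfect_fit` and reported at the
smallest positive double rather than silently p = 0; constant series get
p = 1. Batch detection applies Benjamini–Hochberg step-up across all
successfully fitted series (failed series are flagged and excluded from
the family) and calls a series rhythmic at q < 0.05.

Half-life estimation fits log(labeled fraction) versus time by least
squares; t½ = ln2/k with k = −slope, and k ≤ 0 (within double precision)
sets a `stable` flag instead of a negative half-life. A single noisy
curve at 3% measurement noise determines t½ ≈ 7.3 h only to ±0.5 h at
1σ, so the acceptance experiment averages three replicate curves before
fitting, matching how pulse-chase experiments are usually quantified.

## Synthetic data: what it emulates, and what it does not

Genotypes: per LD block, an ancestor allele frequency is drawn from
`maf_range` and two ancestor haplotypes per sample are copied to each
block SNP with a per-SNP flip probability (default 0.05) — HWE holds
exactly by construction and within-block r² is tunable (~0.75 at flip
0.02). Missing calls are optional (default 0). There is no coalescent
realism, population structure, or allele-frequency spectrum; imputation
quality is a scalar column.

Phenotypes: five traits (PER1/PER2 expression peaks, amplitude, phase,
period) with per-trait native scales (period 24.5 h baseline, 0.75 h per
trait SD); trait = baseline + SD·(Σβ·dosage + β_p·passage + date offset
+ biological + technical noise), replicated over a (biological ×
technical) hierarchy with passage drawn 3–12 and dates assigned per
biological replicate. Traces apply the damped-cosine generative model
above with a 200-count baseline decaying at τ = 48 h, 0.5 h sampling
over 120 h and Gaussian noise. Chronotype cohorts take a freshly
simulated behavioral population, score each individual as a weighted sum
of causal dosages plus N(0,1) noise, and return the lowest-scoring
(larks, default 11) and highest-scoring (owls, default 17) extremes —
the cohort sizes of the behavioral panel being emulated. The RNAi
generator gives background hairpins N(0,1) per trait with a shared
per-gene shift (plus hairpin noise) for genelist genes; timecourse
matrices mix flat series with 24 h sinusoids of random acrophase.

Passing tests on these data show the *statistical machinery* is correct
and calibrated; they do not certify performance on real recordings with
non-sinusoidal waveforms, non-Gaussian noise, batch structure beyond
passage/date, or LD beyond local blocks.

## Numerical and design choices

- One global seed; each generator stage draws from an independent
  substream (`SeedSequence([seed, stage])`), so stages are reproducible
  in isolation and the pipeline is byte-identical under a fixed seed.
- Default pipeline study design: 159 lines × 2,000 SNPs in 5-SNP blocks,
  five causal loci (0.7–0.8 SD), mild passage/date confounding —
  cohort-sized so the default `run-all` exercises every stage with
  realistic signal in about a minute.
- Acceptance experiment sizes (5,000 null SNPs for calibration, 20×
  10,000-SNP cohorts for recovery, 40 enrichment replicates, 200 RSA
  calibration screens) were chosen as the smallest sizes at which the
  sampling bands of the measured quantities are narrow relative to the
  asserted bounds.
- The enrichment acceptance panel uses 5,000 SNPs so the relaxed 1e-3
  set almost surely contains background SNPs (expected ~5): the
  strict-vs-relaxed contrast is undefined when the two sets coincide.
- Degenerate inputs are first-class: constant traces, monomorphic SNPs,
  zero-variance covariates, single date levels, empty threshold sets and
  zero-residual cosinor fits each have a defined, tested behavior rather
  than an exception where the science allows one.

## Known limitations

- The damped-cosine fitter assumes a single dominant oscillation; it
  will not separate multi-component rhythms.
- Mixed-model p-values use large-sample z/Wald statistics; at very small
  cohort sizes they are approximate.
- Spearman p-values use the t approximation at all n; an exact
  permutation reference is used in tests at n ≤ 8 only.
- Under the recovery benchmark's conditions (five loci at 15% variance
  each, n = 150 among 10,000 SNPs), the probability that *all five*
  planted loci reach the top 20 is ≈0.65–0.85 per run — a power ceiling
  of the rank statistic at that sample size, not an implementation
  artifact; single-locus recovery is essentially certain.
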