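# Methods

This note documents the statistical procedures implemented in
deuteromics, the assumptions behind the synthetic-data generators, the
numerical conventions, and what the validation suite does and does not
demonstrate about real data.

## Abundance conventions

All abundances are TPM (transcripts per million): per-feature read
counts are divided by feature length and rescaled so each sample column
sums to 10⁶. `normalize_tpm` implements the classic read-count-derived
definition; tables read from disk are accepted un-normalized and can be
renormalized with `OrfTable.normalized()`. Every statistic that uses TPM
as a weight is invariant under a common positive rescaling of the
weights, so the choice of raw unit (reads vs base coverage) does not
affect weighted means, count shares or fitted slopes — only absolute TPM
values.

## Weighted gene length

The mean and sd of predicted CDS lengths are weighted by TPM
(frequency-weight formulas, no small-sample correction):

    mean = Σ Lᵢwᵢ / Σ wᵢ,   sd = sqrt( Σ wᵢ(Lᵢ − mean)² / Σ wᵢ )

By default only ORFs with both start and stop codons enter, a guard
against assembly-edge fragments biasing the length distribution. The
pooled scope sums TPM across samples before weighting, which is the
natural choice for a co-assembled table where each ORF row is shared by
all samples. Using the same weights for the sd as for the mean keeps the
two estimands consistent; the sd is therefore a population-style spread
of the abundance-weighted length distribution, not a standard error.

## Diversity

Species richness counts distinct species-level tags with TPM > 0 in a
sample; tags of the form `unknown_<k>` (unclassified species) are
excluded unless requested, and both modes are exposed because
known-only and including-unknown richness answer different questions.
β-diversity is Jaccard's index on presence/absence sets — deliberately
abundance-free; abundance-weighted dissimilarities (Bray–Curtis) are out
of scope.

## Functional censuses

A category census needs an explicit membership rule. The default
transposase matcher requires a literal "transposase" gene-name keyword
or an IS3-family orthogroup annotation (COG2801, COG2963); no fuzzy
matching is ever applied, so the census is conservative and the rule is
a first-class, overridable object. Count share uses ORFs with TPM > 0
in the sample as denominator; TPM share is the summed abundance of
matching ORFs (so matcher plus complement always reconstructs the 10⁶
total in a normalized table). Cross-sample mean ± sd are unweighted
sample statistics with n − 1, matching the usual reporting for a small
number of replicate communities.

## Amino-acid composition

Rows are per-sequence relative frequencies over the 20 standard
residues after dropping non-standard symbols. Group coherence is the
mean Pearson correlation over all unordered row pairs. The two-group
enrichment test runs one unpaired t-test per residue — Welch by default,
since equal group variances are not defensible a priori; Student's
variant is a flag. The default is no multiple-testing correction, with
Benjamini–Hochberg available (and recommended when the classification
feeds further inference): at raw α = 0.05 over 20 tests, roughly one
null residue per comparison will be misclassified, which is why the
validation asserts the programmed enrichment pattern as the modal
outcome over many simulated communities rather than in every single
one. The 20 columns are compositionally coupled (they sum to one);
the per-residue tests ignore this dependence, as is common practice.

## Nei–Gojobori ka/ks

Sites: for each sense codon and position, the fraction of the three
single-nucleotide changes that are synonymous contributes to s; changes
producing a stop codon count as nonsynonymous, so s + n = 3 exactly for
all 61 sense codons. Differences: one-step changes are classified
directly; two- and three-step differences average over all orderings of
single steps, discarding orderings that pass through a stop codon; in
the rare case that every ordering does, all orderings are kept with
stop-involving steps counted nonsynonymous. These are the dominant
conventions for the 1986 counting method. Proportions pS = Sd/S,
pN = Nd/N are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4
is flagged saturated and the estimate is returned with the distance
undefined rather than raised as an error. The neutral band (0.9, 1.1)
operationalizes "dN/dS ≈ 1" and is configurable; dS = 0 with dN > 0 is
reported as positive selection with an infinite ratio, and identical
sequences as undefined. The implementation is verified against an
independent exhaustive pathway-enumeration oracle and against a second,
externally maintained NG86 implementation.

## Power-law richness model

For each taxon, A is the summed TPM of its distinct ORF variants in
scope and d_obs their count. The model d_exp = c·Aᵞ is fitted by OLS of
log₁₀ d_obs on log₁₀ A (the base cancels in γ; it only scales the
intercept's standard error). Taxa with d_obs = 0 or A ≤ 0 are excluded
(the logarithm is undefined) and reported; a minimum-richness threshold
is exposed for sensitivity analysis. Standard errors are the analytic
OLS ones. δ = d_obs/d_exp is reported per taxon; because δ is computed
against the OLS fit of the same points, log₁₀ δ has mean zero (the
geometric mean of δ is one), and the spread of log₁₀ δ — visualized with
a Gaussian KDE, Scott bandwidth by default, grid spanning the observed
range ± 3 bandwidths — is the environment-level dispersion statistic.
Two fitted slopes are compared with z = (γ₁ − γ₂)/√(se₁² + se₂²) against
the standard normal; this treats the two fits as independent, which is
appropriate for different environments.

## Synthetic-data generators

The generators exist so that every analysis can be exercised, and its
estimators calibrated, without sequencing data. They emulate the
*statistical* structure the analyses assume, not biological sequence
content.

**ORF tables.** Per-taxon base-10 log abundances are uniform on a
4-decade range, then rescaled by a common factor so the expected total
richness Σ c·Aᵞ equals the requested table size — a rescaling of A that
preserves the generating law with the same c and γ. Realized per-taxon
richness is Poisson around c·Aᵞ; taxa that realize zero variants are
kept in the table metadata so their exclusion from fitting stays
visible. Defaults are chosen to mirror the heavy-water study system:
319 taxa, slope γ = 0.757, a 2.71% transposase ORF fraction, 5.95%
orphan fraction, G+C ~ N(0.663, 0.05) clipped to [0, 1], and lengths
from a lognormal (median 700 bp, σ = 0.45 on the natural-log scale,
giving a right-skewed distribution with mean ≈ 775 bp) truncated by
resampling to the observed 60–8,748 bp range and rounded to codon
multiples. Completeness flags are independent Bernoulli(0.95) per end.
Within a taxon, abundance is split across variants by a Dirichlet
(concentration 5); across samples, taxon abundances get lognormal
jitter (sd 0.1 on the log₁₀ scale). An optional transposase TPM share
rescales the labelled ORFs to hold an exact fraction of each sample's
abundance before the final normalization to 10⁶ — used when calibrating
the census to a target abundance. A `noiseless` mode replaces Poisson
scatter by rounding and back-solves A = (d/c)^(1/γ) so points lie
exactly on the law; it is meant for exact-recovery tests together with
`normalize=False`, because per-sample renormalization rescales all A by
a common factor, which leaves γ identifiable but shifts the intercept c.

What the table generator does *not* emulate: every sample shares the
same community (samples are jittered replicates, as in a co-assembly),
so cross-sample presence/absence variation is near zero — Jaccard
between generated samples is ≈ 1 by design, and β-diversity behaviour
is validated instead with `generate_presence_sets`, which constructs
sets with exact sizes and pairwise intersections. There is also no
annotation error, no chimerism, and no phylogenetic structure among
taxa. Calibration results on these tables therefore demonstrate
estimator correctness under the stated stochastic model, not robustness
to assembly or annotation artefacts.

**Codon pairs.** An ancestor of random sense codons receives a fixed
number of proposed single-nucleotide substitutions; proposals creating
stops are rejected, synonymous proposals are accepted with probability
1/(1 + ω) and nonsynonymous ones with probability ω/(1 + ω), so accepted
changes realize the nonsynonymous/synonymous rate ratio ω per proposal.
This acceptance-weighting scheme is deliberately simpler than a full
codon rate matrix (Goldman–Yang models are out of scope): it is adequate
for rank-level validation (purifying/neutral/positive recovery,
monotonicity of the estimated ratio in ω). One known artefact: because
stop-creating proposals are rejected while the NG86 site counts treat
stop-producing changes as nonsynonymous opportunities, the estimated
ratio at ω = 1 sits slightly below 1 (≈ 0.93 at high event counts).

**Composition matrices.** Group mean compositions are base ± profile/2
(uniform base 0.05 by default; profiles should sum to zero, otherwise
renormalization leaks the imbalance into unshifted residues); rows are
Dirichlet draws with concentration 500 around the group mean, keeping
every row on the simplex with realistic per-residue scatter (sd ≈ 0.01
at frequency 0.05).

## Validation problem sizes

The calibration suite uses: 100 replicate communities of 50,000 ORFs
over 319 (or 351) taxa for slope recovery — mean fitted γ agrees with
the generating value to well within ±0.03; single 3 × 50,000-ORF tables
for census recovery; 1,000 null replicates at group sizes 129 vs 70 for
t-test type-I calibration; 50 seeds per ω for regime recovery. The
regime-recovery simulations use 2,000 codons and 1,200 proposed events
per pair, sized by a power analysis so that the estimated ratio's
sampling spread is narrow enough for a (0.9, 1.1) neutral band to
capture the majority of ω = 1 runs; shorter pairs (300 codons, 60
events) are used where only the direction of the effect is asserted.

## Known limitations

* The richness fit ignores heteroskedasticity (Poisson noise on d means
  the log-scale variance shrinks with A) and the zero-truncation of
  excluded taxa; both are negligible at the calibrated community sizes
  but would bias γ on sparse communities with many one-variant taxa.
* The NG86 estimator is a counting method; likelihood-based estimators
  are more efficient at high divergence and are intentionally not
  provided.
* Per-residue enrichment ignores compositional dependence among the 20
  frequencies.
* The generators share one community across samples; they cannot be
  used to calibrate cross-sample β-diversity statistics (use the
  presence-set generator for that).
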