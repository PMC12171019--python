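# deuteromics

Downstream statistics for metagenomic ORF summary tables, built for the
kind of question raised by bacterial communities surviving in extreme,
nutrient-poor environments (the motivating case: decades-old heavy-water
storage drums): once a co-assembly pipeline has produced one row per
predicted ORF — taxonomy, functional annotations, length, completeness
flags, G+C and per-sample TPM — what do the abundances and sequences say
about community structure, gene repertoire and adaptation?

The package is aimed at microbial ecologists and bioinformaticians who
already have such a per-ORF table (or want to simulate one) and need the
bespoke statistics that general-purpose tools do not provide:

* **Abundance-weighted genomic statistics** — TPM-weighted mean and sd of
  gene length (complete ORFs only), G+C content, with the convention that
  every sample's abundances sum to 10⁶ TPM.
* **Diversity** — per-sample species richness with or without unclassified
  (`unknown_<k>`) species tags, and Jaccard presence/absence β-diversity,
  J(A, B) = |A∩B| / |A∪B|.
* **Functional censuses** — share of ORF counts and of TPM held by a
  category such as IS3-family transposases (gene-name keyword or
  COG2801/COG2963 orthogroup match), per-gene TPM matrices with alias
  groups, and the orphan (unannotated) fraction.
* **Amino-acid composition enrichment** — per-residue Welch t-tests between
  two protein groups, classifying each of the 20 residues as enriched,
  depleted or same, plus within-group composition self-correlation.
* **Selection screening** — Nei–Gojobori (1986) pairwise ka/ks: per-codon
  synonymous/nonsynonymous site counts, pathway-averaged difference
  counts, Jukes–Cantor correction, and classification into purifying
  (dN/dS < 0.9), neutral (≈ 1) or positive (> 1.1) regimes.
* **Sequence-richness modelling** — the power law d_exp = c·Aᵞ linking a
  taxon's summed abundance A (TPM) to its number of distinct sequence
  variants d, fitted by OLS in log10–log10 space as a Model/Results pair;
  per-taxon deviation coefficients δ = d_obs/d_exp with a Gaussian-KDE
  view of log₁₀ δ, spread comparison between environments, and a
  two-sample z test comparing fitted slopes.
* **Synthetic data** — seeded generators for every input above (ORF
  tables with power-law richness structure, codon pairs evolved at a
  chosen ω, two-group composition matrices, presence/absence sets), so
  the whole pipeline is testable without any sequencing data.

## Worked example

```python
import deuteromics as dm

table = dm.generate_orf_table(dm.CommunityConfig(
    n_taxa=150, n_orfs=20_000, n_samples=3, seed=11))

wl = dm.weighted_gene_length(table)
cen = dm.transposase_census(table)
fit = dm.PowerLawRichnessModel.from_orf_table(table, environment="drum1").fit()
print(f"weighted gene length: {wl.mean_bp:.1f} +/- {wl.sd_bp:.1f} bp")
print(f"transposase census: {cen.mean_count_pct:.2f}% of counts, "
      f"{cen.mean_tpm:.1f} TPM")
print(fit.summary())
z, p = dm.compare_slopes(fit.gamma, fit.se_gamma, 0.78, 0.023)
print(f"slope vs ocean reference: z = {z:.3f}, p = {p:.3f}")
```

prints

```
weighted gene length: 774.7 +/- 365.0 bp
transposase census: 2.74% of counts, 26816.8 TPM
Power-law richness fit: d_exp = c * A^gamma
  environment : drum1
  n points    : 145  (excluded: 0)
  gamma       : 0.7512 +/- 0.0111
  c           : 0.1006  (log10 se 0.0390)
  R^2         : 0.9695
slope vs ocean reference: z = -1.126, p = 0.260
```

The simulated community was generated with a transposase ORF fraction of
2.71% and a richness slope of 0.757, and both come back from the analysis
side: the census recovers the count share (2.74%), and the fitted slope
(0.751 ± 0.011) is statistically indistinguishable from an oceanic
reference slope of 0.78 ± 0.023 (|z| < 1.96), the same comparison one
would run between a real community and a reference environment.

A command-line interface mirrors the library (`deuteromics simulate`,
`stats`, `census`, `aacomp`, `kaks`, `richness`, and `deuteromics all
--config run.cfg` for a manifest-tracked multi-stage run).

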