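# Methods

## The problem and the model

A hemizygous deletion halves the DNA dosage of every gene it spans. In a
tumor specimen with tumor-cell fraction f ∈ (0, 1], the deletion signal of a
region carried by the tumor cells is diluted by the 1 − f admixture of normal
cells. `brcadel` models this one latent state — per sample: group label,
tumor fraction f, set of carried deletion regions — and propagates it through
four observation channels:

* **Expression.** x_gj = μ_g + 1{g deleted in j} · f_j · β + ε,
  ε ~ N(0, σ_e). β (`expr_effect`) is the expected log2 shift for a fully
  hemizygous gene; μ_g ~ N(7, 1.5) on the log2 scale, the typical intensity
  range of RMA-normalized arrays.
* **Array CGH.** log2 ratio = log2((f·c + 2(1 − f))/2) + N(0, σ_c), with
  c ∈ {1, 2} the tumor-cell copy number. At f = 1 a hemizygous probe sits at
  −1; at f = 0.5 at log2 0.75 ≈ −0.415.
* **BAF.** Heterozygous SNPs sit at 0.5 when balanced; under a one-copy loss
  they split into symmetric bands at 1/(2 − f) and (1 − f)/(2 − f)
  (which allele is lost is random per SNP). Homozygous SNPs sit at 0/1.
  Gaussian noise, clipped to [0, 1]. The paired-normal genotype is recorded
  (`is_het`).
* **FISH.** Each scored nucleus is a tumor cell with probability f (touch
  imprints contain normal cells at rate 1 − f). Green (pericentromeric)
  spots ~ Binomial(2, eff); red (deletion-probe) spots ~ Binomial(c_red, eff)
  with c_red = 1 in deleted tumor cells.

## Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| n_case / n_control | 7 / 24 | the training-cohort design being emulated |
| tumor_fraction_range | (0.50, 0.95) | the observed spread of tumor-cell content |
| penetrance | 1.0 | 13q/14q deletions as a hallmark of the case group |
| expr_effect | −0.7 log2 | hemizygosity under partial dosage compensation; the true per-copy expression drop is not identifiable from the published data, so this is a package choice |
| expr_noise_sd | 0.4 log2 | residual SD typical of RMA-normalized two-group arrays |
| cgh_noise_sd | 0.15 | BAC-array probe-level noise |
| baf_noise_sd | 0.03 | Illumina BAF scatter for well-behaved SNPs |
| fish_nuclei_per_sample / detection eff | 100 / 0.95 | routine interphase scoring; a probe occasionally fails to yield a visible spot |

The default genome is a compact 31-band layout (25 genes, 10 probes, 40 SNPs
per 10-Mb band): chromosomes 13 and 14 host the two deletion regions
(13q13–13q14, 14q24–14q32); five other chromosomes provide the neutral
background. One `SeedSequence` is split per modality in a fixed order
(truth, expression, CGH, BAF, FISH), so outputs are byte-identical under a
fixed seed and adding one modality never perturbs another.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: batch effects and normalization artifacts,
amplifications, subclonal heterogeneity beyond a single tumor fraction,
probe GC bias, gene–gene correlation beyond the shared deletion, and
heteroscedastic per-gene noise. The last point matters for interpretation:
with a single `expr_noise_sd` the log-variances are underdispersed relative
to chi-squared sampling noise, so the moderated-t prior df is typically
estimated as infinite on simulated cohorts (full shrinkage). On real arrays
d₀ is finite; the estimator is exercised on heteroscedastic inputs in the
unit tests, including a cross-check against the Bioconductor reference
implementation.

## Statistical machinery

**Moderated t.** Pooled two-group variance s²_g on d = n₁ + n₂ − 2 df.
Hyperparameters by moment matching of z_g = log s²_g: with
e_g = z_g − ψ(d/2) + log(d/2), the prior satisfies E[e] = log s₀² − ψ(d₀/2) +
log(d₀/2) and Var[e] = ψ′(d/2) + ψ′(d₀/2); d₀ solves the trigamma equation by
Newton iteration on 1/ψ′ (tolerance 1e-8, ≤ 50 iterations). If the observed
spread of e is below the chi-squared sampling noise, d₀ = ∞ and every gene is
shrunk fully to s₀² = exp(mean e). p-values are two-sided on d₀ + d df,
capped at the pooled residual df. Zero-variance genes are excluded from the
moment matching and flagged; their t is ±∞ (p = 0) unless the mean difference
is also zero (t = 0, p = 1). `df_prior` can be forced: 0 recovers the
ordinary pooled t exactly, ∞ gives fully shrunk statistics.

**BH adjustment** delegates to `statsmodels.stats.multitest` (`fdr_bh`); a
quadratic-time literal step-up definition serves as the test oracle.

**Signature and score.** Genes at adjusted p < 0.01 carry their t as weight;
the score is the weighted sum of mean-centered expression. Centering means
default to the training cohort's per-gene means and are frozen when scoring
a held-out cohort (`center="reference"`); `center="self"` reproduces a
within-set analysis. Both modes exist because the right choice for external
validation (frozen training means) is a convention, not a theorem. AUC is
the Mann–Whitney statistic with midranks, identical to the trapezoidal area
under the empirical ROC.

**Positional GSEA.** Weighted-KS running sum with exponent p = 1; ties in the
ranking statistic keep input order, so scores are deterministic. The null is
gene permutation: each permutation draws one shared reshuffling of the ranked
list for all sets, which keeps the family-wise statistics coherent. NES
divides ES by the mean |null ES| of matching sign; nominal p is the matching-
sign tail fraction floored at 1/(n_perm + 1) (a permutation p of exactly zero
is not meaningful); FWER is the fraction of permutations whose most extreme
sign-matched normalized null beats the observed NES. Sets with all-zero
in-set weights fall back to unweighted increments rather than failing.

**Copy number.** Calls are thresholded at ±0.25 log2 by default — the
conventional BAC-CGH operating point, exposed as a parameter since the
appropriate value depends on platform noise and expected tumor fraction
(at f = 0.7 a hemizygous probe sits at −0.62, comfortably below −0.25 at
σ_c = 0.15). The common region of overlap requires loss in 100% of case
samples; a single neutral probe breaks a run unless `gap_tolerance` > 0
(default 0 — interior breaks never move the outer boundaries, which is what
the recovery guarantee is about). Coordinates are 0-based half-open
throughout. BAF imbalance uses non-overlapping windows of consecutive
heterozygous SNPs (default 25) flagged when mean |BAF − 0.5| > 0.15; the
paired-normal genotype column is preferred for het selection because tumor
BAF alone under-calls hets inside strong imbalance.

**FISH scoring.** The modal green count defines ploidy; ties break toward
the larger count so partial centromeric dropout does not spuriously lower
ploidy. The deletion percentage uses modal-green nuclei as the denominator
(the reading consistent with scoring "nuclei with the modal number of green
spots"); nuclei with green ≠ modal are excluded. The single-green/single-red
clause makes (1,1) nuclei count as deleted monosomy when the modal count is
1. The all-nuclei denominator is available (`denominator="all"`) because the
published convention cannot be pinned down from text alone; the downstream
contingency tables are invariant to the choice at the printed precision.
Fisher's exact test uses the probability-ordering two-sided definition,
computed with exact integer arithmetic (binomial-coefficient numerators over
C(n, c1)), so ties in table probabilities are resolved exactly; the battery
of unit tests compares it against an independent floating-point
implementation.

**Centroid clustering.** Agglomerative centroid linkage (cluster centroid =
mean of member rows) with 1 − Pearson distance, ties broken by lowest
cluster-index pair. Hand-rolled because library implementations define
centroid linkage only for Euclidean geometry; O(n³), intended for
signature-scale matrices. Constant rows get correlation 0 by convention.

## Validation experiments (`brcadel.reproduce`)

* `published_fish_analysis` / `published_signature_counts` re-derive the
  packaged tables' contingency statistics and band bookkeeping from the raw
  TSVs at run time.
* `synthetic_recovery` (10 seeds; penetrance 1, effect −0.7, f ∈ [0.7, 0.95],
  10 + 20 samples): deleted bands must occupy the most negative NES ranks,
  common-region boundaries must sit within one probe spacing of truth
  (1 Mb in the default genome), and the held-out AUC uses a second cohort
  simulated from a derived seed and scored with frozen training means.
* `enrichment_null_calibration` (200 replicates × 5 random sets on random
  rankings, 250 permutations each) measures the nominal-p type-I rate.
* `fish_null_rejection` (200 penetrance-zero replicates of a 9 + 9 cohort):
  with no deletions, every deletion percentage sits near
  f · 0 + (1 − eff²) ≈ 10%, far below the 50% rule; the contingency table is
  degenerate (all "other") and the exact test returns p = 1, so the
  rejection rate is ~0 — the test is conservative, never anticonservative,
  under this null.

Problem sizes (10 seeds, 200 replicates, 250–1000 permutations, the 31-band
genome) were chosen so the full validation runs in well under a minute while
keeping binomial standard errors small enough for the calibration checks to
be informative.

## Known limitations

* The moderated-t implementation covers the two-group design only (no
  multi-factor linear models, no intensity-trend or robust variants).
* GSEA uses the gene-permutation null; phenotype permutation is out of scope
  because the ranking enters as a precomputed statistic.
* No segmentation (CBS/HMM) or purity/ploidy inference: copy-number calls
  are per-probe thresholds, appropriate for the high-amplitude hemizygous
  losses modelled here but not for focal low-amplitude events.
* FWER p-values are reported unfloored and can be exactly 0 when no
  permutation beats the observed NES.
* The FISH model treats nuclei as independent and ignores sectioning
  artifacts (spot loss is a single detection-efficiency parameter).
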