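# brcadel

Breast tumors arising in carriers of germline *BRCA2* mutations tend to carry
hemizygous deletions of large regions on chromosome arms 13q and 14q. Because
the deletions reduce the DNA dosage of the genes they span, they leave a
coordinated footprint across four read-outs: reduced log2 expression of the
resident genes, negative array-CGH log2 ratios, splitting of heterozygous
B-allele frequencies on SNP arrays, and reduced deletion-probe spot counts in
two-color interphase FISH. `brcadel` implements the full inference chain that
turns this footprint into a screening test, for statisticians and
bioinformaticians working on tumor classification from expression and
copy-number data:

1. **Differential expression** — probeset collapse (most variable probeset
   per gene symbol) and the empirical-Bayes *moderated t-statistic*: the
   per-gene pooled variance s²_g with d residual df is shrunk toward a prior
   s₀² with d₀ prior df estimated by moment matching of log s²_g,

       s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
       t_g  = (x̄_case − x̄_control) / (s̃_g · √(1/n₁ + 1/n₂)),

   with Benjamini–Hochberg FDR control and signature selection at FDR < 0.01.
2. **Signature scoring** — the BRCA2 score S_j = Σ_g w_g (x_gj − m_g), with
   weights w_g the moderated t-values and m_g per-gene centering means,
   evaluated by ROC/AUC (rank-sum definition, ties counted ½).
3. **Positional enrichment** — preranked GSEA over cytogenetic-band gene
   sets: weighted Kolmogorov–Smirnov enrichment score (exponent p = 1),
   gene-permutation null, NES, nominal p and family-wise error rate.
4. **Copy-number profiling** — threshold gain/loss calls on ordered probe
   log2 ratios, per-group cumulative aberration frequencies, the common
   region of overlap (probes lost in 100% of case tumors), and window-based
   BAF allelic-imbalance flagging.
5. **FISH deletion test** — per-nucleus green/red spot counts reduced to a
   deletion percentage (share of modal-green nuclei with fewer red spots),
   loss calls at the ≥50% rule, and exact 2×2 evaluation: a two-sided Fisher
   exact test computed by exact integer lattice enumeration, plus
   sensitivity/specificity.
6. **Synthetic cohorts** — a ground-truthed generator producing all four
   modalities from one latent state (per-sample tumor fraction and carried
   deletions), used to validate every stage end to end.

The 66-gene signature table and the 18-sample FISH screen ship with the
package as plain TSV (`brcadel.datasets`).

## Worked example

```python
from brcadel.simulate import CohortConfig, simulate_cohort
from brcadel import diffexp, enrichment, score, fish

cohort = simulate_cohort(CohortConfig(seed=1))   # 7 case vs 24 control tumors
stats = diffexp.moderated_t(cohort.expression)
sig = diffexp.select_signature(stats, fdr_threshold=0.01)
print(f"signature: {len(sig)} genes at FDR<0.01")

ranked = enrichment.rank_genes(stats.table.index.to_numpy(), stats.t.to_numpy())
ann = cohort.truth.genes.reset_index().rename(columns={"gene_id": "gene"})
gsea = enrichment.preranked_gsea(ranked, enrichment.make_band_sets(ann, ranked),
                                 n_perm=1000, seed=1)
print(gsea.head(5).round(3))

scores = score.score_samples(cohort.expression, sig)
print(f"training AUC = {score.roc_auc(scores, cohort.expression.labels).auc:.3f}")

calls = fish.summarize_fish(cohort.fish, cohort.expression.labels)
table = fish.build_contingency(calls, scope="both")
print(f"FISH 2x2 {table.tolist()}  Fisher p = {fish.fisher_exact_two_sided(table):.2e}")
```

prints

```
signature: 19 genes at FDR<0.01
       size     es    nes  p_nominal  p_fwer
band
13q13    25 -0.833 -2.202      0.001     0.0
14q24    25 -0.814 -2.151      0.001     0.0
14q31    25 -0.810 -2.140      0.001     0.0
14q32    25 -0.805 -2.127      0.001     0.0
13q14    25 -0.782 -2.066      0.001     0.0
training AUC = 1.000
FISH 2x2 [[0, 7], [24, 0]]  Fisher p = 3.80e-07
```

The five bands with the most negative NES are exactly the five bands inside
the two planted deletion regions (13q13–13q14 and 14q24–14q32), each with a
nominal p at the permutation floor (< 1/1000); the t-weighted signature
separates the groups perfectly on this cohort; and the FISH screen calls
every fully penetrant case tumor "loss" on both chromosomes
(Fisher p ≈ 4 × 10⁻⁷).

The same analyses run from the shell:

```sh
brcadel simulate --seed 1 --out cohort/
brcadel run --seed 1 --out run/          # full pipeline + manifest.json
brcadel fishcall --counts cohort/fish_counts.tsv --labels cohort/labels.tsv \
        --threshold 50 --scope both --out-prefix fish
```

Sklearn-style estimators (`brcadel.diffexp.ModeratedTTest`,
`brcadel.score.SignatureScorer`) expose the moderated t-test and signature
scoring with `fit` / `decision_function` / `get_params` for use in sklearn
pipelines and model selection.

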