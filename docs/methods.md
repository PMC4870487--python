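# Methods

## Scope and model

`methylotype` analyses promoter-centric methylation-array data (27K-style:
one beta value per CpG probe, `β = M/(M+U) ∈ [0,1]`) from luminal (ER+)
breast tumors and adjacent normal tissue, and asks whether the tumors split
into a *methylator* epigenotype — widespread CpG-island promoter
hypermethylation, enriched for Polycomb (PRC2) target genes — and a
low-methylator group, and whether a handful of CpGs suffices to call that
split per sample. The chain is:

1. **Differential methylation.** Testing happens on M-values
   (`M = log2(β/(1−β))`, variance-stabilized); effect sizes stay on the
   beta scale (`Δβ` = difference of group mean betas, directly
   interpretable as a methylation-fraction change). A probe is
   differentially methylated when the Benjamini–Hochberg q-value of its
   moderated t-test is `< 0.05` **and** `|Δβ| > 0.2` (both strict). The
   moderated t shrinks each probe's pooled variance toward a prior fitted
   to all probes: with per-probe residual variance `s_g²` on
   `d_g = n1+n2−2` df, the marginal model `s_g² ~ s_0² F(d_g, d_0)` is
   fitted by method of moments on `log s_g²` (trigamma inversion by Newton
   iteration), the posterior variance is
   `s̃_g² = (d_0 s_0² + d_g s_g²)/(d_0 + d_g)`, and
   `t̃ = Δmean / (s̃ √(1/n1+1/n2))` is referred to `t(d_0 + d_g)`.
2. **Clustering.** Tumor samples are clustered on the beta values of the
   tumor-vs-normal signature probes, Manhattan distance + Ward.D2 linkage
   (Lance–Williams on squared dissimilarities, heights reported
   unsquared). Cluster confidence comes from multiscale bootstrap of the
   probes: at scale ratios `r = 0.5 … 1.4` (step 0.1), `B` replicates of
   `n′ = round(r·n)` probes are drawn with replacement, the tree is
   recomputed, and a cluster's `BP_r` is the fraction of replicate trees
   containing its exact leaf set. With `σ = √(n/n′)`, the quantiles
   `z_r = Φ⁻¹(1−BP_r)` are fitted by weighted least squares (binomial
   delta-method weights) to `z(σ) = vσ + c/σ`, and the approximately
   unbiased support is `AU = 100·(1−Φ(v−c))`. Clusters with `AU > 95`
   and ≥ 5 members (maximal, non-nested, root excluded) are reported; when
   exactly two partition the tumors they are labelled CI (lower mean
   methylation) and CII (methylator).
3. **Signature characterization.** Cluster-specific signatures (CI vs
   normal, CII vs normal, CII vs CI, same dual criterion, known-SNP probes
   excluded) are cross-tabulated by gene-region category
   (TSS1500/Promoter/Body/3′UTR) and CpG class (island/shore/poor) and
   compared by Pearson chi-squared without continuity correction. PRC2
   enrichment of promoter methylation events is a one-sided
   hypergeometric tail against the tested promoter background.
4. **Marker panel and Epi-calls.** From the CII-vs-CI signature, *perfect
   markers* are probes whose beta ranges in CI and CII do not overlap
   (AUC exactly 1, verified as set separation, never a float comparison
   to 1.0); ties beyond the panel size are broken by separation margin,
   then probe id. Each marker's cutoff is `μ_A + 2σ_A` over the
   luminal-A samples (sample SD, n−1). A sample exceeding the cutoffs of
   a strict majority of the (default three) classifier markers is called
   `Epi_lumB_HER2`, else `Epi_lumA`.
5. **Clinical association.** Continuous covariates (Ki-67, size) by
   Mann–Whitney U (exact null when combined n ≤ 12 and tie-free, normal
   approximation with tie correction otherwise); categorical ones (grade,
   node, PgR status at the 20 % positivity threshold) by chi-squared,
   with Fisher's exact substituted automatically when an expected cell
   is below 5.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `q_threshold` | 0.05 | — | conventional FDR level of the dual criterion |
| `delta_threshold` | 0.2 | beta | biologically meaningful methylation change; strict `>` |
| `au_threshold` | 95 | % | support level used for the headline two-cluster finding; 90 also defensible and exposed |
| `min_cluster_size` | 5 | samples | below this, AU estimates are dominated by single samples |
| `scales` | 0.5–1.4 step 0.1 | ratio | standard multiscale grid; ≥3 informative scales needed for the WLS fit |
| `n_boot` (B) | 1000 | replicates/scale | binomial SE of BP ≈ 1.6 % at BP = 0.5 |
| `panel_k` | 25 | markers | size of the reported perfect-marker panel |
| `classifier_markers` | 3 | markers | the cutoff classifier uses the top 3 by margin |
| `rule` | majority | — | the combination of per-marker exceedance flags is not dictated by the science; strict majority is the symmetric default, `all`/`any` are exposed (with 3 markers, `all` trades sensitivity for specificity, `any` the reverse) |
| `epsilon` (logit clip) | 1e−6 | beta | keeps M-values finite at β ∈ {0,1}; standard practice |

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
a desk scale mirroring the discovery cohort's proportions: 8 normals and
28 tumors (8 luminal A, 16 luminal B with half latent methylators, 4
luminal B-HER2) over 5,000 probes.

* Per-probe baseline means are a bimodal mixture (65 % low, N(0.10,
  0.05²); 35 % high, N(0.85, 0.05²); clipped to [0.02, 0.98]) — the
  classic two-peak beta-value histogram of promoter arrays.
* Measurement noise is Beta(mc, (1−m)c) with concentration `c = 50`:
  bounded, heteroscedastic (variance shrinks toward 0/1), SD ≈ 0.07 at
  m = 0.5 — typical for 27K-era arrays.
* 300 *tumor-dm* probes gain `+Δβ` (default 0.3) in every tumor; 300
  *methylator* probes — drawn preferentially from low-baseline
  island/promoter probes — gain `+Δβ` in every tumor **plus** a further
  `+Δβ` in methylator-epigenotype samples only. The nesting is
  deliberate: the low-methylator cluster's aberrant CpGs are thereby a
  subset of the methylator cluster's, the pattern seen in luminal tumors.
* Every luminal B-HER2 tumor is a latent methylator, a configurable half
  of luminal Bs are, and no luminal A is. IHC values are drawn truncated
  to each subtype's St Gallen region with Ki-67 moments matching the
  discovery cohort (luminal A 10 ± 4 %, luminal B 43 ± 23 %, B-HER2
  50 ± 22 %), so surrogate subtyping of the generated sheet reproduces
  the intended subtype by construction.
* PRC2 target flags: background rate 0.12; methylator probes get the
  background odds multiplied by `prc2_enrichment_factor` (default 4).
  5 % of probes carry a known-SNP flag.

**What it does not emulate:** batch/chip effects, probe cross-reactivity,
detection failures, tumor purity gradients, copy-number interference, and
correlated probes within islands (probes are independent given their
class). Passing tests therefore certify the statistical machinery under
the assumed model, not robustness to those artifacts on real arrays.

## Numerical choices and degenerate inputs

* Zero-variance probes keep `s² = 0` but receive finite posterior
  variance whenever `d_0 > 0`; if `d_0 = 0` their statistics are NaN with
  a warning. If *all* log variances are identical the prior is that
  common variance with `d_0 = ∞`, making shrinkage an exact no-op.
* BH q-values propagate NaN inputs as NaN (warned) without counting them
  toward the number of tests.
* Quantile normalization averages reference values across tied runs and
  is exactly idempotent on tie-free input; it refuses single-column and
  incomplete matrices.
* AU fits need ≥ 3 scales with BP strictly inside (0,1); otherwise the
  node is clamped to 0 or 100 and flagged degenerate (a cluster seen in
  every replicate at every scale is reported as 100, never extrapolated).
  The root node is excluded from significant-cluster selection.
* Ward.D2 is delegated to `scipy.cluster.hierarchy.linkage(method="ward")`
  on the precomputed Manhattan condensed distances — mathematically the
  same recurrence as the R `hclust ward.D2` convention; an independent
  brute-force agglomerator backs it in the tests. scipy's nearest-neighbor
  chain resolves ties internally (deterministically); merge heights at
  exact ties can order differently from a lowest-index rule, which is
  immaterial for tie-free continuous data.
* All randomness flows from a single config seed; the bootstrap stage
  seed is spawned from it via `SeedSequence`, so reruns are bit-identical.

## Design choices made where the design was open

* **Test scale vs effect scale.** Moderated t on M-values, `Δβ` and
  clustering on beta values: the statistically efficient scale for
  testing, the interpretable one for effects and distances.
* **SNP filter timing.** Known-SNP probes are removed at signature
  selection (after testing), not before; the filter is an
  interpretability measure, not a power measure.
* **Normalization entry point.** Raw two-channel intensity processing is
  out of scope; the matrix-level quantile method is provided and is
  off by default for inputs that are already normalized (including the
  generator's output, which simulates clean betas).
* **Validation cutoffs.** `fit_cutoffs` can be re-run on any cohort's
  luminal-A samples (the CLI `classify --luma-ids` path); frozen
  discovery cutoffs are the alternative when no reference samples exist.
* **Enrichment background.** The tested probe set (post-QC universe), not
  the whole array; a different background may be passed explicitly.

## Problem sizes used by the test suite

Unit tests run on 1,200–4,000-probe cohorts; the simulation studies
(cluster support calibration, selection operating characteristics,
end-to-end marker recovery) use the default 5,000 × 36 desk-scale cohort
over 20 seeds with B = 1000 bootstrap replicates per scale, sizes at which
every targeted property is comfortably identified while the whole suite
stays interactive.

## Known limitations

* Two-group contrasts only; no design-matrix generality (covers every
  comparison the pipeline makes).
* AU values are themselves bootstrap estimates; at B = 1000 their SE near
  95 % is roughly 0.7 %, so borderline clusters can flip across seeds.
* The perfect-marker criterion (strict range separation) is brittle under
  label noise by construction; the margin ranking partially mitigates it.
* The mean + 2 SD cutoff presumes approximately unimodal luminal-A betas
  at panel CpGs; heavy contamination of the reference group would inflate
  cutoffs and depress sensitivity.
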