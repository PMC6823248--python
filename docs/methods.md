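# Methods

## The synthetic splenocyte experiment

The generator emulates bulk RNA-seq of whole splenocytes from a two-group
(control vs treated) mouse cohort in which treatment depletes specific
immune populations. The tissue is modelled as a mixture of cell modules
c ∈ {PC, GC, Tfh, B, Myeloid} with latent proportions π_c, plus an
unmodelled "other" remainder. Treatment multiplies each π_c by κ_c.
Marker genes of module c are expressed λ-fold higher inside their own cell
type than elsewhere, so their bulk mean scales with the latent proportion:

    μ_ij = L_j · b_i · (1 + (λ−1) · π_{c(i),j})   for marker gene i,
    μ_ij = L_j · b_i                              otherwise,

multiplied by 2^δ_i for direct-effect genes in treated samples. Counts are
negative binomial with Var = μ + φμ² (Poisson at φ = 0). Proportions are
fixed within a group (control π_c, treated κ_c π_c), so the mean model is
exact given the drawn baselines and library sizes; the ground-truth object
records every latent and can reproduce the full μ matrix.

### Parameters, defaults, and why

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | desk-scale panel; large enough for a stable variance prior |
| samples | 4 vs 4 | typical mouse cohort size for this design |
| modules | PC/GC/Tfh/B/Myeloid × 20 markers | the populations a splenitis readout tracks |
| π_c | 0.05 / 0.05 / 0.05 / 0.40 / 0.10 | realistic splenocyte composition: B cells dominate, GC/Tfh/PC are small compartments |
| κ_c | 0.2 (PC, GC, Tfh), 0.6 (B, Myeloid) | strong ablation of the germinal-center axis, milder reduction elsewhere |
| λ (marker_fold) | 10 | strong lineage markers are ≥10-fold enriched in their own cell type |
| φ (dispersion) | 0.01 | biological CV of 10% (√φ), the conventional value for genetically identical model organisms (inbred/F1 mice); φ is the NB dispersion, not the CV — conflating the two would put mouse replicates at human-cohort noise levels and no analysis could see a 2-fold change at n = 4 |
| δ (direct_lfc) | ±1 log2 on 100 genes | a 2-fold direct transcriptional response |
| library size | 10⁶, log-normal σ = 0.2 | exercises CPM normalization without dominating it; means are mean-centered so depth is unbiased across groups |
| baseline b_i | log-normal σ = 1, normalized | wide but not extreme abundance spread |

What the generator does **not** emulate: batch effects, gene length/GC
bias, correlated genes beyond the module structure, single-cell zero
inflation, and compositional coupling (depleting one population does not
renormalize the others' proportions upward). Passing recovery tests
therefore show the chain detects composition and direct effects under
clean NB noise — not robustness to confounding found in real cohorts.

## Differential expression

Counts are transformed per sample to log2(CPM + 0.5); the +0.5 offset
keeps zeros finite and is a declared convention. The two-group fit gives
logFC = mean(treatment) − mean(reference) and the pooled variance on
d = n₁+n₂−2 df. The variance prior is fitted by moment matching on
e_g = log s²_g − ψ(d/2) + log(d/2): d₀ solves ψ′(d₀/2) = var(e) − ψ′(d/2)
(monotone root-finding on the trigamma; d₀ = ∞ when the excess spread is
non-positive, in which case s₀² is the mean of the variances — the
convention of limma's `fitFDist`, against which the whole chain is
cross-checked via Rscript). Moderation is global: the single (d₀, s₀²)
pair shrinks every gene. An intensity-dependent ("trend") prior is
deliberately not implemented — the global model is the documented core of
the procedure and the trend variant would add an unverifiable smoothing
choice.

Conventions: two-sided p throughout; d₀ = 0 is accepted and reproduces the
classical pooled t; s̃² = 0 with logFC ≠ 0 reports t = ±∞, p = 0; genes
with zero variance are excluded from prior fitting (warning above 10%).
The FDR threshold is configurable; the treated-vs-control contrast
defaults to q < 0.1 and the disease-tissue contrasts in the compare stage
to q < 0.05, both exposed in `PipelineConfig`.

## Single-sample module scores

Gene-level statistic: z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) with Gaussian
Φ and h_i = s_i/4 (sample sd, ddof = 1) — the standard kernel choice for
continuous log2 data. Constant genes get z = 0.5. Genes are ranked by z
descending within each sample; ties break by input row order (stable,
documented, deterministic). The walk weight is ρ^τ with ρ = |p/2 − r| and
τ = 1 by default (τ = 0 gives the classical unweighted KS walk).

The reported ES defaults to ES⁺ + ES⁻ ("signed_sum"), which matches
"difference of the two extreme deviations" and yields one score per
(module, sample) cell for heat maps; `max_abs` (the single extremum of
larger magnitude, exact ties resolved positive with a 1e-12 tolerance) is
a config switch. If every member of a module sits exactly at rank p/2
with τ > 0, the weight sum vanishes; the walk falls back to unweighted
steps so the score stays defined. Scores are relative within the cohort
passed in — they are not comparable across independently scored datasets.

The packaged GMT carries the printed 7-gene GC and 5-gene Tfh modules; the
plasma-cell record is a synthetic placeholder (marked as such in the file)
that users should replace with a curated PC signature.

## Category counting and enrichment

Registries are strictly one-category-per-gene (duplicate genes are a load
error); compound names like "T & B cells" are single vocabulary entries.
Counting never drops genes silently — unmatched genes appear as an
explicit row. Enrichment uses the genes that entered DE as the universe
(not a whole-genome annotation, which would inflate significance with
never-tested genes). Chi-square is Pearson without continuity correction,
flagged at p ≤ 0.05 with over-representation; the exact upper-tail
hypergeometric test is flagged at p < 0.01 and doubles as the oracle for
the chi-square in tests. Raw-p thresholds are the convention for these
category screens; a BH option across categories exists but is off by
default. No GO hierarchy is modelled: functional enrichment is plain
overlap against a flat user registry.

## Pathway activation and concordance

Z = (N⁺ − N⁻)/√(N⁺+N⁻) over pathway genes whose DE direction matches /
opposes the registry's expected direction; |Z| ≤ √(N⁺+N⁻) with equality
iff unanimity. Significance thresholds are inclusive (|Z| ≥ 2, overlap
p ≤ 0.05). Pathways with zero DE members are retained with missing Z so
rows stay aligned across datasets. Concordance counts, for each pathway
suppressed in the treated contrast, the disease-tissue profiles with
Z > 2; missing pathways (or missing Z) count as non-concordant; the
classification needs ≥ 2 of 3 tissues by default (both configurable).
Gene symbols are matched after trimming and upper-casing on both sides, so
mouse Title-case and human upper-case symbols co-match; ortholog mapping
beyond symbol identity is out of scope.

## Numerical and design notes

- Determinism: one run seed; every stochastic stage derives a sub-seed via
  `SeedSequence([seed, stream])`. Output tables are tab-separated with
  floats at 6 significant digits; the JSON manifest is sorted-key, and a
  manifest alone replays a run byte-for-byte.
- Duplicate gene rows in raw counts are summed (per-gene aggregation);
  duplicates in log2 input are ambiguous and rejected.
- The trigamma inverse uses bracketed Brent root-finding on [1e-8, 1e8]
  with asymptotic fallbacks at both ends.
- Validation sizes: oracle-equivalence tests run 20 seeded 50×8 matrices;
  recovery tests run 100 seeds of the default experiment (DE recovery
  averaged over 20); the acceptance script uses 20 runs — sizes chosen to
  make Monte-Carlo noise small relative to the margins being checked.

## Known limitations

- Two-group, single-factor designs only; no precision weights, surrogate
  variables or batch correction.
- The activation Z is the unweighted published form; commercial
  pathway tools add proprietary edge weights and causal-network logic, so
  numerical agreement with their scores is not expected and not claimed.
- The chi-square and exact overlap p agree within ~2× only in the bulk of
  typical tables; deep-tail p-values diverge multiplicatively (use the
  exact test when tails matter).
- No permutation significance for module scores; ES magnitudes are
  descriptive within a cohort.
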