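# Methods

## The question and the two estimators

In species with heteromorphic sex chromosomes (XY males here), males carry
one X against two copies of every autosome. *Complete dosage compensation*
means regulatory hyperexpression of the single male X up to autosomal
levels. The package implements the two standard transcriptomic tests:

1. **Within-species X:AA ratio.** For each sex,
   `X:AA = median(RPKM of X-linked genes) / median(RPKM of autosomal genes)`.
   Under complete compensation the male ratio is ≈ 1; with no compensation
   it is ≈ 0.5; regulatory-network buffering without a dedicated mechanism
   is expected to land in ≈ 0.6–0.75. The female ratio is ≈ 1 throughout
   (two X copies) and serves as an internal control. Because lowly
   expressed genes can distort median ratios, the statistic is swept over
   filtering regimes: no filter, removal of genes with RPKM = 0 in both
   sexes, and removal of genes with RPKM below a cutoff c ∈ {1, 2, 3, 4}
   in at least one sex. A two-sample Wilcoxon rank-sum test per regime
   asks whether X-linked and autosomal expression levels differ at all.

2. **Cross-species ortholog ratio.** The X:AA ratio inherits any
   difference in gene content between the X and the autosomes. The
   sharper test compares each X-linked gene with its one-to-one ortholog
   in a related species whose sex-determining chromosomes are homomorphic
   (both sexes effectively diploid genome-wide). Per sex, the per-pair
   ratio r_g = RPKM_focal / RPKM_ortholog is rescaled by
   λ = 1 / median{r_g : g autosomal}, which absorbs depth and global
   expression-level differences between species; the autosomal normalized
   median is exactly 1 by construction, and the X-linked normalized
   median reads out compensation directly (≈ 1 complete, ≈ 0.5 none in
   males; ≈ 1 in females either way).

## Scaffold-to-arm assignment

Fragmented assemblies rarely name chromosomes. Scaffolds are assigned to
the five anopheline chromosome elements (X, 2R, 2L, 3R, 3L) by a vote of
their genes' one-to-one orthologs in a reference species with
chromosome-level placements. A scaffold is assigned to the modal arm of
its ortholog-bearing genes iff

* at least 3 genes on the scaffold carry orthologs,
* strictly more than 92% of those genes point to the modal arm, and
* no run of more than 3 consecutive ortholog-bearing genes points to a
  different arm.

Genes without orthologs contribute neither to the percentage nor to runs
(the vote is defined on ortholog evidence). Ties for the modal arm give
UNASSIGNED — determinism over arbitrary choice. Genes inherit their
scaffold's arm; genes on unassigned scaffolds are excluded downstream.
The rule is orientation-symmetric and invariant to gene renaming.

## Normalization

Library composition is corrected with TMM (trimmed mean of M-values,
Robinson & Oshlack 2010), reimplemented from the published definition:
reference = sample whose 75th-percentile count fraction is closest to the
across-sample mean; for sample k vs reference r over genes positive in
both, M_g = log2((y_gk/N_k)/(y_gr/N_r)) and A_g = ½·log2 of the product;
the top/bottom 30% by M and 5% by A are trimmed; the factor is
2^(Σ w_g M_g / Σ w_g) with inverse delta-method variance weights, and
factors are rescaled to geometric mean 1. Expression is then
RPKM = 10⁹ · count / (exonic length in bp × effective library size), with
"per million mapped reads" realized as per million counted reads — the
only totals a count table carries. Replicates are pooled by count
summation (equivalent to concatenating read files before counting); a
per-replicate-RPKM averaging alternative is exposed via
`sex_expression(..., method="average")` because published descriptions of
"average RPKM from combined files" are ambiguous between the two.

## Sex-biased genes and their chromosomal distribution

Sex-biased genes are defined by consensus: a gene is biased iff at least
two differential-expression methods flag it significant with the same
direction; any direction conflict demotes it. The package ingests
external call tables (edgeR/DESeq2/Cuffdiff or anything else) and ships
two lightweight internal stand-ins — a Welch t on log2(RPKM + 0.5) across
replicates and a pooled-count proportion z-test, both BH-adjusted — so
the consensus machinery and everything downstream can run on simulated
counts alone. The stand-ins are deliberately simple detectors, not
substitutes for dedicated DE models; their only calibrated guarantee
(tested) is per-gene type-I control near the nominal level under the null.

Fold-change magnitude uses pooled RPKM with a pseudocount ε = 0.01,
oriented high-sex/low-sex. Genes expressed (RPKM ≥ 2) in exactly one sex
are additionally labeled sex-specific and always count as maximally
biased. Biased genes are binned into half-open fold-ratio bins
[e_i, e_{i+1}) with default edges {1.5, 2, 3, 4, 8, 16}, top bin
unbounded.

**Permutation test.** For a biased set at fold threshold t, the statistic
is the proportion of biased genes on the X among expressed, arm-labeled
genes. The null permutes the biased/unbiased labels over genes; because
only the X-overlap count matters, null draws are taken from the
equivalent sampling-without-replacement (hypergeometric) distribution,
which is mathematically identical to label permutation and vectorizes.
One-sided p-values use the (1 + #extreme)/(1 + n_perm) correction,
n_perm = 10,000 by default; the exact hypergeometric tail is always
reported alongside as a cross-check. Depletion of male-biased genes on
the X is *demasculinization*; enrichment of female-biased genes is
*feminization*. A threshold sweep reports the smallest fold cutoff at
which each becomes significant.

**Enrichment.** Term overrepresentation in a gene set is the upper
hypergeometric tail P(X ≥ k) for k annotated genes among n selected, K
annotated among N universe genes; terms with K < 3 are skipped and BH
values reported next to raw p. Annotations are used as given (no
ontology-graph propagation). The universe defaults to expressed genes.

## The synthetic-data generator

The generator produces the structure the analysis assumes, with known
truth, so every stage is testable without external data:

* **Genome.** Five arms × 1,000 genes on 8 scaffolds per arm. A fraction
  (default 0.1) of scaffolds is "mixed": a contiguous run of 1–5 genes is
  relabeled to a second arm, exercising both branches of the
  contiguous-run rule. 90% of genes carry a reference-species ortholog
  whose arm equals the gene's true arm. Gene models are single-exon with
  log-normal exonic length (μ = 7.5, σ = 0.7; median ≈ 1.8 kb).
* **Counts.** Expected count of gene g in sample s is
  lib_s · b_g L_g d_gs / Σ_h b_h L_h d_hs with log-normal baseline b,
  length L in kb, and multiplier d = 1 for females and male autosomal
  genes; for male X genes d is 1 (complete), 0.5 (none) or the buffer
  factor (buffered, default 0.7) — female X expression is never altered.
  Sex-biased genes multiply the male side by 2^effect; sex-specific genes
  have the mean zeroed in the other sex. Counts are negative binomial via
  gamma–Poisson mixing with shared dispersion φ = 0.1 (variance
  m + φm²); φ = 0 is the deterministic limit (counts = rounded means).
  Default 3 replicates per sex, library sizes log-normal with mean 5×10⁶
  and CV 0.2.
* **Effect sizes.** |log2 FC| ~ Exponential(mean 2), sign ± with equal
  probability, capped at 12 (≈ 4,000-fold). The cap matters: an uncapped
  exponential with mean 2 has rate 0.5 < ln 2, so the expected fold
  change is infinite and single genes can absorb most of a library;
  real whole-body libraries have strongly expressed sex-specific genes
  (sperm and chorion proteins) but not single-gene dominance. 35% of
  genes are biased, 5% of those sex-specific.
* **Second species.** Every focal gene gets exactly one ortholog in a
  homomorphic species (d = 1 everywhere). Ortholog log-baselines come
  from a Gaussian copula whose latent correlation is inflated by the
  analytic attenuation factor R = σ_b²/(σ_b² + φ/m_reps + 1/(reps·m̄)),
  so the *realized* rank correlation of log-expression — what one
  measures on data — matches the requested `ortholog_rho` (default 0.6,
  emulating reported cross-species correlations of ~0.5–0.65). At
  ρ = ±1 the latent correlation clamps and baselines are comonotone.

**Why baseline σ = 0.3.** The recovery contracts pin the male X:AA
median ratio into ±0.05 bands at 1,000 X genes. The sampling SE of the
log median ratio is ≈ sqrt(σ_b² + φ/reps)·1.2533·sqrt(1/n_X + 1/n_A);
σ_b = 0.3 with φ = 0.1 gives ≈ 0.016, putting the band edges at ≥ 3 SE.
Real transcriptomes are considerably broader (log-SD ≥ 1.5); the narrow
spread trades realism of the expression *distribution* for precise
recovery of the *ratio*, which is the quantity under test. A consequence
worth knowing: with 5,000 genes the simulated median RPKM sits in the
tens under unbiased configurations (the statistic is scale-free, so this
is cosmetic), and low-expression filters remove few genes unless
sex-specific zeros are present.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: isoforms and multi-exon structure, GC and
length biases, batch effects, read-level errors and mapping ambiguity,
correlated dispersion (expression-level-dependent φ), inter-gene
correlation, chromosome-specific gene content, and tissue allometry
(gonad-driven bias in whole-body comparisons).

## Numerical choices and degenerate inputs

* Filter comparisons are strict: a gene exactly at the cutoff is kept;
  bin edges are half-open with the boundary in the higher bin.
* The Wilcoxon test enumerates the exact rank-sum null (dynamic
  programming) when n_a + n_b ≤ 12 without ties; otherwise it uses the
  normal approximation with midranks, tie-corrected variance and 0.5
  continuity correction. Two-sided throughout.
* TMM falls back to factor 1 when the trim empties the gene set; a
  sample sharing no expressed gene with the reference is an error.
* Genes with identical replicate values give NaN Welch p-values, treated
  as p = 1.
* Ratios are kept at full precision internally; 2-decimal columns are
  provided for display parity with conventional tables.
* All randomness flows from a single integer seed through named
  substreams (genome/counts/ortholog), so identical configurations are
  byte-reproducible; permutation sub-tests derive per-threshold seeds
  from spawned seed sequences.

## Problem sizes

Default validation runs use 5,000 genes, 3 replicates per sex and five
simulation seeds per compensation regime; calibration checks use 500
null replicates (2,000-gene universes for the permutation test, 200-gene
genomes for the DE stand-in). These sizes make median-ratio Monte-Carlo
error ≈ 1.5–2% and binomial error on rejection rates ≈ 1%, which is the
precision the recovery and calibration bands require.

## Known limitations

* The consensus requires identical gene universes across method tables;
  harmonize externally filtered call sets before ingestion.
* The internal DE stand-ins are underpowered at 3 replicates for small
  fold changes; consensus counts on simulated data recover only the
  strong tail of planted effects. Use real DE callers for inference.
* The ortholog-ratio test assumes the reference species is itself
  uncompensated *and* unbiased between sexes for the genes compared; the
  generator enforces this, real data may not.
* GFF3 parsing expects `gene` features with `exon` children (or an
  explicit `exonic_length` attribute); other feature hierarchies are out
  of scope.
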