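"""Synthetic genomes, count matrices and ortholog tables with known truth.

The generator emulates the statistical structure a dosage-compensation
analysis assumes: genes laid out on scaffolds that belong to chromosome
arms (X plus four autosomal arms), log-normal baseline abundances,
negative-binomial read counts with replicate structure, configurable
male-X compensation regimes, sex-biased effect sizes, and a second
"homomorphic" species whose one-to-one ortholog expression is rank-
correlated with the focal species.

Compensation regimes act as a multiplier on the male X mean only
(female X expression is left unchanged):

* ``complete`` - multiplier 1: the single male X is hyper-expressed to
  autosomal levels, so the male X:AA ratio is ~1.
* ``none``     - multiplier 0.5: one X copy, no compensation, ratio ~0.5.
* ``buffered`` - multiplier ``buffer_factor`` in (0.5, 1): regulatory
  network buffering without a dedicated compensation mechanism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

DEFAULT_ARMS = ("X", "2R", "2L", "3R", "3L")
COMPENSATION_MODES = ("complete", "none", "buffered")

_GENOME_STREAM = 11
_COUNTS_STREAM = 22
_ORTHOLOG_STREAM = 33


class SimConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    The first entry of ``arms`` is treated as the X chromosome.  Baseline
    abundances and exonic lengths are log-normal; the baseline sigma
    default (0.3) keeps the Monte-Carlo error of median-based X:AA ratios
    near 1.5% at 1,000 X genes so recovery bands of +/-5% are ~3 standard
    errors wide.  Counts are negative binomial with gamma-Poisson mixing
    and shared dispersion ``phi`` (variance m + phi m^2); ``dispersion=0``
    is the deterministic limit where counts equal rounded expected means.
    """

    arms: tuple[str, ...] = DEFAULT_ARMS
    genes_per_arm: int = 1000
    scaffolds_per_arm: int = 8
    frac_mixed_scaffolds: float = 0.1
    frac_with_ortholog: float = 0.9
    gene_length_lognorm: tuple[float, float] = (7.5, 0.7)  # median ~1.8 kb
    baseline_lognorm: tuple[float, float] = (2.0, 0.3)
    compensation_mode: str = "complete"
    buffer_factor: float = 0.7
    frac_sex_biased: float = 0.35
    effect_log2_mean: float = 2.0  # mean |log2 FC| of biased genes (exponential)
    effect_log2_max: float = 12.0  # cap on |log2 FC| (~4,000-fold)
    frac_sex_specific: float = 0.05
    dispersion: float = 0.1
    replicates_per_sex: int = 3
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.2
    ortholog_rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise SimConfigError("need at least the X and one autosomal arm")
        if self.genes_per_arm <= 0:
            raise SimConfigError("genes_per_arm must be positive")
        if self.scaffolds_per_arm <= 0:
            raise SimConfigError("scaffolds_per_arm must be positive")
        for name in ("frac_mixed_scaffolds", "frac_with_ortholog",
                     "frac_sex_biased", "frac_sex_specific"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {value}")
        if self.compensation_mode not in COMPENSATION_MODES:
            raise SimConfigError(
                f"compensation_mode must be one of {COMPENSATION_MODES}")
        if self.compensation_mode == "buffered" and not 0.5 < self.buffer_factor < 1.0:
            raise SimConfigError("buffer_factor must be in (0.5, 1.0)")
        if self.effect_log2_mean <= 0 or self.effect_log2_max <= 0:
            raise SimConfigError("effect-size parameters must be positive")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.replicates_per_sex < 1:
            raise SimConfigError("replicates_per_sex must be >= 1")
        if self.lib_size_mean <= 0 or self.lib_size_cv < 0:
            raise SimConfigError("library size parameters must be positive")
        if not -1.0 <= self.ortholog_rho <= 1.0:
            raise SimConfigError("ortholog_rho must be in [-1, 1]")

    @property
    def x_arm(self) -> str:
        return self.arms[0]

    @property
    def n_genes(self) -> int:
        return self.genes_per_arm * len(self.arms)

    def male_x_multiplier(self) -> float:
        if self.compensation_mode == "complete":
            return 1.0
        if self.compensation_mode == "none":
            return 0.5
        return self.buffer_factor


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed % (2 ** 31), stream]))


def simulate_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Lay genes out on scaffolds and record the true arm of each.

    A fraction of scaffolds is "mixed": a contiguous run of 1-5 genes is
    relabeled to a second arm, exercising both the acceptance and the
    rejection branch of the contiguous-run assignment rule.  A fraction of
    genes carries a reference-species ortholog whose chromosome element
    equals the gene's true arm (arms are conserved elements).

    Returns
    -------
    genes
        DataFrame with columns gene_id, scaffold, start, end, strand,
        exonic_length, order_index, true_arm, ref_gene, ref_arm.
    scaffold_truth
        Series mapping scaffold id to its designed arm.
    """
    rng = _rng(config, _GENOME_STREAM)
    n_scaffolds = len(config.arms) * config.scaffolds_per_arm

    scaffold_ids = [f"scaf{i:05d}" for i in range(n_scaffolds)]
    scaffold_arm: list[str] = []
    scaffold_sizes: list[int] = []
    for arm in config.arms:
        splits = np.array_split(np.arange(config.genes_per_arm),
                                config.scaffolds_per_arm)
        for chunk in splits:
            scaffold_arm.append(arm)
            scaffold_sizes.append(len(chunk))

    n_genes = config.n_genes
    true_arm = np.repeat(scaffold_arm, scaffold_sizes)
    scaffold_of_gene = np.repeat(scaffold_ids, scaffold_sizes)

    # relabel a contiguous run on mixed scaffolds to a foreign arm
    n_mixed = int(round(config.frac_mixed_scaffolds * n_scaffolds))
    offsets = np.concatenate([[0], np.cumsum(scaffold_sizes)])
    eligible = [i for i, size in enumerate(scaffold_sizes) if size >= 2]
    mixed = rng.choice(eligible, size=min(n_mixed, len(eligible)), replace=False) \
        if n_mixed else np.array([], dtype=int)
    for scaf_idx in sorted(mixed):
        native = scaffold_arm[scaf_idx]
        others = [a for a in config.arms if a != native]
        foreign = others[rng.integers(len(others))]
        size = scaffold_sizes[scaf_idx]
        run = int(min(rng.integers(1, 6), size - 1))
        start = int(rng.integers(0, size - run + 1))
        lo = offsets[scaf_idx] + start
        true_arm[lo:lo + run] = foreign

    lengths = np.maximum(1, np.rint(rng.lognormal(*config.gene_length_lognorm,
                                                  size=n_genes))).astype(int)
    gaps = rng.integers(200, 5001, size=n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    has_ref = rng.random(n_genes) < config.frac_with_ortholog

    starts = np.empty(n_genes, dtype=int)
    ends = np.empty(n_genes, dtype=int)
    order_index = np.empty(n_genes, dtype=int)
    for scaf_idx in range(n_scaffolds):
        lo, hi = offsets[scaf_idx], offsets[scaf_idx + 1]
        pos = 1
        for j, g in enumerate(range(lo, hi)):
            starts[g] = pos + gaps[g]
            ends[g] = starts[g] + lengths[g] - 1  # single-exon gene models
            pos = ends[g]
            order_index[g] = j

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "scaffold": scaffold_of_gene,
        "start": starts,
        "end": ends,
        "strand": strands,
        "exonic_length": lengths,
        "order_index": order_index,
        "true_arm": true_arm,
        "ref_gene": [f"REF{i:05d}" if flag else pd.NA
                     for i, flag in enumerate(has_ref)],
    })
    genes["ref_arm"] = genes["true_arm"].where(has_ref, pd.NA)
    scaffold_truth = pd.Series(scaffold_arm, index=pd.Index(scaffold_ids,
                                                            name="scaffold"),
                               name="true_arm")
    return genes, scaffold_truth


def _library_sizes(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    if config.lib_size_cv == 0:
        return np.full(n, float(config.lib_size_mean))
    sigma2 = math.log1p(config.lib_size_cv ** 2)
    mu = math.log(config.lib_size_mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _nb_counts(rng: np.random.Generator, means: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with variance m + phi m^2; phi=0 is rounded means."""
    if dispersion == 0:
        return np.rint(means).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_counts(config: SimConfig,
                    genes: pd.DataFrame) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw replicate read counts for the focal (heteromorphic-X) species.

    The expected count of gene g in sample s is
    ``lib_s * b_g * L_g * d_gs / sum_h(b_h * L_h * d_hs)`` with b the
    baseline abundance, L the exonic length in kb, and d the sex/arm
    multiplier: 1 for females and male autosomal genes, the compensation
    multiplier for male X genes, times 2^effect on the male side of
    sex-biased genes.  Sex-specific genes have the mean zeroed in the
    other sex.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    rng = _rng(config, _COUNTS_STREAM)
    n = len(genes)

    mu_b, sigma_b = config.baseline_lognorm
    baseline = rng.lognormal(mu_b, sigma_b, size=n)

    biased = rng.random(n) < config.frac_sex_biased
    magnitude = np.minimum(rng.exponential(config.effect_log2_mean, size=n),
                           config.effect_log2_max)
    sign = rng.choice(np.array([-1.0, 1.0]), size=n)
    effect = np.where(biased, magnitude * sign, 0.0)
    specific = biased & (rng.random(n) < config.frac_sex_specific)

    x_mask = (genes["true_arm"] == config.x_arm).to_numpy()
    male_mult = np.where(x_mask, config.male_x_multiplier(), 1.0)
    male_mult = male_mult * np.exp2(effect)
    female_mult = np.ones(n)
    female_mult[specific & (effect > 0)] = 0.0  # male-specific genes
    male_mult[specific & (effect < 0)] = 0.0    # female-specific genes

    length_kb = genes["exonic_length"].to_numpy() / 1000.0
    weight = {"female": baseline * length_kb * female_mult,
              "male": baseline * length_kb * male_mult}

    reps = config.replicates_per_sex
    sample_ids, sexes, replicates = [], [], []
    for sex in ("female", "male"):
        for r in range(1, reps + 1):
            sample_ids.append(f"A_{sex}_{r}")
            sexes.append(sex)
            replicates.append(r)
    libs = _library_sizes(rng, config, len(sample_ids))

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, sex in enumerate(sexes):
        w = weight[sex]
        means = libs[j] * w / w.sum()
        counts[:, j] = _nb_counts(rng, means, config.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes["gene_id"], name="gene_id"),
                     columns=sample_ids),
        pd.DataFrame({"sex": sexes, "replicate": replicates, "species": "A"},
                     index=pd.Index(sample_ids, name="sample")),
    )

    spec_label = np.full(n, "none", dtype=object)
    spec_label[specific & (effect > 0)] = "male_specific"
    spec_label[specific & (effect < 0)] = "female_specific"
    truth = pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "true_arm": genes["true_arm"].to_numpy(),
        "baseline": baseline,
        "effect_log2": effect,
        "sex_specific": spec_label,
        "compensated": pd.array(
            np.where(x_mask, config.compensation_mode == "complete", None),
            dtype="boolean"),
    })
    return cm, truth


def _latent_copula_rho(config: SimConfig) -> float:
    """Latent Gaussian correlation whose *observed* log-expression rank
    correlation matches ortholog_rho after negative-binomial attenuation."""
    rho_s = config.ortholog_rho
    rho_pearson = 2.0 * math.sin(math.pi * rho_s / 6.0)
    _, sigma_b = config.baseline_lognorm
    mean_count = config.lib_size_mean / config.n_genes
    noise_var = (config.dispersion / config.replicates_per_sex
                 + 1.0 / (config.replicates_per_sex * mean_count))
    attenuation = sigma_b ** 2 / (sigma_b ** 2 + noise_var)
    return float(np.clip(rho_pearson / attenuation, -1.0, 1.0))


def simulate_ortholog_species(
        config: SimConfig,
        truth: pd.DataFrame) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a related species with homomorphic sex chromosomes.

    Every focal-species gene gets exactly one ortholog.  Species-B log
    baselines are drawn from a Gaussian copula against species A so the
    realized rank correlation of log-expression tracks ``ortholog_rho``;
    no gene gets a sex or X multiplier (both sexes effectively diploid
    genome-wide).

    Returns the species-B count matrix, its gene table (ids and exonic
    lengths; species B has no arm assignment), and the one-to-one
    ortholog table (gene_a, gene_b).
    """
    rng = _rng(config, _ORTHOLOG_STREAM)
    n = len(truth)
    if n == 0:
        raise ValueError("empty truth table")
    mu_b, sigma_b = config.baseline_lognorm

    z_a = (np.log(truth["baseline"].to_numpy()) - mu_b) / sigma_b
    rho = _latent_copula_rho(config)
    noise = rng.standard_normal(n)
    z_b = rho * z_a + math.sqrt(max(0.0, 1.0 - rho ** 2)) * noise
    baseline_b = np.exp(mu_b + sigma_b * z_b)

    lengths_b = np.maximum(1, np.rint(rng.lognormal(*config.gene_length_lognorm,
                                                    size=n))).astype(int)
    gene_ids_b = [f"B{i:05d}" for i in range(n)]

    reps = config.replicates_per_sex
    sample_ids, sexes, replicates = [], [], []
    for sex in ("female", "male"):
        for r in range(1, reps + 1):
            sample_ids.append(f"B_{sex}_{r}")
            sexes.append(sex)
            replicates.append(r)
    libs = _library_sizes(rng, config, len(sample_ids))

    w = baseline_b * (lengths_b / 1000.0)  # d = 1 everywhere: no X, no sex bias
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        means = libs[j] * w / w.sum()
        counts[:, j] = _nb_counts(rng, means, config.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids_b, name="gene_id"),
                     columns=sample_ids),
        pd.DataFrame({"sex": sexes, "replicate": replicates, "species": "B"},
                     index=pd.Index(sample_ids, name="sample")),
    )
    genes_b = pd.DataFrame({
        "gene_id": gene_ids_b,
        "scaffold": "B_chr",
        "exonic_length": lengths_b,
        "baseline": baseline_b,
    })
    orthologs = pd.DataFrame({"gene_a": truth["gene_id"].to_numpy(),
                              "gene_b": gene_ids_b})
    return cm, genes_b, orthologs
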