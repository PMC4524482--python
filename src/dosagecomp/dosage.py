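"""Dosage-compensation statistics.

The X:AA ratio — the median expression of X-linked genes over the median
expression of autosomal genes within one sex — is computed under a sweep
of low-expression filters, with a two-sample Wilcoxon rank-sum test of
the X-vs-autosome difference per regime.  A cross-species test divides
each focal-species gene's RPKM by that of its one-to-one ortholog in a
related homomorphic-X species and rescales so the autosomal median ratio
is exactly 1: under complete compensation the normalized X median is ~1
in males, without compensation ~0.5.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FILTER_MODES = ("original", "zero_both", "cutoff")
FILTER_SCOPES = ("either_sex", "both_sexes")


@dataclass(frozen=True)
class FilterSpec:
    """A low-expression filtering regime.

    ``original`` keeps everything; ``zero_both`` drops genes with RPKM 0
    in both sexes; ``cutoff`` additionally drops genes with RPKM strictly
    below ``cutoff`` in at least one sex (scope ``either_sex``, the
    default) or in both sexes (scope ``both_sexes``).
    """

    mode: str = "cutoff"
    cutoff: float = 2.0
    scope: str = "either_sex"

    def __post_init__(self) -> None:
        if self.mode not in FILTER_MODES:
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.scope not in FILTER_SCOPES:
            raise ValueError(f"unknown filter scope {self.scope!r}")
        if self.mode == "cutoff" and not self.cutoff > 0:
            raise ValueError("cutoff must be > 0 when mode='cutoff'")

    @property
    def label(self) -> str:
        if self.mode == "original":
            return "original"
        if self.mode == "zero_both":
            return "zero_both"
        return f"cutoff_{self.cutoff:g}"


def filter_genes(expr: pd.DataFrame, spec: FilterSpec) -> pd.Index:
    """Apply a FilterSpec to a female/male RPKM table; returns kept genes.

    Comparisons are strict: a gene exactly at the cutoff is retained.
    """
    f = expr["female"]
    m = expr["male"]
    if spec.mode == "original":
        return expr.index
    zero_both = (f == 0) & (m == 0)
    if spec.mode == "zero_both":
        return expr.index[~zero_both]
    if spec.scope == "either_sex":
        low = (f < spec.cutoff) | (m < spec.cutoff)
    else:
        low = (f < spec.cutoff) & (m < spec.cutoff)
    return expr.index[~(zero_both | low)]


def _exact_ranksum_p(w: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p for rank sum w of sample a (no ties).

    Enumerates the null distribution of the rank sum by dynamic
    programming over which ranks fall in sample a.
    """
    n = n_a + n_b
    # table[j][s] = number of j-subsets of ranks seen so far with sum s
    max_sum = n * (n + 1) // 2
    table = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n_a), 0, -1):
            table[j, rank:] += table[j - 1, :-rank]
    dist = table[n_a]
    total = dist.sum()
    mu = n_a * (n + 1) / 2
    lo = dist[: int(math.floor(w)) + 1].sum() / total
    hi = dist[int(math.ceil(w)):].sum() / total
    # the null distribution is symmetric about mu
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Ties get midranks.  The null is enumerated exactly when
    ``len(a)+len(b) <= 12`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    Returns (rank sum of ``a``, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    has_ties = np.unique(pooled).size < n

    if n <= 12 and not has_ties:
        return w, _exact_ranksum_p(w, n_a, n_b)

    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = max(0.0, abs(w - mu) - 0.5) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(z)))


def xaa_ratio(median_x: float, median_autosome: float) -> float:
    """X:AA ratio of two within-sex median expression values."""
    if median_autosome <= 0:
        raise ValueError("autosomal median must be positive")
    return median_x / median_autosome


def default_sweep_specs(cutoffs=(1, 2, 3, 4), scope: str = "either_sex"):
    specs = [FilterSpec("original"), FilterSpec("zero_both")]
    specs += [FilterSpec("cutoff", float(c), scope) for c in cutoffs]
    return specs


def xaa_sweep(expr: pd.DataFrame, arms: pd.Series, cutoffs=(1, 2, 3, 4), *,
              x_arm: str = "X", scope: str = "either_sex") -> pd.DataFrame:
    """One row per filtering regime: gene counts, medians, X:AA ratios
    and Wilcoxon rank-sum p-values per sex.

    ``arms`` maps gene id to chromosome arm; genes without labels are
    excluded.  Ratios are reported at full precision with a 2-decimal
    display column.
    """
    labeled = expr.loc[expr.index.intersection(arms.index)]
    if len(labeled) == 0:
        raise ValueError("no labeled genes: arm assignment produced no X/autosome "
                         "labels for the expression table")
    arm_of = arms.reindex(labeled.index)
    rows = []
    for spec in default_sweep_specs(cutoffs, scope):
        kept = filter_genes(labeled, spec)
        is_x = arm_of.loc[kept] == x_arm
        x_genes = kept[is_x]
        auto_genes = kept[~is_x]
        if len(x_genes) == 0 or len(auto_genes) == 0:
            raise ValueError(f"filter {spec.label!r} leaves no X or no autosomal genes")
        row = {"filter": spec.label, "n_X": len(x_genes), "n_auto": len(auto_genes)}
        for sex in ("female", "male"):
            x_vals = labeled.loc[x_genes, sex].to_numpy()
            a_vals = labeled.loc[auto_genes, sex].to_numpy()
            med_x = float(np.median(x_vals))
            med_a = float(np.median(a_vals))
            ratio = xaa_ratio(med_x, med_a)
            _, p = wilcoxon_ranksum(x_vals, a_vals)
            row.update({f"median_X_{sex}": med_x, f"median_auto_{sex}": med_a,
                        f"xaa_ratio_{sex}": ratio,
                        f"xaa_ratio_{sex}_2dp": round(ratio, 2),
                        f"wilcoxon_p_{sex}": p})
        rows.append(row)
    return pd.DataFrame(rows)


def ortholog_ratio_test(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                        pairs: pd.DataFrame, arms_a: pd.Series, *,
                        cutoff: float = 2.0, x_arm: str = "X",
                        require_both: bool = True) -> pd.DataFrame:
    """Cross-species ortholog expression-ratio test.

    Per sex: keep pairs whose RPKM passes ``cutoff`` in both species
    (``require_both=False`` keeps pairs passing in either), form the raw
    ratio focal/ortholog, rescale by ``lambda`` = 1/median autosomal
    ratio, and report the normalized median ratio per focal-species arm.
    The autosomal aggregate is 1 by construction.

    Returns a tidy DataFrame (sex, arm, n_pairs, normalized_median,
    scale_factor); ``arm`` includes each focal arm plus "autosomes".
    """
    merged = pairs.merge(expr_a.rename_axis("gene_a").reset_index(), on="gene_a")
    merged = merged.merge(expr_b.rename_axis("gene_b").reset_index(), on="gene_b",
                          suffixes=("_a", "_b"))
    merged["arm"] = merged["gene_a"].map(arms_a)
    merged = merged.dropna(subset=["arm"])
    rows = []
    for sex in ("female", "male"):
        ra = merged[f"{sex}_a"].to_numpy(dtype=float)
        rb = merged[f"{sex}_b"].to_numpy(dtype=float)
        if require_both:
            keep = (ra >= cutoff) & (rb >= cutoff)
        else:
            keep = (ra >= cutoff) | (rb >= cutoff)
        keep &= rb > 0
        sub = merged.loc[keep, ["arm"]].copy()
        sub["ratio"] = ra[keep] / rb[keep]
        auto = sub[sub["arm"] != x_arm]
        if len(auto) == 0:
            raise ValueError(f"no autosomal ortholog pairs left for {sex} "
                             f"after the RPKM>={cutoff:g} filter")
        lam = 1.0 / float(np.median(auto["ratio"]))
        for arm, group in sub.groupby("arm", sort=True):
            rows.append({"sex": sex, "arm": arm, "n_pairs": len(group),
                         "normalized_median": lam * float(np.median(group["ratio"])),
                         "scale_factor": lam})
        rows.append({"sex": sex, "arm": "autosomes", "n_pairs": len(auto),
                     "normalized_median": lam * float(np.median(auto["ratio"])),
                     "scale_factor": lam})
    return pd.DataFrame(rows)


def ortholog_log2_table(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                        pairs: pd.DataFrame, arms_a: pd.Series, *,
                        cutoff: float = 2.0) -> pd.DataFrame:
    """Per-gene normalized log2 ortholog ratios (violin-plot export)."""
    summary = ortholog_ratio_test(expr_a, expr_b, pairs, arms_a, cutoff=cutoff)
    lam = summary.set_index(["sex", "arm"])
    merged = pairs.merge(expr_a.rename_axis("gene_a").reset_index(), on="gene_a")
    merged = merged.merge(expr_b.rename_axis("gene_b").reset_index(), on="gene_b",
                          suffixes=("_a", "_b"))
    merged["arm"] = merged["gene_a"].map(arms_a)
    merged = merged.dropna(subset=["arm"])
    out = []
    for sex in ("female", "male"):
        scale = float(lam.loc[(sex, "autosomes"), "scale_factor"])
        ra = merged[f"{sex}_a"]
        rb = merged[f"{sex}_b"]
        keep = (ra >= cutoff) & (rb >= cutoff)
        sub = merged.loc[keep]
        out.append(pd.DataFrame({
            "gene_a": sub["gene_a"], "gene_b": sub["gene_b"], "arm": sub["arm"],
            "sex": sex,
            "log2_normalized_ratio": np.log2(scale * ra[keep] / rb[keep]),
        }))
    return pd.concat(out, ignore_index=True)
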