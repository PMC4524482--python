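"""Consensus sex-bias calling and chromosomal-distribution tests.

Sex-biased genes are those flagged as differentially expressed between
the sexes by at least two independent methods agreeing in direction.
The module ingests external differential-expression call tables (e.g.
from edgeR, DESeq2 or Cuffdiff) and also provides two lightweight
internal stand-in detectors so the consensus and downstream tests can be
exercised on replicate count data alone.  Downstream, biased genes are
binned by fold-change magnitude and their proportion on the X chromosome
is compared against a permutation null to detect demasculinization
(depletion of male-biased genes on X) or feminization (enrichment of
female-biased genes).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .normalize import rpkm, tmm_factors

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["method", "gene", "significant", "direction", "score"]


def internal_de_test(cm: CountMatrix, lengths: pd.Series, *,
                     alpha: float = 0.05,
                     method: str = "welch_t") -> pd.DataFrame:
    """Stand-in differential-expression detector on replicate counts.

    ``welch_t``: Welch two-sample t on log2(per-replicate TMM-RPKM + 0.5)
    per gene, Benjamini-Hochberg adjusted across genes.
    ``pooled_proportion``: two-sided normal test of the pooled male count
    against the male share of effective sequencing depth, BH adjusted.
    Both are plumbing for the consensus, not replacements for dedicated
    DE models.
    """
    sexes = cm.samples["sex"]
    n_m = int((sexes == "male").sum())
    n_f = int((sexes == "female").sum())
    if n_m < 2 or n_f < 2:
        raise ValueError(
            "internal DE test needs >=2 replicates per sex; supply external "
            "differential-expression call tables instead")
    stats = tmm_factors(cm)
    expr = rpkm(cm, lengths, stats)
    male_cols = cm.samples.index[sexes == "male"]
    female_cols = cm.samples.index[sexes == "female"]

    if method == "welch_t":
        log_m = np.log2(expr[male_cols].to_numpy() + 0.5)
        log_f = np.log2(expr[female_cols].to_numpy() + 0.5)
        with warnings.catch_warnings():
            # genes with identical replicate values yield NaN p; treated as 1
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(log_m, log_f, axis=1, equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        delta = log_m.mean(axis=1) - log_f.mean(axis=1)
    elif method == "pooled_proportion":
        eff = stats["effective_lib"]
        k_m = cm.counts[male_cols].sum(axis=1).to_numpy(dtype=float)
        k_f = cm.counts[female_cols].sum(axis=1).to_numpy(dtype=float)
        p0 = float(eff[male_cols].sum() / eff.sum())
        total = k_m + k_f
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (k_m - total * p0) / np.sqrt(total * p0 * (1 - p0))
        pvals = np.where(total > 0, 2 * sps.norm.sf(np.abs(z)), 1.0)
        delta = np.where(total > 0, k_m / np.maximum(total, 1) - p0, 0.0)
    else:
        raise ValueError(f"unknown internal DE method {method!r}")

    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "method": method,
        "gene": cm.counts.index,
        "significant": qvals < alpha,
        "direction": np.where(delta > 0, "male", "female"),
        "score": qvals,
        "p_raw": pvals,
    })


def consensus_calls(method_calls: list[pd.DataFrame], expr: pd.DataFrame, *,
                    min_support: int = 2, pseudocount: float = 0.01,
                    expressed_cutoff: float = 2.0) -> pd.DataFrame:
    """Combine >=2 methods' calls into a consensus sex-bias table.

    A gene is biased iff at least ``min_support`` methods flag it with
    the same direction; any direction conflict among significant calls
    demotes the gene to unbiased.  ``log2_ratio`` is oriented high/low
    sex from pooled RPKM with a pseudocount; genes whose RPKM passes
    ``expressed_cutoff`` in exactly one sex are labeled sex-specific.
    """
    if len(method_calls) < 2:
        raise ValueError("consensus needs call tables from >=2 distinct methods")
    universes = [frozenset(c["gene"]) for c in method_calls]
    if len(set(universes)) != 1:
        raise ValueError("method call tables cover different gene universes")
    methods = [c["method"].iloc[0] for c in method_calls]
    if len(set(methods)) != len(methods):
        raise ValueError("method call tables must come from distinct methods")

    stacked = pd.concat(method_calls, ignore_index=True)
    sig = stacked[stacked["significant"]]
    by_gene = sig.groupby("gene")["direction"]
    n_sig = by_gene.size()
    n_dir = by_gene.nunique()
    modal_dir = by_gene.agg(lambda d: d.iloc[0])

    genes = method_calls[0]["gene"]
    consensus = pd.Series("unbiased", index=genes.to_numpy(), dtype=object)
    support = pd.Series(0, index=genes.to_numpy())
    agreeing = n_sig[(n_sig >= min_support) & (n_dir == 1)]
    consensus.loc[agreeing.index] = (modal_dir.loc[agreeing.index] + "_biased")
    support.loc[agreeing.index] = agreeing
    conflicted = n_sig.index[(n_sig >= min_support) & (n_dir > 1)]
    if len(conflicted):
        logger.warning("%d genes had conflicting directions among supporting "
                       "methods; left unbiased", len(conflicted))

    f = expr["female"].reindex(consensus.index)
    m = expr["male"].reindex(consensus.index)
    high = np.maximum(f, m)
    low = np.minimum(f, m)
    log2_ratio = np.log2((high + pseudocount) / (low + pseudocount))
    f_exp = f >= expressed_cutoff
    m_exp = m >= expressed_cutoff
    specific = np.select(
        [f_exp & ~m_exp, m_exp & ~f_exp],
        ["female_specific", "male_specific"], default="none")

    return pd.DataFrame({
        "gene": consensus.index,
        "consensus": consensus.to_numpy(),
        "n_supporting": support.to_numpy(),
        "log2_ratio": log2_ratio.to_numpy(),
        "specific": specific,
    })


DEFAULT_BIN_EDGES = (1.5, 2.0, 3.0, 4.0, 8.0, 16.0)


def bin_by_magnitude(calls: pd.DataFrame, arms: pd.Series,
                     bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Count biased genes per (arm, direction, fold-change bin).

    Bins are half-open ``[e_i, e_{i+1})`` on the fold-ratio scale, the
    top bin unbounded; a leading ``[1, e_1)`` bin is added when the first
    edge exceeds 1.  Sex-specific genes land in the top bin.
    """
    edges = [float(e) for e in bin_edges]
    if any(e < 1 for e in edges) or edges != sorted(edges) or \
            len(set(edges)) != len(edges):
        raise ValueError("bin edges must be >= 1, ascending and unique")
    if edges and edges[0] > 1.0:
        edges = [1.0] + edges
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]
    labels.append(f"[{edges[-1]:g},inf)")

    biased = calls[calls["consensus"] != "unbiased"].copy()
    fold = np.exp2(biased["log2_ratio"].to_numpy(dtype=float))
    idx = np.searchsorted(edges, fold, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    idx[(biased["specific"] != "none").to_numpy()] = len(labels) - 1
    biased["bin"] = pd.Categorical([labels[i] for i in idx], categories=labels)
    biased["arm"] = biased["gene"].map(arms)
    biased = biased.dropna(subset=["arm"])
    out = (biased.groupby(["arm", "consensus", "bin"], observed=False)
           .size().rename("n_genes").reset_index())
    return out


def biased_fraction_by_threshold(calls: pd.DataFrame, arms: pd.Series,
                                 thresholds, direction: str) -> pd.DataFrame:
    """Percentage of each arm's labeled genes biased toward ``direction``
    at fold ratio >= each threshold (denominator: expressed labeled genes
    present in ``calls``)."""
    labeled = calls[calls["gene"].map(arms).notna()].copy()
    labeled["arm"] = labeled["gene"].map(arms)
    fold = np.exp2(labeled["log2_ratio"].to_numpy(dtype=float))
    is_dir = labeled["consensus"] == f"{direction}_biased"
    rows = []
    for arm, group_idx in labeled.groupby("arm").groups.items():
        group = labeled.loc[group_idx]
        g_fold = fold[labeled.index.get_indexer(group_idx)]
        g_dir = is_dir.loc[group_idx].to_numpy()
        for t in thresholds:
            n_hit = int((g_dir & (g_fold >= t)).sum())
            rows.append({"arm": arm, "threshold": t, "n_biased": n_hit,
                         "n_genes": len(group),
                         "percent": 100.0 * n_hit / len(group)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationResult:
    """Permutation test of the X-linked share of a biased gene set."""

    threshold: float
    side: str  # depletion | enrichment
    n_total: int
    n_x: int
    n_biased: int
    k_obs: int
    observed_prop: float
    null_mean: float
    p_perm: float
    p_hyper: float
    n_perm: int
    seed: int


def permutation_distribution_test(arms: pd.Series, biased, *,
                                  side: str = "depletion",
                                  n_perm: int = 10_000, seed: int = 0,
                                  x_arm: str = "X",
                                  threshold: float = float("nan")
                                  ) -> PermutationResult:
    """Test whether biased genes are depleted from / enriched on the X.

    The statistic is the proportion of biased genes on the X among all
    expressed, arm-labeled genes.  The null permutes the biased/unbiased
    labels over genes; since only the X-overlap count matters, the null
    counts are drawn directly from the equivalent sampling-without-
    replacement (hypergeometric) distribution.  The one-sided empirical p
    uses the +1 correction; the exact hypergeometric tail is reported as
    a cross-check.
    """
    if side not in ("depletion", "enrichment"):
        raise ValueError(f"side must be depletion or enrichment, got {side!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    biased_idx = pd.Index(biased)
    stray = biased_idx.difference(arms.index)
    if len(stray):
        raise ValueError(
            f"biased genes missing from the labeled universe: {stray[:5].tolist()}")
    if len(biased_idx) == 0:
        raise ValueError("biased gene set is empty")
    n_total = len(arms)
    n_x = int((arms == x_arm).sum())
    if n_x == 0:
        raise ValueError("no expressed genes on the X chromosome")
    n_biased = len(biased_idx)
    k_obs = int((arms.loc[biased_idx] == x_arm).sum())

    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(n_x, n_total - n_x, n_biased, size=n_perm)
    if side == "depletion":
        extreme = int((null <= k_obs).sum())
        p_hyper = float(sps.hypergeom.cdf(k_obs, n_total, n_x, n_biased))
    else:
        extreme = int((null >= k_obs).sum())
        p_hyper = float(sps.hypergeom.sf(k_obs - 1, n_total, n_x, n_biased))
    p_perm = (1 + extreme) / (1 + n_perm)
    return PermutationResult(
        threshold=threshold, side=side, n_total=n_total, n_x=n_x,
        n_biased=n_biased, k_obs=k_obs,
        observed_prop=k_obs / n_biased,
        null_mean=float(null.mean()) / n_biased,
        p_perm=float(p_perm), p_hyper=p_hyper, n_perm=n_perm, seed=seed)


def threshold_sweep(calls: pd.DataFrame, arms: pd.Series, thresholds, *,
                    direction: str = "male", n_perm: int = 10_000,
                    seed: int = 0, x_arm: str = "X") -> pd.DataFrame:
    """Permutation tests across ascending fold-change thresholds.

    For each threshold t, the biased set is the genes called
    ``{direction}_biased`` with fold ratio >= t (sex-specific genes
    always qualify); both depletion and enrichment sides are tested.
    The returned frame carries one row per (threshold, side); the
    smallest threshold with p < 0.05 per side summarizes where
    demasculinization/feminization becomes detectable.
    """
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("empty threshold list")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    labeled = calls[calls["gene"].map(arms).notna()]
    universe = pd.Series(labeled["gene"].map(arms).to_numpy(),
                         index=labeled["gene"].to_numpy())
    fold = pd.Series(np.exp2(labeled["log2_ratio"].to_numpy(dtype=float)),
                     index=labeled["gene"].to_numpy())
    is_dir = pd.Series((labeled["consensus"] == f"{direction}_biased").to_numpy(),
                       index=labeled["gene"].to_numpy())
    is_specific = pd.Series((labeled["specific"] != "none").to_numpy(),
                            index=labeled["gene"].to_numpy())

    seeds = np.random.SeedSequence(seed % (2 ** 31)).spawn(len(thresholds) * 2)
    rows = []
    for i, t in enumerate(thresholds):
        biased = universe.index[is_dir & ((fold >= t) | is_specific)]
        for j, side in enumerate(("depletion", "enrichment")):
            child_seed = int(seeds[2 * i + j].generate_state(1)[0] % (2 ** 31))
            if len(biased) == 0:
                rows.append({"threshold": t, "side": side, "n_biased": 0,
                             "k_obs": 0, "observed_prop": float("nan"),
                             "p_perm": float("nan"), "p_hyper": float("nan")})
                continue
            res = permutation_distribution_test(
                universe, biased, side=side, n_perm=n_perm, seed=child_seed,
                x_arm=x_arm, threshold=t)
            rows.append({"threshold": t, "side": side, "n_biased": res.n_biased,
                         "k_obs": res.k_obs, "observed_prop": res.observed_prop,
                         "p_perm": res.p_perm, "p_hyper": res.p_hyper})
    return pd.DataFrame(rows)


def smallest_significant_threshold(sweep: pd.DataFrame, side: str,
                                   alpha: float = 0.05) -> float:
    """Smallest threshold whose permutation p is below alpha (NaN if none)."""
    hits = sweep[(sweep["side"] == side) & (sweep["p_perm"] < alpha)]
    return float(hits["threshold"].min()) if len(hits) else float("nan")
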