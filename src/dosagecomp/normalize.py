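"""Replicate pooling, TMM scale factors, and TMM-adjusted RPKM.

TMM (trimmed mean of M-values, Robinson & Oshlack 2010) rescales library
sizes so that the bulk of genes shows no between-sample log-ratio; RPKM
then converts pooled counts to reads per kilobase of exonic gene model
per million effectively sequenced reads.  Replicates of the same sex are
pooled by count summation, equivalent to concatenating their read files
before counting; a per-replicate averaging alternative is exposed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix


def pool_replicates(cm: CountMatrix) -> CountMatrix:
    """Sum replicate counts into one sample per (species, sex)."""
    keys = list(zip(cm.samples["species"], cm.samples["sex"]))
    pooled_ids, columns, meta = [], {}, []
    for species, sex in sorted(set(keys)):
        members = [s for s, k in zip(cm.samples.index, keys) if k == (species, sex)]
        pid = f"{species}_{sex}"
        pooled_ids.append(pid)
        columns[pid] = cm.counts[members].sum(axis=1)
        meta.append({"sex": sex, "replicate": 0, "species": species,
                     "n_pooled": len(members)})
    counts = pd.DataFrame(columns, index=cm.counts.index)
    samples = pd.DataFrame(meta, index=pd.Index(pooled_ids, name="sample"))
    return CountMatrix(counts, samples)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.DataFrame:
    """Per-sample TMM scale factors and effective library sizes.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the across-sample mean.  For each sample, genes with
    positive counts in both it and the reference contribute a log-ratio
    M and log-abundance A; the top and bottom ``trim_m`` fraction by M
    and ``trim_a`` fraction by A are discarded and the factor is the
    precision-weighted mean of the surviving M values, exponentiated.
    Factors are rescaled to geometric mean 1.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    y = cm.counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, l in zip(cm.counts.columns, lib) if l <= 0]
        raise ValueError(f"samples with zero library size: {bad}")

    f75 = np.quantile(y / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = y[:, ref], lib[ref]

    log_factors = np.zeros(y.shape[1])
    for k in range(y.shape[1]):
        yk, nk = y[:, k], lib[k]
        mask = (yk > 0) & (yr > 0)
        if not mask.any():
            raise ValueError(
                f"sample {cm.counts.columns[k]!r} shares no expressed genes "
                "with the TMM reference")
        pk, pr = yk[mask] / nk, yr[mask] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # inverse of the delta-method variance of M
        w = 1.0 / ((nk - yk[mask]) / (nk * yk[mask])
                   + (nr - yr[mask]) / (nr * yr[mask]))
        n = mask.sum()
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n - np.floor(n * trim_m)
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n - np.floor(n * trim_a)
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            log_factors[k] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    log_factors -= log_factors.mean()  # geometric mean 1
    factors = np.exp2(log_factors)
    return pd.DataFrame(
        {"raw_lib": lib, "tmm_factor": factors, "effective_lib": lib * factors},
        index=cm.counts.columns.rename("sample"))


def rpkm(cm: CountMatrix, lengths: pd.Series,
         libstats: pd.DataFrame | None = None) -> pd.DataFrame:
    """RPKM = 1e9 * count / (exonic length [bp] * effective library size)."""
    missing = cm.counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing exonic length for genes: {missing[:5].tolist()}")
    length = lengths.reindex(cm.counts.index).to_numpy(dtype=float)
    if (length < 1).any():
        bad = cm.counts.index[length < 1][:5].tolist()
        raise ValueError(f"exonic length < 1 bp for genes: {bad}")
    if libstats is None:
        effective = cm.counts.sum(axis=0).to_numpy(dtype=float)
    else:
        effective = libstats["effective_lib"].reindex(cm.counts.columns).to_numpy()
    if (effective <= 0).any():
        raise ValueError("effective library sizes must be positive")
    values = 1e9 * cm.counts.to_numpy(dtype=float) / np.outer(length, effective)
    return pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns)


def sex_expression(cm: CountMatrix, lengths: pd.Series,
                   method: str = "pooled") -> pd.DataFrame:
    """Per-gene female/male RPKM for one species.

    method="pooled" (default): sum replicates, TMM across the two pooled
    libraries, RPKM of pooled counts.  method="average": TMM across all
    replicate libraries, per-replicate RPKM, arithmetic mean per sex.
    """
    species = set(cm.samples["species"])
    if len(species) != 1:
        raise ValueError(f"expected one species, got {sorted(species)}")
    if method == "pooled":
        pooled = pool_replicates(cm)
        stats = tmm_factors(pooled)
        expr = rpkm(pooled, lengths, stats)
        expr.columns = pooled.samples["sex"].tolist()
        return expr[["female", "male"]]
    if method == "average":
        stats = tmm_factors(cm)
        per_rep = rpkm(cm, lengths, stats)
        out = {}
        for sex in ("female", "male"):
            cols = cm.samples.index[cm.samples["sex"] == sex]
            out[sex] = per_rep[cols].mean(axis=1)
        return pd.DataFrame(out)
    raise ValueError(f"unknown method {method!r}")
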