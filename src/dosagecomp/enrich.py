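"""Hypergeometric term enrichment for gene sets.

Given a selected gene set, a universe, and gene-to-term annotations
(e.g. GO), each term is tested for overrepresentation with the upper
tail of the hypergeometric distribution; Benjamini-Hochberg adjusted
values are reported alongside raw p.  Annotations are used as given —
no ontology-graph propagation is performed.
"""
from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_enrich(selected, universe, annotations: pd.DataFrame, *,
                     min_term_size: int = 3) -> pd.DataFrame:
    """Test each term for overrepresentation in ``selected``.

    Parameters
    ----------
    selected, universe
        Gene id collections with ``selected`` a subset of ``universe``.
    annotations
        DataFrame with columns ``gene`` and ``term`` (optional
        ``term_name``, ``namespace``); rows outside the universe are
        ignored, duplicate (gene, term) pairs collapsed.
    min_term_size
        Terms annotating fewer than this many universe genes are skipped.

    Returns a DataFrame sorted by ``p_hyper`` with columns term, k, n, K,
    N, p_hyper, p_adj (+ any term metadata present).
    """
    selected = set(selected)
    universe = set(universe)
    offenders = sorted(selected - universe)
    if offenders:
        raise ValueError(
            f"selected genes missing from the universe: {offenders[:10]}"
            + (" ..." if len(offenders) > 10 else ""))
    if {"gene", "term"} - set(annotations.columns):
        raise ValueError("annotations need columns 'gene' and 'term'")

    ann = annotations[annotations["gene"].isin(universe)]
    ann = ann.drop_duplicates(subset=["gene", "term"])
    n_sel = len(selected)
    n_uni = len(universe)

    meta_cols = [c for c in ("term_name", "namespace") if c in ann.columns]
    rows = []
    for term, group in ann.groupby("term", sort=True):
        big_k = len(group)
        if big_k < min_term_size:
            continue
        k = int(group["gene"].isin(selected).sum())
        p = float(hypergeom.sf(k - 1, n_uni, big_k, n_sel))
        row = {"term": term, "k": k, "n": n_sel, "K": big_k, "N": n_uni,
               "p_hyper": p}
        for c in meta_cols:
            row[c] = group[c].iloc[0]
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N",
                                     "p_hyper", "p_adj"] + meta_cols)
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
    return out.sort_values("p_hyper", kind="mergesort").reset_index(drop=True)
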