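"""Gene models, ortholog tables, and orthology-vote scaffold assignment.

Scaffolds of a fragmented assembly are placed on chromosome arms by the
chromosome element of their genes' one-to-one orthologs in a reference
species with chromosome-level assignments.  A scaffold is assigned to an
arm only when (i) at least ``min_genes`` of its genes carry orthologs,
(ii) strictly more than ``majority_threshold`` of those ortholog-bearing
genes point to the same arm, and (iii) no run of more than ``max_run``
consecutive ortholog-bearing genes points elsewhere.  Genes without
orthologs contribute neither to the vote nor to runs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

GENE_TABLE_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand",
                      "exonic_length"]


class GeneTableError(ValueError):
    """Raised when a gene table or GFF3 file fails validation."""


@dataclass(frozen=True)
class ArmAssignment:
    """Outcome of the orthology vote for one scaffold."""

    scaffold: str
    arm: str  # arm label or UNASSIGNED
    n_genes_with_orthologs: int
    majority_fraction: float
    max_foreign_run: int
    reason: str  # "" when assigned; else too_few | tie | low_majority | contiguous_run

    @property
    def assigned(self) -> bool:
        return self.arm != UNASSIGNED


def _merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for start, end in ivs:
        if cur_start is None or start > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def _read_gene_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("gene table %s is empty", path)
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    df = df.rename(columns={"exonic_length_bp": "exonic_length"})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"{path}: missing columns {missing}")
    return df


def _read_gene_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for gene in db.features_of_type("gene"):
        exons = [(child.start, child.end)
                 for child in db.children(gene, featuretype="exon")]
        if exons:
            exonic = _merged_interval_length(exons)
        elif "exonic_length" in gene.attributes:
            exonic = int(gene.attributes["exonic_length"][0])
        else:
            raise GeneTableError(
                f"{path}: gene {gene.id} has neither exon children nor an "
                "exonic_length attribute")
        rows.append({"gene_id": gene.id, "scaffold": gene.seqid,
                     "start": gene.start, "end": gene.end,
                     "strand": gene.strand or ".", "exonic_length": exonic})
    if not rows:
        logger.warning("GFF3 %s contains no gene features", path)
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read gene models from a TSV gene table or a GFF3 file.

    Returns genes sorted by (scaffold, start) with a per-scaffold
    ``order_index``.  GFF3 exonic length is the union of exon intervals.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    if not is_gff and path.exists():
        with open(path) as fh:
            first = fh.readline()
        is_gff = first.startswith("##gff-version")
    df = _read_gene_gff3(path) if is_gff else _read_gene_tsv(path)
    if len(df) == 0:
        df["order_index"] = pd.Series(dtype=int)
        return df

    for col in ("start", "end", "exonic_length"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise GeneTableError(
                f"{path}: non-numeric {col} at line(s) {[i + 2 for i in bad[:5]]}")
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise GeneTableError(
            f"{path}: start > end at line(s) {[i + 2 for i in bad[:5].tolist()]}")
    bad = df.index[df["exonic_length"] < 1]
    if len(bad):
        raise GeneTableError(
            f"{path}: exonic_length < 1 at line(s) {[i + 2 for i in bad[:5].tolist()]}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise GeneTableError(
            f"{path}: duplicate gene ids {sorted(set(dup))[:5]} "
            f"at line(s) {[i + 2 for i in dup.index[:5].tolist()]}")

    df = df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(drop=True)
    df["order_index"] = df.groupby("scaffold", sort=False).cumcount()
    return df


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read one-to-one ortholog pairs (gene_a, gene_b[, arm_b])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise GeneTableError(f"{path}: need columns gene_a and gene_b")
    for col in ("gene_a", "gene_b"):
        dup = sorted(set(df[col][df[col].duplicated()]))
        if dup:
            raise GeneTableError(
                f"{path}: ortholog table is not one-to-one; duplicated {col}: {dup[:5]}")
    return df


def assign_scaffold(arm_votes: Sequence[Optional[str]], *, scaffold: str = "",
                    min_genes: int = 3, majority_threshold: float = 0.92,
                    max_run: int = 3) -> ArmAssignment:
    """Run the orthology vote for one scaffold.

    Parameters
    ----------
    arm_votes
        Reference-species arm of each gene in scaffold order; ``None``/NaN
        for genes without orthologs (excluded from the vote and from runs).
    """
    votes = [v for v in arm_votes if v is not None and not pd.isna(v)]
    n = len(votes)
    if n < min_genes:
        return ArmAssignment(scaffold, UNASSIGNED, n, 0.0, 0, "too_few")

    tally = pd.Series(votes).value_counts()
    top = tally.iloc[0]
    fraction = top / n
    if (tally == top).sum() > 1:
        return ArmAssignment(scaffold, UNASSIGNED, n, fraction, 0, "tie")
    modal = tally.index[0]

    max_foreign = run = 0
    for vote in votes:
        run = run + 1 if vote != modal else 0
        max_foreign = max(max_foreign, run)

    if not fraction > majority_threshold:
        return ArmAssignment(scaffold, UNASSIGNED, n, fraction, max_foreign,
                             "low_majority")
    if max_foreign > max_run:
        return ArmAssignment(scaffold, UNASSIGNED, n, fraction, max_foreign,
                             "contiguous_run")
    return ArmAssignment(scaffold, str(modal), n, fraction, max_foreign, "")


def assign_scaffolds(genes: pd.DataFrame, orthologs: pd.DataFrame, *,
                     min_genes: int = 3, majority_threshold: float = 0.92,
                     max_run: int = 3) -> pd.DataFrame:
    """Vote every scaffold in a gene table.

    ``orthologs`` must carry gene_a (focal gene id) and arm_b (reference
    arm); genes absent from it count as ortholog-less.
    """
    if "arm_b" not in orthologs.columns:
        raise GeneTableError("ortholog table lacks the arm_b column needed "
                             "for scaffold assignment")
    arm_of = orthologs.set_index("gene_a")["arm_b"]
    ordered = genes.sort_values(["scaffold", "order_index"], kind="mergesort")
    rows = []
    for scaffold, group in ordered.groupby("scaffold", sort=True):
        votes = [arm_of.get(g) for g in group["gene_id"]]
        rows.append(assign_scaffold(votes, scaffold=str(scaffold),
                                    min_genes=min_genes,
                                    majority_threshold=majority_threshold,
                                    max_run=max_run))
    return pd.DataFrame([vars(r) for r in rows])


def gene_arm_labels(assignments: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Propagate scaffold arms to genes.

    Genes on UNASSIGNED scaffolds are dropped (excluded from downstream
    X/autosome analyses).  Returns a Series gene_id -> arm.
    """
    arm_of_scaffold = assignments.set_index("scaffold")["arm"]
    unknown = set(genes["scaffold"]) - set(arm_of_scaffold.index)
    if unknown:
        raise GeneTableError(
            f"genes reference scaffolds without assignments: {sorted(unknown)[:5]}")
    arms = genes["scaffold"].map(arm_of_scaffold)
    labels = pd.Series(arms.to_numpy(), index=pd.Index(genes["gene_id"],
                                                       name="gene_id"),
                       name="arm")
    return labels[labels != UNASSIGNED]
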