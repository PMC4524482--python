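"""Core in-memory containers shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_SEXES = ("female", "male")


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integers.
    samples
        DataFrame indexed by sample id with columns ``sex`` (``female`` or
        ``male``), ``replicate`` (int) and ``species``; pooled matrices
        additionally carry ``n_pooled``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata rows must match in order")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in count matrix: {dups[:5]}")
        for col in ("sex", "replicate", "species"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing required column {col!r}")
        bad_sex = set(self.samples["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise ValueError(f"invalid sex labels: {sorted(bad_sex)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_species(self, species: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["species"] == species]
        if len(keep) == 0:
            raise ValueError(f"no samples for species {species!r}")
        return CountMatrix(self.counts[keep], self.samples.loc[keep])
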