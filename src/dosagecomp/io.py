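"""TSV round-tripping with a comment header recording provenance.

Every stage writes plain tab-separated tables.  Lines starting with ``#``
carry ``key=value`` metadata (package version, seed, stage parameters) and
are ignored on read.
"""
from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def write_tsv(df: pd.DataFrame, path: str | Path, params: Mapping[str, Any] | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dosagecomp={__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(cm, counts_path: str | Path, samples_path: str | Path,
                 params: Mapping[str, Any] | None = None) -> None:
    """Write a CountMatrix as a counts TSV plus a sample sheet TSV."""
    counts = cm.counts.rename_axis("gene_id").reset_index()
    write_tsv(counts, counts_path, params)
    samples = cm.samples.rename_axis("sample").reset_index()
    write_tsv(samples, samples_path, params)


def read_counts(counts_path: str | Path, samples_path: str | Path):
    from .containers import CountMatrix

    counts = read_tsv(counts_path).set_index("gene_id")
    samples = read_tsv(samples_path).set_index("sample")
    return CountMatrix(counts[samples.index.tolist()], samples)
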