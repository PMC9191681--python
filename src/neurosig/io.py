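"""Delimited-text readers and writers for the pipeline's tables.

Everything is tab-separated with a one-line header; genotype matrices are
written as integers with ``NA`` for missing calls.  The cohort, feature,
and cognition tables carry the participant id as the first column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_genotypes(geno: pd.DataFrame, path: str | Path) -> None:
    out = geno.copy()
    # integer counts where present, NA for missing
    write_table(out.astype("Int64"), path)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return read_table(path).astype(float)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", na_values=["NA"])
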