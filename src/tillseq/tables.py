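"""The allele-count table: the pipeline's common currency.

A count table is a long-form DataFrame with one row per
(pool, amplicon, 1-based position) holding the reference base and the
observed counts of A/C/G/T bases plus insertion and deletion events.
Both the screen simulator (counts mode) and the demultiplex-align-pileup
path (reads mode) produce this schema; the variant caller consumes it.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

COUNT_COLUMNS = ["pool", "amplicon", "position", "ref", "A", "C", "G", "T", "ins", "del"]
BASES = ["A", "C", "G", "T"]


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    for col in BASES + ["ins", "del"]:
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    return df


def base_coverage(df: pd.DataFrame) -> pd.Series:
    """Per-row base coverage (A+C+G+T); indel observations excluded."""
    return df[BASES].sum(axis=1)


def write_counts(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a count table as TSV, with provenance in '#' header lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        validate_counts(df).to_csv(fh, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t", comment="#"))


def concat_counts(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts of several tables over (pool, amplicon, position, ref)."""
    df = pd.concat(list(tables), ignore_index=True)
    return (
        df.groupby(["pool", "amplicon", "position", "ref"], as_index=False)[
            BASES + ["ins", "del"]
        ]
        .sum()
    )


def frequency_matrix(freq: pd.DataFrame) -> pd.DataFrame:
    """Pivot a frequency table to a (pool x position.substitution) matrix.

    Convenient for plotting per-pool frequency traces along an amplicon.
    """
    f = freq.copy()
    f["key"] = (
        f["amplicon"].astype(str)
        + ":"
        + f["position"].astype(str)
        + ":"
        + f["ref"].astype(str)
        + ">"
        + f["alt"].astype(str)
    )
    return f.pivot_table(index="pool", columns="key", values="frequency", fill_value=0.0)
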