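"""Reading and writing the tool's delimited-text interchange formats.

All tables are tab-separated with a header row; comma-separated input is
accepted via ``sep=','``.  Count matrices carry gene ids in the first
column and one column per sample.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, VarianceTrack, validate_annotation

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_variance_track",
    "write_variance_track",
    "read_condition_map",
    "track_from_counts",
    "parse_groups_flag",
]


def read_count_matrix(path, condition_map: dict | pd.Series, sep: str = "\t") -> CountMatrix:
    """Read a gene x sample count table and attach condition labels.

    ``condition_map`` maps every sample id in the header to its group
    label; a sample missing from the map is a configuration error.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            where = bad[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric entry in sample {col!r} (gene {where!r})"
            )
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(
                f"{path}: negative count at gene {neg[0]!r}, sample {col!r}"
            )
    cond = pd.Series(dict(condition_map) if not isinstance(condition_map, pd.Series) else condition_map)
    missing = [s for s in df.columns if s not in cond.index]
    if missing:
        raise ValueError(f"samples in {path} missing from condition map: {missing}")
    return CountMatrix(df, cond.loc[df.columns])


def write_count_matrix(cm: CountMatrix, path, sep: str = "\t") -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep=sep)


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read gene annotation (gene_id, length in bp, gc_fraction in [0,1])."""
    df = pd.read_csv(path, sep=sep)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: annotation needs a gene_id column")
    df = df.set_index("gene_id")
    return validate_annotation(df)


def write_annotation(ann: pd.DataFrame, path, sep: str = "\t") -> None:
    ann.rename_axis("gene_id").to_csv(path, sep=sep)


def read_variance_track(path, source_label: str | None = None, sep: str = "\t") -> VarianceTrack:
    df = pd.read_csv(path, sep=sep)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: variance track needs a gene_id column")
    return VarianceTrack(df.set_index("gene_id"), source_label or str(path))


def write_variance_track(track: VarianceTrack, path, sep: str = "\t") -> None:
    track.table.rename_axis("gene_id").to_csv(path, sep=sep)


def read_condition_map(path, sep: str = "\t") -> pd.Series:
    """Read a two-column sample_id / group table into a condition map."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: condition map needs sample_id and group columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def parse_groups_flag(spec: str) -> pd.Series:
    """Parse ``A:s1,s2 B:s3,s4`` into a condition map."""
    mapping = {}
    for block in spec.split():
        group, _, samples = block.partition(":")
        if not samples:
            raise ValueError(f"malformed group block {block!r}; expected G:s1,s2")
        for s in samples.split(","):
            if s in mapping:
                raise ValueError(f"sample {s!r} assigned to two groups")
            mapping[s] = group
    return pd.Series(mapping)


def track_from_counts(external: CountMatrix | pd.DataFrame, source_label: str = "") -> VarianceTrack:
    """Summarise an external count matrix into a gene-wise variance track.

    Per gene: sample mean and unbiased (n-1) sample variance across all
    columns, with the column count as the replicate number.  Conditions on
    the external matrix, if any, are ignored: the track summarises overall
    gene variability in that dataset.
    """
    counts = external.counts if isinstance(external, CountMatrix) else external
    if counts.shape[1] < 2:
        raise ValueError("external matrix needs >= 2 samples to define a variance")
    table = pd.DataFrame(
        {
            "ext_mean": counts.mean(axis=1),
            "ext_variance": counts.var(axis=1, ddof=1),
            "n_replicates": counts.shape[1],
        }
    )
    return VarianceTrack(table, source_label)
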