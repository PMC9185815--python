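"""Taxonomic profile and count tables: I/O and abundance/prevalence filtering.

A profile table is a :class:`pandas.DataFrame` with species (feature) IDs as
the row index and sample IDs as columns, holding relative abundances; a count
table is the same shape with non-negative integer read counts.  Tables are
exchanged as TSV in the mOTUs-profile dialect: an optional block of ``#``
comment lines, a header line that may start with ``#feature_id``, then one row
per feature.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileFormatError",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "filter_taxa",
    "filter_model_features",
    "qc_count_table",
    "to_counts",
]

HEADER_PREFIX = "#feature_id"


class ProfileFormatError(ValueError):
    """Malformed profile/metadata TSV (duplicate IDs, ragged rows, bad cells)."""


def _validate_table(df: pd.DataFrame, path: str) -> None:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ProfileFormatError(f"{path}: duplicated feature IDs: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ProfileFormatError(f"{path}: duplicated sample IDs: {dups}")
    if (df.to_numpy() < 0).any():
        raise ProfileFormatError(f"{path}: negative abundance values")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features-by-samples TSV table.

    Leading ``#`` lines are comments, except a line starting with
    ``#feature_id`` which is the (mOTUs-style) header.  A header without the
    ``#`` prefix is accepted too.  Errors name the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header = None
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith(HEADER_PREFIX):
            header = line[1:]
            data_start = i + 1
            break
        if not line.startswith("#"):
            header = line
            data_start = i + 1
            break
    if header is None:
        raise ProfileFormatError(f"{path}: no header line found")

    cols = header.split("\t")
    sample_ids = cols[1:]
    ncol = len(cols)
    index, rows = [], []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ProfileFormatError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        index.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ProfileFormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    df = pd.DataFrame(rows, index=pd.Index(index, name="feature_id"), columns=sample_ids)
    _validate_table(df, str(path))
    return df


def write_profile_tsv(table: pd.DataFrame, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a profile table; round-trips bit-identically through ``repr`` floats."""
    path = Path(path)
    buf = io.StringIO()
    for c in comments or []:
        buf.write(f"# {c}\n")
    buf.write(HEADER_PREFIX + "".join(f"\t{s}" for s in table.columns) + "\n")
    values = table.to_numpy()
    for i, fid in enumerate(table.index):
        buf.write(str(fid) + "".join(f"\t{float(v)!r}" for v in values[i]) + "\n")
    path.write_text(buf.getvalue())


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata table (sample_id index), '#' comments skipped."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ProfileFormatError(f"{path}: duplicated sample IDs in metadata: {dups}")
    return df


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        metadata.to_csv(fh, sep="\t", index_label="sample_id")


def filter_taxa(
    table: pd.DataFrame, min_abund: float = 1e-5, min_prev_frac: float = 0.02
) -> pd.DataFrame:
    """Retain features observed at >= ``min_abund`` in >= ``min_prev_frac`` of samples.

    Both comparisons are inclusive.  The functional-profile variant of the same
    screen is this call with ``min_prev_frac=0.15``.  Values of retained
    features are untouched; sample set unchanged.
    """
    if min_abund < 0:
        raise ValueError("min_abund must be >= 0")
    if not 0 <= min_prev_frac <= 1:
        raise ValueError("min_prev_frac must be in [0, 1]")
    prev = (table.to_numpy() >= min_abund).mean(axis=1)
    keep = prev >= min_prev_frac
    if not keep.any():
        warnings.warn("filter_taxa removed every feature", stacklevel=2)
    return table.loc[keep]


def filter_model_features(table: pd.DataFrame, abund_cutoff: float = 0.001) -> pd.DataFrame:
    """Retain features whose maximum relative abundance reaches ``abund_cutoff``.

    This is the pre-modelling screen removing low-abundance taxa before
    normalization; prevalence screening happens upstream in :func:`filter_taxa`.
    """
    if abund_cutoff < 0:
        raise ValueError("abund_cutoff must be >= 0")
    keep = table.to_numpy().max(axis=1) >= abund_cutoff
    if not keep.any():
        warnings.warn("filter_model_features removed every feature", stacklevel=2)
    return table.loc[keep]


def qc_count_table(
    table: pd.DataFrame, min_reads: int = 500, min_taxon_samples: int = 5
) -> pd.DataFrame:
    """Amplicon QC: drop samples with < ``min_reads`` total reads, then taxa
    present in fewer than ``min_taxon_samples`` of the remaining samples."""
    keep_samples = table.sum(axis=0) >= min_reads
    if not keep_samples.any():
        raise ValueError("qc_count_table: every sample fell below the read threshold")
    out = table.loc[:, keep_samples]
    keep_taxa = (out.to_numpy() > 0).sum(axis=1) >= min_taxon_samples
    return out.loc[keep_taxa]


def to_counts(profile: pd.DataFrame, depths: pd.Series) -> pd.DataFrame:
    """Turn relative abundances into integer read counts at per-sample depths."""
    depths = depths.reindex(profile.columns)
    counts = np.rint(profile.to_numpy() * depths.to_numpy()[None, :]).astype(np.int64)
    return pd.DataFrame(counts, index=profile.index, columns=profile.columns)
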