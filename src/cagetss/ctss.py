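"""CTSS extraction, pooling and normalization.

A CTSS (CAGE-defined transcription start site) is a single genomic base and
strand carrying a tag count: the 5' end of every uniquely mapped read,
tallied per sample.  Counts are normalized to tags per million (TPM) using
the library-wide mapped-tag total, and across samples by relative log
expression (RLE, median-of-ratios) size factors.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .config import SampleLibrary

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


class CTSSTable:
    """Per-base, per-strand 5'-end tag counts for one sample library.

    The table is kept sorted by (chrom, strand, pos) with unique keys and
    strictly positive integer counts; coordinates are 0-based.
    """

    def __init__(self, df: pd.DataFrame, library: SampleLibrary):
        df = df.loc[:, CTSS_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["count"] = df["count"].astype(np.int64)
        if (df["count"] <= 0).any():
            raise ValueError("CTSS counts must be positive integers")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {sorted(df.loc[bad, 'strand'].unique())}")
        # collapse duplicate keys (e.g. per-lane files) by summing
        df = (
            df.groupby(["chrom", "strand", "pos"], as_index=False, sort=True)["count"]
            .sum()
            .loc[:, CTSS_COLUMNS]
        )
        total = int(df["count"].sum())
        if total > library.total_mapped_tags:
            raise ValueError(
                f"sample {library.sample_id}: CTSS counts sum to {total} > "
                f"total_mapped_tags {library.total_mapped_tags}"
            )
        self.df = df.reset_index(drop=True)
        self.library = library

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CTSSTable):
            return NotImplemented
        return self.library == other.library and self.df.equals(other.df)

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    def tpm(self) -> pd.Series:
        """Tags per million for every CTSS: count * 1e6 / total mapped tags."""
        return tpm_normalize(self)


def tpm_from_counts(counts, total_mapped_tags: int):
    """count * 1e6 / library total; the paper's 10-count ~ 1-TPM equivalence
    holds at a 10-million-tag library."""
    if total_mapped_tags <= 0:
        raise ValueError("total_mapped_tags must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / float(total_mapped_tags)


def tpm_normalize(table: CTSSTable) -> pd.Series:
    return pd.Series(
        tpm_from_counts(table.df["count"].to_numpy(), table.library.total_mapped_tags),
        index=table.df.index,
        name="tpm",
    )


def extract_ctss(path: str | Path, library: SampleLibrary, min_quality: int = 10) -> CTSSTable:
    """Extract CTSS counts from aligned reads (SAM/BAM/CRAM or BED12).

    The CTSS of a forward-strand read is its leftmost aligned base, of a
    reverse-strand read its rightmost aligned base (both 0-based).  Unmapped,
    secondary and supplementary records and reads below ``min_quality`` are
    skipped (counted in ``extract_ctss.last_skipped``).
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        rows, skipped = _ctss_from_bed12(path)
    else:
        rows, skipped = _ctss_from_alignments(path, min_quality)
    extract_ctss.last_skipped = skipped
    if not rows:
        df = pd.DataFrame(columns=CTSS_COLUMNS)
    else:
        df = pd.DataFrame(rows, columns=CTSS_COLUMNS[:3])
        df["count"] = 1
    return CTSSTable(df, library)


def _ctss_from_alignments(path: Path, min_quality: int):
    rows = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped += 1
                continue
            if read.mapping_quality < min_quality:
                skipped += 1
                continue
            if read.is_reverse:
                rows.append((read.reference_name, read.reference_end - 1, "-"))
            else:
                rows.append((read.reference_name, read.reference_start, "+"))
    return rows, skipped


def _ctss_from_bed12(path: Path):
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED12 line has {len(fields)} fields, need >= 6")
            chrom, start, end, _, _, strand = fields[:6]
            if strand == "+":
                rows.append((chrom, int(start), "+"))
            elif strand == "-":
                rows.append((chrom, int(end) - 1, "-"))
            else:
                skipped += 1
    return rows, skipped


def rle_size_factors(counts: pd.DataFrame, pseudocount: float | None = None) -> pd.Series:
    """RLE (median-of-ratios) size factors across samples.

    The reference profile is the per-feature geometric mean over samples,
    using only features positive in every sample (unless ``pseudocount`` is
    given, in which case it is added to every cell first).  Each sample's
    factor is the median of its count/reference ratios, rescaled so the
    factors' geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("RLE needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    if pseudocount is not None:
        mat = mat + pseudocount
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature is positive in all samples; pass pseudocount= to regularize"
        )
    mat = mat[positive]
    ref = np.exp(np.log(mat).mean(axis=1))
    factors = np.median(mat / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def pool_counts(tables: Sequence[CTSSTable]) -> pd.DataFrame:
    """Pool CTSS tables across samples.

    Returns a frame indexed by row with columns chrom, pos, strand, one count
    column per sample_id, and ``pooled`` (the cross-sample sum), sorted by
    (chrom, strand, pos).  All tables must share one chromosome namespace:
    a chromosome seen in some tables only in a conflicting case/prefix form
    (e.g. both ``chr1`` and ``1``) is rejected.
    """
    if not tables:
        raise ValueError("no CTSS tables to pool")
    names = [t.library.sample_id for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample ids among pooled tables")
    _check_chrom_namespace(tables)
    parts = []
    for t in tables:
        part = t.df.copy()
        part["sample"] = t.library.sample_id
        parts.append(part)
    long = pd.concat(parts, ignore_index=True)
    wide = (
        long.pivot_table(
            index=["chrom", "strand", "pos"],
            columns="sample",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(np.int64)
    )
    # keep sample column order as given; samples with empty tables keep a zero column
    wide = wide.reindex(columns=names, fill_value=0)
    wide.columns.name = None
    wide["pooled"] = wide[names].sum(axis=1)
    out = wide.reset_index().loc[:, ["chrom", "pos", "strand"] + names + ["pooled"]]
    out = out.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _normalize_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _check_chrom_namespace(tables: Iterable[CTSSTable]) -> None:
    seen: dict[str, set[str]] = {}
    for t in tables:
        for chrom in t.df["chrom"].unique():
            seen.setdefault(_normalize_chrom(str(chrom)), set()).add(str(chrom))
    conflicts = {k: sorted(v) for k, v in seen.items() if len(v) > 1}
    if conflicts:
        raise ValueError(f"conflicting chromosome names across samples: {conflicts}")
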