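"""Readers and writers for the standard formats the pipeline touches.

Conventions: all in-memory coordinates are 0-based half-open (BED); GTF/GFF
input (1-based closed) is converted at the boundary.  CTSS files are BED6
single-base intervals with the tag count in the score column; peaks are
BED6 plus two extra columns (representative position, tier) with a
tab-separated per-sample TPM sidecar matrix.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import SampleLibrary
from .ctss import CTSS_COLUMNS, CTSSTable

GENE_SOURCES = ("refseq", "ensembl", "noncode", "other")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CTSS BED
# ---------------------------------------------------------------------------

def read_ctss_bed(path: str | Path, library: SampleLibrary) -> CTSSTable:
    """Read a CTSS BED6 file (single-base intervals, score = tag count).

    Duplicate (chrom, pos, strand) lines are summed.  Malformed lines raise
    :class:`ParseError` carrying the 1-based line number; intervals whose
    length is not exactly one base are format errors.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(fields)}")
            chrom, start, end, _name, score, strand = fields[:6]
            try:
                start_i, end_i, count = int(start), int(end), int(score)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate or count ({exc})") from None
            if end_i - start_i != 1:
                raise ParseError(
                    f"{path}:{lineno}: CTSS interval [{start_i}, {end_i}) is not a single base"
                )
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            if count <= 0:
                raise ParseError(f"{path}:{lineno}: count must be a positive integer, got {count}")
            rows.append((chrom, start_i, strand, count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    return CTSSTable(df, library)


def write_ctss_bed(table: CTSSTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{table.library.sample_id}\t{r.count}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models(path: str | Path, source: str = "other") -> pd.DataFrame:
    """Read gene models from GTF/GFF (1-based closed) or BED6 (0-based).

    Returns one row per gene with its annotated TSS: the 5'-most transcript
    start on the gene's strand, as a 0-based position.  Genes without a
    strand are skipped with a warning attribute (``read_gene_models.skipped``).
    Columns: gene_id, symbol, chrom, strand, tss, source.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gtf", ".gff", ".gff3"}:
        df = _genes_from_gtf(path)
    elif suffix == ".bed":
        df = _genes_from_bed6(path)
    else:
        raise ParseError(f"unknown gene-model extension {suffix!r} (need .gtf/.gff/.gff3/.bed)")
    df["source"] = source if source in GENE_SOURCES else "other"
    return df.reset_index(drop=True)


def _genes_from_gtf(path: Path) -> pd.DataFrame:
    records = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in {"transcript", "mRNA", "gene"}:
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id") or attr.get("ID") or attr.get("Parent")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: no gene_id attribute")
            if strand not in "+-":
                skipped += 1
                continue
            records.append(
                (gene_id, attr.get("gene_name", gene_id), chrom, strand, feature, int(start) - 1, int(end))
            )
    read_gene_models.skipped = skipped
    if not records:
        return pd.DataFrame(columns=["gene_id", "symbol", "chrom", "strand", "tss"])
    df = pd.DataFrame(records, columns=["gene_id", "symbol", "chrom", "strand", "feature", "start", "end"])
    # prefer transcript-level records; fall back to gene extents
    tx = df[df["feature"] != "gene"]
    use = tx if len(tx) else df
    out = []
    for (gene_id, symbol, chrom, strand), grp in use.groupby(
        ["gene_id", "symbol", "chrom", "strand"], sort=True
    ):
        # 5'-most transcript start: min start on '+', max end - 1 on '-'
        tss = int(grp["start"].min()) if strand == "+" else int(grp["end"].max()) - 1
        out.append((gene_id, symbol, chrom, strand, tss))
    return pd.DataFrame(out, columns=["gene_id", "symbol", "chrom", "strand", "tss"])


def _genes_from_bed6(path: Path) -> pd.DataFrame:
    records = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in "+-":
                skipped += 1
                continue
            tss = int(start) if strand == "+" else int(end) - 1
            records.append((name, name, chrom, strand, tss))
    read_gene_models.skipped = skipped
    return pd.DataFrame(records, columns=["gene_id", "symbol", "chrom", "strand", "tss"])


# ---------------------------------------------------------------------------
# Plain BED intervals (CpG islands, HCE/ASHCE, ...)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields, got {len(fields)}")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed_intervals(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(df.itertuples(index=False)):
            name = getattr(r, name_col) if name_col else f"iv{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def write_peak_bed(peaks: pd.DataFrame, tpm: pd.DataFrame, path: str | Path) -> None:
    """Peak BED6+2: name = peak_id, score = round(max pooled TPM), then the
    representative position and the permissive/robust tier."""
    max_tpm = tpm.max(axis=1)
    with open(path, "w") as fh:
        for r in peaks.itertuples(index=False):
            score = int(round(max_tpm.loc[r.peak_id]))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\t{score}\t{r.strand}"
                f"\t{r.representative_pos}\t{r.tier}\n"
            )


def read_peak_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 peak fields, got {len(fields)}")
            chrom, start, end, peak_id, _score, strand, rep, tier = fields[:8]
            rows.append((peak_id, chrom, strand, int(start), int(end), int(rep), tier))
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "strand", "start", "end", "representative_pos", "tier"]
    )


# ---------------------------------------------------------------------------
# Expression matrices and generic TSV
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_slice(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) (clipped) from a dict of strings or a
    pyfaidx.Fasta handle, always returning an upper-case string."""
    seq = genome[chrom]
    n = len(seq)
    start, end = max(0, start), min(end, n)
    if start >= end:
        return ""
    return str(seq[start:end]).upper()
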