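"""Peak annotation: gene association, interval overlap, promoter GC.

Peaks are associated to the closest gene whose annotated TSS lies within a
window (default 500 bp) of the peak's representative position on the same
strand; overlap with interval sets (CpG islands, conserved elements) is
strand-blind and counted from a single shared base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GENE_SOURCES, genome_slice

_SOURCE_PRIORITY = {src: i for i, src in enumerate(GENE_SOURCES)}


def associate_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 500,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Associate each peak with the closest gene TSS within ``window_bp``.

    Candidates must share the chromosome (and strand, unless
    ``ignore_strand``); the closest absolute distance wins, with ties broken
    by source priority (refseq > ensembl > others) and then lexicographic
    gene id, so the result is independent of gene-list order.  The reported
    distance is strand-oriented: positive means the peak representative lies
    downstream of the gene TSS.
    """
    gene_cols = ["gene_id", "symbol", "chrom", "strand", "tss", "source"]
    g = genes.loc[:, gene_cols].copy()
    g["priority"] = g["source"].map(lambda s: _SOURCE_PRIORITY.get(s, len(GENE_SOURCES)))
    out_gene, out_dist = [], []
    grouped = {k: v for k, v in g.groupby(["chrom"] if ignore_strand else ["chrom", "strand"])}
    for r in peaks.itertuples(index=False):
        key = (r.chrom,) if ignore_strand else (r.chrom, r.strand)
        cand = grouped.get(key)
        if cand is None:
            out_gene.append(None)
            out_dist.append(np.nan)
            continue
        dist = (cand["tss"] - r.representative_pos).abs()
        within = cand[dist <= window_bp].copy()
        if len(within) == 0:
            out_gene.append(None)
            out_dist.append(np.nan)
            continue
        within["absdist"] = (within["tss"] - r.representative_pos).abs()
        within = within.sort_values(["absdist", "priority", "gene_id"], kind="mergesort")
        best = within.iloc[0]
        signed = r.representative_pos - best.tss
        if r.strand == "-":
            signed = -signed
        out_gene.append(best.gene_id)
        out_dist.append(signed)
    out = peaks.loc[:, ["peak_id"]].copy()
    out["gene_id"] = out_gene
    out["distance_bp"] = out_dist
    return out


def interval_overlap(peaks: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """True iff the peak interval shares >= 1 bp with any set interval
    (half-open, strand-blind)."""
    trees: dict[str, IntervalTree] = {}
    for r in intervals.itertuples(index=False):
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    flags = [
        bool(trees.get(r.chrom) and trees[r.chrom].overlap(r.start, r.end))
        for r in peaks.itertuples(index=False)
    ]
    return pd.Series(flags, index=peaks.index, name="overlap")


def gc_content(genome, chrom: str, representative_pos: int, flank: int = 50) -> float:
    """GC fraction in [rep - flank, rep + flank), clipped to the chromosome.

    Ambiguous bases are excluded from numerator and denominator; NaN when no
    unambiguous base remains.
    """
    window = genome_slice(genome, chrom, representative_pos - flank, representative_pos + flank)
    gc = sum(window.count(b) for b in "GC")
    acgt = gc + sum(window.count(b) for b in "AT")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame | None,
    genome,
    interval_sets: dict[str, pd.DataFrame] | None = None,
    window_bp: int = 500,
    flank: int = 50,
) -> pd.DataFrame:
    """One row per peak: gene association, interval-set flags, promoter GC."""
    if genes is not None and len(genes):
        out = associate_genes(peaks, genes, window_bp=window_bp)
    else:
        out = peaks.loc[:, ["peak_id"]].copy()
        out["gene_id"] = None
        out["distance_bp"] = np.nan
    for name, intervals in (interval_sets or {}).items():
        out[f"{name}_overlap"] = interval_overlap(peaks, intervals).to_numpy()
    if genome is not None:
        out["gc_100bp"] = [
            gc_content(genome, r.chrom, r.representative_pos, flank=flank)
            for r in peaks.itertuples(index=False)
        ]
    return out


def tss_per_gene(
    annotations: pd.DataFrame, tpm: pd.DataFrame | None = None, min_tpm: float = 0.0
) -> pd.Series:
    """Number of associated peaks per gene, over peaks whose maximum TPM
    passes ``min_tpm`` (all peaks when no matrix is given)."""
    ann = annotations[annotations["gene_id"].notna()]
    if tpm is not None and min_tpm > 0:
        passing = tpm.max(axis=1) > min_tpm
        ann = ann[ann["peak_id"].map(passing).fillna(False)]
    return ann.groupby("gene_id")["peak_id"].nunique().rename("n_peaks")
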