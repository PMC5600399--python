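"""TSS peak calling from pooled CTSS signal.

A deterministic decomposition variant: strand-specific single-linkage
clustering of CTSS positions (gap <= ``gap_bp``), Gaussian smoothing and
valley splitting of long clusters, permissive/robust thresholding, and
selection of a representative position (the CTSS with the highest pooled
count, ties to the 5'-most on the peak's strand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .config import PipelineConfig, SampleLibrary

PEAK_COLUMNS = ["peak_id", "chrom", "strand", "start", "end", "representative_pos", "tier", "pooled_count"]


def cluster_ctss(pooled: pd.DataFrame, gap_bp: int) -> pd.Series:
    """Assign every pooled CTSS row a cluster id.

    Consecutive CTSS on one (chrom, strand) join a cluster iff their
    positional gap is <= ``gap_bp``; clusters partition the table.  The
    input must be sorted by (chrom, strand, pos), as ``pool_counts``
    returns it.
    """
    if len(pooled) == 0:
        return pd.Series([], dtype=np.int64, name="cluster_id")
    chrom = pooled["chrom"].to_numpy()
    strand = pooled["strand"].to_numpy()
    pos = pooled["pos"].to_numpy()
    same_run = (chrom[1:] == chrom[:-1]) & (strand[1:] == strand[:-1])
    if not (pos[1:][same_run] > pos[:-1][same_run]).all():
        raise ValueError("pooled table must be sorted by (chrom, strand, pos) with unique keys")
    new_cluster = np.empty(len(pooled), dtype=bool)
    new_cluster[0] = True
    new_cluster[1:] = ~same_run | (pos[1:] - pos[:-1] > gap_bp)
    return pd.Series(np.cumsum(new_cluster) - 1, index=pooled.index, name="cluster_id")


def split_cluster(positions: np.ndarray, counts: np.ndarray, config: PipelineConfig) -> list[tuple[int, int]]:
    """Split one tag cluster into peak intervals (0-based half-open).

    Clusters spanning <= ``max_unsplit_bp`` pass through unsplit.  Longer
    clusters are smoothed with a Gaussian kernel (sigma ``smooth_sigma``,
    truncated at 3 sigma) and cut at local minima deeper than
    ``valley_frac`` times the smaller flanking maximum.  Deterministic; the
    cut goes at the first (leftmost) minimum of each qualifying valley.
    """
    positions = np.asarray(positions)
    counts = np.asarray(counts)
    if len(positions) == 0:
        return []
    order = np.argsort(positions)
    positions, counts = positions[order], counts[order]
    start, end = int(positions[0]), int(positions[-1]) + 1
    if end - start <= config.max_unsplit_bp:
        return [(start, end)]
    dense = np.zeros(end - start, dtype=float)
    dense[positions - start] = counts
    smooth = gaussian_filter1d(dense, sigma=config.smooth_sigma, truncate=3.0, mode="constant")
    maxima, _ = find_peaks(smooth)
    cuts = []
    for left, right in zip(maxima[:-1], maxima[1:]):
        seg = smooth[left : right + 1]
        valley = int(left + np.argmin(seg))
        if smooth[valley] < config.valley_frac * min(smooth[left], smooth[right]):
            cuts.append(valley)
    if not cuts:
        return [(start, end)]
    bounds = [start] + [start + c + 1 for c in cuts] + [end]
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        member = (positions >= s) & (positions < e)
        if member.any():
            segments.append((int(positions[member][0]), int(positions[member][-1]) + 1))
    return segments


def representative_position(positions: np.ndarray, pooled_counts: np.ndarray, strand: str) -> int:
    """The member position with the highest pooled count; ties break to the
    5'-most position on the peak's strand."""
    pooled_counts = np.asarray(pooled_counts)
    if len(pooled_counts) == 0:
        raise ValueError("empty positional counts")
    positions = np.asarray(positions)
    order = np.argsort(positions)
    positions, pooled_counts = positions[order], pooled_counts[order]
    if strand == "+":
        return int(positions[np.argmax(pooled_counts)])
    reversed_idx = np.argmax(pooled_counts[::-1])
    return int(positions[len(positions) - 1 - reversed_idx])


@dataclass
class PeakSet:
    """Called TSS peaks plus their per-sample expression.

    ``peaks`` has one row per peak (PEAK_COLUMNS); ``counts``/``tpm`` are
    peak x sample matrices; ``members`` is the pooled CTSS table with a
    ``peak_id`` column assigning every surviving CTSS to its peak.
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    tpm: pd.DataFrame
    members: pd.DataFrame
    samples: list[SampleLibrary]

    def profile(self, peak_id: str) -> pd.DataFrame:
        m = self.members[self.members["peak_id"] == peak_id]
        return m.loc[:, ["pos", "pooled"]].reset_index(drop=True)


def call_peaks(pooled: pd.DataFrame, samples: list[SampleLibrary], config: PipelineConfig) -> PeakSet:
    """Full peak calling: cluster, split, threshold, represent.

    Peaks failing the permissive rule (no CTSS with
    >= ``permissive_min_count`` tags in any one sample) are dropped; a peak
    is robust when one CTSS in one sample reaches >= ``robust_min_count``
    tags and >= ``robust_min_tpm`` TPM simultaneously.
    """
    sample_ids = [s.sample_id for s in samples]
    totals = np.array([s.total_mapped_tags for s in samples], dtype=float)
    work = pooled.reset_index(drop=True).copy()
    cluster_ids = cluster_ctss(work, config.gap_bp).to_numpy()
    work["cluster_id"] = cluster_ids

    pos_all = work["pos"].to_numpy()
    pooled_all = work["pooled"].to_numpy()
    chrom_all = work["chrom"].to_numpy()
    strand_all = work["strand"].to_numpy()
    peak_of_row = np.full(len(work), -1, dtype=np.int64)
    peak_rows: list[tuple[str, str, int, int, int, int]] = []  # chrom,strand,start,end,rep,pooled

    # clusters are contiguous row ranges in the sorted table
    starts = np.flatnonzero(np.r_[True, np.diff(cluster_ids) != 0]) if len(work) else np.empty(0, int)
    ends = np.r_[starts[1:], len(work)] if len(work) else np.empty(0, int)
    for lo, hi in zip(starts, ends):
        chrom = chrom_all[lo]
        strand = strand_all[lo]
        positions = pos_all[lo:hi]
        cts = pooled_all[lo:hi]
        for seg_start, seg_end in split_cluster(positions, cts, config):
            member_mask = (positions >= seg_start) & (positions < seg_end)
            rep = representative_position(positions[member_mask], cts[member_mask], strand)
            peak_idx = len(peak_rows)
            peak_rows.append(
                (chrom, strand, int(seg_start), int(seg_end), rep, int(cts[member_mask].sum()))
            )
            peak_of_row[lo:hi][member_mask] = peak_idx
    assert (peak_of_row >= 0).all() or len(work) == 0

    work["_peak_idx"] = peak_of_row
    counts_mat = work[sample_ids].to_numpy(dtype=np.int64)
    tpm_mat = counts_mat * (1e6 / totals)[None, :]
    permissive_cell = counts_mat >= config.permissive_min_count
    robust_cell = (counts_mat >= config.robust_min_count) & (tpm_mat >= config.robust_min_tpm)

    n_peaks = len(peak_rows)
    permissive = np.zeros(n_peaks, dtype=bool)
    robust = np.zeros(n_peaks, dtype=bool)
    np.logical_or.at(permissive, peak_of_row, permissive_cell.any(axis=1))
    np.logical_or.at(robust, peak_of_row, robust_cell.any(axis=1))

    keep = permissive
    peaks_df = pd.DataFrame(peak_rows, columns=["chrom", "strand", "start", "end", "representative_pos", "pooled_count"])
    peaks_df["tier"] = np.where(robust, "robust", "permissive")
    peaks_df = peaks_df[keep].copy()
    # genome order, stable ids
    peaks_df = peaks_df.sort_values(["chrom", "strand", "start"], kind="mergesort").reset_index()
    old_to_new = {old: f"peak{n:05d}" for n, old in enumerate(peaks_df["index"])}
    peaks_df["peak_id"] = [old_to_new[i] for i in peaks_df["index"]]

    member_keep = keep[peak_of_row] & (peak_of_row >= 0)
    members = work[member_keep].copy()
    members["peak_id"] = [old_to_new[i] for i in members["_peak_idx"]]
    members = members.drop(columns=["cluster_id", "_peak_idx"])

    per_peak_counts = members.groupby("peak_id", sort=True)[sample_ids].sum()
    per_peak_counts = per_peak_counts.reindex(peaks_df["peak_id"])
    tpm = per_peak_counts / totals[None, :] * 1e6

    peaks_df = peaks_df.drop(columns=["index"]).loc[:, PEAK_COLUMNS].reset_index(drop=True)
    _validate_peaks(peaks_df)
    return PeakSet(peaks_df, per_peak_counts, tpm, members, list(samples))


def _validate_peaks(peaks: pd.DataFrame) -> None:
    bad = ~((peaks["start"] <= peaks["representative_pos"]) & (peaks["representative_pos"] < peaks["end"]))
    if bad.any():
        raise AssertionError("representative position outside peak interval")
    for (_, _), grp in peaks.groupby(["chrom", "strand"]):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise AssertionError("peak intervals overlap within a strand")
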