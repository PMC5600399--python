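"""Promoter shape and super-cluster structure.

The shape index SI = 2 + sum_i p_i log2 p_i summarises how concentrated a
peak's within-peak tag distribution is: 2 when every tag maps to a single
base, lower as the profile broadens.  Peaks with SI above the boundary
(default -1) are "sharp", at or below it "broad".  Peaks reaching 1 TPM are
merged into super clusters at a 100 bp gap, modelling multimodal promoters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .peaks import PeakSet


def shape_index(counts) -> float:
    """SI = 2 + sum p_i log2 p_i over within-peak tag fractions.

    Terms with p_i = 0 contribute nothing; the maximum, 2, is attained when
    all tags share one position.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("shape index needs a profile with positive total count")
    if (c < 0).any():
        raise ValueError("negative counts in profile")
    p = c / c.sum()
    nz = p > 0
    return float(2.0 + np.sum(p[nz] * np.log2(p[nz])))


def classify_shape(si: float, boundary: float = -1.0) -> str:
    """Sharp iff SI > boundary; the boundary value itself is called broad."""
    return "sharp" if si > boundary else "broad"


def peak_shapes(peakset: PeakSet, boundary: float = -1.0) -> pd.DataFrame:
    """Shape index and class for every peak, from pooled member counts."""
    members = peakset.members
    rows = []
    for peak_id, grp in members.groupby("peak_id", sort=False):
        si = shape_index(grp["pooled"].to_numpy())
        rows.append((peak_id, si, classify_shape(si, boundary)))
    df = pd.DataFrame(rows, columns=["peak_id", "shape_index", "shape_class"])
    order = {p: i for i, p in enumerate(peakset.peaks["peak_id"])}
    return df.sort_values("peak_id", key=lambda s: s.map(order), kind="mergesort").reset_index(drop=True)


def super_clusters(
    peaks: pd.DataFrame,
    tpm: pd.DataFrame,
    min_tpm: float = 1.0,
    gap: int = 100,
    scope: list[str] | None = None,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Merge peaks into super clusters.

    A peak is included iff its maximum TPM over the in-scope samples (all
    samples when ``scope`` is None) reaches ``min_tpm``.  Included peaks
    whose inter-peak gap (next start - previous end) is <= ``gap`` merge,
    strand-aware by default.  Returns one row per super cluster with
    cluster_id, chrom, strand, start, end, n_members and the member peak
    ids (comma-joined, in genome order).
    """
    cols = list(tpm.columns) if scope is None else list(scope)
    max_tpm = tpm.loc[:, cols].max(axis=1)
    included = peaks[peaks["peak_id"].map(max_tpm) >= min_tpm].copy()
    if len(included) == 0:
        return pd.DataFrame(
            columns=["cluster_id", "chrom", "strand", "start", "end", "n_members", "member_peak_ids"]
        )
    keys = ["chrom"] if ignore_strand else ["chrom", "strand"]
    included = included.sort_values(keys + ["start"], kind="mergesort")
    rows = []
    for key, grp in included.groupby(keys, sort=True):
        chrom = key[0] if isinstance(key, tuple) else key
        strand = "." if ignore_strand else key[1]
        current: list = []
        cur_end = None
        for r in grp.itertuples(index=False):
            if current and r.start - cur_end <= gap:
                current.append(r.peak_id)
                cur_end = max(cur_end, r.end)
            else:
                if current:
                    rows.append((chrom, strand, cur_start, cur_end, current))
                current = [r.peak_id]
                cur_start, cur_end = r.start, r.end
        if current:
            rows.append((chrom, strand, cur_start, cur_end, current))
    out = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", "members"])
    out.insert(0, "cluster_id", [f"sc{i:05d}" for i in range(len(out))])
    out["n_members"] = out["members"].map(len)
    out["member_peak_ids"] = out["members"].map(",".join)
    return out.drop(columns=["members"])


def size_distribution(superclusters: pd.DataFrame) -> dict:
    """Histogram of member counts and span statistics of super clusters."""
    counts = superclusters["n_members"].value_counts().sort_index()
    spans = (superclusters["end"] - superclusters["start"]).to_numpy()
    return {
        "n_members_histogram": {int(k): int(v) for k, v in counts.items()},
        "spans_bp": spans,
        "median_span_bp": float(np.median(spans)) if len(spans) else float("nan"),
    }
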