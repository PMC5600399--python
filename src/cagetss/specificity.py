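"""Expression classification and ordination.

Classifies peaks from their TPM matrix: expressed (> 3 TPM), ubiquitous
tiers (active in every sample above 3 / 100 / 300-with-700-mean TPM),
group-enriched (mean over a sample group above 10 TPM and 10-fold over a
cross-sample reference) and housekeeping (> 10 TPM in every sample with
sigma(log2 TPM) < 1).  Sample relationships are summarised by principal
coordinates analysis (classical multidimensional scaling) of a sample
distance matrix, by default 1 - Spearman correlation of log2(TPM + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr


def expression_stats(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-feature summary: mean/median/min/max TPM, sigma(log2 TPM), fold.

    sd_log2 and fold are defined only for features positive in every sample
    (NaN otherwise).
    """
    mat = tpm.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "mean_tpm": mat.mean(axis=1),
            "median_tpm": np.median(mat, axis=1),
            "min_tpm": mat.min(axis=1),
            "max_tpm": mat.max(axis=1),
        },
        index=tpm.index,
    )
    all_pos = (mat > 0).all(axis=1)
    sd = np.full(len(out), np.nan)
    fold = np.full(len(out), np.nan)
    if all_pos.any():
        sd[all_pos] = np.log2(mat[all_pos]).std(axis=1, ddof=1)
        fold[all_pos] = mat[all_pos].max(axis=1) / mat[all_pos].min(axis=1)
    out["sd_log2"] = sd
    out["fold"] = fold
    return out


def expressed_calls(tpm: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Strictly greater than the expression cutoff (3 TPM ~ one transcript
    per cell)."""
    return tpm > threshold


def enrichment_score(
    tpm: pd.DataFrame, reference: str = "median", pseudocount: float = 0.1
) -> pd.DataFrame:
    """log10((x + eps) / (ref + eps)) against the cross-sample reference."""
    ref = _reference(tpm, reference)
    return np.log10((tpm + pseudocount).div(ref + pseudocount, axis=0))


def _reference(tpm: pd.DataFrame, reference: str) -> pd.Series:
    if reference == "median":
        return tpm.median(axis=1)
    if reference == "mean":
        return tpm.mean(axis=1)
    raise ValueError(f"reference must be 'median' or 'mean', got {reference!r}")


def group_enriched(
    tpm: pd.DataFrame,
    groups: dict[str, list[str]],
    min_tpm: float = 10.0,
    fold: float = 10.0,
    reference: str = "mean",
) -> dict[str, pd.Index]:
    """Peaks enriched in each sample group.

    A peak is enriched in group G iff its mean TPM over G exceeds
    ``min_tpm`` and ``fold`` times the cross-sample reference (mean by
    default; the median variant is exposed).
    """
    ref = _reference(tpm, reference)
    out: dict[str, pd.Index] = {}
    for group, members in groups.items():
        missing = [m for m in members if m not in tpm.columns]
        if missing:
            raise KeyError(f"group {group!r} members absent from matrix: {missing}")
        gmean = tpm.loc[:, members].mean(axis=1)
        mask = (gmean > min_tpm) & (gmean > fold * ref)
        out[group] = tpm.index[mask]
    return out


def housekeeping_set(
    tpm: pd.DataFrame,
    min_tpm: float = 10.0,
    max_sd_log2: float = 1.0,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Index | None]:
    """Housekeeping peaks: above ``min_tpm`` in every sample with
    sigma(log2 TPM) below ``max_sd_log2``, ranked by stability.

    Returns (peak table sorted by ascending sd_log2, gene index or None);
    the gene-level set collapses qualifying peaks through ``annotations``
    (peak_id -> gene_id).
    """
    mat = tpm.to_numpy(dtype=float)
    ubiquitous = (mat > min_tpm).all(axis=1)
    sd = np.full(len(tpm), np.inf)
    sd[ubiquitous] = np.log2(mat[ubiquitous]).std(axis=1, ddof=1)
    mask = ubiquitous & (sd < max_sd_log2)
    peaks = pd.DataFrame({"sd_log2": sd[mask]}, index=tpm.index[mask])
    peaks = peaks.sort_values("sd_log2", kind="mergesort")
    genes = None
    if annotations is not None:
        ann = annotations.set_index("peak_id")["gene_id"]
        genes = pd.Index(sorted(ann.reindex(peaks.index).dropna().unique()), name="gene_id")
    return peaks, genes


def ubiquity_tiers(tpm: pd.DataFrame) -> pd.Series:
    """Nested ubiquity tiers per peak.

    ubiquitous: > 3 TPM in every sample; high: > 100 TPM in every sample;
    extreme: > 300 TPM in every sample and cross-sample mean > 700 TPM.
    Returns 'none' / 'ubiquitous' / 'high' / 'extreme' (the deepest tier).
    """
    mn = tpm.min(axis=1)
    mean = tpm.mean(axis=1)
    tier = pd.Series("none", index=tpm.index, name="tier")
    tier[mn > 3] = "ubiquitous"
    tier[mn > 100] = "high"
    tier[(mn > 300) & (mean > 700)] = "extreme"
    return tier


# ---------------------------------------------------------------------------
# Principal coordinates analysis (classical MDS)
# ---------------------------------------------------------------------------

def classical_mds(distances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical multidimensional scaling of a symmetric distance matrix.

    Double-centres B = -1/2 J D^2 J, eigendecomposes, and returns
    coordinates built from the positive eigenpairs in non-increasing
    eigenvalue order.  The sign of each axis is fixed by making its first
    nonzero loading positive.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigvals[0]), 1.0))
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords, eigvals[keep]


def sample_distances(tpm: pd.DataFrame, distance: str = "one_minus_spearman") -> pd.DataFrame:
    """Sample-by-sample distance matrix from a TPM matrix."""
    if tpm.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    log = np.log2(tpm.to_numpy(dtype=float) + 1.0)
    if distance == "one_minus_spearman":
        if log.shape[0] < 2 or np.allclose(log, log[0:1, :]):
            d = np.zeros((tpm.shape[1], tpm.shape[1]))
        else:
            rho = spearmanr(log, axis=0).statistic
            rho = np.atleast_2d(rho)
            d = 1.0 - rho
            np.fill_diagonal(d, 0.0)
            d = np.clip((d + d.T) / 2, 0.0, None)
    elif distance == "euclidean_log":
        d = squareform(pdist(log.T, metric="euclidean"))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return pd.DataFrame(d, index=tpm.columns, columns=tpm.columns)


def pcoa(
    tpm: pd.DataFrame, distance: str = "one_minus_spearman"
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCoA of samples: returns (coordinates frame samples x axes,
    eigenvalues in non-increasing order).  All-identical samples yield an
    empty (all-zero) coordinate set."""
    d = sample_distances(tpm, distance=distance)
    coords, eigvals = classical_mds(d.to_numpy())
    if coords.shape[1] == 0:
        coords = np.zeros((d.shape[0], 1))
        eigvals = np.zeros(1)
    frame = pd.DataFrame(
        coords, index=d.index, columns=[f"axis{i + 1}" for i in range(coords.shape[1])]
    )
    return frame, eigvals
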