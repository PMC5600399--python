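"""Promoter window extraction, PWM scanning and motif enrichment.

Windows span (-300, +100) around the representative TSS, oriented 5'->3'
with the TSS at offset 300.  PWMs (JASPAR-style count matrices) are scanned
by sliding log-odds score; a window "hits" when any offset reaches a
fraction (default 80%) of the motif's maximum attainable score.  Enrichment
of a foreground window set against a background set is a one-sided exact
test on the per-motif hit/no-hit 2x2 table, Benjamini-Hochberg adjusted
across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import genome_slice
from .simulate import reverse_complement

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PWM:
    """A position weight matrix with its scanning threshold.

    ``matrix`` is 4 x L (rows A, C, G, T), columns summing to 1 after
    pseudocount regularization.  Scores are log2 odds against the
    background; the hit threshold is ``threshold_frac`` of the maximum
    attainable score.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray
    threshold_frac: float = 0.8

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1 (after pseudocount regularization)")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        threshold_frac: float = 0.8,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(motif_id, counts / counts.sum(axis=0), np.asarray(background, float), threshold_frac)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def read_jaspar(path: str | Path, pseudocount: float = 0.01, threshold_frac: float = 0.8) -> list[PWM]:
    """Read JASPAR-format count matrices (4-row A/C/G/T blocks)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        name = m.matrix_id or m.name
        out.append(PWM.from_counts(name, counts, pseudocount=pseudocount, threshold_frac=threshold_frac))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            for base, row in zip("ACGT", np.round(p.matrix * scale).astype(int)):
                fh.write(f"{base}  [ " + " ".join(f"{v:4d}" for v in row) + " ]\n")


def _consensus_counts(consensus: str, strength: int = 97) -> np.ndarray:
    counts = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts[_BASE_INDEX[base], j] = strength
    return counts


def bundled_test_pwms(seed: int = 7) -> list[PWM]:
    """A small built-in PWM set for tests and the synthetic study: a
    TATA-box-like motif, a GC-box-like motif, and three random motifs."""
    rng = np.random.default_rng(seed)
    pwms = [
        PWM.from_counts("TATA_box", _consensus_counts("TATAAA")),
        PWM.from_counts("GC_box", _consensus_counts("GGGCGG")),
    ]
    for k in range(3):
        consensus = "".join(rng.choice(list("ACGT"), size=8))
        pwms.append(PWM.from_counts(f"random_{k + 1}", _consensus_counts(consensus)))
    return pwms


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def promoter_windows(
    peaks: pd.DataFrame, genome, window: tuple[int, int] = (-300, 100)
) -> pd.DataFrame:
    """Strand-aware sequence windows around each representative TSS.

    On '+' the genomic slice is [rep + upstream, rep + downstream); on '-'
    it is [rep - downstream + 1, rep - upstream + 1) reverse-complemented,
    so every output reads 5'->3' with the TSS at offset -upstream.  Windows
    clipped at chromosome edges are flagged.
    """
    up, down = window
    full_len = down - up
    rows = []
    for r in peaks.itertuples(index=False):
        rep = r.representative_pos
        if r.strand == "+":
            start, end = rep + up, rep + down
            seq = genome_slice(genome, r.chrom, start, end)
            clipped = len(seq) < full_len
        else:
            start, end = rep - down + 1, rep - up + 1
            seq = genome_slice(genome, r.chrom, start, end)
            clipped = len(seq) < full_len
            seq = reverse_complement(seq)
        rows.append((r.peak_id, seq, clipped))
    return pd.DataFrame(rows, columns=["peak_id", "sequence", "clipped"])


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = i
    return idx


def pwm_scan(sequence: str, pwm: PWM, both_strands: bool = True) -> int:
    """Number of offsets whose log-odds score reaches the PWM threshold.

    Any offset containing an ambiguous base scores -inf.  When
    ``both_strands`` is set the reverse complement is scanned too.
    """
    count = _scan_one(sequence.upper(), pwm)
    if both_strands:
        count += _scan_one(reverse_complement(sequence), pwm)
    return count


def _scan_one(seq: str, pwm: PWM) -> int:
    L = pwm.length
    n = len(seq) - L + 1
    if n <= 0:
        return 0
    idx = _encode(seq)
    lo = pwm.log_odds
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j : j + n]
        ok = col >= 0
        valid &= ok
        scores[ok] += lo[col[ok], j]
    return int(np.count_nonzero(valid & (scores >= pwm.threshold - 1e-12)))


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(
    fg: Mapping[str, str],
    bg: Mapping[str, str],
    pwms: Sequence[PWM],
    both_strands: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif over-representation of foreground vs background windows.

    For each PWM, sequences are reduced to hit/no-hit; the 2x2 table
    (fg/bg x hit/no-hit) gets a one-sided exact test for foreground
    over-representation and rows are Benjamini-Hochberg adjusted across
    motifs, ranked by adjusted p then descending odds ratio.  ``enriched``
    marks adjusted p <= alpha.
    """
    if not fg or not bg:
        raise ValueError("foreground and background sets must be non-empty")
    shared = set(fg) & set(bg)
    if shared:
        raise ValueError(f"foreground and background share sequence ids: {sorted(shared)[:5]}")
    rows = []
    for pwm in pwms:
        fg_hits = sum(1 for s in fg.values() if pwm_scan(s, pwm, both_strands) > 0)
        bg_hits = sum(1 for s in bg.values() if pwm_scan(s, pwm, both_strands) > 0)
        table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append((pwm.motif_id, fg_hits, len(fg), bg_hits, len(bg), odds, p))
    out = pd.DataFrame(
        rows, columns=["motif_id", "fg_hits", "fg_total", "bg_hits", "bg_total", "odds_ratio", "p_value"]
    )
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["adjusted_p"] <= alpha
    out = out.sort_values(
        ["adjusted_p", "odds_ratio"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return out


def topk_overlap(rowsets: Mapping[str, pd.DataFrame], k: int = 50, alpha: float = 0.05) -> dict:
    """Top-k overlap summary across named enrichment tables.

    Takes the top-k enriched motifs (adjusted p <= alpha, in table order)
    of each set; reports the pairwise intersection counts and the motifs
    unique to each set.
    """
    tops: dict[str, list[str]] = {}
    for name, rows in rowsets.items():
        sel = rows[rows["adjusted_p"] <= alpha]
        tops[name] = list(sel["motif_id"].head(k))
    names = list(tops)
    overlap = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            overlap.loc[a, b] = len(set(tops[a]) & set(tops[b]))
    unique = {
        a: sorted(set(tops[a]) - set().union(*(set(tops[b]) for b in names if b != a)) )
        if len(names) > 1
        else sorted(tops[a])
        for a in names
    }
    return {"top": tops, "pairwise": overlap, "unique": unique}
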