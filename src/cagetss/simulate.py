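"""Synthetic CAGE study generator with planted ground truth.

The generator emulates the shape of a developmental CAGE study: a random
genome with CpG islands, ~300 planted promoters that are either sharp
(narrow, TATA-box at -31..-26) or broad (wide CpG-island distributions), and
26 sample libraries -- a 16-stage developmental series plus 10 cell/tissue
libraries.  Expression programs are housekeeping (stable across samples),
early/late ramps (exponential in stage), group-specific (high in one
cell/tissue group only) or silent.  Per-sample tag counts at each promoter
are Poisson at the analytic mean (expected TPM x library size / 1e6), with
tag positions multinomial from the promoter's emission profile; a uniform
background (default 2% of the library) exercises the permissive/robust
filters.  Every planted promoter is recorded in a truth table keyed by
promoter id, the anchor for all downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    PipelineConfig,
    SampleLibrary,
    check_unique_samples,
    default_samples,
)
from .ctss import CTSS_COLUMNS, CTSSTable

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: spread of the per-sample log2 expression offsets of housekeeping programs;
#: kept well inside the sigma(log2 TPM) < 1 housekeeping rule.
HK_JITTER_SD_LOG2 = 0.25

#: fraction of a broad promoter's emission concentrated on its anchor CTSS,
#: so broad promoters keep an identifiable representative position while no
#: single position exceeds 20% of the mass.
BROAD_ANCHOR_SPIKE = 0.12

PROGRAM_KINDS = ("housekeeping", "early_specific", "late_specific", "group_specific", "silent")

DEFAULT_N_PER_CLASS = {
    "housekeeping": 100,
    "early_specific": 30,
    "late_specific": 30,
    "group_specific": 100,
    "silent": 40,
}


@dataclass(frozen=True)
class ExpressionProgram:
    """How a promoter's expected TPM varies over the sample series.

    ``fold_range`` is the program's dynamic range: the on/off ratio for
    group-specific programs and the total range of the stage ramp for
    early/late programs.  ``jitter_sd_log2`` only applies to housekeeping
    programs.
    """

    kind: str
    base_tpm: float
    fold_range: float = 120.0
    target_group: str | None = None
    jitter_sd_log2: float = HK_JITTER_SD_LOG2

    def __post_init__(self):
        if self.kind not in PROGRAM_KINDS:
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.kind == "group_specific" and self.target_group is None:
            raise ValueError("group_specific programs need a target_group")


@dataclass(frozen=True)
class PromoterSpec:
    promoter_id: str
    chrom: str
    anchor_pos: int
    strand: str
    shape_class: str  # sharp | broad
    width_bp: int
    program: ExpressionProgram
    has_tata: bool = False
    has_cpg: bool = False

    def emission(self) -> tuple[np.ndarray, np.ndarray]:
        """Offsets (relative to anchor, strand-aware sign-free) and their
        emission probabilities."""
        if self.shape_class == "sharp":
            offsets = np.array([0, -1, 1, -2, 2][: self.width_bp])
            probs = np.array([0.86, 0.05, 0.05, 0.02, 0.02][: self.width_bp])
        else:
            w = self.width_bp
            lo = -(w // 2)
            offsets = np.arange(lo, lo + w)
            sigma = w / 5.0
            gauss = np.exp(-(offsets.astype(float) ** 2) / (2 * sigma**2))
            probs = (1.0 - BROAD_ANCHOR_SPIKE) * gauss / gauss.sum()
            probs[offsets == 0] += BROAD_ANCHOR_SPIKE
        probs = probs / probs.sum()
        if self.shape_class == "sharp":
            assert probs[np.abs(offsets) <= 5].sum() >= 0.8
        else:
            assert probs.max() <= 0.20 + 1e-9
        return offsets, probs


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int,
    length_bp: int,
    gc: float,
    seed: int,
    n_islands_per_chrom: int | None = None,
    island_len: int = 1000,
    island_gc: float = 0.72,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Random i.i.d. genome at the requested GC, with CpG islands.

    Islands are evenly spaced intervals re-drawn at ``island_gc`` (i.i.d.
    composition keeps their observed/expected CpG ratio near 1, comfortably
    above the 0.6 island rule).  Returns ``(sequences, islands)`` where
    sequences maps chromosome name -> mutable byte array and islands is a
    BED-like frame (chrom, start, end).
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must lie in (0, 1), got {gc}")
    if length_bp < 10_000:
        raise ValueError(f"chromosome length must be >= 10 kb, got {length_bp}")
    if n_islands_per_chrom is None:
        n_islands_per_chrom = length_bp // 50_000
    rng = np.random.default_rng(seed)
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_island = np.array([(1 - island_gc) / 2, island_gc / 2, island_gc / 2, (1 - island_gc) / 2])
    genome: dict[str, np.ndarray] = {}
    island_rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = rng.choice(BASES, size=length_bp, p=p_bg)
        if n_islands_per_chrom > 0:
            slot = length_bp // (n_islands_per_chrom + 1)
            if slot < island_len + 2000:
                raise ValueError(
                    f"chromosome of {length_bp} bp too short for {n_islands_per_chrom} "
                    f"islands of {island_len} bp at >= 2 kb spacing"
                )
            for k in range(n_islands_per_chrom):
                start = (k + 1) * slot - island_len // 2
                end = start + island_len
                seq[start:end] = rng.choice(BASES, size=island_len, p=p_island)
                island_rows.append((chrom, start, end))
        genome[chrom] = seq
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return genome, islands


def genome_strings(genome: Mapping[str, np.ndarray]) -> dict[str, str]:
    """Immutable string view of a mutable genome (for slicing/windows)."""
    return {chrom: arr.tobytes().decode("ascii") for chrom, arr in genome.items()}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Promoter planting
# ---------------------------------------------------------------------------

def plant_promoters(
    genome: Mapping[str, np.ndarray],
    islands: pd.DataFrame,
    n_per_class: Mapping[str, int],
    config: PipelineConfig,
    seed: int,
    group_targets: Sequence[str] = ("extraembryonic", "limb", "aortic_smc", "hepatocyte", "msc"),
    min_spacing: int = 2000,
) -> list[PromoterSpec]:
    """Place promoters on the genome, editing it in place.

    Broad promoters sit at CpG-island centres (``has_cpg``); sharp promoters
    get a TATAAA box written at -31..-26 relative to the anchor,
    strand-aware (``has_tata``).  Anchors keep >= ``min_spacing`` bp from
    each other (on either strand).  Raises when the genome cannot host the
    requested count at that spacing.
    """
    unknown = set(n_per_class) - set(PROGRAM_KINDS)
    if unknown:
        raise ValueError(f"unknown promoter classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    counts = {k: int(n_per_class.get(k, 0)) for k in PROGRAM_KINDS}
    n_total = sum(counts.values())
    genome_len = sum(len(s) for s in genome.values())
    if n_total * min_spacing + 1000 > genome_len:
        raise ValueError(
            f"genome of {genome_len} bp cannot host {n_total} promoters at "
            f"{min_spacing} bp spacing; need >= {n_total * min_spacing + 1000} bp"
        )

    n_broad_hk = int(round(counts["housekeeping"] * 0.6))
    if n_broad_hk > len(islands):
        raise ValueError(
            f"{n_broad_hk} CpG-island promoters requested but only {len(islands)} islands available"
        )
    island_order = rng.permutation(len(islands))

    chroms = sorted(genome)
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    island_iv = [
        (r.chrom, r.start, r.end) for r in islands.itertuples(index=False)
    ]

    def in_island(chrom: str, pos: int, margin: int = 500) -> bool:
        return any(c == chrom and s - margin <= pos < e + margin for c, s, e in island_iv)

    def place_random(chrom_rng) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chroms[int(chrom_rng.integers(len(chroms)))]
            pos = int(chrom_rng.integers(600, len(genome[chrom]) - 600))
            if in_island(chrom, pos):
                continue
            if all(abs(pos - q) >= min_spacing for q in taken[chrom]):
                taken[chrom].append(pos)
                return chrom, pos
        raise ValueError("could not place promoter: genome too crowded for requested spacing")

    specs: list[PromoterSpec] = []
    pid = 0
    island_cursor = 0

    def next_island() -> tuple[str, int]:
        nonlocal island_cursor
        while island_cursor < len(island_order):
            row = islands.iloc[island_order[island_cursor]]
            island_cursor += 1
            centre = int((row.start + row.end) // 2)
            if all(abs(centre - q) >= min_spacing for q in taken[row.chrom]):
                taken[row.chrom].append(centre)
                return str(row.chrom), centre
        raise ValueError("ran out of CpG islands with free spacing for broad promoters")

    def add(shape: str, program: ExpressionProgram, cpg: bool) -> None:
        nonlocal pid
        strand = "+" if rng.random() < 0.5 else "-"
        if cpg:
            chrom, anchor = next_island()
            width = int(rng.integers(30, 121))
            spec = PromoterSpec(
                f"prom{pid:04d}", chrom, anchor, strand, "broad", width, program, has_cpg=True
            )
        else:
            chrom, anchor = place_random(rng)
            if shape == "sharp":
                width = int(rng.integers(1, 6))
                has_tata = program.kind != "silent"
                spec = PromoterSpec(
                    f"prom{pid:04d}", chrom, anchor, strand, "sharp", width, program, has_tata=has_tata
                )
                if has_tata:
                    _write_tata(genome[chrom], anchor, strand)
            else:
                width = int(rng.integers(30, 121))
                spec = PromoterSpec(f"prom{pid:04d}", chrom, anchor, strand, "broad", width, program)
        pid += 1
        specs.append(spec)

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for i in range(counts["housekeeping"]):
        if i < n_broad_hk:
            program = ExpressionProgram("housekeeping", log_uniform(150, 800))
            add("broad", program, cpg=True)
        else:
            program = ExpressionProgram("housekeeping", log_uniform(40, 400))
            add("sharp", program, cpg=False)
    for kind in ("early_specific", "late_specific"):
        for _ in range(counts[kind]):
            add("sharp", ExpressionProgram(kind, log_uniform(30, 120), fold_range=4096.0), cpg=False)
    for i in range(counts["group_specific"]):
        target = group_targets[i % len(group_targets)]
        add(
            "sharp",
            ExpressionProgram("group_specific", log_uniform(30, 120), fold_range=120.0, target_group=target),
            cpg=False,
        )
    for _ in range(counts["silent"]):
        add("sharp", ExpressionProgram("silent", 0.0), cpg=False)
    return specs


def _write_tata(seq: np.ndarray, anchor: int, strand: str) -> None:
    """TATAAA at transcript coordinates -31..-26 relative to the anchor."""
    tata = np.frombuffer(b"TATAAA", dtype="S1")
    if strand == "+":
        seq[anchor - 31 : anchor - 25] = tata
    else:
        # genomic forward strand carries the reverse complement
        seq[anchor + 26 : anchor + 32] = np.frombuffer(b"TTTATA", dtype="S1")


# ---------------------------------------------------------------------------
# Expected expression
# ---------------------------------------------------------------------------

def expected_tpm_matrix(
    specs: Sequence[PromoterSpec], samples: Sequence[SampleLibrary], seed: int
) -> pd.DataFrame:
    """Per-promoter, per-sample expected TPM implied by the programs."""
    check_unique_samples(samples)
    stages = np.array([-1 if s.stage is None else s.stage for s in samples])
    max_stage = stages.max() if (stages >= 0).any() else 0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    rows = []
    for spec, child in zip(specs, children):
        prog = spec.program
        if prog.kind == "silent":
            rows.append(np.zeros(len(samples)))
            continue
        if prog.kind == "housekeeping":
            rng = np.random.default_rng(child)
            offsets = rng.standard_normal(len(samples))
            offsets -= offsets.mean()
            sd = offsets.std()
            if sd > 0 and prog.jitter_sd_log2 > 0:
                offsets *= prog.jitter_sd_log2 / sd
            else:
                offsets[:] = 0.0
            rows.append(prog.base_tpm * np.exp2(offsets))
            continue
        if prog.kind in ("early_specific", "late_specific"):
            decay_per_stage = np.log2(prog.fold_range) / max(max_stage, 1)
            vals = np.empty(len(samples))
            for i, s in enumerate(samples):
                if s.stage is None:
                    vals[i] = prog.base_tpm / prog.fold_range
                else:
                    t = s.stage if prog.kind == "early_specific" else max_stage - s.stage
                    vals[i] = prog.base_tpm * 2.0 ** (-decay_per_stage * t)
            rows.append(vals)
            continue
        # group_specific
        vals = np.array(
            [prog.base_tpm if s.group == prog.target_group else prog.base_tpm / prog.fold_range for s in samples]
        )
        rows.append(vals)
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(samples))),
        index=[s.promoter_id for s in specs],
        columns=[s.sample_id for s in samples],
    )


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def simulate_ctss(
    specs: Sequence[PromoterSpec],
    samples: Sequence[SampleLibrary],
    chrom_sizes: Mapping[str, int],
    config: PipelineConfig,
    seed: int,
) -> tuple[dict[str, CTSSTable], pd.DataFrame]:
    """Draw per-sample CTSS counts and the truth table.

    Each promoter's tag total in a sample is Poisson with mean
    expected TPM x total_mapped_tags / 1e6; tags land on positions by a
    multinomial draw from the promoter's emission.  Background noise of
    round(background_rate x total_mapped_tags) tags is scattered uniformly
    over both strands of the genome.  Counts are non-negative integers and
    their sum never exceeds the library total.
    """
    expected = expected_tpm_matrix(specs, samples, seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total_len = int(offsets[-1])
    chrom_index = {c: i for i, c in enumerate(chroms)}

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(len(samples) + 1)
    tables: dict[str, CTSSTable] = {}
    for si, sample in enumerate(samples):
        rng = np.random.default_rng(ss[si])
        idx_parts, cnt_parts = [], []
        for spec in specs:
            mean = expected.at[spec.promoter_id, sample.sample_id] * sample.total_mapped_tags / 1e6
            if mean <= 0:
                continue
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            off, probs = spec.emission()
            draws = rng.multinomial(n, probs)
            nz = draws > 0
            pos = spec.anchor_pos + off[nz]
            pos = np.clip(pos, 0, chrom_sizes[spec.chrom] - 1)
            cell = offsets[chrom_index[spec.chrom]] + pos
            if spec.strand == "-":
                cell = cell + total_len
            idx_parts.append(cell)
            cnt_parts.append(draws[nz])
        n_bg = int(round(config.background_rate * sample.total_mapped_tags))
        if n_bg:
            bg = rng.integers(0, 2 * total_len, size=n_bg)
            bg_idx, bg_cnt = np.unique(bg, return_counts=True)
            idx_parts.append(bg_idx)
            cnt_parts.append(bg_cnt)
        if idx_parts:
            idx = np.concatenate(idx_parts)
            cnt = np.concatenate(cnt_parts)
            order = np.argsort(idx, kind="stable")
            idx, cnt = idx[order], cnt[order]
            uniq, boundaries = np.unique(idx, return_index=True)
            sums = np.add.reduceat(cnt, boundaries)
        else:
            uniq = np.empty(0, dtype=np.int64)
            sums = np.empty(0, dtype=np.int64)
        strand = np.where(uniq >= total_len, "-", "+")
        pos_lin = np.where(uniq >= total_len, uniq - total_len, uniq)
        ci = np.searchsorted(offsets, pos_lin, side="right") - 1
        df = pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "pos": pos_lin - offsets[ci],
                "strand": strand,
                "count": sums.astype(np.int64),
            },
            columns=CTSS_COLUMNS,
        )
        tables[sample.sample_id] = CTSSTable(df, sample)

    truth = _truth_table(specs, samples, expected)
    return tables, truth


def _truth_table(
    specs: Sequence[PromoterSpec], samples: Sequence[SampleLibrary], expected: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for spec in specs:
        e = expected.loc[spec.promoter_id]
        pooled_tags = float(
            sum(e[s.sample_id] * s.total_mapped_tags / 1e6 for s in samples)
        )
        rows.append(
            {
                "promoter_id": spec.promoter_id,
                "chrom": spec.chrom,
                "anchor_pos": spec.anchor_pos,
                "strand": spec.strand,
                "shape_class": spec.shape_class,
                "width_bp": spec.width_bp,
                "program": spec.program.kind,
                "target_group": spec.program.target_group or "",
                "base_tpm": spec.program.base_tpm,
                "has_tata": spec.has_tata,
                "has_cpg": spec.has_cpg,
                "expected_pooled_tags": pooled_tags,
            }
        )
    truth = pd.DataFrame(rows)
    if len(truth):
        _check_spacing(truth)
        truth = truth.join(expected.add_prefix("tpm_"), on="promoter_id")
    return truth


def _check_spacing(truth: pd.DataFrame, min_spacing: int = 2000) -> None:
    for (_, _), grp in truth.groupby(["chrom", "strand"]):
        pos = np.sort(grp["anchor_pos"].to_numpy())
        if len(pos) > 1 and np.diff(pos).min() < min_spacing:
            raise ValueError("planted anchors closer than the 2 kb spacing invariant")


# ---------------------------------------------------------------------------
# One-call study generation
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    genome: dict[str, np.ndarray]
    sequences: dict[str, str]
    islands: pd.DataFrame
    specs: list[PromoterSpec]
    samples: list[SampleLibrary]
    truth: pd.DataFrame
    tables: dict[str, CTSSTable]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_study(
    config: PipelineConfig | None = None,
    samples: Sequence[SampleLibrary] | None = None,
    n_per_class: Mapping[str, int] | None = None,
    n_chrom: int = 2,
    chrom_length: int = 2_000_000,
    gc: float = 0.45,
    seed: int = 0,
) -> Simulation:
    """Generate genome, promoters and per-sample CTSS tables in one call."""
    config = config or PipelineConfig()
    samples = list(samples) if samples is not None else default_samples()
    n_per_class = dict(n_per_class) if n_per_class is not None else dict(DEFAULT_N_PER_CLASS)
    ss = np.random.SeedSequence(seed).spawn(3)
    genome, islands = generate_genome(n_chrom, chrom_length, gc, ss[0])
    specs = plant_promoters(genome, islands, n_per_class, config, ss[1])
    tables, truth = simulate_ctss(specs, samples, {c: len(s) for c, s in genome.items()}, config, ss[2])
    return Simulation(genome, genome_strings(genome), islands, specs, list(samples), truth, tables)
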