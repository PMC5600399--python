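"""End-to-end study driver: simulate (or load) CTSS, call peaks, annotate,
profile, classify and test motifs in one pass."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import motifs as motifs_mod
from . import profiles as profiles_mod
from . import specificity as spec_mod
from .config import DEVELOPMENTAL_GROUPS, PipelineConfig, SampleLibrary, group_members
from .ctss import CTSSTable, pool_counts
from .peaks import PeakSet, call_peaks
from .simulate import Simulation, simulate_study

log = logging.getLogger("cagetss")


@dataclass
class StudyResult:
    """Everything one pipeline run produces."""

    config: PipelineConfig
    samples: list[SampleLibrary]
    pooled: pd.DataFrame
    peakset: PeakSet
    shapes: pd.DataFrame
    annotations: pd.DataFrame | None
    superclusters: pd.DataFrame
    tiers: pd.Series
    housekeeping: pd.DataFrame
    enriched: dict[str, pd.Index]
    pcoa_coords: pd.DataFrame
    pcoa_eigvals: np.ndarray
    motif_tables: dict[str, pd.DataFrame]
    simulation: Simulation | None = None

    @property
    def robust(self) -> pd.DataFrame:
        return self.peakset.peaks[self.peakset.peaks["tier"] == "robust"]


def analyze(
    tables: Mapping[str, CTSSTable],
    samples: Sequence[SampleLibrary],
    config: PipelineConfig,
    genome=None,
    genes: pd.DataFrame | None = None,
    interval_sets: dict[str, pd.DataFrame] | None = None,
    pwms: Sequence[motifs_mod.PWM] | None = None,
    enrichment_reference: str = "mean",
    simulation: Simulation | None = None,
) -> StudyResult:
    """Run every analysis stage on a set of per-sample CTSS tables."""
    samples = list(samples)
    log.info(
        "thresholds: gap=%d bp, permissive>=%d tags, robust>=%d tags & >=%g TPM, "
        "expressed>%g TPM, specific>%g TPM @ %gx, housekeeping>%g TPM sd<%g, SI boundary %g",
        config.gap_bp,
        config.permissive_min_count,
        config.robust_min_count,
        config.robust_min_tpm,
        config.expressed_tpm,
        config.specific_tpm,
        config.specific_fold,
        config.housekeeping_min_tpm,
        config.housekeeping_max_sd_log2,
        config.si_boundary,
    )
    pooled = pool_counts([tables[s.sample_id] for s in samples])
    peakset = call_peaks(pooled, samples, config)
    log.info(
        "called %d permissive peaks, %d robust",
        len(peakset.peaks),
        int((peakset.peaks["tier"] == "robust").sum()),
    )
    shapes = profiles_mod.peak_shapes(peakset, boundary=config.si_boundary)

    annotations = None
    if genes is not None or interval_sets or genome is not None:
        annotations = annotate_mod.annotate_peaks(
            peakset.peaks,
            genes,
            genome,
            interval_sets=interval_sets,
            window_bp=config.annotation_window_bp,
        )

    robust_mask = peakset.peaks["tier"] == "robust"
    robust_ids = peakset.peaks.loc[robust_mask, "peak_id"]
    robust_tpm = peakset.tpm.loc[robust_ids]

    superclusters = profiles_mod.super_clusters(
        peakset.peaks[robust_mask],
        peakset.tpm,
        min_tpm=config.robust_min_tpm,
        gap=config.supercluster_gap_bp,
    )
    tiers = spec_mod.ubiquity_tiers(robust_tpm)
    housekeeping, _ = spec_mod.housekeeping_set(
        robust_tpm,
        min_tpm=config.housekeeping_min_tpm,
        max_sd_log2=config.housekeeping_max_sd_log2,
    )
    groups = group_members(samples)
    enriched = spec_mod.group_enriched(
        robust_tpm,
        groups,
        min_tpm=config.specific_tpm,
        fold=config.specific_fold,
        reference=enrichment_reference,
    )
    dev_ids = [s.sample_id for s in samples if s.group in DEVELOPMENTAL_GROUPS and s.stage is not None]
    pcoa_input = robust_tpm.loc[:, dev_ids] if len(dev_ids) >= 3 else robust_tpm
    coords, eigvals = spec_mod.pcoa(pcoa_input)

    motif_tables: dict[str, pd.DataFrame] = {}
    if genome is not None and pwms:
        windows = motifs_mod.promoter_windows(
            peakset.peaks[robust_mask], genome, window=config.motif_window
        )
        shape_of = shapes.set_index("peak_id")["shape_class"]
        seqs = windows.set_index("peak_id")["sequence"]
        sharp_ids = [p for p in robust_ids if shape_of.get(p) == "sharp"]
        broad_ids = [p for p in robust_ids if shape_of.get(p) == "broad"]
        if sharp_ids and broad_ids:
            sharp_seqs = {p: seqs[p] for p in sharp_ids}
            broad_seqs = {p: seqs[p] for p in broad_ids}
            motif_tables["sharp_vs_broad"] = motifs_mod.motif_enrichment(sharp_seqs, broad_seqs, pwms)
            motif_tables["broad_vs_sharp"] = motifs_mod.motif_enrichment(broad_seqs, sharp_seqs, pwms)

    return StudyResult(
        config=config,
        samples=samples,
        pooled=pooled,
        peakset=peakset,
        shapes=shapes,
        annotations=annotations,
        superclusters=superclusters,
        tiers=tiers,
        housekeeping=housekeeping,
        enriched=enriched,
        pcoa_coords=coords,
        pcoa_eigvals=eigvals,
        motif_tables=motif_tables,
        simulation=simulation,
    )


def run_synthetic_study(
    config: PipelineConfig | None = None,
    seed: int = 0,
    samples: Sequence[SampleLibrary] | None = None,
    n_per_class: Mapping[str, int] | None = None,
    with_motifs: bool = True,
    enrichment_reference: str = "mean",
) -> StudyResult:
    """Simulate a study and run the full analysis on it."""
    config = config or PipelineConfig()
    sim = simulate_study(config=config, samples=samples, n_per_class=n_per_class, seed=seed)
    pwms = motifs_mod.bundled_test_pwms() if with_motifs else None
    return analyze(
        sim.tables,
        sim.samples,
        config,
        genome=sim.sequences,
        interval_sets={"cpg": sim.islands},
        pwms=pwms,
        enrichment_reference=enrichment_reference,
        simulation=sim,
    )
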