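"""Run-wide configuration and sample metadata.

Every numeric threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`, so a run is fully described by one flat document
(YAML on disk) plus a seed.  Sample libraries carry the per-library tag
totals that anchor tags-per-million normalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

#: All recognised sample groups.  The first four are the ordered phases of the
#: developmental series; the rest are cell/tissue libraries.
GROUPS = (
    "early",
    "mid",
    "mid_late",
    "late",
    "extraembryonic",
    "limb",
    "aortic_smc",
    "hepatocyte",
    "msc",
    "other",
)

DEVELOPMENTAL_GROUPS = ("early", "mid", "mid_late", "late")


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults reproduce the study conditions: tag clusters are built with a
    20 bp single-linkage gap and merged into super clusters at 100 bp; peaks
    are kept when one CTSS reaches 3 tags in one sample (permissive) and
    called robust at >=11 tags and >=1 TPM on the same CTSS/sample; genes are
    associated within 500 bp; promoters are "expressed" above 3 TPM,
    group-specific above 10 TPM and 10-fold enrichment, housekeeping above
    10 TPM everywhere with sigma(log2 TPM) < 1; the sharp/broad shape
    boundary sits at SI = -1; motif windows span (-300, +100) around the
    representative TSS.
    """

    gap_bp: int = 20
    supercluster_gap_bp: int = 100
    annotation_window_bp: int = 500
    permissive_min_count: int = 3
    robust_min_count: int = 11
    robust_min_tpm: float = 1.0
    expressed_tpm: float = 3.0
    specific_tpm: float = 10.0
    specific_fold: float = 10.0
    housekeeping_min_tpm: float = 10.0
    housekeeping_max_sd_log2: float = 1.0
    si_boundary: float = -1.0
    motif_window: tuple[int, int] = (-300, 100)
    # peak splitting (deterministic decomposition variant)
    max_unsplit_bp: int = 49
    smooth_sigma: float = 5.0
    valley_frac: float = 0.1
    # simulation
    background_rate: float = 0.02
    # scoring
    enrichment_pseudocount_tpm: float = 0.1
    pwm_threshold_frac: float = 0.8
    pwm_pseudocount: float = 0.01
    min_quality: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive_ints = (
            "gap_bp",
            "supercluster_gap_bp",
            "annotation_window_bp",
            "permissive_min_count",
            "robust_min_count",
            "max_unsplit_bp",
        )
        for name in positive_ints:
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ConfigError(f"{name} must be a strictly positive integer, got {value!r}")
        positive_floats = (
            "robust_min_tpm",
            "expressed_tpm",
            "specific_tpm",
            "specific_fold",
            "housekeeping_min_tpm",
            "housekeeping_max_sd_log2",
            "smooth_sigma",
        )
        for name in positive_floats:
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        up, down = self.motif_window
        if not (up <= 0 <= down):
            raise ConfigError(
                f"motif_window must bracket the TSS (upstream <= 0 <= downstream), got {self.motif_window!r}"
            )
        if not 0 <= self.background_rate < 1:
            raise ConfigError(f"background_rate must lie in [0, 1), got {self.background_rate!r}")
        if not 0 < self.valley_frac < 1:
            raise ConfigError(f"valley_frac must lie in (0, 1), got {self.valley_frac!r}")
        if not 0 < self.pwm_threshold_frac <= 1:
            raise ConfigError(f"pwm_threshold_frac must lie in (0, 1], got {self.pwm_threshold_frac!r}")

    def replace(self, **updates) -> "PipelineConfig":
        return dataclasses.replace(self, **updates)

    # -- flat key/value round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_window"] = list(self.motif_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "motif_window" in data:
            data = dict(data)
            data["motif_window"] = tuple(data["motif_window"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} must hold a flat mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class SampleLibrary:
    """One CAGE library: identity, biological group and sequencing depth.

    ``stage`` orders the developmental series (0 = earliest); it is ``None``
    for cell/tissue libraries.
    """

    sample_id: str
    group: str
    total_mapped_tags: int
    stage: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.total_mapped_tags <= 0:
            raise ConfigError(f"total_mapped_tags must be > 0 for sample {self.sample_id!r}")


def check_unique_samples(samples: Sequence[SampleLibrary]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate sample ids: {dupes}")


def default_samples(total_tags: int = 1_000_000) -> list[SampleLibrary]:
    """The default 26-library design: a 16-stage developmental series split
    into early/mid/mid-late/late phases, plus 10 cell and tissue libraries."""
    phase_of_stage = ["early"] * 5 + ["mid"] * 4 + ["mid_late"] * 4 + ["late"] * 3
    samples = [
        SampleLibrary(f"dev{i:02d}", phase_of_stage[i], total_tags, stage=i) for i in range(16)
    ]
    cells = [
        ("extraembryonic", 2),
        ("limb", 2),
        ("aortic_smc", 3),
        ("hepatocyte", 2),
        ("msc", 1),
    ]
    for group, n in cells:
        for j in range(n):
            samples.append(SampleLibrary(f"{group}_{j + 1}", group, total_tags))
    check_unique_samples(samples)
    return samples


def group_members(samples: Iterable[SampleLibrary]) -> dict[str, list[str]]:
    """Group label -> member sample ids, in sample order (disjoint by construction)."""
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(s.group, []).append(s.sample_id)
    return out


def samples_to_frame(samples: Sequence[SampleLibrary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "total_mapped_tags": [s.total_mapped_tags for s in samples],
            "stage": [s.stage if s.stage is not None else -1 for s in samples],
        }
    )


def frame_to_samples(df: pd.DataFrame) -> list[SampleLibrary]:
    samples = [
        SampleLibrary(
            str(r.sample_id),
            str(r.group),
            int(r.total_mapped_tags),
            stage=None if int(r.stage) < 0 else int(r.stage),
        )
        for r in df.itertuples()
    ]
    check_unique_samples(samples)
    return samples
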