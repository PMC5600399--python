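import numpy as np
import pandas as pd
import pytest

from cagetss.pipeline import run_synthetic_study

#: seed of the shared synthetic study used by the recovery tests
STUDY_SEED = 0


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (26 x 1M-tag libraries, ~300 planted
    promoters) analysed end to end; shared across recovery tests."""
    return run_synthetic_study(seed=STUDY_SEED)


def match_truth_to_robust(result):
    """For every planted promoter, the nearest robust peak representative on
    the same chromosome/strand: promoter_id -> (peak_id, |rep - anchor|)."""
    peaks = result.peakset.peaks
    robust = peaks[peaks["tier"] == "robust"]
    out = {}
    for r in result.simulation.truth.itertuples():
        cand = robust[(robust["chrom"] == r.chrom) & (robust["strand"] == r.strand)]
        if len(cand) == 0:
            out[r.promoter_id] = (None, np.inf)
            continue
        dist = (cand["representative_pos"] - r.anchor_pos).abs()
        i = dist.idxmin()
        out[r.promoter_id] = (cand.loc[i, "peak_id"], int(dist.loc[i]))
    return out


def expected_enrichment_group(truth: pd.DataFrame) -> dict[str, str]:
    """Planted promoter -> the sample group it should be flagged enriched in
    (group-specific targets plus the early/late ramp programs)."""
    out = {}
    for r in truth.itertuples():
        if r.program == "group_specific":
            out[r.promoter_id] = r.target_group
        elif r.program == "early_specific":
            out[r.promoter_id] = "early"
        elif r.program == "late_specific":
            out[r.promoter_id] = "late"
    return out
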