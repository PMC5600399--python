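import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cagetss.specificity import (
    classical_mds,
    enrichment_score,
    expressed_calls,
    expression_stats,
    group_enriched,
    housekeeping_set,
    pcoa,
    ubiquity_tiers,
)


def matrix(rows, columns=None):
    columns = columns or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).astype(float)


class TestExpressedCalls:
    def test_strictly_greater_than_cutoff(self):
        m = matrix({"p1": [3.1, 3.0, 0.0]})
        assert expressed_calls(m).iloc[0].tolist() == [True, False, False]


class TestEnrichmentScore:
    def test_tenfold_over_reference(self):
        m = matrix({"p1": [100.0, 10.0, 10.0, 10.0, 10.0]})
        score = enrichment_score(m, reference="median", pseudocount=0.0)
        assert score.iloc[0, 0] == pytest.approx(1.0)

    def test_at_reference_is_zero(self):
        m = matrix({"p1": [10.0, 10.0, 10.0]})
        assert np.allclose(enrichment_score(m), 0.0)

    def test_all_zero_is_zero(self):
        m = matrix({"p1": [0.0, 0.0, 0.0]})
        assert np.allclose(enrichment_score(m), 0.0)


class TestGroupEnriched:
    def test_rule_arithmetic_mean_reference(self):
        # one-sample group at 50 TPM among 21 near-zero samples:
        # overall mean ~2.4, tenfold ~24 < 50 -> enriched
        values = [50.0] + [0.1] * 21
        m = matrix({"p1": values})
        groups = {"g": ["s0"], "rest": [f"s{i}" for i in range(1, 22)]}
        enr = group_enriched(m, groups, reference="mean")
        assert list(enr["g"]) == ["p1"]
        assert list(enr["rest"]) == []

    def test_fold_clause_blocks(self):
        # group mean 50 but tenfold the overall mean (260) blocks enrichment
        m = matrix({"p1": [50.0, 50.0, 2.0, 2.0]})
        enr = group_enriched(m, {"g": ["s0", "s1"]}, reference="mean")
        assert list(enr["g"]) == []

    def test_cutoff_clause_blocks(self):
        values = [8.0] + [0.0] * 21
        m = matrix({"p1": values})
        enr = group_enriched(m, {"g": ["s0"]}, reference="mean")
        assert list(enr["g"]) == []

    def test_median_reference_variant(self):
        values = [50.0, 50.0, 50.0] + [0.5] * 23
        m = matrix({"p1": values})
        groups = {"g": ["s0", "s1", "s2"]}
        # mean reference cannot flag a 3-of-26 group at 10-fold ...
        assert list(group_enriched(m, groups, reference="mean")["g"]) == []
        # ... the median reference can
        assert list(group_enriched(m, groups, reference="median")["g"]) == ["p1"]

    def test_unknown_member_rejected(self):
        m = matrix({"p1": [1.0, 2.0]})
        with pytest.raises(KeyError):
            group_enriched(m, {"g": ["nope"]})


class TestHousekeeping:
    def test_constant_profile_qualifies(self):
        m = matrix({"p1": [50.0] * 26})
        peaks, _ = housekeeping_set(m)
        assert list(peaks.index) == ["p1"]
        assert peaks.iloc[0]["sd_log2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_low_sample_disqualifies(self):
        m = matrix({"p1": [50.0] * 25 + [5.0]})
        peaks, _ = housekeeping_set(m)
        assert len(peaks) == 0

    def test_alternating_16_64_disqualified_by_sd(self):
        # log2 alternates 4/6: sample sd over 26 values is ~1.02 > 1
        m = matrix({"p1": [16.0, 64.0] * 13})
        peaks, _ = housekeeping_set(m)
        assert len(peaks) == 0

    def test_gene_collapse(self):
        m = matrix({"p1": [50.0] * 4, "p2": [40.0] * 4, "p3": [1.0] * 4})
        ann = pd.DataFrame({"peak_id": ["p1", "p2", "p3"], "gene_id": ["gA", "gA", "gB"]})
        peaks, genes = housekeeping_set(m, annotations=ann)
        assert list(genes) == ["gA"]

    def test_ranked_by_stability(self):
        m = matrix({"wobbly": [20.0, 40.0] * 13, "steady": [30.0] * 26})
        peaks, _ = housekeeping_set(m)
        assert list(peaks.index) == ["steady", "wobbly"]


class TestUbiquityTiers:
    def test_rule_arithmetic(self):
        m = matrix(
            {
                "extreme": [350.0] * 25 + [12000.0],  # min 350, mean >700
                "high_only": [350.0] * 26,  # mean 350 < 700
                "ubiquitous": [5.0] * 26,
                "none": [2.0] * 26,
            }
        )
        tiers = ubiquity_tiers(m)
        assert tiers["extreme"] == "extreme"
        assert tiers["high_only"] == "high"
        assert tiers["ubiquitous"] == "ubiquitous"
        assert tiers["none"] == "none"

    def test_nesting(self, study):
        robust = study.peakset.peaks[study.peakset.peaks["tier"] == "robust"]
        tpm = study.peakset.tpm.loc[robust["peak_id"]]
        tiers = ubiquity_tiers(tpm)
        mn = tpm.min(axis=1)
        assert (mn[tiers == "extreme"] > 100).all()
        assert (mn[tiers == "high"] > 3).all()
        hk, _ = housekeeping_set(tpm)
        assert (mn.loc[hk.index] > 3).all()  # housekeeping is a subset of ubiquitous


class TestPCoA:
    def test_identical_samples_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, 50)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.uniform(0, 100, 50), "d": rng.uniform(0, 100, 50)}
        )
        coords, _ = pcoa(m, distance="euclidean_log")
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_classical_mds_recovers_euclidean_distances(self):
        rng = np.random.default_rng(1)
        points = rng.uniform(-5, 5, size=(6, 2))
        d = squareform(pdist(points))
        coords, eigvals = classical_mds(d)
        recovered = squareform(pdist(coords))
        assert np.allclose(recovered, d, atol=1e-8)
        assert (np.diff(eigvals) <= 1e-9).all()  # non-increasing

    def test_all_identical_matrix_yields_zero_coordinates(self):
        m = matrix({"p1": [5.0, 5.0, 5.0], "p2": [1.0, 1.0, 1.0]})
        coords, eigvals = pcoa(m)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(0, 50, size=(40, 5)), columns=list("abcde"))
        c1, _ = pcoa(m)
        c2, _ = pcoa(m)
        assert np.allclose(c1.to_numpy(), c2.to_numpy())
        first_rows = c1.to_numpy()[0]
        assert (first_rows >= -1e-12).all()

    def test_against_skbio_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        points = rng.uniform(-3, 3, size=(7, 3))
        d = squareform(pdist(points))
        coords, eigvals = classical_mds(d)
        ref = skbio_pcoa(DistanceMatrix(d), number_of_dimensions=3)
        ref_eig = ref.eigvals.to_numpy()[:3]
        assert np.allclose(eigvals[:3], ref_eig, atol=1e-8)
        ref_coords = ref.samples.to_numpy()[:, :3]
        for k in range(3):
            a, b = coords[:, k], ref_coords[:, k]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def test_expression_stats_definitions():
    m = matrix({"p1": [1.0, 4.0, 16.0], "p2": [0.0, 2.0, 4.0]})
    stats = expression_stats(m)
    assert stats.loc["p1", "min_tpm"] == 1.0
    assert stats.loc["p1", "fold"] == 16.0
    assert stats.loc["p1", "sd_log2"] == pytest.approx(2.0)
    assert np.isnan(stats.loc["p2", "sd_log2"])  # undefined with a zero
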