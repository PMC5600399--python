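import numpy as np
import pandas as pd
import pytest

from cagetss.config import PipelineConfig, SampleLibrary, default_samples
from cagetss.simulate import (
    ExpressionProgram,
    PromoterSpec,
    expected_tpm_matrix,
    generate_genome,
    genome_strings,
    plant_promoters,
    simulate_ctss,
    simulate_study,
)

CFG = PipelineConfig()


class TestGenerateGenome:
    def test_gc_near_target(self):
        genome, _ = generate_genome(1, 100_000, 0.5, seed=11)
        seq = genome_strings(genome)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) <= 0.02

    def test_same_seed_reproduces(self):
        g1, i1 = generate_genome(1, 20_000, 0.4, seed=3)
        g2, i2 = generate_genome(1, 20_000, 0.4, seed=3)
        assert (g1["chr1"] == g2["chr1"]).all()
        assert i1.equals(i2)

    def test_n_chrom_records(self):
        genome, _ = generate_genome(2, 20_000, 0.5, seed=1)
        assert sorted(genome) == ["chr1", "chr2"]

    def test_gc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 20_000, 1.2, seed=1)

    def test_islands_are_gc_rich_with_cpg(self):
        genome, islands = generate_genome(1, 200_000, 0.45, seed=5)
        seq = genome_strings(genome)["chr1"]
        assert len(islands) > 0
        for r in islands.itertuples():
            island = seq[r.start : r.end]
            gc = (island.count("G") + island.count("C")) / len(island)
            assert gc >= 0.65
            # observed/expected CpG dinucleotides
            cg = sum(1 for i in range(len(island) - 1) if island[i : i + 2] == "CG")
            oe = cg / ((island.count("C") * island.count("G")) / len(island))
            assert oe >= 0.6


class TestPlantPromoters:
    def test_tata_written_upstream_on_plus(self):
        genome, islands = generate_genome(1, 50_000, 0.45, seed=2, n_islands_per_chrom=0)
        specs = plant_promoters(genome, islands, {"early_specific": 10}, CFG, seed=9)
        plus = [s for s in specs if s.strand == "+"]
        assert plus, "expected at least one plus-strand promoter"
        seq = genome_strings(genome)
        for s in plus:
            assert s.has_tata
            assert seq[s.chrom][s.anchor_pos - 31 : s.anchor_pos - 25] == "TATAAA"

    def test_tata_written_upstream_on_minus(self):
        genome, islands = generate_genome(1, 200_000, 0.45, seed=4)
        specs = plant_promoters(genome, islands, {"early_specific": 10}, CFG, seed=5)
        minus = [s for s in specs if s.strand == "-"]
        assert minus, "expected at least one minus-strand promoter"
        seq = genome_strings(genome)
        for s in minus:
            assert seq[s.chrom][s.anchor_pos + 26 : s.anchor_pos + 32] == "TTTATA"

    def test_broad_promoters_anchor_in_islands(self):
        genome, islands = generate_genome(1, 400_000, 0.45, seed=6)
        specs = plant_promoters(genome, islands, {"housekeeping": 8}, CFG, seed=7)
        broad = [s for s in specs if s.shape_class == "broad"]
        assert broad
        for s in broad:
            inside = (
                (islands["chrom"] == s.chrom)
                & (islands["start"] <= s.anchor_pos)
                & (s.anchor_pos < islands["end"])
            )
            assert inside.any()

    def test_zero_request_leaves_genome_unchanged(self):
        genome, islands = generate_genome(1, 20_000, 0.45, seed=2, n_islands_per_chrom=0)
        before = genome["chr1"].copy()
        specs = plant_promoters(genome, islands, {}, CFG, seed=1)
        assert specs == []
        assert (genome["chr1"] == before).all()

    def test_insufficient_space_reports_requirement(self):
        genome, islands = generate_genome(1, 20_000, 0.45, seed=2, n_islands_per_chrom=0)
        with pytest.raises(ValueError, match="need >="):
            plant_promoters(genome, islands, {"silent": 100}, CFG, seed=1)

    def test_spacing_invariant(self):
        genome, islands = generate_genome(2, 400_000, 0.45, seed=8)
        specs = plant_promoters(
            genome, islands, {"housekeeping": 20, "silent": 30, "group_specific": 30}, CFG, seed=9
        )
        df = pd.DataFrame(
            {"chrom": [s.chrom for s in specs], "strand": [s.strand for s in specs],
             "pos": [s.anchor_pos for s in specs]}
        )
        for _, grp in df.groupby(["chrom", "strand"]):
            pos = np.sort(grp["pos"].to_numpy())
            assert len(pos) < 2 or np.diff(pos).min() >= 2000


class TestEmission:
    def test_sharp_mass_concentrated_near_anchor(self):
        for width in range(1, 6):
            spec = PromoterSpec("p", "chr1", 1000, "+", "sharp", width,
                                ExpressionProgram("housekeeping", 50.0))
            off, probs = spec.emission()
            assert probs[np.abs(off) <= 5].sum() >= 0.8

    def test_broad_mass_capped_per_position(self):
        for width in (30, 60, 120):
            spec = PromoterSpec("p", "chr1", 1000, "+", "broad", width,
                                ExpressionProgram("housekeeping", 200.0))
            _, probs = spec.emission()
            assert probs.max() <= 0.20 + 1e-9
            assert probs.sum() == pytest.approx(1.0)


def _one_promoter_setup(kind="housekeeping", base=50.0, jitter=0.0):
    spec = PromoterSpec(
        "p0", "chr1", 5000, "+", "sharp", 3,
        ExpressionProgram(kind, base, jitter_sd_log2=jitter),
    )
    sample = SampleLibrary("s1", "other", 1_000_000)
    return spec, sample


class TestSimulateCtss:
    def test_tag_totals_match_analytic_mean(self):
        # expected 50 TPM in a 1M-tag library -> Poisson mean 50 per replicate
        spec, sample = _one_promoter_setup()
        cfg = CFG.replace(background_rate=0.0)
        totals = []
        for seed in range(50):
            tables, _ = simulate_ctss([spec], [sample], {"chr1": 10_000}, cfg, seed)
            totals.append(tables["s1"].total_count)
        assert abs(np.mean(totals) - 50.0) <= 3.0

    def test_silent_program_emits_nothing(self):
        spec, sample = _one_promoter_setup(kind="silent", base=0.0)
        cfg = CFG.replace(background_rate=0.0)
        tables, truth = simulate_ctss([spec], [sample], {"chr1": 10_000}, cfg, seed=1)
        assert tables["s1"].total_count == 0
        assert truth.iloc[0]["expected_pooled_tags"] == 0.0

    def test_sharp_tags_land_within_5bp(self):
        spec, sample = _one_promoter_setup(base=500.0)
        cfg = CFG.replace(background_rate=0.0)
        tables, _ = simulate_ctss([spec], [sample], {"chr1": 10_000}, cfg, seed=2)
        df = tables["s1"].df
        near = df[(df["pos"] - 5000).abs() <= 5]["count"].sum()
        assert near / df["count"].sum() >= 0.8

    def test_background_tags_budgeted_and_bounded(self):
        spec, sample = _one_promoter_setup(base=10.0)
        tables, _ = simulate_ctss([spec], [sample], {"chr1": 100_000}, CFG, seed=3)
        t = tables["s1"]
        assert t.total_count <= sample.total_mapped_tags
        # background is 2% of the library plus the promoter's ~10 tags
        assert abs(t.total_count - 0.02 * 1_000_000 - 10) < 500

    def test_seed_changes_output(self):
        spec, sample = _one_promoter_setup()
        t1, _ = simulate_ctss([spec], [sample], {"chr1": 10_000}, CFG, seed=1)
        t2, _ = simulate_ctss([spec], [sample], {"chr1": 10_000}, CFG, seed=2)
        assert not t1["s1"].df.equals(t2["s1"].df)

    def test_same_seed_reproduces(self):
        spec, sample = _one_promoter_setup()
        t1, tr1 = simulate_ctss([spec], [sample], {"chr1": 10_000}, CFG, seed=4)
        t2, tr2 = simulate_ctss([spec], [sample], {"chr1": 10_000}, CFG, seed=4)
        assert t1["s1"] == t2["s1"]
        assert tr1.equals(tr2)


class TestPrograms:
    def test_housekeeping_jitter_within_margin(self):
        samples = default_samples()
        spec = PromoterSpec("p0", "chr1", 5000, "+", "sharp", 1,
                            ExpressionProgram("housekeeping", 100.0))
        e = expected_tpm_matrix([spec], samples, seed=0).iloc[0]
        assert (e >= 2 * 10.0).all()  # twice the housekeeping TPM floor
        assert np.log2(e).std() <= 0.5

    def test_group_specific_margin_over_median(self):
        samples = default_samples()
        spec = PromoterSpec("p0", "chr1", 5000, "+", "sharp", 1,
                            ExpressionProgram("group_specific", 60.0, target_group="hepatocyte"))
        e = expected_tpm_matrix([spec], samples, seed=0).iloc[0]
        in_group = [s.sample_id for s in samples if s.group == "hepatocyte"]
        assert e[in_group].min() >= 20 * e.median()

    def test_ramps_are_monotone_in_stage(self):
        samples = default_samples()
        dev = [s.sample_id for s in samples if s.stage is not None]
        early = PromoterSpec("pe", "chr1", 5000, "+", "sharp", 1,
                             ExpressionProgram("early_specific", 60.0, fold_range=4096.0))
        late = PromoterSpec("pl", "chr1", 9000, "+", "sharp", 1,
                            ExpressionProgram("late_specific", 60.0, fold_range=4096.0))
        e = expected_tpm_matrix([early, late], samples, seed=0)
        assert (np.diff(e.loc["pe", dev]) < 0).all()
        assert (np.diff(e.loc["pl", dev]) > 0).all()


def test_study_truth_consistency():
    sim = simulate_study(
        n_per_class={"housekeeping": 4, "silent": 2},
        n_chrom=1,
        chrom_length=200_000,
        seed=5,
    )
    assert len(sim.truth) == 6
    assert set(sim.truth["program"]) == {"housekeeping", "silent"}
    # per-sample totals never exceed the library size
    for sid, table in sim.tables.items():
        assert table.total_count <= table.library.total_mapped_tags
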