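"""The synthetic cohort generator."""

import numpy as np
import pytest

from cghkit.regions import harmonize
from cghkit.synthetic import PlantedRegion, SimulationSpec, make_tracks, simulate_bac, simulate_oligo


def null_spec(**kw):
    return SimulationSpec(planted_regions=[], **kw)


class TestSpecValidation:
    def test_region_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationSpec(
                planted_regions=[PlantedRegion("chr1", 0, 200_000_000, "pathology_1", "gain")]
            )

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SimulationSpec(
                n_groups=1,
                planted_regions=[PlantedRegion("chr1", 0, 2_000_000, "pathology_9", "gain")],
            )

    def test_penetrance_and_effect_validated(self):
        with pytest.raises(ValueError):
            PlantedRegion("chr1", 0, 10, "pathology_1", "gain", penetrance=1.5)
        with pytest.raises(ValueError):
            PlantedRegion("chr1", 0, 10, "pathology_1", "loss", effect=-1.0)
        with pytest.raises(ValueError):
            PlantedRegion("chr1", 0, 10, "pathology_1", "sideways")


class TestBac:
    def test_null_noiseless_is_all_zero(self):
        spec = null_spec(noise_sd=0.0, background_rate=0.0, samples_per_group=2)
        mat, labels, truth = simulate_bac(spec)
        assert np.all(mat.values == 0)
        assert truth == []
        assert len(labels) == 4

    def test_deterministic_limit_exact_effects(self):
        spec = SimulationSpec(
            noise_sd=0.0,
            background_rate=0.0,
            samples_per_group=3,
            planted_regions=[
                PlantedRegion("chr1", 10_000_000, 14_000_000, "pathology_1", "gain", 1.0, 1.0),
                PlantedRegion("chr2", 30_000_000, 34_000_000, "pathology_2", "loss", 1.0, 0.5),
            ],
        )
        mat, labels, _ = simulate_bac(spec)
        cases = [j for j, s in enumerate(mat.samples) if labels[s] == "pathology_1"]
        controls = [j for j, s in enumerate(mat.samples) if labels[s] == "pathology_2"]
        gained = [
            i for i, s in enumerate(mat.segments)
            if s.chrom == "chr1" and s.start >= 10_000_000 and s.end <= 14_000_000
        ]
        assert np.all(mat.values[np.ix_(gained, cases)] == 1.0)
        assert np.all(mat.values[np.ix_(gained, controls)] == 0.0)
        lost = [
            i for i, s in enumerate(mat.segments)
            if s.chrom == "chr2" and 30_000_000 <= s.start and s.end <= 34_000_000
        ]
        assert np.all(mat.values[np.ix_(lost, controls)] == -0.5)

    def test_same_seed_identical(self):
        a, _, _ = simulate_bac(SimulationSpec(seed=11))
        b, _, _ = simulate_bac(SimulationSpec(seed=11))
        np.testing.assert_array_equal(a.values, b.values)
        c, _, _ = simulate_bac(SimulationSpec(seed=12))
        assert not np.array_equal(a.values, c.values)

    def test_carrier_frequency_matches_penetrance(self):
        penetrance = 0.7
        spec = SimulationSpec(
            samples_per_group=500,
            noise_sd=0.0,
            background_rate=0.0,
            planted_regions=[
                PlantedRegion("chr1", 10_000_000, 12_000_000, "pathology_1", "gain", penetrance, 1.0)
            ],
            seed=4,
        )
        mat, labels, _ = simulate_bac(spec)
        cases = [j for j, s in enumerate(mat.samples) if labels[s] == "pathology_1"]
        region = [
            i for i, s in enumerate(mat.segments)
            if s.chrom == "chr1" and s.start >= 10_000_000 and s.end <= 12_000_000
        ]
        freq = np.mean(mat.values[np.ix_(region, cases)] == 1.0)
        sd = np.sqrt(penetrance * (1 - penetrance) / 500)
        assert abs(freq - penetrance) < 3 * sd

    def test_unaligned_planted_region_rejected(self):
        spec = SimulationSpec(
            planted_regions=[PlantedRegion("chr1", 100, 200, "pathology_1", "gain")]
        )
        with pytest.raises(ValueError, match="grid"):
            simulate_bac(spec)


class TestOligo:
    small = dict(
        chrom_lengths={"chr1": 2_000_000},
        segments_per_chrom={"chr1": 4},
        breakpoint_rate=2e-6,
        planted_regions=[
            PlantedRegion("chr1", 500_000, 1_000_000, "pathology_1", "gain")
        ],
    )

    def test_rate_zero_carrier_gets_three_segments(self):
        spec = SimulationSpec(
            breakpoint_rate=0.0,
            noise_sd=0.0,
            background_rate=0.0,
            samples_per_group=1,
            chrom_lengths={"chr1": 2_000_000},
            segments_per_chrom={"chr1": 4},
            planted_regions=[
                PlantedRegion("chr1", 500_000, 1_000_000, "pathology_1", "gain", 1.0, 1.0)
            ],
        )
        profiles, labels, _ = simulate_oligo(spec)
        carrier = profiles[0]
        assert labels[carrier.sample_id] == "pathology_1"
        assert [(s.start, s.end, s.value) for s in carrier.segments] == [
            (0, 500_000, 0.0),
            (500_000, 1_000_000, 1.0),
            (1_000_000, 2_000_000, 0.0),
        ]

    def test_same_seed_identical(self):
        spec = SimulationSpec(seed=9, samples_per_group=2, **self.small)
        a, _, _ = simulate_oligo(spec)
        b, _, _ = simulate_oligo(spec)
        assert [
            [(s.chrom, s.start, s.end, s.value) for s in p.segments] for p in a
        ] == [[(s.chrom, s.start, s.end, s.value) for s in p.segments] for p in b]

    def test_segment_count_matches_poisson_rate(self):
        length, rate = 1_000_000, 1e-5  # expect ~11 segments per sample
        spec = null_spec(
            samples_per_group=250,
            chrom_lengths={"chr1": length},
            segments_per_chrom={"chr1": 4},
            breakpoint_rate=rate,
            seed=2,
        )
        profiles, _, _ = simulate_oligo(spec)
        counts = [len(p.segments) for p in profiles]
        expected = 1 + rate * length
        # duplicate draw positions make the observed count slightly low
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < max(5 * se, 0.1 * expected)

    def test_harmonize_conserves_simulated_values(self):
        spec = SimulationSpec(seed=21, samples_per_group=3, **self.small)
        profiles, _, _ = simulate_oligo(spec)
        mat = harmonize(profiles)
        for j, prof in enumerate(profiles):
            for i, s in enumerate(mat.segments):
                orig = prof.value_at(s.chrom, s.start)
                if orig is None:
                    assert mat.missing[i, j]
                else:
                    assert mat.values[i, j] == orig


class TestTracks:
    def test_manifest_marks_alternating_cnv_cover(self):
        spec = SimulationSpec()
        tracks, manifest = make_tracks(spec)
        assert [m["masked"] for m in manifest] == [True, False, True]
        cnv_names = {r.payload["name"] for r in tracks["cnv"]}
        assert {"CNV_PR1", "CNV_PR3"} <= cnv_names
        assert "CNV_PR2" not in cnv_names

    def test_each_planted_region_has_a_gene_inside(self):
        spec = SimulationSpec()
        tracks, manifest = make_tracks(spec)
        genes = {r.payload["name"]: r for r in tracks["gene"]}
        for m in manifest:
            (gname,) = m["genes"]
            g = genes[gname]
            assert g.chrom == m["chrom"] and g.start >= m["start"] and g.end <= m["end"]

    def test_decoys_avoid_planted_regions(self):
        spec = SimulationSpec()
        tracks, manifest = make_tracks(spec)
        planted = [(m["chrom"], m["start"], m["end"]) for m in manifest]
        for rec in tracks["gene"]:
            if rec.payload["name"].startswith("DECOY"):
                for chrom, s, e in planted:
                    assert rec.chrom != chrom or rec.end <= s or rec.start >= e
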