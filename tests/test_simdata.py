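import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from piedmap import cross, simdata
from piedmap.cross import MISSING, haldane_r
from piedmap.simdata import (
    CNEPlant,
    CrossSpec,
    DupPlantSpec,
    PanelSpec,
    QTLSpec,
)


class TestF2Cross:
    def test_same_seed_reproduces_byte_identical_output(self):
        spec = CrossSpec(30, [(10, 50.0)], 0.02, 0.1, seed=5)
        a = simdata.sim_f2_cross(spec)
        b = simdata.sim_f2_cross(spec)
        assert (a[0].calls == b[0].calls).all()
        assert (a[1].calls == b[1].calls).all()
        assert a[2].table.equals(b[2].table)

    def test_no_noise_observed_equals_truth(self):
        truth, observed, _ = simdata.sim_f2_cross(CrossSpec(50, [(8, 40.0)], seed=1))
        assert (truth.calls == observed.calls).all()

    def test_zero_distance_markers_coinherited(self):
        # two markers 0 cM apart recombine with probability 0
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(300, [(2, 1e-12)], seed=2))
        assert (truth.calls[0] == truth.calls[1]).all()

    def test_adjacent_recombination_matches_haldane(self):
        # 10 cM apart: r = (1 - e^-0.2)/2; compare per-gamete recombination
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(10_000, [(2, 10.0)], seed=3))
        r = float(haldane_r(10.0))
        # count observable recombination events between genotype classes:
        # use hom x hom transitions (informative for both gametes)
        a, b = truth.calls[0], truth.calls[1]
        hom = (a != 1) & (b != 1)
        rec = ((a != b) & hom).sum()
        n_hom = hom.sum()
        p_disc = (2 * r * (1 - r) + r**2 * 0) if False else None
        # P(both gametes recombine or exactly one) given both hom at A:
        # hom->other hom requires both gametes to recombine (prob r^2),
        # staying hom-equal has prob (1-r)^2; conditional on ending hom:
        p = r**2 / (r**2 + (1 - r) ** 2)
        se = np.sqrt(p * (1 - p) / n_hom)
        assert abs(rec / n_hom - p) < 3 * se + 1e-9

    def test_marker_frequencies_consistent_with_1_2_1(self):
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(1000, [(5, 50.0)], seed=4))
        for row in truth.calls:
            counts = np.bincount(row, minlength=3)
            exp = np.array([250, 500, 250])
            x2 = ((counts - exp) ** 2 / exp).sum()
            assert chi2.sf(x2, 2) > 0.001

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CrossSpec(0, [(5, 50.0)])
        with pytest.raises(ValueError):
            CrossSpec(10, [(1, 50.0)])
        with pytest.raises(ValueError):
            CrossSpec(10, [(5, -1.0)])
        with pytest.raises(ValueError):
            CrossSpec(10, [(5, 50.0)], genotyping_error_rate=1.5)


class TestPhenotypes:
    def test_no_qtl_no_noise_is_constant(self, small_cross):
        truth, _, tmap = small_cross
        table, info = simdata.sim_phenotypes(truth, tmap, [], seed=1, residual_sd=0.0)
        assert table.iloc[:, 0].nunique() == 1

    def test_single_additive_qtl_gives_three_levels(self, small_cross):
        truth, _, tmap = small_cross
        q = QTLSpec(1, 30.0, 0.2, 0.0, 0.0)
        table, _ = simdata.sim_phenotypes(truth, tmap, [q], seed=1)
        assert table.iloc[:, 0].nunique() == 3

    def test_target_pve_realized(self):
        spec = CrossSpec(500, [(30, 100.0)], seed=6)
        truth, _, tmap = simdata.sim_f2_cross(spec)
        a, target = 0.25, 0.5
        sd = np.sqrt((a * a / 2) * (1 - target) / target)
        _, info = simdata.sim_phenotypes(
            truth, tmap, [QTLSpec(1, 50.0, a, 0.0, sd)], seed=6
        )
        assert abs(info["realized_pve"] - target) < 0.1

    def test_off_map_qtl_rejected(self, small_cross):
        truth, _, tmap = small_cross
        with pytest.raises(ValueError):
            simdata.sim_phenotypes(truth, tmap, [QTLSpec(1, 500.0, 0.2)], seed=1)
        with pytest.raises(ValueError):
            simdata.sim_phenotypes(truth, tmap, [QTLSpec(9, 10.0, 0.2)], seed=1)


class TestPanel:
    def test_zero_gl_error_ml_genotype_equals_call(self):
        sites = simdata.sim_population_sites(
            PanelSpec(5, 5, 30, planted_sites=(0,), gl_error_rate=0.0, seed=7)
        )
        for s in sites:
            assert (np.argmin(s.pl, axis=1) == s.gt).all()

    def test_planted_sites_recovered_by_candidate_filter(self, small_panel):
        from piedmap.popdiff import candidate_snp_filter

        cands = candidate_snp_filter(small_panel)
        assert cands["pos"].tolist() == [small_panel[5].pos, small_panel[6].pos]

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec(0, 5, 10)
        with pytest.raises(ValueError):
            PanelSpec(5, 5, 10, planted_sites=(10,))


class TestAlignment:
    def test_full_identity_every_base_qualifies(self):
        from piedmap.cneseek import species_conserved_regions

        block, _ = simdata.sim_alignment(2, 0, [], 1.0, [], seed=8, length=500)
        for sp in block.species_seqs:
            assert species_conserved_regions(block, sp) == [(0, 500)]

    def test_planted_element_detected(self):
        from piedmap.cneseek import detect_cnes

        block, _ = simdata.sim_alignment(
            12, 0, [CNEPlant(5000, 5150, 0.95, n_avian=12)], 0.40, [],
            seed=9, length=20_000)
        cnes = detect_cnes(block, [])
        assert len(cnes) == 1
        assert cnes[0].start <= 5005 and cnes[0].end >= 5145

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError):
            simdata.sim_alignment(
                5, 0,
                [CNEPlant(100, 300, 0.9, n_avian=5), CNEPlant(200, 400, 0.9, n_avian=5)],
                0.4, [], seed=1, length=1000)


class TestCoverage:
    def test_fixed_noise_copy_number_exact(self):
        from piedmap.svdup import normalize_coverage

        ds = DupPlantSpec(100_000, 5_000, (20_000, 40_000), "homozygous",
                          30.0, "fixed", seed=1)
        track, _ = simdata.sim_coverage(ds)
        norm = normalize_coverage(track)["normalized"].to_numpy()
        inside = (track["start"] >= 20_000) & (track["end"] <= 40_000)
        assert np.allclose(norm[inside.to_numpy()], 4.0)
        assert np.allclose(norm[~inside.to_numpy()], 2.0)

    def test_evidence_points_at_planted_junction(self):
        ds = DupPlantSpec(200_000, 5_000, (50_000, 90_000), "heterozygous",
                          30.0, "poisson", seed=2)
        _, ev = simdata.sim_coverage(ds)
        clips = ev["softclip"]
        right = clips[clips["clip_side"] == "right"]
        assert (right["position"] == 90_000).all()
        assert (right["remap_pos"] == 50_000).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DupPlantSpec(1000, 5000, (0, 100))  # window > genome
        with pytest.raises(ValueError):
            DupPlantSpec(10_000, 100, (5_000, 20_000))  # dup outside


class TestAlleleCounts:
    def test_no_planted_no_copy_specific_calls(self):
        from piedmap.svdup import classify_copy_specific

        table, _ = simdata.sim_allele_counts(30, 50, 50, set(), seed=3)
        classes = classify_copy_specific(table)
        assert (classes["class"] != "copy_specific").all()

    def test_high_depth_recovers_planted_exactly(self):
        from piedmap.svdup import classify_copy_specific

        table, truth = simdata.sim_allele_counts(30, 1000, 1000, {2, 9, 17}, seed=4)
        classes = classify_copy_specific(table)
        called = set(classes.loc[classes["class"] == "copy_specific", "snp_id"])
        assert called == set(truth)

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            simdata.sim_allele_counts(5, 0, 10, set(), seed=1)


class TestRoundTrips:
    def test_genotype_and_map_tsv(self, tmp_path, noisy_cross):
        _, observed, tmap = noisy_cross
        cross.write_genotypes_tsv(observed, tmp_path / "g.tsv")
        back = cross.read_genotypes_tsv(tmp_path / "g.tsv")
        assert (back.calls == observed.calls).all()
        assert list(back.markers.index) == list(observed.markers.index)
        cross.write_map_tsv(tmap, tmp_path / "m.tsv")
        mback = cross.read_map_tsv(tmp_path / "m.tsv")
        assert np.allclose(mback.table["cM"], tmap.table["cM"])

    def test_vcf_roundtrip_through_cyvcf2(self, tmp_path, small_panel):
        from piedmap import popdiff

        simdata.write_vcf(small_panel, tmp_path / "p.vcf")
        simdata.write_sample_sheet(small_panel, tmp_path / "s.tsv")
        back = popdiff.read_vcf(tmp_path / "p.vcf", tmp_path / "s.tsv")
        assert len(back) == len(small_panel)
        for a, b in zip(small_panel, back):
            assert (a.gt == b.gt).all()
            assert np.array_equal(a.pl, b.pl)
            assert (a.groups == b.groups).all()

    def test_alignment_roundtrip(self, tmp_path):
        from piedmap import cneseek

        block, _ = simdata.sim_alignment(
            3, 2, [CNEPlant(100, 250, 0.95, n_avian=3)], 0.4, [], seed=5, length=1000)
        cneseek.write_alignment(block, tmp_path / "a.fa", tmp_path / "m.tsv")
        back = cneseek.read_alignment(tmp_path / "a.fa", tmp_path / "m.tsv")
        assert back.ref_seq == block.ref_seq
        assert back.species_seqs == block.species_seqs
        assert back.clades == block.clades

    def test_coverage_roundtrip(self, tmp_path):
        ds = DupPlantSpec(100_000, 5_000, (20_000, 40_000), "heterozygous",
                          30.0, "poisson", seed=6)
        track, _ = simdata.sim_coverage(ds)
        simdata.write_coverage_tsv(track, tmp_path / "c.tsv")
        back = simdata.read_coverage_tsv(tmp_path / "c.tsv")
        assert np.allclose(back["depth"], track["depth"])
        assert (back["start"] == track["start"]).all()
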