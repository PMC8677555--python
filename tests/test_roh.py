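"""ROH detection: scan semantics, oracle equivalence, annotation and reporting."""

import numpy as np
import pytest

from consangmap import (
    GeneInterval,
    GenotypeMatrix,
    Marker,
    RohParams,
    annotate_control_overlap,
    detect_roh,
    genes_in_regions,
    genome_roh_fraction,
    gwas_loci_in_regions,
    regions_table,
    shared_identical_regions,
)
from consangmap.roh import read_bed_genes, write_regions_bed
from conftest import multi_sample_matrix, single_sample_matrix
from oracles import brute_force_roh, _shared_status, _single_status

MISS = -1


class TestDetect:
    def test_sixty_homozygous_markers_over_1_5_mb(self):
        gm = single_sample_matrix([2] * 60, spacing_bp=25_424)  # ~1.5 Mb span
        regions = detect_roh(gm, "S1")
        assert len(regions) == 1
        r = regions[0]
        assert r.n_markers == 60
        assert (r.start_bp, r.end_bp) == (gm.markers[0].bp, gm.markers[-1].bp)
        assert r.length_bp >= 1_000_000

    def test_forty_nine_markers_with_two_embedded_hets_rejected(self):
        """Two true heterozygous calls must not be silently erased: a
        49-homozygous-marker stretch is not reported as a run."""
        calls = [0] * 20 + [1] + [0] * 15 + [1] + [0] * 14  # 49 hom, 2 het
        gm = single_sample_matrix(calls, spacing_bp=60_000)
        assert detect_roh(gm, "S1") == []

    def test_length_below_one_mb_rejected(self):
        gm = single_sample_matrix([2] * 120, spacing_bp=6_700)  # ~0.8 Mb
        assert detect_roh(gm, "S1") == []

    def test_het_tolerance_absorbs_isolated_het(self):
        calls = [2] * 30 + [1] + [2] * 30
        gm = single_sample_matrix(calls, spacing_bp=25_000)
        assert detect_roh(gm, "S1") == []  # split at default tolerance 0
        regions = detect_roh(gm, "S1", RohParams(het_tolerance=1))
        assert len(regions) == 1 and regions[0].n_markers == 60

    def test_missing_calls_transparent_but_uncounted(self):
        calls = [2] * 30 + [MISS] * 5 + [2] * 30
        gm = single_sample_matrix(calls, spacing_bp=25_000)
        regions = detect_roh(gm, "S1", RohParams(min_snps=55))
        assert len(regions) == 1 and regions[0].n_markers == 60

    def test_max_missing_run_breaks_low_density_stretch(self):
        calls = [2] * 30 + [MISS] * 5 + [2] * 30
        gm = single_sample_matrix(calls, spacing_bp=25_000)
        p = RohParams(min_snps=10, min_length_bp=100_000, max_missing_run=3)
        regions = detect_roh(gm, "S1", p)
        assert len(regions) == 2 and all(r.n_markers == 30 for r in regions)

    def test_low_maf_markers_excluded_from_input(self):
        markers = [
            Marker(id=f"m{k}", chrom="1", bp=1 + k * 25_000,
                   ref_maf=0.3 if k % 2 else 0.01)
            for k in range(120)
        ]
        gm = GenotypeMatrix(["S1"], markers, np.full((1, 120), 2, dtype=np.int8))
        regions = detect_roh(gm, "S1", RohParams(min_snps=50))
        assert len(regions) == 1 and regions[0].n_markers == 60


class TestShared:
    def test_both_cases_hom_alt_identical(self):
        rows = {"A": [2] * 55, "B": [2] * 55}
        gm = multi_sample_matrix(rows, spacing_bp=22_300)  # ~1.2 Mb
        regions = shared_identical_regions(gm, ["A", "B"])
        assert len(regions) == 1
        assert regions[0].members == frozenset({"A", "B"})
        assert regions[0].n_markers == 55

    def test_opposite_homozygotes_split_the_run(self):
        a = [2] * 55
        b = [2] * 27 + [0] + [2] * 27
        gm = multi_sample_matrix({"A": a, "B": b}, spacing_bp=22_300)
        assert shared_identical_regions(gm, ["A", "B"]) == []

    def test_restricting_the_case_set_recovers_the_pair_region(self):
        """A third case heterozygous inside the run abolishes the all-case
        region; mapping the two concordant cases alone recovers it."""
        rows = {
            "A": [2] * 60,
            "B": [2] * 60,
            "C": [2] * 30 + [1] + [2] * 29,
        }
        gm = multi_sample_matrix(rows, spacing_bp=25_000)
        assert shared_identical_regions(gm, ["A", "B", "C"]) == []
        pair = shared_identical_regions(gm, ["A", "B"])
        assert len(pair) == 1 and pair[0].n_markers == 60

    def test_fewer_than_two_cases_rejected(self):
        gm = single_sample_matrix([2] * 60)
        with pytest.raises(ValueError, match="two cases"):
            shared_identical_regions(gm, ["S1"])

    def test_shared_contained_in_each_case_roh(self):
        rng = np.random.default_rng(11)
        rows = {s: rng.integers(0, 3, 400).tolist() for s in ("A", "B")}
        for s in rows:
            rows[s][100:300] = [2] * 200
        gm = multi_sample_matrix(rows, spacing_bp=20_000)
        p = RohParams(min_snps=20, min_length_bp=200_000)
        shared = shared_identical_regions(gm, ["A", "B"], p)
        assert shared
        for case in ("A", "B"):
            own = detect_roh(gm, case, p)
            for s in shared:
                assert any(
                    o.start_bp <= s.start_bp and o.end_bp >= s.end_bp for o in own
                )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_single_sample_equals_all_substrings_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        calls = rng.choice([0, 1, 2, MISS], size=n, p=[0.35, 0.1, 0.5, 0.05])
        spacing = int(rng.integers(5_000, 40_000))
        gm = single_sample_matrix(calls.tolist(), spacing_bp=spacing)
        p = RohParams(
            min_snps=int(rng.integers(5, 40)),
            min_length_bp=int(rng.integers(50_000, 800_000)),
            het_tolerance=int(rng.integers(0, 3)),
            max_missing_run=None if rng.random() < 0.5 else int(rng.integers(1, 4)),
        )
        got = sorted(
            (r.start_bp, r.end_bp, r.n_markers) for r in detect_roh(gm, "S1", p)
        )
        statuses = [_single_status(int(c)) for c in calls]
        bps = [m.bp for m in gm.markers]
        expected = brute_force_roh(
            statuses, bps, p.min_snps, p.min_length_bp, p.het_tolerance, p.max_missing_run
        )
        assert got == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_shared_equals_all_substrings_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(100, 400))
        rows = {
            s: rng.choice([0, 1, 2, MISS], size=n, p=[0.3, 0.08, 0.57, 0.05]).tolist()
            for s in ("A", "B", "C")
        }
        gm = multi_sample_matrix(rows, spacing_bp=20_000)
        p = RohParams(min_snps=10, min_length_bp=150_000,
                      het_tolerance=int(rng.integers(0, 2)))
        got = sorted(
            (r.start_bp, r.end_bp, r.n_markers)
            for r in shared_identical_regions(gm, ["A", "B", "C"], p)
        )
        cols = np.array(list(rows.values()))
        statuses = [_shared_status(cols[:, k]) for k in range(n)]
        bps = [m.bp for m in gm.markers]
        expected = brute_force_roh(
            statuses, bps, p.min_snps, p.min_length_bp, p.het_tolerance, None
        )
        assert got == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        """Raising min_snps or min_length never adds regions."""
        rng = np.random.default_rng(200 + seed)
        calls = rng.choice([0, 1, 2], size=300, p=[0.3, 0.08, 0.62]).tolist()
        gm = single_sample_matrix(calls, spacing_bp=20_000)
        base = RohParams(min_snps=10, min_length_bp=100_000)
        base_set = {
            (r.start_bp, r.end_bp) for r in detect_roh(gm, "S1", base)
        }
        for p in (
            RohParams(min_snps=20, min_length_bp=100_000),
            RohParams(min_snps=10, min_length_bp=400_000),
        ):
            stricter = {(r.start_bp, r.end_bp) for r in detect_roh(gm, "S1", p)}
            assert stricter <= base_set

    def test_emitted_regions_satisfy_their_own_invariants(self):
        rng = np.random.default_rng(42)
        calls = rng.choice([0, 1, 2, MISS], size=500, p=[0.3, 0.06, 0.59, 0.05]).tolist()
        gm = single_sample_matrix(calls, spacing_bp=15_000)
        p = RohParams(min_snps=15, min_length_bp=200_000)
        for r in detect_roh(gm, "S1", p):
            assert r.end_bp > r.start_bp
            assert r.n_markers >= p.min_snps
            assert r.length_bp >= p.min_length_bp
            assert r.members


class TestControlOverlap:
    def make_case_control(self, control_calls):
        rows = {"case1": [2] * 60, "case2": [2] * 60, "ctrl": control_calls}
        return multi_sample_matrix(rows, spacing_bp=25_000)

    def test_fully_homozygous_control_listed(self):
        gm = self.make_case_control([0] * 60)
        regions = shared_identical_regions(gm, ["case1", "case2"])
        annotated = annotate_control_overlap(regions, gm, ["ctrl"])
        assert annotated[0].control_overlaps == frozenset({"ctrl"})

    def test_no_control_roh_reports_none(self):
        gm = self.make_case_control([0, 1] * 30)
        regions = shared_identical_regions(gm, ["case1", "case2"])
        annotated = annotate_control_overlap(regions, gm, ["ctrl"])
        assert annotated[0].control_overlaps == frozenset()
        assert regions_table(annotated).loc[0, "control_overlaps"] == "None"

    def test_exclusion_mode_drops_overlapped_region(self):
        gm = self.make_case_control([0] * 60)
        regions = shared_identical_regions(gm, ["case1", "case2"])
        assert annotate_control_overlap(regions, gm, ["ctrl"], exclude=True) == []


class TestGenomeFraction:
    def test_no_roh_is_zero(self):
        gm = single_sample_matrix([0, 1] * 50, spacing_bp=25_000)
        assert genome_roh_fraction(gm, "S1") == 0.0

    def test_single_chromosome_fully_homozygous_is_one(self):
        gm = single_sample_matrix([2] * 100, spacing_bp=101_011)  # ~10 Mb chrom
        assert genome_roh_fraction(gm, "S1") == 1.0

    def test_empty_panel_is_error(self):
        gm = single_sample_matrix([2] * 10)
        with pytest.raises(ValueError):
            genome_roh_fraction(gm.subset(marker_mask=np.zeros(10, dtype=bool)), "S1")


def region_fixture(start=10_000_000, end=12_000_000):
    from consangmap.roh import ROHRegion

    return ROHRegion(chrom="16", start_bp=start, end_bp=end, n_markers=100,
                     members=frozenset({"A", "B"}))


class TestAnnotation:
    def test_gene_fully_inside_listed(self):
        genes = [GeneInterval("NOD2", "16", 10_500_000, 10_540_000)]
        out = genes_in_regions([region_fixture()], genes)
        assert out[0].genes == ("NOD2",)

    def test_gene_abutting_past_end_not_listed(self):
        genes = [GeneInterval("NEXT", "16", 12_000_001, 12_100_000)]
        out = genes_in_regions([region_fixture()], genes)
        assert out[0].genes == ()

    def test_thirteen_of_twenty_panel_genes_recovered(self):
        from consangmap.synth import tiled_gene_panel

        genes = tiled_gene_panel("16", 9_000_000, 14_000_000, 20)
        region = region_fixture(start=10_000_000, end=13_249_999)
        out = genes_in_regions([region], genes)
        assert len(out[0].genes) == 13

    def test_gwas_hit_membership(self):
        region = region_fixture()
        snps = [
            ("rs_mid", "16", 11_000_000),
            ("rs_before", "16", 9_999_999),
            ("rs_other_chrom", "2", 11_000_000),
        ]
        out = gwas_loci_in_regions([region], snps)
        assert out[0].gwas_hits == ("rs_mid",)
        empty = gwas_loci_in_regions([region], [])
        assert empty[0].gwas_hits == ()
        assert regions_table(empty).loc[0, "gwas_hits"] == "No IBD GWAS loci"

    def test_bed_round_trip(self, tmp_path):
        region = region_fixture()
        bed = tmp_path / "regions.bed"
        write_regions_bed([region], bed)
        genes = read_bed_genes(bed)
        # BED is 0-based half-open; reading back restores 1-based inclusive
        assert genes[0].start_bp == region.start_bp
        assert genes[0].end_bp == region.end_bp
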