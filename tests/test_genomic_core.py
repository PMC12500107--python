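"""Coordinate conventions, file round trips, and interval algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cutrunkit import (
    BinnedTrack,
    GeneModel,
    Genome,
    GenomeMismatchError,
    Region,
    RegionSet,
    annotate_location,
    classify_h2aub_loci,
    classify_promoters,
    closest_feature,
    consensus_regions,
    intersect_regions,
    load_genes,
    load_regions,
    load_track,
    overlap_fraction,
    save_genes,
    save_regions,
    save_track,
    subtract_regions,
)
from cutrunkit.io import BedParseError

from conftest import (
    bitmap,
    bitmap_to_intervals,
    brute_force_overlaps,
    random_region_set,
    regions_as_tuples,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class TestContainers:
    def test_region_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            Region("chr1", 100, 100)
        with pytest.raises(ValueError):
            Region("chr1", -5, 10)

    def test_region_set_rejects_out_of_bounds(self, small_genome):
        with pytest.raises(ValueError, match="exceeds"):
            RegionSet([Region("chr1", 0, 200_000)], small_genome)
        with pytest.raises(KeyError, match="unknown"):
            RegionSet([Region("chrX", 0, 10)], small_genome)

    def test_region_set_sorts(self, small_genome):
        rs = RegionSet(
            [Region("chr2", 0, 10), Region("chr1", 50, 60), Region("chr1", 0, 10)],
            small_genome,
        )
        assert regions_as_tuples(rs) == [
            ("chr1", 0, 10), ("chr1", 50, 60), ("chr2", 0, 10)
        ]

    def test_merge_collapses_overlaps(self, small_genome):
        rs = RegionSet(
            [Region("chr1", 0, 100), Region("chr1", 50, 150), Region("chr1", 300, 400)],
            small_genome,
        )
        assert regions_as_tuples(rs.merge()) == [("chr1", 0, 150), ("chr1", 300, 400)]

    def test_track_requires_full_vectors(self, tiny_genome):
        with pytest.raises(ValueError, match="bins"):
            BinnedTrack(tiny_genome, {"chr1": np.zeros(3)})
        with pytest.raises(ValueError, match="negative"):
            BinnedTrack(tiny_genome, {"chr1": -np.ones(20)})

    def test_gene_model_tss_follows_strand(self):
        plus = GeneModel("g1", "chr1", "+", 100, 500, ((100, 200),))
        minus = GeneModel("g2", "chr1", "-", 100, 500, ((400, 500),))
        assert plus.tss == 100 and minus.tss == 500
        assert plus.promoter(50).start == 50 and plus.promoter(50).end == 100
        assert minus.promoter(50).start == 500 and minus.promoter(50).end == 550

    def test_gene_model_rejects_exon_outside_body(self):
        with pytest.raises(ValueError, match="exon"):
            GeneModel("g", "chr1", "+", 100, 200, ((50, 150),))


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

class TestRegionIO:
    def test_basic_parse(self, small_genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        rs = load_regions(p, small_genome)
        assert regions_as_tuples(rs) == [("chr1", 0, 100)]

    def test_empty_file(self, small_genome, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(load_regions(p, small_genome)) == 0

    def test_unsorted_input_is_sorted(self, small_genome, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr1\t500\t600\nchr1\t0\t100\nchr1\t200\t300\n")
        rs = load_regions(p, small_genome)
        coords = regions_as_tuples(rs)
        assert coords == sorted(coords)

    def test_malformed_line_reports_number(self, small_genome, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tnope\t100\n")
        with pytest.raises(BedParseError, match=":2:"):
            load_regions(p, small_genome)

    def test_unknown_chromosome_named(self, small_genome, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr9\t0\t100\n")
        with pytest.raises(BedParseError, match="chr9"):
            load_regions(p, small_genome)

    def test_out_of_bounds_rejected(self, small_genome, tmp_path):
        p = tmp_path / "oob.bed"
        p.write_text("chr2\t0\t60000\n")
        with pytest.raises(BedParseError, match="exceeds"):
            load_regions(p, small_genome)

    def test_round_trip_with_names_and_scores(self, small_genome, tmp_path):
        rs = RegionSet(
            [
                Region("chr1", 0, 100, name="peak1", score=3.5),
                Region("chr1", 200, 300),
                Region("chr2", 10, 20, name="peak2"),
            ],
            small_genome,
        )
        p = tmp_path / "rt.bed"
        save_regions(rs, p)
        assert load_regions(p, small_genome) == rs

    def test_round_trip_empty(self, small_genome, tmp_path):
        p = tmp_path / "rt.bed"
        save_regions(RegionSet([], small_genome), p)
        assert len(load_regions(p, small_genome)) == 0

    def test_round_trip_random(self, small_genome, tmp_path):
        rng = np.random.default_rng(0)
        rs = random_region_set(rng, small_genome, 100)
        p = tmp_path / "rt.bed"
        save_regions(rs, p)
        assert load_regions(p, small_genome) == rs


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

class TestTrackIO:
    def test_aligned_interval(self, small_genome, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = load_track(p, small_genome)
        assert track.values["chr1"][0] == 2.0 and track.values["chr1"][1] == 2.0
        assert track.values["chr1"][2] == 0.0

    def test_partial_bin_coverage_weighted(self, small_genome, tmp_path):
        # [0, 75) at 4.0 -> bin0 fully covered (4.0), bin1 half covered (2.0)
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t75\t4.0\n")
        track = load_track(p, small_genome)
        assert track.values["chr1"][0] == 4.0
        assert track.values["chr1"][1] == 2.0

    def test_uncovered_chromosome_is_zero(self, small_genome, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t50\t1.0\n")
        track = load_track(p, small_genome)
        assert not track.values["chr2"].any()

    def test_overlapping_intervals_rejected(self, small_genome, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(BedParseError, match="overlap"):
            load_track(p, small_genome)

    def test_save_merges_runs_and_skips_zeros(self, small_genome, tmp_path):
        vals = {"chr1": np.zeros(2000), "chr2": np.zeros(1000)}
        vals["chr1"][:2] = 1.0
        vals["chr1"][2] = 2.0
        track = BinnedTrack(small_genome, vals)
        p = tmp_path / "t.bedGraph"
        save_track(track, p)
        lines = p.read_text().splitlines()
        assert lines == ["chr1\t0\t100\t1.0", "chr1\t100\t150\t2.0"]

    def test_all_zero_track_writes_nothing(self, small_genome, tmp_path):
        p = tmp_path / "z.bedGraph"
        save_track(BinnedTrack(small_genome, {}), p)
        assert p.read_text() == ""

    def test_random_round_trip_bitwise(self, small_genome, tmp_path):
        rng = np.random.default_rng(3)
        vals = {
            "chr1": np.round(rng.exponential(2.0, 2000), 6),
            "chr2": rng.poisson(1.0, 1000).astype(float),
        }
        track = BinnedTrack(small_genome, vals)
        p = tmp_path / "rt.bedGraph"
        save_track(track, p)
        again = load_track(p, small_genome)
        for chrom in small_genome.chroms:
            np.testing.assert_array_equal(track.values[chrom], again.values[chrom])

    def test_round_trip_with_short_final_bin(self, tmp_path):
        genome = Genome({"chr1": 75}, bin_width=50)  # last bin is 25 bp
        track = BinnedTrack(genome, {"chr1": np.array([2.0, 3.0])})
        p = tmp_path / "rt.bedGraph"
        save_track(track, p)
        np.testing.assert_array_equal(
            load_track(p, genome).values["chr1"], track.values["chr1"]
        )


# ---------------------------------------------------------------------------
# gene model I/O
# ---------------------------------------------------------------------------

class TestGeneIO:
    def test_table_round_trip(self, small_genome, tmp_path):
        genes = [
            GeneModel("g1", "chr1", "+", 1000, 5000, ((1000, 1500), (4000, 5000))),
            GeneModel("g2", "chr2", "-", 0, 2000, ((100, 400),)),
        ]
        p = tmp_path / "genes.tsv"
        save_genes(genes, p)
        assert load_genes(p, small_genome) == genes

    def test_bed12_parsing(self, small_genome, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t1000\t5000\tg1\t0\t+\t1000\t5000\t0\t2\t500,1000\t0,3000\n"
        )
        (gene,) = load_genes(p, small_genome)
        assert gene.exons == ((1000, 1500), (4000, 5000))
        assert gene.strand == "+"

    def test_inconsistent_tss_rejected(self, small_genome, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tchrom\tstrand\ttss\tbody\texons\ng1\tchr1\t+\t999\t1000-2000\t\n")
        with pytest.raises(BedParseError, match="tss"):
            load_genes(p, small_genome)


# ---------------------------------------------------------------------------
# interval algebra vs the per-base bitmap oracle
# ---------------------------------------------------------------------------

class TestIntervalAlgebra:
    def test_intersect_basic(self, small_genome):
        a = RegionSet([Region("chr1", 0, 100)], small_genome)
        b = RegionSet([Region("chr1", 50, 150)], small_genome)
        assert regions_as_tuples(intersect_regions(a, b)) == [("chr1", 50, 100)]

    def test_intersect_disjoint_empty(self, small_genome):
        a = RegionSet([Region("chr1", 0, 100)], small_genome)
        b = RegionSet([Region("chr1", 200, 300)], small_genome)
        assert len(intersect_regions(a, b)) == 0

    def test_genome_mismatch_rejected(self, small_genome, tiny_genome):
        a = RegionSet([Region("chr1", 0, 100)], small_genome)
        b = RegionSet([Region("chr1", 0, 100)], tiny_genome)
        with pytest.raises(GenomeMismatchError):
            intersect_regions(a, b)

    def test_subtract_region_level(self, small_genome):
        a = RegionSet([Region("chr1", 0, 100)], small_genome)
        b = RegionSet([Region("chr1", 50, 150)], small_genome)
        assert len(subtract_regions(a, b)) == 0  # any overlap discards whole region
        c = RegionSet([Region("chr1", 200, 300)], small_genome)
        assert regions_as_tuples(subtract_regions(a, c)) == [("chr1", 0, 100)]

    def test_subtract_empty_is_identity(self, small_genome):
        rng = np.random.default_rng(5)
        a = random_region_set(rng, small_genome, 30)
        assert subtract_regions(a, RegionSet([], small_genome)) == a

    def test_intersect_self_is_merge(self, small_genome):
        rng = np.random.default_rng(6)
        a = random_region_set(rng, small_genome, 30)
        assert intersect_regions(a, a) == a.merge()

    def test_consensus_requires_two_sets(self, small_genome):
        with pytest.raises(ValueError, match=">= 2"):
            consensus_regions([RegionSet([], small_genome)])

    def test_consensus_identical_replicates(self, small_genome):
        rng = np.random.default_rng(7)
        a = random_region_set(rng, small_genome, 20).merge()
        assert consensus_regions([a, a, a]) == a

    def test_consensus_disjoint_is_empty(self, small_genome):
        a = RegionSet([Region("chr1", 0, 100)], small_genome)
        b = RegionSet([Region("chr1", 200, 300)], small_genome)
        assert len(consensus_regions([a, b])) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_against_bitmap_oracle(self, small_genome, seed):
        """intersect/subtract/consensus/overlap_fraction vs per-base truth."""
        rng = np.random.default_rng(seed)
        a = random_region_set(rng, small_genome, 50)
        b = random_region_set(rng, small_genome, 50)
        c = random_region_set(rng, small_genome, 50)
        bm_a, bm_b, bm_c = bitmap(a), bitmap(b), bitmap(c)

        inter = intersect_regions(a, b)
        expected = bitmap_to_intervals(
            {ch: bm_a[ch] & bm_b[ch] for ch in bm_a}, small_genome
        )
        assert regions_as_tuples(inter) == expected

        cons = consensus_regions([a, b, c])
        expected = bitmap_to_intervals(
            {ch: bm_a[ch] & bm_b[ch] & bm_c[ch] for ch in bm_a}, small_genome
        )
        assert regions_as_tuples(cons) == expected

        sub = subtract_regions(a, b)
        keep = ~brute_force_overlaps(a, b)
        assert regions_as_tuples(sub) == [
            t for t, k in zip(regions_as_tuples(a), keep) if k
        ]

        fa, fb = overlap_fraction(a, b)
        assert fa == pytest.approx(brute_force_overlaps(a, b).mean())
        assert fb == pytest.approx(brute_force_overlaps(b, a).mean())

    def test_overlap_fraction_identity_and_disjoint(self, small_genome):
        a = RegionSet([Region("chr1", 0, 100), Region("chr1", 200, 300)], small_genome)
        assert overlap_fraction(a, a) == (1.0, 1.0)
        b = RegionSet([Region("chr2", 0, 100)], small_genome)
        assert overlap_fraction(a, b) == (0.0, 0.0)
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(a, RegionSet([], small_genome))


# ---------------------------------------------------------------------------
# locus classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_promoter_classes_basic(self, small_genome):
        k4 = RegionSet([Region("chr1", 0, 100)], small_genome)
        k27 = RegionSet([Region("chr1", 50, 150)], small_genome)
        bivalent, k4_only = classify_promoters(k4, k27)
        assert regions_as_tuples(bivalent) == [("chr1", 50, 100)]
        assert len(k4_only) == 0

    def test_promoter_classes_empty_k27(self, small_genome):
        k4 = RegionSet([Region("chr1", 0, 100)], small_genome)
        bivalent, k4_only = classify_promoters(k4, RegionSet([], small_genome))
        assert len(bivalent) == 0 and k4_only == k4

    def test_h2aub_classes_partition(self, small_genome):
        rng = np.random.default_rng(11)
        h2 = random_region_set(rng, small_genome, 40).merge()
        k27 = random_region_set(rng, small_genome, 40)
        co, prc1_only = classify_h2aub_loci(h2, k27)
        n_overlapping = int(brute_force_overlaps(h2, k27).sum())
        assert len(prc1_only) + n_overlapping == len(h2)
        # classes never overlap each other
        for r in prc1_only:
            assert not any(r.overlaps(s) for s in co)

    def test_h2aub_all_prc1_only_without_k27(self, small_genome):
        h2 = RegionSet([Region("chr1", 0, 100), Region("chr2", 0, 50)], small_genome)
        co, prc1_only = classify_h2aub_loci(h2, RegionSet([], small_genome))
        assert len(co) == 0 and prc1_only == h2

    def test_h2aub_subset_of_k27(self, small_genome):
        h2 = RegionSet([Region("chr1", 10, 20)], small_genome)
        k27 = RegionSet([Region("chr1", 0, 100)], small_genome)
        co, prc1_only = classify_h2aub_loci(h2, k27)
        assert len(prc1_only) == 0 and regions_as_tuples(co) == [("chr1", 10, 20)]


# ---------------------------------------------------------------------------
# gene proximity
# ---------------------------------------------------------------------------

class TestGeneProximity:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("gA", "chr1", "+", 10_000, 20_000),
            GeneModel("gB", "chr1", "-", 40_000, 50_000),
            GeneModel("gC", "chr2", "+", 0, 5_000),
        ]

    def test_region_inside_gene(self, small_genome, genes):
        rs = RegionSet([Region("chr1", 12_000, 12_100)], small_genome)
        ((gene, dist),) = closest_feature(rs, genes)
        assert gene.gene_id == "gA" and dist == 0

    def test_region_beyond_max_dist(self, small_genome, genes):
        rs = RegionSet([Region("chr1", 30_050, 30_100)], small_genome)
        ((gene, dist),) = closest_feature(rs, genes, max_dist=5_000)
        assert gene is None and dist is None

    def test_tie_broken_by_gene_start(self, small_genome):
        genes = [
            GeneModel("right", "chr1", "+", 20_000, 30_000),
            GeneModel("left", "chr1", "+", 0, 10_000),
        ]
        rs = RegionSet([Region("chr1", 14_000, 16_000)], small_genome)  # equidistant
        ((gene, dist),) = closest_feature(rs, genes)
        assert gene.gene_id == "left" and dist == 4_000

    def test_random_layout_matches_all_pairs_scan(self, small_genome):
        rng = np.random.default_rng(13)
        genes = []
        for i in range(20):
            chrom = "chr1" if i % 2 == 0 else "chr2"
            start = int(rng.integers(0, small_genome.length(chrom) - 3_000))
            genes.append(GeneModel(f"g{i}", chrom, "+", start, start + 2_000))
        regions = random_region_set(rng, small_genome, 50, max_len=500)
        result = closest_feature(regions, genes, max_dist=10_000)
        for r, (gene, dist) in zip(regions, result):
            dists = {
                g.gene_id: max(g.start - r.end, r.start - g.end, 0)
                for g in genes if g.chrom == r.chrom
            }
            in_range = {k: v for k, v in dists.items() if v <= 10_000}
            if not in_range:
                assert gene is None
            else:
                best = min(in_range.values())
                assert dist == best and dists[gene.gene_id] == best

    def test_annotate_location(self, small_genome, genes):
        summits = RegionSet(
            [Region("chr1", 15_000, 15_001), Region("chr2", 40_000, 40_001)],
            small_genome,
        )
        labels, fractions = annotate_location(summits, genes)
        assert labels == ["intragenic", "intergenic"]
        assert fractions == {"intragenic": 0.5, "intergenic": 0.5}

    def test_annotate_random_matches_membership(self, small_genome, genes):
        rng = np.random.default_rng(17)
        summits = random_region_set(rng, small_genome, 100, max_len=50)
        labels, _ = annotate_location(summits, genes)
        for r, label in zip(summits, labels):
            m = r.midpoint
            inside = any(g.chrom == r.chrom and g.start <= m < g.end for g in genes)
            assert (label == "intragenic") == inside


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@st.composite
def region_lists(draw):
    n = draw(st.integers(0, 25))
    regions = []
    for _ in range(n):
        start = draw(st.integers(0, 99_000))
        length = draw(st.integers(1, 900))
        regions.append(Region("chr1", start, start + length))
    return regions


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a_regs=region_lists(), b_regs=region_lists())
def test_intersect_commutes_and_save_round_trips(tmp_path_factory, a_regs, b_regs):
    genome = Genome({"chr1": 100_000}, bin_width=50)
    a = RegionSet(a_regs, genome)
    b = RegionSet(b_regs, genome)
    assert intersect_regions(a, b) == intersect_regions(b, a)
    path = tmp_path_factory.mktemp("hyp") / "rt.bed"
    save_regions(a, path)
    assert load_regions(path, genome) == a
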