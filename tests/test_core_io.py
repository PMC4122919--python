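import numpy as np
import pytest

from mitopopcons import (
    AnnotationSet,
    CoordinateMap,
    ElementSet,
    GeneRecord,
    ScoreTrack,
    SiteTable,
    build_coordinate_map,
    lift_position,
    read_annotations,
    read_elements,
    read_score_track,
    read_snp_table,
    write_annotations,
    write_elements,
    write_snp_table,
)
from mitopopcons.synthetic_data import SyntheticConfig, generate_layout, simulate_site_alleles

from _oracles import exhaustive_alignment_score


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------


class TestSnpTable:
    def test_distinct_alleles_counted_across_rows(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("10\tA\tG\n10\tA\tC\n")
        sites = read_snp_table(path, "positions_with_alleles", genome_length=100)
        assert sites.allele_count[9] == 3
        assert (np.delete(sites.allele_count, 9) == 1).all()

    def test_empty_file_is_monomorphic_fill(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        sites = read_snp_table(path, "positions_with_alleles", genome_length=100)
        assert sites.length == 100
        assert (sites.allele_count == 1).all()

    def test_position_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("101\tA\tG\n")
        with pytest.raises(ValueError, match="101"):
            read_snp_table(path, "positions_with_alleles", genome_length=100)

    def test_non_acgt_symbol_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("5\tA\tR\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            read_snp_table(path, "positions_with_alleles", genome_length=100)

    def test_indel_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "indel.tsv"
        path.write_text("5\tA\tAT\n7\tA\tG\n")
        with pytest.warns(UserWarning, match="non-SNP"):
            sites = read_snp_table(path, "positions_with_alleles", genome_length=100)
        assert sites.allele_count[4] == 1 and sites.allele_count[6] == 2

    def test_counts_dialect_round_trip(self, tmp_path):
        config = SyntheticConfig(
            genome_length=400, seed=3, n_samples=500,
            layout=[("G1", "tRNA", 100, "+"), ("x", "intergenic", 300, "+")],
        )
        _, truth = generate_layout(config)
        sites = simulate_site_alleles(config, truth, seed=4)
        path = tmp_path / "rt.tsv"
        write_snp_table(sites, path, reference=truth.sequence)
        back = read_snp_table(path, "positions_with_counts")
        assert np.array_equal(back.allele_count, sites.allele_count)
        assert np.array_equal(np.sort(back.sample_counts, 1), np.sort(sites.sample_counts, 1))


# ---------------------------------------------------------------------------
# score tracks
# ---------------------------------------------------------------------------


class TestScoreTrack:
    def test_fixedstep_positions(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text("fixedStep chrom=chrM start=1 step=1\n0.5\n-1.2\n")
        track = read_score_track(path, "wiggle", "phylop", length=4)
        assert track.values[0] == 0.5 and track.values[1] == -1.2
        assert not track.missing[:2].any() and track.missing[2:].all()

    def test_bedgraph_half_open(self, tmp_path):
        path = tmp_path / "t.bg"
        path.write_text("chrM\t0\t3\t0.9\n")
        track = read_score_track(path, "bedGraph", "phylop", length=5)
        assert (track.values[:3] == 0.9).all() and track.missing[3:].all()

    def test_overlapping_bedgraph_rejected(self, tmp_path):
        path = tmp_path / "t.bg"
        path.write_text("chrM\t0\t3\t0.9\nchrM\t2\t4\t0.1\n")
        with pytest.raises(ValueError, match="overlap"):
            read_score_track(path, "bedGraph", "phylop", length=5)

    def test_negation_flips_sign_and_kind(self):
        track = ScoreTrack(3, np.array([0.5, -1.0, 2.0]), "phylop")
        neg = track.negated()
        assert neg.kind == "negated_phylop"
        assert np.array_equal(neg.values, [-0.5, 1.0, -2.0])

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError, match="probabilit"):
            ScoreTrack(2, np.array([0.5, 1.4]), "conservation_probability")


# ---------------------------------------------------------------------------
# annotations and elements
# ---------------------------------------------------------------------------


class TestBedIo:
    def test_one_based_inclusive_gene_row_maps_to_bed(self, tmp_path):
        # tRNA phenylalanine spans 579..649 1-based inclusive = BED 578..649
        path = tmp_path / "genes.bed"
        path.write_text("chrM\t578\t649\tMT-TF|tRNA|tRNA phenylalanine\t0\t+\n")
        ann = read_annotations(path, genome_length=16569)
        rec = ann.records[0]
        assert (rec.name, rec.start, rec.end, rec.strand, rec.gene_class) == (
            "MT-TF", 578, 649, "+", "tRNA"
        )
        assert rec.end - rec.start == 649 - 579 + 1

    def test_unknown_class_token_rejected(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chrM\t0\t10\tX|plasmid\t0\t+\n")
        with pytest.raises(ValueError, match="unknown class"):
            read_annotations(path, genome_length=100)

    def test_annotations_round_trip(self, tmp_path):
        ann = AnnotationSet(
            1000,
            [
                GeneRecord("A", 10, 80, "+", "tRNA", "tRNA alanine"),
                GeneRecord("B", 100, 400, "-", "protein", "subunit"),
            ],
        )
        path = tmp_path / "ann.bed"
        write_annotations(ann, path)
        back = read_annotations(path)
        assert back.genome_length == 1000
        assert [(r.name, r.start, r.end, r.strand, r.gene_class, r.description)
                for r in back.records] == [
            (r.name, r.start, r.end, r.strand, r.gene_class, r.description)
            for r in ann.records
        ]

    def test_empty_element_set_writes_header_only(self, tmp_path):
        empty = ElementSet(500, np.array([], dtype=int), np.array([], dtype=int))
        path = tmp_path / "empty.bed"
        write_elements(empty, path)
        lines = path.read_text().splitlines()
        assert lines == ["#genome_length=500"]
        assert len(read_elements(path)) == 0

    def test_elements_round_trip_random(self, tmp_path, rng):
        cuts = np.sort(rng.choice(np.arange(1, 5000), size=100, replace=False))
        starts, ends = cuts[0::2], cuts[1::2]
        elements = ElementSet(5000, starts, ends)
        path = tmp_path / "el.bed"
        write_elements(elements, path)
        back = read_elements(path)
        assert np.array_equal(back.starts, starts) and np.array_equal(back.ends, ends)
        assert back.labels == elements.labels

    def test_overlapping_elements_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            ElementSet(100, np.array([0, 5]), np.array([10, 20]))


# ---------------------------------------------------------------------------
# coordinate liftover
# ---------------------------------------------------------------------------


class TestCoordinateMap:
    def test_identical_sequences_give_identity_map(self):
        seq = "ACGTACGTGG"
        cmap = build_coordinate_map(seq, seq)
        assert np.array_equal(cmap.mapping, np.arange(10))

    def test_insertion_shifts_downstream_positions(self):
        source = "AACGTACGTT"
        k = 4  # insert a base after source position 4
        target = source[: k + 1] + "G" + source[k + 1 :]
        cmap = build_coordinate_map(source, target)
        for i in range(len(source)):
            assert lift_position(cmap, i) == (i if i <= k else i + 1)

    def test_deletion_maps_to_none(self):
        source = "AACGTACGTT"
        k = 5
        target = source[:k] + source[k + 1 :]
        cmap = build_coordinate_map(source, target)
        assert lift_position(cmap, k) is None
        for i in range(len(source)):
            if i < k:
                assert lift_position(cmap, i) == i
            elif i > k:
                assert lift_position(cmap, i) == i - 1

    def test_out_of_range_position_rejected(self):
        cmap = build_coordinate_map("ACGT", "ACGT")
        with pytest.raises(ValueError):
            lift_position(cmap, 4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_coordinate_map("", "ACGT")

    def test_score_matches_exhaustive_alignment(self, rng):
        """Affine-gap optimum agrees with enumeration of all alignments."""
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 8)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 8)))
            cmap = build_coordinate_map(a, b)
            assert cmap.score == pytest.approx(exhaustive_alignment_score(a, b), abs=1e-9)

    def test_n_never_matches(self):
        # N-vs-N columns score as mismatches, so the aligner prefers real bases
        cmap = build_coordinate_map("NNNN", "NNNN")
        assert cmap.score == pytest.approx(4 * -2.0)

    def test_map_monotonicity_random_pairs(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            cmap = build_coordinate_map(a, b)
            defined = cmap.mapping[cmap.mapping >= 0]
            assert (np.diff(defined) > 0).all()

    def test_monotonicity_enforced_by_type(self):
        with pytest.raises(ValueError, match="increasing"):
            CoordinateMap(3, 3, np.array([2, 1, -1]))
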