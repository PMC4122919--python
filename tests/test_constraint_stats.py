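import numpy as np
import pytest
from scipy import stats

from mitopopcons import (
    AnnotationSet,
    GeneRecord,
    ScoreTrack,
    SyntheticConfig,
    classify_sites,
    generate_layout,
    maf_divergence_correlation,
    per_gene_correlations,
    simulate_divergence,
    simulate_site_alleles,
    spearman,
    window_average,
)
from mitopopcons.constraint_stats import fourfold_degenerate_prefixes

from _oracles import naive_spearman


class TestSpearman:
    def test_perfect_agreement_and_reversal(self):
        assert spearman([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_matches_naive_midrank_oracle_on_tied_vectors(self, rng):
        for _ in range(50):
            n = rng.integers(5, 60)
            x = rng.integers(1, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(1, 8, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(naive_spearman(x, y), abs=1e-12)

    def test_p_value_uses_t_approximation(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        res = spearman(x, y)
        expected = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(expected.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(expected.pvalue, rel=1e-6)

    def test_reporting_floor_preserves_raw_p(self):
        x = np.arange(200.0)
        res = spearman(x, x + 0.0)
        assert res.p_value == 0.0
        assert res.p_reported == 2.2e-16

    def test_zero_variance_returns_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.rho is None and res.p_value is None

    def test_symmetry(self, rng):
        x = rng.integers(1, 4, size=50).astype(float)
        y = rng.normal(size=50)
        assert spearman(x, y).rho == spearman(y, x).rho

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y - 7).rho == pytest.approx(base, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1.0, 2.0], [1.0, 2.0])


class TestWindowAverage:
    def test_constant_track_any_width(self):
        values = np.full(30, 2.5)
        assert (window_average(values, 7, 3) == 2.5).all()

    def test_adjacent_windows_count(self):
        out = window_average(np.arange(30.0), width=10, step=10)
        assert len(out) == 3
        assert out[0] == pytest.approx(np.arange(10).mean())

    def test_width_one_step_one_is_identity(self, rng):
        values = rng.normal(size=25)
        assert np.allclose(window_average(values, 1, 1), values)

    def test_circular_wraparound_matches_manual_means(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = window_average(values, width=5, step=1, circular=True)
        manual = [values[np.arange(s, s + 5) % 6].mean() for s in range(6)]
        assert np.allclose(out, manual)

    def test_trailing_partial_window_kept_when_half_full(self):
        # 25 sites, width 10, step 10: windows [0,10), [10,20), tail [20,25) of 5 >= width/2
        out = window_average(np.arange(25.0), width=10, step=10)
        assert len(out) == 3
        assert out[2] == pytest.approx(np.arange(20, 25).mean())
        # 22 sites: tail of 2 < 5 dropped
        assert len(window_average(np.arange(22.0), width=10, step=10)) == 2

    def test_masked_sites_excluded_from_means(self):
        values = np.array([1.0, 100.0, 3.0, 5.0])
        mask = np.array([False, True, False, False])
        out = window_average(values, width=2, step=2, mask=mask)
        assert out[0] == 1.0 and out[1] == 4.0

    def test_width_beyond_track_rejected(self):
        with pytest.raises(ValueError, match="width"):
            window_average(np.arange(5.0), width=6)


class TestClassifySites:
    @staticmethod
    def annotation(seq_len, records):
        return AnnotationSet(seq_len, records)

    def test_codon_positions_on_plus_strand(self):
        seq = "TT" + "CTACTGCTT" + "T"  # gene [2, 11): codons CTA CTG CTT
        ann = self.annotation(12, [GeneRecord("G", 2, 11, "+", "protein")])
        mask = classify_sites(ann, seq)
        assert mask.labels[3] == "second_codon_position"
        assert mask.labels[6] == "second_codon_position"
        # CT* is 4-fold degenerate (all leucine)
        assert mask.labels[4] == "fourfold_degenerate"
        assert mask.labels[0] == "noncoding_other"

    def test_fourfold_prefixes_from_vertebrate_mito_code(self):
        prefixes = fourfold_degenerate_prefixes()
        assert "CT" in prefixes  # CTN all Leu in table 2
        assert "GT" in prefixes  # GTN all Val
        assert "AT" not in prefixes  # ATA=Met vs ATT=Ile
        assert "TA" not in prefixes  # stop codons involved
        assert len(prefixes) == 8

    def test_minus_strand_codons_read_on_reverse_complement(self):
        # gene [0, 6) on minus strand; genomic TAGCAT -> coding ATGCTA: codons ATG CTA
        seq = "TAGCAT"
        ann = self.annotation(6, [GeneRecord("G", 0, 6, "-", "protein")])
        mask = classify_sites(ann, seq)
        # coding order maps to genomic positions 5,4,3,2,1,0
        assert mask.labels[4] == "second_codon_position"  # codon1 pos2
        assert mask.labels[1] == "second_codon_position"  # codon2 pos2
        assert mask.labels[0] == "fourfold_degenerate"  # CTA third base, CT prefix

    def test_partial_codon_skipped_with_warning(self):
        seq = "ATGCTAGG"
        ann = self.annotation(8, [GeneRecord("G", 0, 8, "+", "protein")])
        with pytest.warns(UserWarning, match="partial codon"):
            mask = classify_sites(ann, seq)
        assert mask.labels[6] == "noncoding_other"

    def test_rna_control_and_other_labels(self):
        seq = "A" * 30
        ann = self.annotation(
            30,
            [GeneRecord("T", 0, 10, "+", "tRNA"), GeneRecord("CR", 10, 20, "+", "control")],
        )
        mask = classify_sites(ann, seq)
        assert (mask.labels[:10] == "rna_gene").all()
        assert (mask.labels[10:20] == "noncoding_control").all()
        assert (mask.labels[20:] == "noncoding_other").all()

    def test_second_position_count_per_clean_gene(self, default_dataset):
        config, annotations, truth, _ = default_dataset
        mask = classify_sites(annotations, truth.sequence)
        protein_bp = sum(
            r.end - r.start for r in annotations.records if r.gene_class == "protein"
        )
        n_second = (mask.labels == "second_codon_position").sum()
        assert n_second == protein_bp // 3


class TestPerGeneCorrelations:
    def test_row_structure_matches_gene_table_convention(self, rng):
        ann = AnnotationSet(
            1000, [GeneRecord("MT-TF", 578, 649, "+", "tRNA", "tRNA phenylalanine")]
        )
        sites_ac = rng.integers(1, 5, size=1000)
        from mitopopcons import SiteTable

        sites = SiteTable(1000, sites_ac)
        scores = ScoreTrack(1000, rng.normal(size=1000), "negated_phylop")
        table, tally = per_gene_correlations(sites, scores, ann)
        row = table.iloc[0]
        assert (row["gene"], row["description"]) == ("MT-TF", "tRNA phenylalanine")
        assert (row["start"], row["end"]) == (578, 649)
        for col in ("rho", "p", "rho_corrected", "p_corrected"):
            assert col in table.columns
        assert tally["n_genes"] == 1

    def test_monomorphic_gene_has_undefined_rho(self, rng):
        from mitopopcons import SiteTable

        ann = AnnotationSet(100, [GeneRecord("G", 10, 40, "+", "tRNA")])
        sites = SiteTable(100, np.ones(100, dtype=int))
        scores = ScoreTrack(100, rng.normal(size=100), "negated_phylop")
        table, tally = per_gene_correlations(sites, scores, ann)
        assert np.isnan(table.iloc[0]["rho"])
        assert tally["n_significant"] == 0

    def test_genic_constraint_beats_intergenic_correlation(self):
        """Genes with internal constraint show stronger polymorphism-divergence
        coupling than neutral intergenic spans of the same size."""
        blocks = []
        for i in range(12):
            blocks.append((f"P{i}", "protein", 300, "+"))
            blocks.append((f"ig{i}", "intergenic", 300, "+"))
        config = SyntheticConfig(
            genome_length=7200, seed=41, n_samples=2000, layout=blocks
        )
        annotations, truth = generate_layout(config)
        sites = simulate_site_alleles(config, truth, seed=42)
        neg, _ = simulate_divergence(config, truth, seed=43)
        table, _ = per_gene_correlations(sites, neg, annotations)
        gene_rhos = table["rho"].abs().to_numpy()
        intergenic_rhos = []
        for i in range(12):
            lo, hi = 600 * i + 300, 600 * i + 600
            res = spearman(sites.allele_count[lo:hi].astype(float), neg.values[lo:hi])
            intergenic_rhos.append(abs(res.rho))
        assert np.median(gene_rhos) > np.median(intergenic_rhos)


class TestMafCorrelation:
    def test_no_biallelic_sites_gives_undefined(self):
        from mitopopcons import SiteTable

        sites = SiteTable(10, np.ones(10, dtype=int))
        scores = ScoreTrack(10, np.arange(10.0), "negated_phylop")
        with pytest.warns(UserWarning):
            res = maf_divergence_correlation(sites, scores)
        assert res.rho is None

    def test_identical_mafs_give_undefined(self):
        from mitopopcons import SiteTable

        counts = np.zeros((10, 4), dtype=int)
        counts[:, 0] = 90
        counts[:, 1] = 10
        sites = SiteTable(10, np.full(10, 2), sample_counts=counts)
        scores = ScoreTrack(10, np.arange(10.0), "negated_phylop")
        with pytest.warns(UserWarning, match="zero variance"):
            res = maf_divergence_correlation(sites, scores)
        assert res.rho is None

    def test_frequency_capping_couples_maf_to_divergence(self):
        """Constraint caps derived-allele frequencies, so MAF correlates
        positively with divergence across a constrained/neutral mosaic."""
        config = SyntheticConfig(
            genome_length=48_000, seed=51, n_samples=2000, theta_neutral=1.0,
            dssh_effect=0.0,
            layout=[("x", "intergenic", 48_000, "+")],
            constraint_layout=[(i * 1000, i * 1000 + 500, 0.9) for i in range(48)],
        )
        _, truth = generate_layout(config)
        sites = simulate_site_alleles(config, truth, seed=52)
        neg, _ = simulate_divergence(config, truth, seed=53)
        res = maf_divergence_correlation(sites, neg)
        assert res.n >= 10_000
        assert res.rho > 0.0 and res.p_value < 0.05
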