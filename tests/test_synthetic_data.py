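"""Generator ground truth: placement, seeding, enrichment kernel, mirroring."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

import tssenrich as te
from tssenrich.io import write_genes_bed12
from tssenrich.synthetic_data import GenePlacementError, rank_percentiles


class TestGenerateGenome:
    def test_zero_genes_gives_empty_annotation(self):
        genome, genes = te.generate_genome(1, 100_000, 0, seed=1)
        assert genome.names == ("chr1",)
        assert genes == []

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        outs = []
        for rep in range(2):
            _, genes = te.generate_genome(1, 1_000_000, 200, seed=7)
            buf = io.StringIO()
            path = tmp_path / f"genes{rep}.bed12"
            write_genes_bed12(genes, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_infeasible_placement_raises(self):
        with pytest.raises(GenePlacementError, match="overlap|length"):
            te.generate_genome(1, 1000, 500, seed=1)

    def test_transcripts_do_not_overlap_and_exons_are_valid(self):
        genome, genes = te.generate_genome(3, 200_000, 80, seed=5)
        per_chrom: dict[str, list] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
            assert g.exons[0][0] == g.tx_start and g.exons[-1][1] == g.tx_end
            assert 1 <= len(g.exons) <= 5
        for ivs in per_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_minus_strand_tss_is_five_prime_base(self):
        g = te.GeneModel("g", "chr1", "-", 100, 200, ((100, 200),))
        assert g.tss == 199
        assert g.tes == 100


class TestSimulateExpression:
    def test_zero_fraction_zero_gives_all_positive(self):
        _, genes = te.generate_genome(1, 500_000, 50, seed=2)
        expr = te.simulate_expression(genes, zero_fraction=0.0, seed=3)
        assert (expr["fpkm"] > 0).all()

    def test_exact_zero_count_by_construction(self):
        _, genes = te.generate_genome(1, 2_000_000, 200, seed=2)
        expr = te.simulate_expression(genes, zero_fraction=0.25, seed=3)
        assert (expr["fpkm"] == 0).sum() == 50
        assert len(expr) == 200

    def test_seeded_table_is_reproducible(self):
        _, genes = te.generate_genome(1, 500_000, 50, seed=2)
        a = te.simulate_expression(genes, 0.1, seed=4)
        b = te.simulate_expression(genes, 0.1, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateReads:
    def test_no_background_no_spec_gives_empty_reads(self, toy_genome):
        reads = te.simulate_reads(toy_genome, [], pd.DataFrame(
            {"gene_id": [], "fpkm": []}), None, background_depth=0.0, seed=1)
        assert len(reads) == 0

    def test_enrichment_midpoints_average_to_offset_downstream_of_tss(self):
        genome = te.GenomeModel((("chr1", 1_000_000),))
        gene = te.GeneModel("g", "chr1", "+", 500_000, 505_000,
                            ((500_000, 505_000),))
        expr = pd.DataFrame({"gene_id": ["g"], "fpkm": [5.0]})
        spec = te.EnrichmentSpec(500, 500, 20_000.0, "independent")
        reads = te.simulate_reads(genome, [gene], expr, spec, 0.0, 200, seed=9)
        mids = ((reads["start"] + reads["end"]) // 2).to_numpy()
        n = len(mids)
        assert abs(mids.mean() - (500_000 + 500)) < 3 * 500 / np.sqrt(n)

    def test_dependent_coupling_scales_with_rank_percentile(self):
        expr = pd.DataFrame({"gene_id": ["a", "b"], "fpkm": [100.0, 1.0]})
        # with 10 hypothetical genes the top and the rank-1 gene would sit
        # at percentiles 1.0 and 0.1; with two genes percentiles are 1, 0.5
        pct = rank_percentiles(expr)
        assert pct["a"] == 1.0 and pct["b"] == 0.5
        exp_ratio = (1.0 ** 1) / (0.5 ** 1)
        assert exp_ratio == 2.0

    def test_read_coordinates_respect_genome_bounds(self, small_dataset):
        genome, _, _, chip, inp = small_dataset
        lengths = genome.lengths
        for reads in (chip, inp):
            L = reads["chrom"].map(lengths)
            assert (reads["start"] >= 0).all()
            assert (reads["start"] < reads["end"]).all()
            assert (reads["end"] <= L).all()

    def test_total_read_count_within_poisson_expectation(self):
        genome, genes = te.generate_genome(2, 2_000_000, 200, seed=21)
        expr = te.simulate_expression(genes, 0.1, seed=22)
        spec = te.EnrichmentSpec(500, 500, 40.0, "independent")
        reads = te.simulate_reads(genome, genes, expr, spec,
                                  background_depth=5.0, seed=23)
        lam = 5.0 * genome.total_length / 1000 + 40.0 * len(genes)
        assert lam >= 1e4
        assert abs(len(reads) - lam) <= 5 * np.sqrt(lam)

    def test_minus_strand_enrichment_mirrors_plus_strand(self):
        genome = te.GenomeModel((("chr1", 1_000_000),))
        plus = te.GeneModel("g", "chr1", "+", 500_000, 505_000,
                            ((500_000, 505_000),))
        minus = te.GeneModel("g", "chr1", "-", 495_000, 500_001,
                             ((495_000, 500_001),))  # same TSS base
        assert plus.tss == minus.tss == 500_000
        expr = pd.DataFrame({"gene_id": ["g"], "fpkm": [5.0]})
        spec = te.EnrichmentSpec(500, 500, 5000.0, "independent")
        rp = te.simulate_reads(genome, [plus], expr, spec, 0.0, 200, seed=9)
        rm = te.simulate_reads(genome, [minus], expr, spec, 0.0, 200, seed=10)
        mp = ((rp["start"] + rp["end"]) // 2).to_numpy() - 500_000
        mm = 500_000 - ((rm["start"] + rm["end"]) // 2).to_numpy()
        assert min(len(mp), len(mm)) >= 4500
        assert ks_2samp(mp, mm).pvalue > 0.01


def test_mirror_dataset_flips_strands_and_reflects_reads(small_dataset):
    genome, genes, _, chip, _ = small_dataset
    mirrored_genes, mirrored = te.mirror_dataset(genome, genes, chip)
    lengths = genome.lengths
    for g, m in zip(genes, mirrored_genes):
        L = lengths[g.chrom]
        assert m.strand != g.strand
        assert (m.tx_start, m.tx_end) == (L - g.tx_end, L - g.tx_start)
        assert m.tss == L - 1 - g.tss
    L = chip["chrom"].map(lengths)
    assert (mirrored["start"] == L - chip["end"]).all()
    assert (mirrored["end"] == L - chip["start"]).all()
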