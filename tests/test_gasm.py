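"""Genotype/annotation I/O and haplotype-marker assembly."""

import numpy as np
import pandas as pd
import pytest

from shadenet import gasm, io, simdata
from shadenet.errors import ParseError, ValidationError
from shadenet.gasm import GeneAnnotation, SNPTable, assemble_gasms, gasm_summary


def _snp_table(matrix, positions, chrom="chr01", line_prefix="L"):
    matrix = np.asarray(matrix, dtype=np.int8)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"{chrom}_{p}" for p in positions]}
    )
    return SNPTable(sites=sites, matrix=matrix, line_ids=[f"{line_prefix}{i}" for i in range(matrix.shape[0])])


def _genes(*intervals, chrom="chr01"):
    recs = [
        {"gene_id": gid, "chrom": chrom, "start": s, "end": e, "strand": "+"}
        for gid, s, e in intervals
    ]
    return GeneAnnotation(pd.DataFrame(recs))


class TestGenotypeIO:
    def test_vcf_and_tsv_roundtrip_identical(self, small_rils, tmp_path):
        io.write_vcf(small_rils, tmp_path / "geno.vcf")
        io.write_genotype_tsv(small_rils, tmp_path / "geno.tsv")
        from_vcf = gasm.read_genotypes(tmp_path / "geno.vcf")
        from_tsv = gasm.read_genotypes(tmp_path / "geno.tsv")
        assert from_vcf.line_ids == from_tsv.line_ids == small_rils.line_ids
        pd.testing.assert_frame_equal(from_vcf.sites, from_tsv.sites)
        assert np.array_equal(from_vcf.matrix, from_tsv.matrix)

    def test_vcf_transcribes_genotypes(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr01,length=50000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "chr01\t100\ts1\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t./.\n"
            "chr01\t200\ts2\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"
        )
        table = gasm.read_genotypes(vcf)
        assert table.line_ids == ["A", "B", "C"]
        # het and uncalled both map to missing
        assert np.array_equal(table.matrix, [[0, -1], [1, 0], [-1, 1]])

    def test_multiallelic_site_skipped_and_counted(self, tmp_path):
        vcf = tmp_path / "tri.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr01,length=50000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "chr01\t100\ts1\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            "chr01\t200\ts2\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t2/2\n"
        )
        table = gasm.read_genotypes(vcf)
        assert len(table.sites) == 1
        assert table.n_skipped_multiallelic == 1

    def test_annotation_dialects_agree(self, small_map, tmp_path):
        io.write_gff3(small_map, tmp_path / "genes.gff3")
        io.write_bed(small_map, tmp_path / "genes.bed")
        from_gff = gasm.read_annotation(tmp_path / "genes.gff3")
        from_bed = gasm.read_annotation(tmp_path / "genes.bed")
        cols = ["gene_id", "chrom", "start", "end"]
        pd.testing.assert_frame_equal(
            from_gff.records[cols].reset_index(drop=True),
            from_bed.records[cols].reset_index(drop=True),
        )


class TestAssembly:
    def test_single_biallelic_snp_gives_two_alleles(self):
        snps = _snp_table([[0], [1], [0], [1]], [150])
        out = assemble_gasms(snps, _genes(("gA", 100, 200)))
        assert len(out) == 1
        assert out[0].n_alleles == 2
        assert set(out[0].codes) == {0, 1}

    def test_recombinant_haplotype_adds_third_allele(self):
        # parents 000 / 111 plus one intra-gene recombinant 001
        snps = _snp_table([[0, 0, 0], [1, 1, 1], [0, 0, 1]], [110, 150, 190])
        out = assemble_gasms(snps, _genes(("gA", 100, 200)), min_lines=1)
        assert out[0].n_alleles == 3
        assert sorted(out[0].alleles) == ["000", "001", "111"]

    def test_monomorphic_gene_dropped(self):
        snps = _snp_table([[0, 0], [0, 0], [0, 0]], [110, 150])
        out = assemble_gasms(snps, _genes(("gA", 100, 200)))
        assert len(out) == 0

    def test_match_or_missing_policy(self):
        # alleles 00 and 11; line with (0, missing) uniquely matches 00;
        # after adding allele 01, (0, missing) becomes ambiguous
        snps = _snp_table([[0, 0], [1, 1], [0, -1]], [110, 150])
        out = assemble_gasms(snps, _genes(("gA", 100, 200)), min_lines=1)
        assert out[0].codes[2] == out[0].codes[0]
        snps2 = _snp_table([[0, 0], [1, 1], [0, 1], [0, -1]], [110, 150])
        out2 = assemble_gasms(snps2, _genes(("gA", 100, 200)), min_lines=1)
        assert out2[0].codes[3] == -1
        strict = assemble_gasms(snps, _genes(("gA", 100, 200)), missing_policy="strict", min_lines=1)
        assert strict[0].codes[2] == -1

    def test_min_lines_filter(self):
        snps = _snp_table([[0], [1], [-1], [-1]], [150])
        kept = assemble_gasms(snps, _genes(("gA", 100, 200)), min_lines=2)
        dropped = assemble_gasms(snps, _genes(("gA", 100, 200)), min_lines=3)
        assert len(kept) == 1 and len(dropped) == 0

    def test_line_order_invariance(self):
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 2, size=(12, 4)).astype(np.int8)
        snps = _snp_table(matrix, [110, 130, 160, 190])
        genes = _genes(("gA", 100, 200))
        base = assemble_gasms(snps, genes, min_lines=1)
        perm = rng.permutation(12)
        shuffled = SNPTable(
            sites=snps.sites.copy(), matrix=matrix[perm], line_ids=[snps.line_ids[i] for i in perm]
        )
        other = assemble_gasms(shuffled, genes, min_lines=1)
        # per-line haplotype strings agree regardless of input order
        for g1, g2 in zip(base, other):
            h1 = {snps.line_ids[i]: g1.alleles[g1.codes[i]] for i in range(12)}
            h2 = {shuffled.line_ids[i]: g2.alleles[g2.codes[i]] for i in range(12)}
            assert h1 == h2

    def test_empty_overlap_warns_and_returns_empty(self, caplog):
        snps = _snp_table([[0], [1]], [150], chrom="chr01")
        out = assemble_gasms(snps, _genes(("gA", 100, 200), chrom="chr99"))
        assert len(out) == 0

    def test_allele_count_bounds(self, small_rils):
        snps = SNPTable.from_rils(small_rils)
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(len(small_rils.gene_ids))],
                    "chrom": small_rils.snp_sites.groupby("locus")["chrom"].first().values,
                    "start": small_rils.snp_sites.groupby("locus")["pos"].min().values - 10,
                    "end": small_rils.snp_sites.groupby("locus")["pos"].max().values + 10,
                    "strand": "+",
                }
            )
        )
        out = assemble_gasms(snps, genes)
        # biparental panel without intra-gene recombination: exactly 2 alleles
        assert all(g.n_alleles == 2 for g in out)


class TestSummaryAndRoundTrip:
    def test_summary_counts(self):
        snps = _snp_table([[0, 0, 1, 0, 1], [1, 1, 0, 1, 0], [0, 1, 1, 0, 0]], [110, 310, 510, 710, 910])
        genes = _genes(("g1", 100, 200), ("g2", 300, 400), ("g3", 500, 600),
                       ("g4", 700, 800), ("g5", 900, 1000))
        out = assemble_gasms(snps, genes, min_lines=1)
        summary = gasm_summary(out)
        assert summary["total"] == 5
        assert summary["per_chrom"] == {"chr01": 5}
        assert gasm_summary(gasm.GASMSet([], []))["total"] == 0

    def test_simulated_genome_marker_count_matches_truth(self, small_map, small_rils):
        snps = SNPTable.from_rils(small_rils)
        genes = GeneAnnotation.from_map(small_map)
        out = assemble_gasms(snps, genes)
        src = small_rils.sources
        # polymorphic = both parental sources observed among fixed lines
        polymorphic = sum(
            len(np.unique(src[(src[:, j] == 0) | (src[:, j] == 1), j])) == 2
            for j in range(src.shape[1])
        )
        assert gasm_summary(out)["total"] == polymorphic

    def test_marker_tsv_roundtrip(self, small_rils, tmp_path):
        markers = gasm.GASMSet.from_rils(small_rils)
        gasm.write_gasm_tsv(markers, tmp_path / "markers.tsv")
        back = gasm.read_gasm_tsv(tmp_path / "markers.tsv")
        assert back.line_ids == markers.line_ids
        assert back.gene_ids == markers.gene_ids
        assert np.array_equal(back.codes_matrix(), markers.codes_matrix())
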