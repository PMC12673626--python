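import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoscan.errors import InputError
from cytoscan.genome import (
    CytoBandRecord,
    GeneRecord,
    GenomeAnnotation,
    MajorBand,
    VariantSite,
    assign_genes,
    assign_variants,
    classify_variant_context,
    collapse_to_major_bands,
    dedup_variants,
    parse_cytoband,
    read_bands_bed,
    read_genes_tsv,
    read_variants_bed,
    read_variants_tsv,
    write_bands_bed,
)
from cytoscan.simulate import SimulationConfig, make_genome, simulate_variants


class TestParseCytoband:
    def test_direct_field_mapping(self):
        recs = parse_cytoband(io.StringIO("chr8\t117700000\t127300000\tq24.1\tqneg\n"))
        (r,) = recs
        assert (r.chrom, r.start, r.end, r.name) == ("8", 117700000, 127300000, "q24.1")
        assert r.stain == "qneg"

    def test_chr_prefix_stripped(self):
        (r,) = parse_cytoband(io.StringIO("chrX\t0\t4400000\tp22.33\tgneg\n"))
        assert r.chrom == "X"

    def test_stain_optional(self):
        (r,) = parse_cytoband(io.StringIO("chr1\t0\t100\tp11\n"))
        assert r.stain == ""

    def test_empty_input_rejected(self):
        with pytest.raises(InputError, match="empty"):
            parse_cytoband(io.StringIO(""))

    def test_start_ge_end_names_line(self):
        text = "chr1\t0\t100\tp11\tgneg\nchr1\t200\t100\tp12\tgneg\n"
        with pytest.raises(InputError, match="line 2"):
            parse_cytoband(io.StringIO(text))

    def test_too_few_fields_names_line(self):
        with pytest.raises(InputError, match="line 1"):
            parse_cytoband(io.StringIO("chr1\t0\t100\n"))

    def test_non_integer_coordinate(self):
        with pytest.raises(InputError, match="line 1"):
            parse_cytoband(io.StringIO("chr1\tzero\t100\tp11\tgneg\n"))

    def test_full_fixture_line_count_equals_record_count(self, tmp_path):
        path = tmp_path / "cytoband.tsv"
        make_genome(SimulationConfig(seed=1), cytoband_path=path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        with open(path) as fh:
            records = parse_cytoband(fh)
        assert len(records) == len(lines)
        assert len(records) > 322  # sub-band splitting happened


class TestCollapseToMajorBands:
    def test_adjacent_subbands_merge(self):
        recs = [
            CytoBandRecord("8", 100, 200, "q24.1"),
            CytoBandRecord("8", 200, 350, "q24.2"),
            CytoBandRecord("8", 350, 500, "q24.3"),
        ]
        ann = collapse_to_major_bands(recs)
        (band,) = ann.bands
        assert band.band_id == "8q24"
        assert (band.start, band.end) == (100, 500)

    def test_name_without_dot_passes_through(self):
        ann = collapse_to_major_bands([CytoBandRecord("9", 0, 100, "p11")])
        assert ann.bands[0].band_id == "9p11"

    def test_non_contiguous_constituents_rejected(self):
        recs = [
            CytoBandRecord("8", 100, 200, "q24.1"),
            CytoBandRecord("8", 300, 400, "q24.2"),  # gap
        ]
        with pytest.raises(InputError, match="not contiguous"):
            collapse_to_major_bands(recs)

    def test_fixture_checksum_total_length_preserved(self, tmp_path):
        path = tmp_path / "cytoband.tsv"
        make_genome(SimulationConfig(seed=3), cytoband_path=path)
        with open(path) as fh:
            records = parse_cytoband(fh)
        ann = collapse_to_major_bands(records)
        assert ann.total_length_bp == sum(r.length_bp for r in records)
        # each major band length equals the sum of its constituents
        by_major = {}
        for r in records:
            key = f"{r.chrom}{r.major_name}"
            by_major[key] = by_major.get(key, 0) + r.length_bp
        for band in ann:
            assert band.length_bp == by_major[band.band_id]

    def test_duplicate_band_ids_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            GenomeAnnotation(
                [MajorBand("1p11", "1", 0, 10), MajorBand("1p11", "1", 20, 30)]
            )

    def test_overlapping_bands_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            GenomeAnnotation(
                [MajorBand("1p11", "1", 0, 100), MajorBand("1p12", "1", 50, 150)]
            )


class TestDedupVariants:
    def test_duplicate_ids_removed_first_kept(self):
        vs = [
            VariantSite("1", 100, "rs1"),
            VariantSite("1", 100, "rs1"),
            VariantSite("1", 200, "rs2"),
        ]
        out = dedup_variants(vs)
        assert len(out) == 2
        assert [v.variant_id for v in out] == ["rs1", "rs2"]

    def test_empty_input(self):
        assert dedup_variants([]) == []

    def test_missing_ids_deduped_by_position(self):
        vs = [VariantSite("1", 100), VariantSite("1", 100), VariantSite("1", 101)]
        assert len(dedup_variants(vs)) == 2

    def test_planted_duplicates_1796_to_1346(self, default_genome):
        variants = simulate_variants(
            default_genome, 1346, seed=7, n_duplicates=450
        )
        assert len(variants) == 1796
        assert len(dedup_variants(variants)) == 1346


class TestAssignVariants:
    def test_first_base_of_band(self, toy_annotation):
        counts, unassigned = assign_variants(
            [VariantSite("1", 1, "rs1")], toy_annotation
        )
        assert counts["1p11"] == 1 and not unassigned

    def test_shared_boundary_goes_to_left_band(self, toy_annotation):
        # 1-based pos 1_000_000 is the last base of 1p11 under start < p <= end
        counts, _ = assign_variants([VariantSite("1", 1_000_000, "rs1")], toy_annotation)
        assert counts["1p11"] == 1 and counts["1q11"] == 0

    def test_past_end_unassigned(self, toy_annotation):
        counts, unassigned = assign_variants(
            [VariantSite("2", 3_000_001, "rs1")], toy_annotation
        )
        assert sum(counts.values()) == 0 and len(unassigned) == 1

    def test_unknown_chromosome_unassigned(self, toy_annotation):
        counts, unassigned = assign_variants([VariantSite("17", 5, "rs1")], toy_annotation)
        assert len(unassigned) == 1

    def test_conservation_uniform_toy(self, toy_annotation):
        rng = np.random.default_rng(0)
        vs = [
            VariantSite("1", int(p), f"rs{i}")
            for i, p in enumerate(rng.integers(1, 2_000_001, size=100))
        ]
        counts, unassigned = assign_variants(vs, toy_annotation)
        assert sum(counts.values()) == 100 and not unassigned
        # brute-force enumeration agrees
        brute = sum(1 for v in vs if 0 < v.pos <= 1_000_000)
        assert counts["1p11"] == brute

    def test_empty_annotation_rejected(self):
        with pytest.raises(InputError):
            assign_variants([], GenomeAnnotation([]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 400))
    def test_conservation_property(self, default_genome, n):
        vs = simulate_variants(default_genome, n, seed=n)
        counts, unassigned = assign_variants(vs, default_genome)
        assert sum(counts.values()) + len(unassigned) == n


class TestAssignGenes:
    def test_midpoint_rule_single_band(self, toy_annotation):
        # straddles the 1p11/1q11 boundary, midpoint at 1_100_000 -> 1q11
        g = GeneRecord("G1", "1", 900_000, 1_300_000)
        (out,) = assign_genes([g], toy_annotation)
        assert out.band_id == "1q11"

    def test_outside_annotation_is_none(self, toy_annotation):
        (out,) = assign_genes([GeneRecord("G1", "9", 0, 10)], toy_annotation)
        assert out.band_id is None


def _brute_force_context(variants, gene_spans, exon_spans):
    labels = []
    for v in variants:
        p0 = v.pos - 1
        genic = any(c == v.chrom and s <= p0 < e for c, s, e in gene_spans)
        exonic = any(c == v.chrom and s <= p0 < e for c, s, e in exon_spans)
        if not genic:
            labels.append("intergenic")
        elif exonic:
            labels.append("genic_exonic")
        else:
            labels.append("genic_intronic")
    return labels


class TestClassifyVariantContext:
    GENES = [("1", 100, 500), ("1", 800, 1200), ("2", 0, 300)]
    EXONS = [("1", 100, 150), ("1", 400, 500), ("1", 900, 1000), ("2", 50, 100)]

    def test_intronic_by_definition(self):
        labels, summary = classify_variant_context(
            [VariantSite("1", 201)], self.GENES, self.EXONS
        )
        assert labels == ["genic_intronic"]
        assert summary["genic_intronic"] == 1

    def test_intergenic_by_definition(self):
        labels, _ = classify_variant_context([VariantSite("1", 700)], self.GENES, self.EXONS)
        assert labels == ["intergenic"]

    def test_counts_sum_to_input(self):
        rng = np.random.default_rng(5)
        vs = [VariantSite("1", int(p)) for p in rng.integers(1, 1500, size=40)]
        labels, summary = classify_variant_context(vs, self.GENES, self.EXONS)
        assert sum(summary.values()) == len(vs) == len(labels)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            genes, exons = [], []
            for _ in range(rng.integers(1, 10)):
                chrom = str(rng.integers(1, 3))
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(50, 800))
                genes.append((chrom, s, e))
                xs = s + int(rng.integers(0, (e - s) // 2))
                exons.append((chrom, xs, xs + int(rng.integers(1, (e - s) // 2 + 1))))
            vs = [
                VariantSite(str(rng.integers(1, 3)), int(p))
                for p in rng.integers(1, 6000, size=int(rng.integers(1, 50)))
            ]
            labels, _ = classify_variant_context(vs, genes, exons)
            assert labels == _brute_force_context(vs, genes, exons)

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(InputError, match="nested"):
            classify_variant_context([], [("1", 0, 100)], [("1", 50, 200)])

    def test_overlapping_genes_no_double_count(self):
        genes = [("1", 0, 100), ("1", 50, 200)]
        labels, summary = classify_variant_context([VariantSite("1", 75)], genes, [])
        assert labels == ["genic_intronic"] and sum(summary.values()) == 1


class TestRoundTripsAndReaders:
    def test_bed_round_trip(self, default_genome):
        buf = io.StringIO()
        write_bands_bed(default_genome, buf)
        buf.seek(0)
        again = read_bands_bed(buf)
        assert again.bands == default_genome.bands
        assert again.total_length_bp == default_genome.total_length_bp

    def test_variants_tsv_header_tolerated(self):
        text = "chrom\tpos\tvariant_id\nchr1\t100\trs1\n"
        (v,) = read_variants_tsv(io.StringIO(text))
        assert (v.chrom, v.pos, v.variant_id) == ("1", 100, "rs1")

    def test_variants_bed_converts_to_1based(self):
        (v,) = read_variants_bed(io.StringIO("chr1\t99\t100\trs1\n"))
        assert v.pos == 100

    def test_genes_tsv(self):
        text = "gene_id\tchrom\tstart\tend\tstrand\tcds_length\nG1\tchr2\t10\t500\t-\t300\n"
        (g,) = read_genes_tsv(io.StringIO(text))
        assert (g.gene_id, g.chrom, g.start, g.end, g.strand, g.cds_length_bp) == (
            "G1", "2", 10, 500, "-", 300,
        )

    def test_negative_position_rejected(self):
        with pytest.raises(InputError):
            VariantSite("1", 0)
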