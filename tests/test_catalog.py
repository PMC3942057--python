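"""SNV parsing, context extraction, catalog construction, stratification."""

import numpy as np
import pytest

from mutsig96.catalog import (
    IntervalSet,
    MutationCatalog,
    MutationRecord,
    build_catalog,
    parse_mutations,
    parse_mutations_with_stats,
    pyrimidine_context,
    stratify_by_intervals,
    write_maf_lite,
)
from mutsig96.errors import DataIntegrityError, ValidationError


class TestMutationRecord:
    def test_rejects_non_snv_alleles(self):
        with pytest.raises(ValidationError):
            MutationRecord("S1", "chr1", 10, "CA", "C")

    def test_rejects_ref_equals_alt(self):
        with pytest.raises(ValidationError):
            MutationRecord("S1", "chr1", 10, "C", "C")

    def test_strand_flip_is_involutive(self):
        rec = MutationRecord("S1", "chr1", 10, "C", "T")
        assert rec.strand_flipped().strand_flipped() == rec


class TestMafLiteParsing:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("S1\tchr1\t1000\tC\tT\n")
        recs = parse_mutations(p, "maf-lite")
        assert recs == [MutationRecord("S1", "chr1", 1000, "C", "T")]

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tchrom\tpos\tref\talt\nS1\tchr1\t1000\tC\tT\n")
        assert len(parse_mutations(p, "maf-lite")) == 1

    def test_indel_skipped_and_counted(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("S1\tchr1\t1000\tCA\tC\nS1\tchr1\t2000\tC\tG\n")
        recs, stats = parse_mutations_with_stats(p, "maf-lite")
        assert len(recs) == 1
        assert stats["skipped_non_snv"] == 1

    def test_empty_file_is_empty_list(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        assert parse_mutations(p, "maf-lite") == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("S1\tchr1\t1000\tC\tT\nS1\tchr1\toops\tC\tT\n")
        with pytest.raises(ValidationError, match=":2"):
            parse_mutations(p, "maf-lite")

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        with pytest.raises(ValidationError):
            parse_mutations(p, "bedpe")

    def test_maf_roundtrip(self, tmp_path):
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S2", "chr1", 8, "G", "A"),
        ]
        p = tmp_path / "out.maf.tsv"
        write_maf_lite(recs, p)
        assert parse_mutations(p, "maf-lite") == recs


class TestVcfParsing:
    def _write_vcf(self, path, body, samples=("S1", "S2")):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)

    def test_multisample_expansion(self, tmp_path):
        p = tmp_path / "v.vcf"
        self._write_vcf(p, "chr1\t4\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
                           "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/1\n")
        recs = parse_mutations(p, "vcf")
        assert recs == [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S1", "chr1", 10, "A", "C"),
            MutationRecord("S2", "chr1", 10, "A", "C"),
        ]

    def test_indel_skipped(self, tmp_path):
        p = tmp_path / "v.vcf"
        self._write_vcf(p, "chr1\t4\t.\tCA\tC\t.\tPASS\t.\tGT\t0/1\t0/1\n")
        recs, stats = parse_mutations_with_stats(p, "vcf")
        assert recs == []
        assert stats["skipped_non_snv"] == 1


class TestPyrimidineContext:
    def test_forward_strand(self, tiny_genome):
        rec = MutationRecord("S1", "chr1", 4, "C", "T")  # context ACG
        assert pyrimidine_context(tiny_genome, rec) == "A(C>T)G"

    def test_purine_reference_collapsed(self, tiny_genome):
        rec = MutationRecord("S1", "chr1", 8, "G", "A")  # context AGT -> ACT
        assert pyrimidine_context(tiny_genome, rec) == "A(C>T)T"

    def test_ref_mismatch_raises(self, tiny_genome):
        rec = MutationRecord("S1", "chr1", 4, "T", "A")
        with pytest.raises(DataIntegrityError, match="mismatch"):
            pyrimidine_context(tiny_genome, rec)

    def test_contig_edge_raises(self, tiny_genome):
        rec = MutationRecord("S1", "chr1", 1, "T", "A")
        with pytest.raises(DataIntegrityError):
            pyrimidine_context(tiny_genome, rec)

    def test_ambiguous_context_raises(self):
        genome = {"chr1": "ANCGT"}
        rec = MutationRecord("S1", "chr1", 3, "C", "T")
        with pytest.raises(ValidationError, match="ambiguous"):
            pyrimidine_context(genome, rec)

    def test_strand_flip_same_category(self, tiny_genome):
        # flipped representation of chr1:4 C>T is G>A on the reverse strand;
        # same genomic event reported from the purine strand at chr1:8
        direct = pyrimidine_context(tiny_genome, MutationRecord("S1", "chr1", 4, "C", "T"))
        # build the reverse-strand version of the same mutation explicitly:
        flipped = pyrimidine_context(tiny_genome, MutationRecord("S1", "chr1", 23, "C", "T"))
        assert direct == flipped == "A(C>T)G"


class TestBuildCatalog:
    def test_single_sample_column_sum(self, tiny_genome):
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S1", "chr1", 8, "G", "A"),
            MutationRecord("S1", "chr1", 19, "C", "A"),
        ]
        catalog = build_catalog(recs, tiny_genome)
        assert catalog.sample_ids == ["S1"]
        assert catalog.counts.sum() == 3

    def test_duplicates_counted_once(self, tiny_genome):
        rec = MutationRecord("S1", "chr1", 4, "C", "T")
        catalog = build_catalog([rec, rec], tiny_genome)
        assert catalog.counts.sum() == 1
        assert catalog.provenance["n_duplicates"] == 1

    def test_first_appearance_column_order(self, tiny_genome):
        recs = [
            MutationRecord("B", "chr1", 4, "C", "T"),
            MutationRecord("A", "chr1", 8, "G", "A"),
            MutationRecord("B", "chr1", 19, "C", "A"),
        ]
        assert build_catalog(recs, tiny_genome).sample_ids == ["B", "A"]

    def test_no_valid_records_raises(self, tiny_genome):
        with pytest.raises(ValidationError):
            build_catalog([], tiny_genome)
        bad = [MutationRecord("S1", "chr1", 1, "T", "A")]  # contig edge only
        with pytest.raises(ValidationError):
            build_catalog(bad, tiny_genome)

    def test_bad_records_tallied_not_fatal(self, tiny_genome):
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S1", "chr1", 4, "A", "T"),  # ref mismatch
        ]
        catalog = build_catalog(recs, tiny_genome)
        assert catalog.counts.sum() == 1
        assert catalog.provenance["n_ref_mismatch_or_edge"] == 1

    def test_strand_invariance_of_catalog(self, tiny_genome):
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S1", "chr1", 8, "G", "A"),
            MutationRecord("S1", "chr1", 19, "C", "A"),
        ]
        direct = build_catalog(recs, tiny_genome)
        # a record's category must not depend on which strand reported it:
        # flipping ref/alt makes the record mismatch the reference, so
        # instead verify the collapse at the category level per record
        for rec in recs:
            cat_direct = pyrimidine_context(tiny_genome, rec)
            assert direct.counts[direct.scheme.index(cat_direct),
                                 direct.sample_ids.index(rec.sample_id)] >= 1

    def test_column_sums_equal_retained_records(self, tiny_genome):
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S2", "chr1", 8, "G", "A"),
            MutationRecord("S2", "chr1", 19, "C", "A"),
        ]
        catalog = build_catalog(recs, tiny_genome)
        assert list(catalog.counts.sum(axis=0)) == [1, 2]


class TestIntervalSet:
    def test_merge_and_contains(self):
        ivs = IntervalSet({"chr1": [(10, 20), (15, 30), (40, 50)]})
        assert ivs.intervals("chr1") == [(10, 30), (40, 50)]
        assert ivs.contains("chr1", 10)
        assert ivs.contains("chr1", 29)
        assert not ivs.contains("chr1", 30)
        assert not ivs.contains("chr2", 10)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            IntervalSet({"chr1": [(10, 10)]})

    def test_bed_roundtrip(self, tmp_path):
        ivs = IntervalSet({"chr1": [(0, 10)], "chr2": [(5, 8)]})
        p = tmp_path / "t.bed"
        ivs.to_bed(p)
        back = IntervalSet.from_bed(p)
        assert back.intervals("chr1") == [(0, 10)]
        assert back.intervals("chr2") == [(5, 8)]


class TestStratify:
    def test_examples(self, tiny_genome):
        ivs = IntervalSet({"chr1": [(0, 10)]})
        inside_rec = MutationRecord("S1", "chr1", 4, "C", "T")  # A(C>T)G, pos0 3 inside
        outside_rec = MutationRecord("S1", "chr1", 23, "C", "T")  # A(C>T)G outside
        nonmatch_rec = MutationRecord("S1", "chr1", 19, "C", "A")  # A(C>A)G
        inside, outside, other = stratify_by_intervals(
            [inside_rec, outside_rec, nonmatch_rec], tiny_genome, ivs
        )
        assert inside == [inside_rec]
        assert outside == [outside_rec]
        assert other == [nonmatch_rec]

    def test_partition_property(self, tiny_genome):
        ivs = IntervalSet({"chr1": [(0, 10)]})
        recs = [
            MutationRecord("S1", "chr1", 4, "C", "T"),
            MutationRecord("S1", "chr1", 8, "G", "A"),
            MutationRecord("S2", "chr1", 19, "C", "A"),
            MutationRecord("S2", "chr1", 23, "C", "T"),
        ]
        inside, outside, other = stratify_by_intervals(recs, tiny_genome, ivs)
        combined = inside + outside + other
        assert sorted(map(repr, combined)) == sorted(map(repr, recs))
        assert len(combined) == len(recs)

    def test_empty_predicate_match(self, tiny_genome):
        ivs = IntervalSet({"chr1": [(0, 10)]})
        recs = [MutationRecord("S1", "chr1", 19, "C", "A")]
        inside, outside, other = stratify_by_intervals(
            recs, tiny_genome, ivs, pattern=lambda lab: False
        )
        assert inside == [] and outside == [] and other == recs


class TestCatalogIO:
    def test_tsv_roundtrip(self, small_catalog, tmp_path):
        p = tmp_path / "cat.tsv"
        small_catalog.write_tsv(p)
        back = MutationCatalog.read_tsv(p)
        assert back.sample_ids == small_catalog.sample_ids
        assert np.array_equal(back.counts, small_catalog.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            MutationCatalog(counts=-np.ones((96, 1), dtype=int), sample_ids=["S1"])
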