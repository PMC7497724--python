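"""GEN line parsing, dialect detection, streaming, and .sample reading."""

import gzip
import io

import pytest

from gen2vcf.config import ConversionStats
from gen2vcf.errors import MalformedLine, MalformedSampleFile
from gen2vcf.gen_io import (
    FIVE_COLUMN,
    SIX_COLUMN,
    GenDialect,
    detect_dialect,
    parse_gen_line,
    read_sample_file,
    stream_gen,
)


class TestDetectDialect:
    @pytest.mark.parametrize(
        "token_count,declared,leading",
        [
            (11, None, 5),  # 5 + 3*2
            (12, None, 6),  # 6 + 3*2
            (11, 2, 5),
            (12, 2, 6),
            (8, 1, 5),
            (9, 1, 6),
        ],
    )
    def test_resolves_unique_layout(self, token_count, declared, leading):
        assert detect_dialect(token_count, declared).leading_columns == leading

    @pytest.mark.parametrize("token_count", [13, 10, 7, 4])
    def test_rejects_impossible_counts(self, token_count):
        # mod 3 == 1 fits neither layout; < 8 is below the one-sample minimum
        with pytest.raises(MalformedLine):
            detect_dialect(token_count)

    def test_rejects_contradicting_declared_samples(self):
        with pytest.raises(MalformedLine):
            detect_dialect(11, declared_samples=3)

    def test_total_and_unambiguous_over_all_sample_counts(self):
        for n in range(1, 501):
            assert detect_dialect(5 + 3 * n) == FIVE_COLUMN
            assert detect_dialect(6 + 3 * n) == SIX_COLUMN
            if 4 + 3 * n >= 8:
                with pytest.raises(MalformedLine):
                    detect_dialect(4 + 3 * n)

    def test_dialect_invariants(self):
        assert SIX_COLUMN.has_chrom_column and not FIVE_COLUMN.has_chrom_column
        with pytest.raises(ValueError):
            GenDialect(4)


class TestParseGenLine:
    def test_six_column_positional_mapping(self):
        rec = parse_gen_line("1 snp1 rs1 1000 A G 1 0 0", SIX_COLUMN, 1, 1)
        assert (rec.chrom, rec.varid, rec.rsid) == ("1", "snp1", "rs1")
        assert (rec.pos, rec.allele_a, rec.allele_b) == (1000, "A", "G")
        assert rec.probs.tolist() == [[1.0, 0.0, 0.0]]

    def test_five_column_leaves_chrom_unset(self):
        rec = parse_gen_line("snp1 rs1 1000 A G 0 0 0", FIVE_COLUMN, 1, 1)
        assert rec.chrom is None
        assert rec.probs.tolist() == [[0.0, 0.0, 0.0]]

    @pytest.mark.parametrize(
        "line",
        [
            "snp1 rs1 1000 A G 0.5 x 0.5",  # non-numeric probability
            "snp1 rs1 1000 A G 0.5 0.5",  # wrong token count
            "snp1 rs1 10.5 A G 1 0 0",  # non-integer position
            "snp1 rs1 0 A G 1 0 0",  # non-positive position
            "snp1 rs1 1000 A G 1 0 nan",  # non-finite probability
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, line):
        with pytest.raises(MalformedLine) as exc_info:
            parse_gen_line(line, FIVE_COLUMN, 1, line_number=42)
        assert exc_info.value.line_number == 42

    def test_strict_rejects_negative_probability(self):
        with pytest.raises(MalformedLine):
            parse_gen_line(
                "snp1 rs1 1000 A G -0.1 0.6 0.5", FIVE_COLUMN, 1, 1, strict=True
            )

    def test_lenient_clamps_and_counts(self):
        stats = ConversionStats()
        rec = parse_gen_line(
            "snp1 rs1 1000 A G -0.1 0.6 1.2",
            FIVE_COLUMN, 1, 1, strict=False, stats=stats,
        )
        assert rec.probs.tolist() == [[0.0, 0.6, 1.0]]
        assert stats.clamped_probabilities == 2

    def test_rounding_noise_above_one_is_clamped_even_in_strict(self):
        # 1 + 5e-7 is within the 1e-6 print-rounding tolerance
        stats = ConversionStats()
        rec = parse_gen_line(
            "snp1 rs1 1000 A G 1.0000005 0 0",
            FIVE_COLUMN, 1, 1, strict=True, stats=stats,
        )
        assert rec.probs[0, 0] == 1.0
        assert stats.clamped_probabilities == 1

    def test_reserialization_reproduces_probability_tokens(self, tiny_fixture):
        """Parsing is positionally faithful: writing the parsed probabilities
        back at the generator's precision reproduces the file's tokens."""
        with open(tiny_fixture.gen_path) as fh:
            for number, line in enumerate(fh, start=1):
                rec = parse_gen_line(line, SIX_COLUMN, 3, number)
                tokens = line.split()[6:]
                rendered = [
                    f"{p:.3f}" for row in rec.probs for p in row
                ]
                assert rendered == tokens


class TestStreamGen:
    def test_yields_every_line_in_order(self, gen_lines):
        records = list(stream_gen(io.StringIO(gen_lines)))
        assert [r.rsid for r in records] == ["rs1", "rs2", "rs3"]
        assert [r.line_number for r in records] == [1, 2, 3]

    def test_empty_stream_yields_nothing(self):
        assert list(stream_gen(io.StringIO(""))) == []

    def test_blank_lines_skipped_and_counted(self, gen_lines):
        stats = ConversionStats()
        text = "\n" + gen_lines.replace("2000", "2000", 1) + "\n\n"
        records = list(stream_gen(io.StringIO(text), stats=stats))
        assert len(records) == 3
        assert stats.blank_lines == 3

    def test_lenient_skips_bad_line_and_counts(self, gen_lines):
        stats = ConversionStats()
        text = gen_lines + "1 snp4 rs4 4000 A G 0.5\n"  # truncated
        records = list(stream_gen(io.StringIO(text), strict=False, stats=stats))
        assert len(records) == 3
        assert stats.malformed_lines == 1

    def test_strict_aborts_on_bad_line(self, gen_lines):
        text = gen_lines + "1 snp4 rs4 4000 A G 0.5\n"
        with pytest.raises(MalformedLine):
            list(stream_gen(io.StringIO(text)))

    def test_sample_count_locked_by_first_line(self):
        # second line has a different sample count -> ragged file
        text = "1 s1 r1 100 A G 1 0 0\n1 s2 r2 200 A G 1 0 0 0 1 0\n"
        with pytest.raises(MalformedLine):
            list(stream_gen(io.StringIO(text)))

    def test_declared_sample_count_checked_against_first_line(self, gen_lines):
        with pytest.raises(MalformedLine):
            list(stream_gen(io.StringIO(gen_lines), expected_samples=5))

    def test_reads_gzip_compressed_path(self, tmp_path, gen_lines):
        path = tmp_path / "input.gen.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(gen_lines)
        records = list(stream_gen(path))
        assert len(records) == 3
        assert records[1].pos == 2000

    def test_conservation_on_generated_fixture(self, tiny_fixture):
        n_lines = sum(1 for _ in open(tiny_fixture.gen_path))
        records = list(stream_gen(tiny_fixture.gen_path))
        assert len(records) == n_lines == 8
        positions = [r.pos for r in records]
        assert positions == sorted(positions)


class TestReadSampleFile:
    def _write(self, tmp_path, text):
        path = tmp_path / "cohort.sample"
        path.write_text(text)
        return path

    def test_two_data_rows(self, tmp_path):
        path = self._write(
            tmp_path,
            "ID_1 ID_2 missing sex\n0 0 0 D\nfam1 ind1 0.01 1\nfam2 ind2 0 2\n",
        )
        samples = read_sample_file(path)
        assert [(s.id_1, s.id_2) for s in samples] == [
            ("fam1", "ind1"), ("fam2", "ind2"),
        ]
        assert samples[0].missing == "0.01"
        assert samples[0].extra_columns == ["1"]

    def test_header_and_type_line_only_gives_empty_list(self, tmp_path):
        path = self._write(tmp_path, "ID_1 ID_2 missing\n0 0 0\n")
        assert read_sample_file(path) == []

    def test_single_line_file_is_malformed(self, tmp_path):
        path = self._write(tmp_path, "ID_1 ID_2 missing\n")
        with pytest.raises(MalformedSampleFile):
            read_sample_file(path)

    def test_short_row_is_malformed(self, tmp_path):
        path = self._write(
            tmp_path, "ID_1 ID_2 missing\n0 0 0\nfam1 ind1\n"
        )
        with pytest.raises(MalformedSampleFile):
            read_sample_file(path)
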