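"""Alignment I/O, cleaning rules, and codon encoding."""

import numpy as np
import pytest

from omegascan import (
    CleaningPolicy,
    RawAlignment,
    clean_alignment,
    decode_codons,
    encode_codons,
    read_fasta_alignment,
    write_fasta_alignment,
)
from omegascan.alignment import (
    AlignmentFormatError,
    AlignmentShapeError,
    DegenerateAlignmentError,
)
from omegascan.genetics import MISSING, STANDARD_CODE


class TestGeneticCode:
    def test_sense_codon_ordering(self, code):
        # independent enumeration: all 64 triplets minus the three stops,
        # lexicographic in A<C<G<T
        import itertools

        all_triplets = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        expected = [t for t in all_triplets if t not in ("TAA", "TAG", "TGA")]
        assert list(code.sense_codons) == expected
        assert code.index("AAA") == 0
        assert code.stop_codons == ("TAA", "TAG", "TGA")

    def test_synonymy_matches_translation(self, code):
        i, j = code.index("AAA"), code.index("AAG")  # Lys, Lys
        k = code.index("AAC")  # Asn
        assert code.is_synonymous(i, j)
        assert not code.is_synonymous(i, k)


class TestFastaIO:
    def test_parse_and_round_trip(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">tax_one\nATGAAA-CCTGA\n>tax_two\natgaaatcctga\n>tax3\nATGAANNCCTGA\n")
        aln = read_fasta_alignment(fa)
        assert aln.taxa == ["tax_one", "tax_two", "tax3"]
        assert aln.n_columns == 12
        assert aln.rows[1] == "ATGAAATCCTGA"  # uppercased
        assert aln.rows[0][6] == "-"  # gaps preserved
        out = tmp_path / "b.fasta"
        write_fasta_alignment(aln, out)
        again = read_fasta_alignment(out)
        assert again.taxa == aln.taxa and again.rows == aln.rows

    def test_unequal_lengths_name_offender(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">x\nATGAAACCTGAT\n>bad_taxon\nATGAAACCTGA\n")
        with pytest.raises(AlignmentShapeError, match="bad_taxon"):
            read_fasta_alignment(fa)

    def test_empty_file_is_format_error(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_fasta_alignment(fa)

    def test_ambiguity_codes_fold_to_n(self, tmp_path, caplog):
        fa = tmp_path / "a.fasta"
        fa.write_text(">x\nATGRAA\n>y\nATGCAA\n")
        aln = read_fasta_alignment(fa)
        assert aln.rows[0] == "ATGNAA"

    def test_non_iupac_symbol_rejected(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">x\nATG*AA\n>y\nATGCAA\n")
        with pytest.raises(AlignmentFormatError):
            read_fasta_alignment(fa)


class TestCleaning:
    def test_single_nt_insertion_column_removed(self, code):
        # one taxon has a base where everyone else gaps: frameshift insertion
        raw = RawAlignment(
            taxa=[f"t{i}" for i in range(12)],
            rows=["ATGAAA-CCCTGG"] * 11 + ["ATGAAATCCCTGG"],
        )
        cleaned, log = clean_alignment(raw, code)
        assert len(cleaned.codon_rows[0]) == 12
        assert len(cleaned.codon_rows[0]) % 3 == 0
        assert any(r.rule == "frameshift_insertion" for r in log)

    def test_lineage_specific_inframe_insertion_removed(self, code):
        # a 6-nt in-frame insertion carried by a single lineage
        base = "ATGAAA" + "-" * 6 + "CCCTGG"
        carrier = "ATGAAA" + "TTTTTT" + "CCCTGG"
        raw = RawAlignment(
            taxa=[f"t{i}" for i in range(12)], rows=[base] * 11 + [carrier]
        )
        cleaned, log = clean_alignment(raw, code)
        assert len(cleaned.codon_rows[0]) == 12
        assert any(r.rule == "lineage_specific_insertion" for r in log)

    def test_stop_codon_site_removed_for_all(self, code):
        rows = ["ATGAAACCCGGGTTTAAACCCTAGAAG"] * 2 + ["ATGAAACCCGGGTTTAAATGATAGAAG"]
        # taxon 3 has TGA at codon site 7; column-wise removal hits all taxa
        raw = RawAlignment(taxa=["a", "b", "c"], rows=rows)
        cleaned, log = clean_alignment(raw, code)
        stops = [r for r in log if r.rule == "stop_codon_site"]
        assert {tuple(r.columns) for r in stops} >= {(19, 20, 21), (22, 23, 24)}
        assert cleaned.n_sites == 7
        assert all("TGA" not in _frame_codons(r) and "TAG" not in _frame_codons(r)
                   for r in cleaned.codon_rows)

    def test_cleaning_is_idempotent(self, small_sim, code):
        first = small_sim["codon_aln"]
        raw = RawAlignment(taxa=first.taxa, rows=list(first.codon_rows))
        second, log = clean_alignment(raw, code)
        assert second.codon_rows == first.codon_rows
        assert not log

    def test_all_stop_sites_degenerate(self, code):
        raw = RawAlignment(taxa=["a", "b"], rows=["TGATAG", "TGATAG"])
        with pytest.raises(DegenerateAlignmentError):
            clean_alignment(raw, code)

    def test_frame_anchor_out_of_bounds(self, code):
        raw = RawAlignment(taxa=["a", "b"], rows=["ATGAAA", "ATGAAA"])
        raw.frame_anchor = 7
        with pytest.raises(IndexError):
            clean_alignment(raw, code)


def _frame_codons(row):
    return {row[i : i + 3] for i in range(0, len(row), 3)}


class TestEncoding:
    def test_encode_known_codons(self, code):
        from omegascan.alignment import CodonAlignment

        aln = CodonAlignment(taxa=["x", "y"], codon_rows=["AAAA-GTTT", "ANAAAGGGG"])
        enc = encode_codons(aln, code)
        assert enc[0, 0] == 0  # AAA is the first sense codon
        assert enc[0, 1] == MISSING  # gap inside triplet
        assert enc[1, 0] == MISSING  # N inside triplet
        assert enc[1, 1] == code.index("AAG")

    def test_stop_after_cleaning_is_internal_error(self, code):
        from omegascan.alignment import CodonAlignment

        aln = CodonAlignment(taxa=["x", "y"], codon_rows=["TAAAAA", "AAAAAA"])
        with pytest.raises(ValueError, match="stop"):
            encode_codons(aln, code)

    def test_decode_inverts_encode(self, small_sim, code):
        aln = small_sim["codon_aln"]
        enc = encode_codons(aln, code)
        dec = decode_codons(enc, code)
        assert dec == list(aln.codon_rows)  # no MISSING in this simulation
        assert set(np.unique(enc)) <= set(range(61)) | {MISSING}
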