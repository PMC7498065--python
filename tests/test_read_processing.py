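"""Read-processing contracts: format conversion, demultiplexing,
translation (against an independent codon table), motif-bounded CDRH3
extraction and deduplication."""

import io

import pytest
from hypothesis import given, strategies as st

from knobminer import (CdrSequence, ConfigurationError, DEFAULT_BARCODES,
                       dedupe_and_count, demultiplex, emit_reads,
                       extract_cdrh3, fastq_to_fasta, process_sample,
                       select_frame_and_collect, theoretical_diversity,
                       translate_three_frames)
from knobminer.read_processing import (REASON_MULTI_FRAME,
                                       REASON_NO_DOWNSTREAM)

# ---------------------------------------------------------------------------
# independent codon-table oracle (NCBI standard table, TCAG ordering)
# ---------------------------------------------------------------------------
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODON_TABLE = {b1 + b2 + b3: _AA[16 * i + 4 * j + k]
                for i, b1 in enumerate(_BASES)
                for j, b2 in enumerate(_BASES)
                for k, b3 in enumerate(_BASES)}


def _translate_oracle(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i:i + 3]]
                   for i in range(0, len(nt) - len(nt) % 3, 3))


class TestFastqToFasta:
    def test_single_record(self):
        out = io.StringIO()
        fastq_to_fasta(io.StringIO("@r1\nACGT\n+\nIIII\n"), out)
        assert out.getvalue() == ">r1\nACGT\n"

    def test_empty_input(self):
        out = io.StringIO()
        assert fastq_to_fasta(io.StringIO(""), out) == 0
        assert out.getvalue() == ""

    def test_order_preserved(self):
        fastq = "".join(f"@r{i}\nAC\n+\nII\n" for i in range(3))
        out = io.StringIO()
        assert fastq_to_fasta(io.StringIO(fastq), out) == 3
        assert [l for l in out.getvalue().splitlines() if l.startswith(">")] \
            == [">r0", ">r1", ">r2"]

    def test_malformed_block_names_record(self):
        with pytest.raises(ValueError, match="record"):
            fastq_to_fasta(io.StringIO("@r1\nACGT\n+\nII\n"), io.StringIO())


class TestDemultiplex:
    ADAPTOR = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"

    def _read(self, barcode, rid="r1"):
        return (rid, self.ADAPTOR + barcode + "ACGT" * 10)

    def test_exact_barcode_binned(self):
        bins = demultiplex([self._read("AAGGTTCC")], list(DEFAULT_BARCODES))
        assert len(bins["AAGGTTCC"]) == 1

    def test_one_mismatch_with_zero_tolerance_is_undetermined(self):
        bins = demultiplex([self._read("AAGGTTCA")], list(DEFAULT_BARCODES),
                           max_mismatch=0)
        assert len(bins["undetermined"]) == 1
        bins = demultiplex([self._read("AAGGTTCA")], list(DEFAULT_BARCODES),
                           max_mismatch=1)
        assert len(bins["AAGGTTCC"]) == 1

    def test_partition_property(self):
        reads = [self._read("AAGGTTCC", f"a{i}") for i in range(5)] + \
                [self._read("CCTTAAGG", f"b{i}") for i in range(7)] + \
                [self._read("GGGGGGGG", "x0")]
        bins = demultiplex(reads, list(DEFAULT_BARCODES), max_mismatch=1)
        assert sum(len(v) for v in bins.values()) == len(reads)

    def test_ambiguous_barcode_set_rejected(self):
        with pytest.raises(ConfigurationError):
            demultiplex([], ["AAAAAAAA", "AAAAAAAT"], max_mismatch=1)

    def test_bins_reproduce_generator_assignment(self, small_repertoire):
        subset = small_repertoire[:50]
        reads = emit_reads(subset, DEFAULT_BARCODES, seed=3)
        bins = demultiplex(reads, list(DEFAULT_BARCODES), max_mismatch=1)
        truth = {}
        for rec in subset:
            truth.setdefault(rec.sample_barcode, set()).update(
                f"{rec.clone_id}_r{i}" for i in range(rec.copy_number))
        for bc in DEFAULT_BARCODES:
            assert {r.id for r in bins[bc]} == truth.get(bc, set())
        assert not bins["undetermined"]


class TestTranslation:
    def test_codon_table_examples(self):
        assert translate_three_frames("ATGGCC") == ("MA", "W", "G")
        assert translate_three_frames("TAA")[0] == "*"

    def test_frame_lengths(self, rng):
        nt = "".join(rng.choice(list("ACGT"), 300))
        frames = translate_three_frames(nt)
        for f, aa in enumerate(frames):
            assert len(aa) == (300 - f) // 3

    def test_against_independent_codon_table(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            nt = "".join(rng.choice(list("ACGT"), n))
            for f, aa in enumerate(translate_three_frames(nt)):
                assert aa == _translate_oracle(nt[f:])


class TestExtractCdrh3:
    def test_valine_variant(self):
        result, reason = extract_cdrh3("XXDSATYYGCGKLLVTVSSXX")
        assert result[0] == "GCGK" and reason is None

    def test_isoleucine_variant(self):
        result, _ = extract_cdrh3("XXDSATYYGCGKLLITVSSXX")
        assert result[0] == "GCGK"

    def test_missing_downstream_motif(self):
        result, reason = extract_cdrh3("XXDSATYYGCGK")
        assert result is None and reason == REASON_NO_DOWNSTREAM

    def test_span_is_half_open_between_motifs(self):
        result, _ = extract_cdrh3("XXDSATYYGCGKLLVTVSSXX")
        aa, (start, end) = result
        assert (start, end) == (8, 12)
        assert "XXDSATYYGCGKLLVTVSSXX"[start:end] == aa

    def test_idempotence_extraction_returns_none_on_extracted(self):
        result, _ = extract_cdrh3("XXDSATYYGCGKLLVTVSSXX")
        again, _ = extract_cdrh3(result[0])
        assert again is None

    def test_stop_inside_region_rejected(self):
        result, reason = extract_cdrh3("XXDSATYYGC*KLLVTVSSXX")
        assert result is None


class TestSelectFrame:
    def test_planted_frame_recovered_on_noiseless_reads(self,
                                                        small_repertoire):
        reads = emit_reads(small_repertoire[:20], DEFAULT_BARCODES, seed=5)
        by_clone = {r.clone_id: r for r in small_repertoire[:20]}
        for read in reads:
            cdr, reason = select_frame_and_collect(str(read.seq))
            assert reason is None
            clone = by_clone[read.id.rsplit("_r", 1)[0]]
            assert cdr.cdrh3_nt == clone.cdrh3_nt
            assert cdr.cdrh3_aa == clone.cdrh3_aa
            assert cdr.frame == 1  # amplicon anatomy puts DSATYY in frame 1

    def test_no_qualifying_frame(self):
        cdr, reason = select_frame_and_collect("ACGT" * 20)
        assert cdr is None

    def test_multi_frame_ambiguity_discarded(self):
        # DSATYY...LLVTVSS planted in frames 0 and 1 of the same read
        frame0 = "GATAGTGCTACTTATTATGGGAAACTGCTGGTCACCGTCTCGAGC"
        read = frame0 + "T" + frame0
        cdr, reason = select_frame_and_collect(read)
        assert cdr is None and reason == REASON_MULTI_FRAME

    def test_n_in_cdrh3_span_discarded(self):
        nt = "GATAGTGCTACTTATTATGGGANACTGCTGGTCACCGTCTCGAGC"
        cdr, reason = select_frame_and_collect(nt)
        assert cdr is None


class TestDedupe:
    def _cdr(self, nt, bc="AAGGTTCC"):
        return CdrSequence(bc, nt, "X" * (len(nt) // 3), 0, 1)

    def test_multiplicities(self):
        x, y = self._cdr("AAACCC"), self._cdr("GGGTTT")
        out = dedupe_and_count([x, x, y])
        assert [(c.cdrh3_nt, c.copy_number) for c in out] == \
            [("AAACCC", 2), ("GGGTTT", 1)]

    def test_empty(self):
        assert dedupe_and_count([]) == []

    def test_mixed_barcodes_rejected(self):
        with pytest.raises(ValueError):
            dedupe_and_count([self._cdr("AAACCC"),
                              self._cdr("AAACCC", bc="CCTTAAGG")])

    def test_sorted_by_count_then_sequence(self):
        cdrs = [self._cdr(nt) for nt in
                ("TTTAAA", "AAACCC", "AAACCC", "CCCGGG", "CCCGGG")]
        out = dedupe_and_count(cdrs)
        assert [c.cdrh3_nt for c in out] == ["AAACCC", "CCCGGG", "TTTAAA"]

    def test_planted_copy_numbers_recovered(self, small_repertoire):
        rec = small_repertoire[0]
        reads = emit_reads([rec], [rec.sample_barcode], depth=7, seed=1)
        out = process_sample(reads, rec.sample_barcode)
        assert len(out) == 1 and out[0].copy_number == 7


class TestRoundTrip:
    def test_noiseless_pipeline_recovers_planted_repertoire(
            self, small_repertoire):
        """Generator -> reads -> demux -> extract -> dedupe reproduces the
        planted unique CDRH3 set and copy numbers exactly."""
        reads = emit_reads(small_repertoire, DEFAULT_BARCODES, seed=8)
        bins = demultiplex(reads, list(DEFAULT_BARCODES), max_mismatch=1)
        recovered = {}
        for bc in DEFAULT_BARCODES:
            for c in process_sample(bins[bc], bc):
                recovered[(bc, c.cdrh3_nt)] = c.copy_number
        truth = {(r.sample_barcode, r.cdrh3_nt): r.copy_number
                 for r in small_repertoire}
        assert recovered == truth


class TestDiversity:
    @pytest.mark.parametrize("v,d,j,expected", [
        (55, 23, 6, 7590),   # human segment counts
        (1, 1, 1, 1),
        (10, 10, 4, 400),    # cattle counts; literature quotes ~4,000
    ])
    def test_product(self, v, d, j, expected):
        assert theoretical_diversity(v, d, j) == expected

    @given(st.integers(min_value=1, max_value=500),
           st.integers(min_value=1, max_value=500),
           st.integers(min_value=1, max_value=500))
    def test_positive_and_multiplicative(self, v, d, j):
        assert theoretical_diversity(v, d, j) == v * d * j

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            theoretical_diversity(0, 5, 5)
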