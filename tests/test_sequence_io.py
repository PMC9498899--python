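import numpy as np
import pytest

from ccchkit.sequence_io import (
    AlignmentParams,
    SequenceRecord,
    deduplicate,
    pairwise_identity,
    read_fasta,
    translate_cds,
    write_fasta,
)
from oracles import gotoh_score

# standard genetic code, frozen independently of any library
_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestReadWriteFasta:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a desc ignored\nMKC\n>b\nMRH\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["a", "b"]
        assert [r.seq for r in records] == ["MKC", "MRH"]

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_fasta(p) == []

    def test_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MKC\n>a\nMKC\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(p)

    def test_duplicate_ids_listed(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nMK\n>b\nMR\n>a\nMW\n")
        with pytest.raises(ValueError, match=r"\['a'\]"):
            read_fasta(p)

    def test_round_trip_byte_identical(self, tmp_path, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        records = [
            SequenceRecord(f"s{i}", "".join(rng.choice(letters, size=n)))
            for i, n in enumerate([1, 59, 60, 61, 200])
        ]
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(records, p1)
        write_fasta(read_fasta(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestTranslateCds:
    def test_terminal_stop_stripped(self):
        rec = SequenceRecord("x", "ATGGGCTGA", kind="cds")
        assert translate_cds(rec).seq == "MG"

    def test_internal_stop_raises(self):
        rec = SequenceRecord("x", "ATGTAGGGC", kind="cds")
        with pytest.raises(ValueError, match="internal stop at codon 2"):
            translate_cds(rec)

    def test_internal_stop_truncates_under_flag(self):
        rec = SequenceRecord("x", "ATGTAGGGC", kind="cds")
        assert translate_cds(rec, truncate_at_stop=True).seq == "M"

    def test_frame_error_and_force(self):
        rec = SequenceRecord("x", "ATGGGCTG", kind="cds")
        with pytest.raises(ValueError, match="not divisible by 3"):
            translate_cds(rec)
        assert translate_cds(rec, force_frame=True).seq == "MG"

    def test_n_codon_becomes_x(self):
        assert translate_cds(SequenceRecord("x", "ATGANG", kind="cds")).seq == "MX"

    def test_matches_codon_table_oracle(self, rng):
        codons = [c for c in _STANDARD_CODE if _STANDARD_CODE[c] != "*"]
        chosen = [codons[i] for i in rng.integers(0, len(codons), size=300)]
        rec = SequenceRecord("x", "".join(chosen), kind="cds")
        expected = "".join(_STANDARD_CODE[c] for c in chosen)
        assert translate_cds(rec).seq == expected
        assert len(expected) == 300


class TestPairwiseIdentity:
    def test_self_identity_is_one(self):
        a = SequenceRecord("a", "MKCRHWAY")
        res = pairwise_identity(a, a)
        assert res.identity == 1.0
        assert res.aligned_columns == 8

    def test_disjoint_alphabets_zero(self):
        a = SequenceRecord("a", "AAAA")
        b = SequenceRecord("b", "TTTT")
        assert pairwise_identity(a, b).identity == 0.0

    def test_symmetric(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = SequenceRecord("a", "".join(rng.choice(letters, size=40)))
        b = SequenceRecord("b", "".join(rng.choice(letters, size=35)))
        assert pairwise_identity(a, b).identity == pytest.approx(
            pairwise_identity(b, a).identity
        )

    def test_mixed_kinds_rejected(self):
        a = SequenceRecord("a", "MK")
        b = SequenceRecord("b", "ATG", kind="cds")
        with pytest.raises(ValueError, match="cannot align"):
            pairwise_identity(a, b)

    def test_single_substitution_matches_dp(self, rng):
        letters = list("ADEGKNPQRSTWY")
        seq = "".join(rng.choice(letters, size=50))
        mutated = seq[:25] + ("W" if seq[25] != "W" else "G") + seq[26:]
        res = pairwise_identity(SequenceRecord("a", seq), SequenceRecord("b", mutated))
        assert res.identity == pytest.approx(49 / 50)
        assert res.aligned_columns == 50

    def test_alignment_score_matches_gotoh_oracle(self, rng):
        from ccchkit.sequence_io import _aligner

        letters = list("ACDEFGHIKLMNPQRSTVWY")
        aligner = _aligner(AlignmentParams())
        for n, m in [(10, 10), (15, 9), (20, 26)]:
            a = "".join(rng.choice(letters, size=n))
            b = "".join(rng.choice(letters, size=m))
            assert aligner.score(a, b) == pytest.approx(gotoh_score(a, b))


class TestDeduplicate:
    def test_identical_pair_collapsed(self):
        recs = [SequenceRecord("a", "MKCRHW" * 10), SequenceRecord("b", "MKCRHW" * 10)]
        kept, removed = deduplicate(recs)
        assert [r.id for r in kept] == ["a"]  # tie broken by id
        assert removed["b"].retained_id == "a"
        assert removed["b"].identity == pytest.approx(1.0)

    def test_ninety_percent_pair_both_kept(self, rng):
        # near-duplicate family members around 91% identity survive the
        # 97% filter, as the published pair with >90.8% similarity did
        letters = list("ADEGKNPQSTWY")
        seq = "".join(rng.choice(letters, size=100))
        mutated = list(seq)
        for pos in rng.choice(100, size=9, replace=False):
            mutated[pos] = "R"
        recs = [SequenceRecord("a", seq), SequenceRecord("b", "".join(mutated))]
        ident = pairwise_identity(*recs).identity
        assert 0.90 <= ident <= 0.97
        kept, removed = deduplicate(recs)
        assert len(kept) == 2 and not removed

    def test_longest_kept_first(self):
        # a one-residue truncation is ~99% identical; the longer isoform
        # must be the retained one regardless of id order
        long = SequenceRecord("short_id_but_long_seq", "MKCRHWAY" * 10)
        short = SequenceRecord("aaa", ("MKCRHWAY" * 10)[:-1])
        kept, removed = deduplicate([short, long])
        assert [r.id for r in kept] == ["short_id_but_long_seq"]
        assert removed["aaa"].retained_id == "short_id_but_long_seq"

    def test_no_pair_above_threshold_and_idempotent(self, rng):
        # family with planted near-duplicates: post-dedup identities must
        # all be <= threshold and a second pass must be a fixed point
        letters = list("ADEGKNPQSTWY")
        base = ["".join(rng.choice(letters, size=60)) for _ in range(8)]
        recs = []
        for i, seq in enumerate(base):
            recs.append(SequenceRecord(f"s{i}", seq))
            near = seq[:1] + seq[1:]  # exact duplicate under a new id
            recs.append(SequenceRecord(f"s{i}dup", near))
        kept, removed = deduplicate(recs, threshold=0.97)
        assert len(kept) == 8 and len(removed) == 8
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert pairwise_identity(a, b).identity <= 0.97
        kept2, removed2 = deduplicate(kept, threshold=0.97)
        assert kept2 == kept and not removed2

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            deduplicate([SequenceRecord("a", "MK")], threshold=1.5)
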