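import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from flavicophy.datasets import FUSION_PEPTIDE_MOTIFS
from flavicophy.screens import (
    STOP_CODONS,
    MotifProfile,
    check_conserved_columns,
    find_overlapping_orfs,
    frameshift_rescue,
    scan_motif,
    translate,
)
from flavicophy.simulate import simulate_frameshift_sequence


def brute_force_best_rescue(seq, shift=1):
    """Independent scan of every (start, offset) pair: longest stop-free
    codon run in the shifted frame starting at or before the first frame-0
    stop."""
    seq = seq.upper()
    stops = [
        i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS
    ]
    if not stops:
        return None, 0
    first = stops[0]
    best = 0
    frame_start = shift % 3
    for q in range(frame_start, first + 3, 3):
        run = 0
        i = q
        while i + 3 <= len(seq) and seq[i : i + 3] not in STOP_CODONS:
            run += 1
            i += 3
        best = max(best, run)
    return first // 3, best


class TestMotifScan:
    def test_planted_motif_found_at_position(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        background = "".join(rng.choice(list(aa), size=300))
        motif = FUSION_PEPTIDE_MOTIFS[0]  # NRGWGTGCFEWGLG
        seq = background[:98] + motif.pattern + background[98:]
        hits = scan_motif({"E_protein": seq}, motif)
        assert ("E_protein", 98, motif.pattern) in hits

    def test_each_packaged_motif_matches_itself(self):
        for m in FUSION_PEPTIDE_MOTIFS:
            variants = (
                ["DRGWXXGCXXFGKG", "DRGWXXGCXXFGKH"]
                if "[" in m.pattern
                else [m.pattern]
            )
            for text in variants:
                hits = scan_motif({"self": text}, m)
                assert hits and hits[0][1] == 0

    def test_absent_motif_empty(self):
        assert scan_motif({"x": "MKTAYIAKQR"}, FUSION_PEPTIDE_MOTIFS[0]) == []

    def test_hit_count_invariant_to_appended_records(self):
        m = FUSION_PEPTIDE_MOTIFS[2]
        seqs = {"a": "GG" + m.pattern + "KL"}
        base = scan_motif(seqs, m)
        seqs["unrelated"] = "MKLVVNNNNPPQQRSTW"
        assert [h for h in scan_motif(seqs, m) if h[0] == "a"] == base

    def test_nucleotide_input_flagged(self):
        with pytest.raises(ValueError):
            scan_motif({"nt": "ACGTACGTACGT"}, FUSION_PEPTIDE_MOTIFS[0],
                       on_nucleotide="error")
        with pytest.warns(UserWarning):
            scan_motif({"nt": "ACGTACGTACGT"}, FUSION_PEPTIDE_MOTIFS[0])

    def test_wildcards_only_where_declared(self):
        # insect-specific motifs carry no wildcard; the traditional one does
        for m in FUSION_PEPTIDE_MOTIFS[:3]:
            assert "X" not in m.pattern
        assert "X" in FUSION_PEPTIDE_MOTIFS[3].pattern

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifProfile(name="bad", pattern="NRG W")


class TestConservedColumns:
    def test_constructed_columns(self):
        aln = {
            "s1": "AACAABBBBBBBBBBBBCAA",
            "s2": "GGCAGGGGGGGGGGGGGCGG",
            "s3": "TTCATTTTTTTTTTTTTCTT",
        }
        assert check_conserved_columns(aln, "C") == [2, 17]

    def test_single_mutation_removes_column(self):
        aln = {"s1": "ACA", "s2": "ACA", "s3": "AAA"}
        assert check_conserved_columns(aln, "C") == []

    def test_gap_disqualifies(self):
        aln = {"s1": "C-C", "s2": "CCC"}
        assert check_conserved_columns(aln, "C") == [0, 2]

    def test_planted_count_recovered(self):
        rng = np.random.default_rng(5)
        aa = list("ADEFGHIKLMNPQRSTVWY")  # no C in the background
        ncol, nseq, k = 120, 6, 7
        cols = sorted(rng.choice(ncol, size=k, replace=False))
        aln = {}
        for s in range(nseq):
            row = rng.choice(aa, size=ncol)
            row[cols] = "C"
            aln[f"s{s}"] = "".join(row)
        assert check_conserved_columns(aln, "C") == cols

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            check_conserved_columns({"a": "CC", "b": "C"}, "C")


class TestTranslationModel:
    def test_stop_codons_match_published_table(self):
        assert STOP_CODONS == frozenset(unambiguous_dna_by_id[1].stop_codons)
        assert STOP_CODONS == {"TAA", "TAG", "TGA"}

    def test_ambiguous_codons_never_stop(self):
        assert translate("TANTARNGA") == "XXX"
        rep = frameshift_rescue("ATG" + "TRA" * 30, min_codons=5)
        assert rep.stop_position is None

    def test_translate_matches_biopython_on_clean_orf(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert translate(seq) == str(Seq(seq).translate())


class TestFrameshiftRescue:
    def test_simulated_rescue_found(self):
        seq, truth = simulate_frameshift_sequence(30, 80, seed=3)
        rep = frameshift_rescue(seq, min_codons=70)
        assert rep.rescue_found
        assert rep.stop_position == truth["stop_position"] == 30
        assert rep.rescued_length >= 70

    def test_short_overlap_not_rescued(self):
        seq, _ = simulate_frameshift_sequence(30, 10, seed=3)
        rep = frameshift_rescue(seq, min_codons=70)
        assert not rep.rescue_found

    def test_stop_free_orf_reports_no_stop(self):
        rep = frameshift_rescue("ATGGCT" * 40, min_codons=5)
        assert rep.stop_position is None and not rep.rescue_found

    def test_shifted_frame_too_short_to_rescue(self):
        # frame 0 stops at codon 1; the +1 frame offers only 4 codons
        seq = "AAATAA" + "TAA" * 3
        rep = frameshift_rescue(seq, min_codons=5)
        assert rep.stop_position == 1
        assert not rep.rescue_found

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            frameshift_rescue("AT")

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(44)
        for _ in range(30):
            n = int(rng.integers(60, 900))
            seq = "".join(rng.choice(list("ACGT"), size=n * 3))
            rep = frameshift_rescue(seq, min_codons=10)
            stop, best = brute_force_best_rescue(seq)
            if stop is None:
                assert rep.stop_position is None
            else:
                assert rep.stop_position == stop
                assert rep.rescued_length == best
                assert rep.rescue_found == (best >= 10)


class TestOverlappingOrfs:
    def test_planted_seventy_codon_overlap(self):
        seq, truth = simulate_frameshift_sequence(25, 70, seed=8)
        hits = find_overlapping_orfs(seq, offsets=(1,), min_codons=70)
        assert any(
            off == 1 and start <= truth["rescue_start"] and length >= 70
            for off, start, length in hits
        )

    def test_all_stop_shifted_frame_empty(self):
        seq = "T" + "TAA" * 60  # +1 frame reads TAA TAA ...
        assert find_overlapping_orfs(seq, offsets=(1,), min_codons=5) == []

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            find_overlapping_orfs("ACGT" * 100, offsets=())

    def test_random_sequence_hit_rate_near_geometric_prediction(self):
        """Stop-free runs of >= L codons in uniform sequence follow the
        geometric tail with stop density 3/64."""
        rng = np.random.default_rng(10)
        L, ncod, nseq = 40, 1200, 80
        p = 3 / 64
        hits = 0
        for _ in range(nseq):
            seq = "".join(rng.choice(list("ACGT"), size=ncod * 3))
            hits += len(find_overlapping_orfs(seq, offsets=(1,), min_codons=L))
        # expected maximal runs >= L per sequence: ~(ncod * p + 1) * (1-p)^L
        expected = nseq * (ncod * p + 1) * (1 - p) ** L
        assert 0.6 * expected < hits < 1.5 * expected
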