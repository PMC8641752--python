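"""Read alignment, substitution calling, strand verification, candidate filters."""

import numpy as np
import pytest

from derlintools.screen import (
    Alignment,
    align_semi_global,
    call_substitutions,
    classify_candidate,
    merge_strand_calls,
    evaluate_read_pair,
    MergedCalls,
)
from derlintools.synthetic import generate_screen_read_pair, reverse_complement
from conftest import SCREEN_MUTANTS


def _perfect_alignment(reference, start=0, end=None):
    end = len(reference) if end is None else end
    return Alignment(
        pairs=[(j, j - start) for j in range(start, end)],
        interval=(start, end),
        cost=0,
    )


class TestAligner:
    def test_exact_substring_aligns_with_zero_cost(self, screen_orf):
        read = screen_orf[40:120]
        aln = align_semi_global(read, screen_orf)
        assert aln.cost == 0
        assert aln.interval == (40, 120)
        assert all(r is not None and q is not None for r, q in aln.pairs)

    def test_single_mismatch_costs_one_and_keeps_interval(self, screen_orf):
        read = list(screen_orf[40:120])
        read[30] = "A" if read[30] != "A" else "C"
        aln = align_semi_global("".join(read), screen_orf)
        assert aln.cost == 1
        assert aln.interval == (40, 120)

    def test_cost_matches_edlib_on_random_pairs(self, screen_orf):
        """Independent oracle: edit distance in infix (free reference
        end-gap) mode."""
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(60):
            start = int(rng.integers(0, len(screen_orf) - 60))
            length = int(rng.integers(40, 100))
            read = list(screen_orf[start : start + length])
            for _ in range(int(rng.integers(0, 3))):
                i = int(rng.integers(0, len(read)))
                op = rng.integers(0, 3)
                if op == 0:
                    read[i] = bases[rng.integers(4)]
                elif op == 1 and len(read) > 35:
                    del read[i]
                else:
                    read.insert(i, bases[rng.integers(4)])
            read = "".join(read)
            aln = align_semi_global(read, screen_orf)
            expected = edlib.align(read, screen_orf, mode="HW")["editDistance"]
            assert aln.cost == expected

    def test_grossly_mismatching_read_rejected(self, screen_orf):
        junk = "G" * 60
        with pytest.raises(ValueError, match="does not match"):
            align_semi_global(junk, screen_orf)

    def test_short_read_rejected(self, screen_orf):
        with pytest.raises(ValueError, match="read length"):
            align_semi_global("ATG", screen_orf)


class TestCallSubstitutions:
    def test_missense_call_with_codon_annotation(self):
        reference = "ATGTTTAAA"
        read = "ATGTCTAAA"
        calls, indels = call_substitutions(
            _perfect_alignment(reference), read, reference, "forward"
        )
        assert indels == []
        (call,) = calls
        assert (call.position, call.ref_base, call.alt_base) == (4, "T", "C")
        assert call.codon_index == 1
        assert call.aa_change == "F2S"

    def test_perfect_read_yields_no_calls(self):
        reference = "ATGTTTAAA"
        calls, indels = call_substitutions(
            _perfect_alignment(reference), reference, reference, "forward"
        )
        assert calls == [] and indels == []

    def test_third_position_synonymous_change_is_silent(self):
        reference = "ATGTTTAAA"
        read = "ATGTTCAAA"  # TTT -> TTC, both Phe
        (call,), _ = call_substitutions(
            _perfect_alignment(reference), read, reference, "forward"
        )
        assert call.aa_change == "silent"

    def test_indels_never_reported_as_substitutions(self, screen_orf):
        read = screen_orf[30:90]
        read = read[:20] + read[21:]  # one deletion
        aln = align_semi_global(read, screen_orf)
        calls, indels = call_substitutions(aln, read, screen_orf, "forward")
        assert calls == []
        assert len(indels) == 1 and indels[0].kind == "deletion"


class TestMergeStrands:
    def _call(self, reference, pos, alt, strand):
        read = reference[:pos] + alt + reference[pos + 1 :]
        calls, _ = call_substitutions(
            _perfect_alignment(reference), read, reference, strand
        )
        return calls

    def test_identical_calls_verify(self, screen_orf):
        fwd = self._call(screen_orf, 172, "C", "forward")
        rev = self._call(screen_orf, 172, "C", "reverse")
        merged = merge_strand_calls(fwd, rev, (0, 336), (0, 336))
        assert len(merged.verified) == 1
        assert merged.verified[0].strands == frozenset({"forward", "reverse"})

    def test_single_strand_call_in_double_covered_region_stays_unverified(
        self, screen_orf
    ):
        fwd = self._call(screen_orf, 172, "C", "forward")
        merged = merge_strand_calls(fwd, [], (0, 336), (0, 336))
        assert merged.verified == []
        assert len(merged.unverified) == 1

    def test_discordant_alt_bases_flagged(self, screen_orf):
        fwd = self._call(screen_orf, 172, "C", "forward")
        rev = self._call(screen_orf, 172, "G", "reverse")
        merged = merge_strand_calls(fwd, rev, (0, 336), (0, 336))
        assert merged.verified == []
        assert len(merged.discordant) == 1

    def test_lenient_policy_accepts_single_coverage_calls(self, screen_orf):
        fwd = self._call(screen_orf, 10, "C" if screen_orf[10] != "C" else "T",
                         "forward")
        strict = merge_strand_calls(fwd, [], (0, 336), (100, 336), "strict")
        lenient = merge_strand_calls(fwd, [], (0, 336), (100, 336), "lenient")
        assert strict.verified == [] and len(strict.unverified) == 1
        assert len(lenient.verified) == 1


class TestClassify:
    def _merged(self, screen_orf, *mutations):
        calls = []
        for pos, alt in mutations:
            read = screen_orf[:pos] + alt + screen_orf[pos + 1 :]
            fwd, _ = call_substitutions(
                _perfect_alignment(screen_orf), read, screen_orf, "forward"
            )
            calls.extend(fwd)
        return MergedCalls(verified=calls)

    def test_single_missense_accepted(self, screen_orf):
        merged = self._merged(screen_orf, SCREEN_MUTANTS["F107S"])
        verdict = classify_candidate(merged, screen_orf)
        assert verdict.status == "accepted"
        assert verdict.reasons == []
        assert verdict.calls[0].aa_change == "F107S"

    def test_premature_stop_rejected(self, screen_orf):
        # find a tyrosine codon TAC and break it to TAA mid-ORF
        idx = screen_orf.index("TAC", 3, 150)
        while idx % 3 != 0:
            idx = screen_orf.index("TAC", idx + 1, 150)
        merged = self._merged(screen_orf, (idx + 2, "A"))
        verdict = classify_candidate(merged, screen_orf)
        assert verdict.status == "rejected"
        assert "premature_stop" in verdict.reasons

    def test_two_verified_calls_rejected(self, screen_orf):
        merged = self._merged(
            screen_orf, SCREEN_MUTANTS["F58S"], SCREEN_MUTANTS["Q101R"]
        )
        verdict = classify_candidate(merged, screen_orf)
        assert verdict.status == "rejected"
        assert verdict.reasons == ["multiple_mutations"]

    def test_no_mutation_rejected(self, screen_orf):
        verdict = classify_candidate(MergedCalls(), screen_orf)
        assert verdict.status == "rejected"
        assert "no_mutation" in verdict.reasons

    def test_mutation_in_excluded_tail_rejected(self, screen_orf):
        pos = 331
        alt = "C" if screen_orf[pos] != "C" else "G"
        merged = self._merged(screen_orf, (pos, alt))
        verdict = classify_candidate(
            merged, screen_orf, excluded_region=(330, 336)
        )
        assert verdict.status == "rejected"
        assert "excluded_region" in verdict.reasons

    def test_unverified_leftovers_poison_acceptance(self, screen_orf):
        merged = self._merged(screen_orf, SCREEN_MUTANTS["F107S"])
        alt = "C" if screen_orf[10] != "C" else "T"
        read = screen_orf[:10] + alt + screen_orf[11:]
        extra, _ = call_substitutions(
            _perfect_alignment(screen_orf), read, screen_orf, "forward"
        )
        merged.unverified.extend(extra)
        verdict = classify_candidate(merged, screen_orf)
        assert verdict.status == "rejected"
        assert "unverified_strand" in verdict.reasons


class TestEndToEnd:
    def test_planted_screen_mutants_are_recovered_by_label(self, screen_orf):
        for label, (pos, alt) in SCREEN_MUTANTS.items():
            pair = generate_screen_read_pair(screen_orf, [(pos, alt)], 0.0, seed=1)
            verdict = evaluate_read_pair(pair, screen_orf)
            assert verdict.status == "accepted"
            assert verdict.calls[0].aa_change == label

    def test_reverse_read_orientation_is_honored(self, screen_orf):
        pair = generate_screen_read_pair(screen_orf, [(172, "C")], 0.0, seed=0)
        assert pair.reverse_seq[0] != screen_orf[0]
        assert reverse_complement(pair.reverse_seq) == pair.forward_seq
        verdict = evaluate_read_pair(pair, screen_orf)
        assert verdict.status == "accepted"
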