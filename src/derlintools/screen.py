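"""Mutation calling for the random-mutagenesis screen.

Forward and reverse Sanger reads of a mutagenized clone are aligned to the
wild-type ORF (semi-global: the read aligns fully, reference end-gaps are
free), substitutions are called per strand, strand-verified against each
other, and the candidate filters applied: exactly one point mutation, no
premature stop codon, verified on both strands, outside any excluded region
(the cytoplasmic SHP tail in the original screen).

Nucleotide positions are 0-based half-open internally; amino-acid change
labels use 1-based protein numbering ("F107S").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .synthetic import ReadPair, reverse_complement

__all__ = [
    "Alignment",
    "SubstitutionCall",
    "IndelCall",
    "MergedCalls",
    "CandidateVerdict",
    "align_semi_global",
    "call_substitutions",
    "merge_strand_calls",
    "classify_candidate",
    "evaluate_read_pair",
]

MAX_EDIT_FRACTION = 0.10
MIN_READ_LENGTH = 30


@dataclass
class Alignment:
    """Semi-global alignment of a read against the reference.

    ``pairs`` lists aligned columns as (ref_pos | None, read_pos | None);
    None marks a gap.  ``interval`` is the covered reference span, 0-based
    half-open.  ``cost`` is the unit-cost edit distance of the aligned
    region.
    """

    pairs: list[tuple[int | None, int | None]]
    interval: tuple[int, int]
    cost: int


def align_semi_global(read: str, reference: str) -> Alignment:
    """Align a read to the reference with free end-gaps on the reference.

    Unit-cost edit distance; among co-optimal alignments the traceback
    prefers diagonal moves, then read-consuming gaps, placing gaps leftmost.
    Rejects reads whose edit distance exceeds 10% of the read length.
    """
    read = read.upper()
    reference = reference.upper()
    m, n = len(read), len(reference)
    if m < MIN_READ_LENGTH:
        raise ValueError(f"read length {m} < minimum {MIN_READ_LENGTH}")

    # D[i, j]: best cost aligning read[:i] ending at reference position j,
    # with the reference prefix before the aligned region free.
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    D[0, :] = 0
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    idx = np.arange(n + 1)
    c = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + (read_arr[i - 1] != ref_arr)
        up = D[i - 1, 1:] + 1  # read base against a reference gap
        c[0] = i
        np.minimum(sub, up, out=c[1:])
        # fold in left moves (reference base against a read gap) in one pass:
        # D[i, j] = min_{j' <= j} c[j'] + (j - j')
        D[i] = idx + np.minimum.accumulate(c - idx)

    end_j = int(np.argmin(D[m, :]))  # leftmost best end on ties
    cost = int(D[m, end_j])
    if cost > MAX_EDIT_FRACTION * m:
        raise ValueError(
            f"read does not match reference (edit distance {cost} > "
            f"{MAX_EDIT_FRACTION:.0%} of read length {m})"
        )

    # traceback; preference order: diagonal, up (read gap vs ref), left
    pairs_rev: list[tuple[int | None, int | None]] = []
    i, j = m, end_j
    while i > 0:
        if j > 0 and D[i, j] == D[i - 1, j - 1] + (read[i - 1] != reference[j - 1]):
            pairs_rev.append((j - 1, i - 1))
            i -= 1
            j -= 1
        elif D[i, j] == D[i - 1, j] + 1:
            pairs_rev.append((None, i - 1))  # insertion relative to reference
            i -= 1
        else:
            pairs_rev.append((j - 1, None))  # deletion relative to reference
            j -= 1
    start_j = j
    pairs = pairs_rev[::-1]
    if not pairs:
        raise ValueError("alignment contains no aligned columns")
    return Alignment(pairs=pairs, interval=(start_j, end_j), cost=cost)


GENETIC_STOP = "*"


@dataclass(frozen=True)
class SubstitutionCall:
    """A single-nucleotide substitution call on the reference frame."""

    position: int
    ref_base: str
    alt_base: str
    strands: frozenset
    codon_index: int
    aa_change: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")


@dataclass(frozen=True)
class IndelCall:
    """An insertion or deletion relative to the reference (never a
    substitution)."""

    position: int
    kind: str  # "insertion" | "deletion"
    strands: frozenset


def _aa_change_label(reference: str, position: int, alt_base: str) -> tuple[int, str]:
    """Codon index and amino-acid change label for a substitution."""
    codon_index = position // 3
    start = codon_index * 3
    ref_codon = reference[start : start + 3]
    if len(ref_codon) < 3:
        return codon_index, "partial_codon"
    alt_codon = list(ref_codon)
    alt_codon[position - start] = alt_base
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return codon_index, "silent"
    return codon_index, f"{ref_aa}{codon_index + 1}{alt_aa}"


def call_substitutions(
    alignment: Alignment,
    read: str,
    reference: str,
    strand: str,
) -> tuple[list[SubstitutionCall], list[IndelCall]]:
    """One call per aligned mismatch; indels reported separately.

    Reverse reads must be reverse-complemented *before* alignment; the
    ``strand`` label only annotates provenance.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError("strand must be 'forward' or 'reverse'")
    read = read.upper()
    reference = reference.upper()
    if not alignment.pairs:
        raise ValueError("alignment contains no aligned columns")
    subs: list[SubstitutionCall] = []
    indels: list[IndelCall] = []
    strands = frozenset({strand})
    for ref_pos, read_pos in alignment.pairs:
        if ref_pos is None:
            indels.append(
                IndelCall(position=-1 if read_pos is None else read_pos,
                          kind="insertion", strands=strands)
            )
        elif read_pos is None:
            indels.append(
                IndelCall(position=ref_pos, kind="deletion", strands=strands)
            )
        elif read[read_pos] != reference[ref_pos]:
            codon_index, aa_change = _aa_change_label(
                reference, ref_pos, read[read_pos]
            )
            subs.append(
                SubstitutionCall(
                    position=ref_pos,
                    ref_base=reference[ref_pos],
                    alt_base=read[read_pos],
                    strands=strands,
                    codon_index=codon_index,
                    aa_change=aa_change,
                )
            )
    return subs, indels


@dataclass
class MergedCalls:
    """Strand-verification outcome for one clone."""

    verified: list[SubstitutionCall] = field(default_factory=list)
    unverified: list[SubstitutionCall] = field(default_factory=list)
    discordant: list[tuple[SubstitutionCall, SubstitutionCall]] = field(
        default_factory=list
    )


def merge_strand_calls(
    forward_calls: Sequence[SubstitutionCall],
    reverse_calls: Sequence[SubstitutionCall],
    forward_interval: tuple[int, int],
    reverse_interval: tuple[int, int],
    policy: str = "strict",
) -> MergedCalls:
    """Verify substitution calls across strands.

    A call is verified when it appears identically in both strands' call
    sets.  Positions covered by only one read cannot be double-verified:
    under the default strict policy they stay unverified; under the lenient
    policy a call in the single covering read is accepted as verified.
    Conflicting alt bases at one position are flagged discordant and never
    verified.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError("policy must be 'strict' or 'lenient'")
    overlap = (
        max(forward_interval[0], reverse_interval[0]),
        min(forward_interval[1], reverse_interval[1]),
    )
    fwd_by_pos = {c.position: c for c in forward_calls}
    rev_by_pos = {c.position: c for c in reverse_calls}
    merged = MergedCalls()
    for pos in sorted(set(fwd_by_pos) | set(rev_by_pos)):
        f = fwd_by_pos.get(pos)
        r = rev_by_pos.get(pos)
        if f is not None and r is not None:
            if f.alt_base == r.alt_base:
                merged.verified.append(
                    SubstitutionCall(
                        position=f.position,
                        ref_base=f.ref_base,
                        alt_base=f.alt_base,
                        strands=frozenset({"forward", "reverse"}),
                        codon_index=f.codon_index,
                        aa_change=f.aa_change,
                    )
                )
            else:
                merged.discordant.append((f, r))
            continue
        call = f if f is not None else r
        double_covered = overlap[0] <= pos < overlap[1]
        if not double_covered and policy == "lenient":
            merged.verified.append(call)
        else:
            merged.unverified.append(call)
    return merged


@dataclass
class CandidateVerdict:
    """Accept/reject decision for one screen candidate, with reasons."""

    status: str  # "accepted" | "rejected"
    reasons: list[str]
    calls: list[SubstitutionCall]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "reasons": list(self.reasons),
            "calls": [
                {
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "alt_base": c.alt_base,
                    "strands": sorted(c.strands),
                    "codon_index": c.codon_index,
                    "aa_change": c.aa_change,
                }
                for c in self.calls
            ],
        }


def _has_premature_stop(reference_orf: str, calls: Sequence[SubstitutionCall]) -> bool:
    seq = list(reference_orf.upper())
    for c in calls:
        seq[c.position] = c.alt_base
    protein = str(Seq("".join(seq)).translate())
    # the natural terminus may or may not be an encoded stop; only internal
    # stops disqualify
    internal = protein[:-1] if protein.endswith(GENETIC_STOP) else protein
    return GENETIC_STOP in internal


def classify_candidate(
    merged: MergedCalls,
    reference_orf: str,
    excluded_region: tuple[int, int] | None = None,
    indels: Sequence[IndelCall] = (),
) -> CandidateVerdict:
    """Apply the screen's candidate filters.

    Accepted iff exactly one verified nucleotide substitution, no
    unverified/discordant leftovers, no indels, the mutated ORF translates
    without an internal stop, and the call lies outside ``excluded_region``.
    """
    if len(reference_orf) % 3 != 0:
        raise ValueError("reference ORF length must be divisible by 3")
    reasons: list[str] = []
    verified = list(merged.verified)

    if len(verified) == 0:
        reasons.append("no_mutation")
    elif len(verified) > 1:
        reasons.append("multiple_mutations")
    if indels:
        # the screen analysed point mutants only; any indel disqualifies
        if "multiple_mutations" not in reasons:
            reasons.append("multiple_mutations")
    if merged.unverified or merged.discordant:
        reasons.append("unverified_strand")
    if verified and _has_premature_stop(reference_orf, verified):
        reasons.append("premature_stop")
    if excluded_region is not None and verified:
        lo, hi = excluded_region
        if any(lo <= c.position < hi for c in verified):
            reasons.append("excluded_region")

    status = "accepted" if not reasons else "rejected"
    return CandidateVerdict(status=status, reasons=reasons, calls=verified)


def evaluate_read_pair(
    pair: ReadPair,
    reference_orf: str,
    excluded_region: tuple[int, int] | None = None,
    policy: str = "strict",
) -> CandidateVerdict:
    """End-to-end pipeline for one clone: align both reads, call, verify,
    classify."""
    fwd_aln = align_semi_global(pair.forward_seq, reference_orf)
    rev_read = reverse_complement(pair.reverse_seq)
    rev_aln = align_semi_global(rev_read, reference_orf)
    fwd_subs, fwd_indels = call_substitutions(
        fwd_aln, pair.forward_seq, reference_orf, "forward"
    )
    rev_subs, rev_indels = call_substitutions(
        rev_aln, rev_read, reference_orf, "reverse"
    )
    merged = merge_strand_calls(
        fwd_subs, rev_subs, fwd_aln.interval, rev_aln.interval, policy=policy
    )
    return classify_candidate(
        merged,
        reference_orf,
        excluded_region=excluded_region,
        indels=list(fwd_indels) + list(rev_indels),
    )
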