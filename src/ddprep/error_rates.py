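"""Sequencing error rates from aligned reads.

Mismatch, insertion and deletion base counts are extracted per mapped read
from the CIGAR string plus either the MD tag or the reference sequence, and
pooled: each rate is the class's total base count divided by the total
number of aligned (reference-matching, i.e. M/X/=) bases over all mapped
reads.  Soft- and hard-clipped bases contribute to neither numerators nor
the denominator; deleted bases are counted in the deletion numerator only.

Insertions and deletions are counted in bases by default; counting events
instead, or including deleted bases in the denominator, are configurable
choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = [
    "AlignmentRecord",
    "ErrorRateReport",
    "extract_counts",
    "compute_error_rates",
    "error_rates_from_sam",
]

# CIGAR operation codes
_OP_M, _OP_I, _OP_D, _OP_EQ, _OP_X = 0, 1, 2, 7, 8
_ALIGN_OPS = (_OP_M, _OP_EQ, _OP_X)


@dataclass
class AlignmentRecord:
    """Per-read error counts over the aligned region."""

    read_id: str
    mapped: bool
    aligned_length: int = 0  # M/X/= bases
    n_mismatch: int = 0
    n_insertion_bases: int = 0
    n_deletion_bases: int = 0
    n_insertion_events: int = 0
    n_deletion_events: int = 0

    def __post_init__(self) -> None:
        if min(
            self.aligned_length,
            self.n_mismatch,
            self.n_insertion_bases,
            self.n_deletion_bases,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if not self.mapped and (
            self.aligned_length or self.n_mismatch or self.n_insertion_bases or self.n_deletion_bases
        ):
            raise ValueError("unmapped records carry no counts")


@dataclass
class ErrorRateReport:
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float
    denominator_bases: int
    n_reads: int = 0


def _mismatches_from_pairs(rec: pysam.AlignedSegment, ref_seq: str | None) -> int:
    """Count mismatching aligned positions using MD or an explicit reference."""
    if rec.has_tag("MD"):
        # with MD present, pysam reconstructs the reference; mismatched
        # reference bases come back lowercase
        n = 0
        for qpos, rpos, base in rec.get_aligned_pairs(with_seq=True, matches_only=True):
            if base is not None and base.islower():
                n += 1
        return n
    if ref_seq is None:
        raise ValueError(
            f"read {rec.query_name!r}: no MD tag and no reference sequence given"
        )
    query = rec.query_sequence
    n = 0
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        if query[qpos].upper() != ref_seq[rpos].upper():
            n += 1
    return n


def extract_counts(
    rec: pysam.AlignedSegment,
    reference: Mapping[str, str] | None = None,
) -> AlignmentRecord:
    """Extract per-read error counts from one SAM record.

    ``reference`` maps reference names to sequences and is only needed when
    the record lacks an MD tag.  Unmapped records return a zero-count record
    flagged unmapped.
    """
    if rec.is_unmapped:
        return AlignmentRecord(read_id=rec.query_name or "", mapped=False)
    aligned = ins_b = del_b = ins_e = del_e = 0
    for op, length in rec.cigartuples or []:
        if op in _ALIGN_OPS:
            aligned += length
        elif op == _OP_I:
            ins_b += length
            ins_e += 1
        elif op == _OP_D:
            del_b += length
            del_e += 1
    ref_seq = None
    if reference is not None and rec.reference_name in reference:
        ref_seq = reference[rec.reference_name]
    mism = _mismatches_from_pairs(rec, ref_seq)
    return AlignmentRecord(
        read_id=rec.query_name or "",
        mapped=True,
        aligned_length=aligned,
        n_mismatch=mism,
        n_insertion_bases=ins_b,
        n_deletion_bases=del_b,
        n_insertion_events=ins_e,
        n_deletion_events=del_e,
    )


def compute_error_rates(
    records: Iterable[AlignmentRecord],
    count_events: bool = False,
    include_deletions_in_denominator: bool = False,
) -> ErrorRateReport:
    """Pool per-read counts into mismatch/insertion/deletion rates.

    Rates are class totals over the total aligned-base denominator of all
    mapped reads; per-read rates weighted by aligned bases give the same
    numbers.
    """
    denom = mism = ins = dele = n_reads = 0
    for r in records:
        if not r.mapped:
            continue
        n_reads += 1
        denom += r.aligned_length
        if include_deletions_in_denominator:
            denom += r.n_deletion_bases
        mism += r.n_mismatch
        ins += r.n_insertion_events if count_events else r.n_insertion_bases
        dele += r.n_deletion_events if count_events else r.n_deletion_bases
    if denom == 0:
        raise ValueError("no aligned bases in any mapped record")
    return ErrorRateReport(
        mismatch_rate=mism / denom,
        insertion_rate=ins / denom,
        deletion_rate=dele / denom,
        denominator_bases=denom,
        n_reads=n_reads,
    )


def _load_reference(fasta_path: str) -> dict[str, str]:
    ref: dict[str, str] = {}
    with open(fasta_path) as fh:
        name = None
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    ref[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            ref[name] = "".join(chunks)
    return ref


def error_rates_from_sam(
    sam_path: str,
    reference_fasta: str | None = None,
    count_events: bool = False,
    include_deletions_in_denominator: bool = False,
) -> ErrorRateReport:
    """Compute pooled error rates for every mapped read in a SAM/BAM file."""
    reference = _load_reference(reference_fasta) if reference_fasta else None

    def stream() -> Iterator[AlignmentRecord]:
        with pysam.AlignmentFile(sam_path, check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                yield extract_counts(rec, reference)

    return compute_error_rates(
        stream(),
        count_events=count_events,
        include_deletions_in_denominator=include_deletions_in_denominator,
    )
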