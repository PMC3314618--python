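"""Demultiplex multiplexed amplicon reads by MID barcode and locus primer.

Each sequencing read of a fusion-primer amplicon library has the layout

    adaptorA - MID - forward_primer - insert - rc(reverse_primer) - rc(MID) - adaptorB'

(or its reverse complement, for reads sequenced off the other strand). The
same MID labels both ends of the product because both fusion primers of one
individual carry it.

A read is kept only if it survives, in order:

1. length filter — reads below 150 bp are removed;
2. mean-quality filter — reads whose raw-read average Phred is below 30 are
   removed;
3. MID match — the barcode immediately after the 5' adaptor and its reverse
   complement at the 3' end must both be present and identify the same
   individual;
4. primer match — the complete template-specific primer (IUPAC-aware, zero
   mismatches) must follow the MID, and the opposite primer's reverse
   complement must precede the 3' MID; matching two loci is ambiguous;
5. quality trimming of the insert (modified-Mott end trimming), then the
   length filter is re-checked on the trimmed insert.

Every input read appears exactly once in the output ledger, either kept with
its (individual, locus, orientation) assignment and trimmed insert, or
discarded with a reason code.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import (
    FormatError,
    LocusDef,
    Read,
    SampleSheetEntry,
    iupac_match,
    reverse_complement,
)

# Roche GS FLX Titanium amplicon fusion adaptors (A on forward primers, B on
# reverse primers). Configurable; reads lacking them (already clipped by the
# basecaller) are tolerated and may begin directly at the MID.
ADAPTOR_A = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTOR_B = "CTATGCGCCTTGCCAGCCCGCTCAG"

FORWARD = "forward"
REVERSE = "reverse"

TOO_SHORT = "too_short"
LOW_MEAN_QUALITY = "low_mean_quality"
MID_MISMATCH = "mid_mismatch"
PRIMER_ABSENT = "primer_absent"
AMBIGUOUS = "ambiguous"

DISCARD_REASONS = (TOO_SHORT, LOW_MEAN_QUALITY, MID_MISMATCH, PRIMER_ABSENT, AMBIGUOUS)


@dataclass
class DemuxParams:
    """Tunables of the demultiplexing stage (defaults = the published rules)."""

    min_len: int = 150
    min_mean_q: float = 30.0
    mid_edits: int = 0          # 0 = exact; 1 allows one substitution per MID
    trim_cutoff: float = 0.05   # modified-Mott error-probability cutoff
    adaptors: tuple[str, ...] = (ADAPTOR_A, ADAPTOR_B)
    # the adaptor is a known constant, not part of the discard rules, so it is
    # *located* with a small mismatch tolerance; MID and primer matching stay
    # exact as the rules demand
    adaptor_mismatches: int = 2


@dataclass(frozen=True)
class DemuxAssignment:
    """Where one read went: a bin (kept) or a reason code (discarded)."""

    read_id: str
    status: str                       # "kept" | "discarded"
    individual_id: Optional[str] = None
    locus_id: Optional[str] = None
    orientation: Optional[str] = None  # forward | reverse
    trimmed_read: Optional[Read] = None
    discard_reason: Optional[str] = None


@dataclass
class LibraryQualityReport:
    """Per-library tally of used vs discarded reads and read lengths."""

    total_reads: int = 0
    kept_reads: int = 0
    discarded_by_reason: dict = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )
    #: histogram of raw read lengths, 50 bp bins keyed by bin start
    length_histogram: dict = field(default_factory=dict)
    #: reads shorter than min_len before vs after quality trimming
    short_pre_trim: int = 0
    short_post_trim: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_reads": self.total_reads,
                "kept_reads": self.kept_reads,
                "discarded_by_reason": self.discarded_by_reason,
                "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
                "short_pre_trim": self.short_pre_trim,
                "short_post_trim": self.short_post_trim,
            },
            indent=2,
        )


def length_filter(read: Read, min_len: int = 150) -> bool:
    """Keep iff the read is at least ``min_len`` bp ("below 150 bp" is strict)."""
    return len(read) >= min_len


def mean_quality_filter(read: Read, min_q: float = 30.0) -> bool:
    """Keep iff the arithmetic mean Phred of the raw read is >= ``min_q``."""
    return read.mean_quality >= min_q


def _strip_adaptor_prefix(bases: str, adaptors: Sequence[str], max_mm: int = 0) -> str:
    for a in adaptors:
        if a and len(bases) >= len(a) and _hamming_le(bases[: len(a)], a, max_mm):
            return bases[len(a):]
    return bases


def _strip_adaptor_suffix(bases: str, adaptors: Sequence[str], max_mm: int = 0) -> str:
    for a in adaptors:
        rc = reverse_complement(a)
        if a and len(bases) >= len(rc) and _hamming_le(bases[-len(rc):], rc, max_mm):
            return bases[: -len(rc)]
    return bases


def _hamming_le(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def build_mid_index(entries: Sequence[SampleSheetEntry]) -> dict[str, SampleSheetEntry]:
    """Map MID sequence -> sample entry for one sequencing region.

    Demultiplexing requires the MIDs in one library to be globally unique
    (the locus table carries no species information that could break a tie
    between two samples sharing a barcode).
    """
    index: dict[str, SampleSheetEntry] = {}
    for e in entries:
        if e.mid in index and index[e.mid].individual_id != e.individual_id:
            raise FormatError(
                f"MID {e.mid!r} is assigned to both "
                f"{index[e.mid].individual_id!r} and {e.individual_id!r}; "
                "MIDs must be unique within one sequencing region"
            )
        index[e.mid] = e
    return index


def match_mid(
    read: Read,
    mid_index: Mapping[str, SampleSheetEntry],
    params: DemuxParams = DemuxParams(),
) -> Optional[tuple[SampleSheetEntry, int, int]]:
    """Find the MID at both ends of a read.

    Returns ``(entry, start, end)`` where ``bases[start:end]`` is the region
    between the two MIDs (primers + insert), or None when the barcode is
    absent from either end or the two ends disagree. The barcode must be
    identical at both ends (as its reverse complement at 3'), because one
    individual's forward and reverse fusion primers carry the same MID.
    """
    bases = read.bases
    core5 = _strip_adaptor_prefix(bases, params.adaptors, params.adaptor_mismatches)
    off5 = len(bases) - len(core5)
    core = _strip_adaptor_suffix(core5, params.adaptors, params.adaptor_mismatches)

    # longest-first so that no MID that is a prefix of another steals the match
    for mid in sorted(mid_index, key=len, reverse=True):
        n = len(mid)
        if len(core) < 2 * n:
            continue
        head, tail = core[:n], core[-n:]
        rc_mid = reverse_complement(mid)
        if params.mid_edits == 0:
            hit = head == mid and tail == rc_mid
        else:
            hit = _hamming_le(head, mid, params.mid_edits) and _hamming_le(
                tail, rc_mid, params.mid_edits
            )
        if hit:
            start = off5 + n
            end = off5 + len(core) - n
            return mid_index[mid], start, end
    return None


def match_primer(
    bases_between_mids: str, locus_defs: Sequence[LocusDef]
) -> tuple[Optional[LocusDef], Optional[str], Optional[str]]:
    """Identify the locus and orientation from the primers flanking the insert.

    ``bases_between_mids`` runs from just after the 5' MID to just before the
    3' reverse-complemented MID. A forward-orientation read starts with the
    forward primer and ends with the reverse complement of the reverse primer;
    a reverse-orientation read starts with the reverse primer and ends with
    the reverse complement of the forward primer. The whole primer must match
    under IUPAC expansion with zero mismatches at both ends.

    Returns ``(locus, orientation, reason)`` where reason is None on success,
    else ``primer_absent`` or ``ambiguous``.
    """
    seg = bases_between_mids
    hits: list[tuple[LocusDef, str]] = []
    for locus in locus_defs:
        f, r = locus.fwd_primer, locus.rev_primer
        if (
            len(seg) >= len(f) + len(r)
            and iupac_match(f, seg[: len(f)])
            and iupac_match(reverse_complement(r), seg[len(seg) - len(r):])
        ):
            hits.append((locus, FORWARD))
        if (
            len(seg) >= len(f) + len(r)
            and iupac_match(r, seg[: len(r)])
            and iupac_match(reverse_complement(f), seg[len(seg) - len(f):])
        ):
            hits.append((locus, REVERSE))
    if not hits:
        return None, None, PRIMER_ABSENT
    if len({locus.locus_id for locus, _ in hits}) > 1:
        return None, None, AMBIGUOUS
    locus, orientation = hits[0]
    return locus, orientation, None


def quality_trim(read: Read, error_prob_cutoff: float = 0.05) -> Read:
    """Modified-Mott end trimming.

    Each base scores ``cutoff - P_error`` (with ``P_error = 10**(-Q/10)``);
    the maximal-scoring contiguous subsequence is kept. Never lengthens a
    read; an all-bad read trims to empty. Removed ends are recorded as clips
    on the returned read.
    """
    best_score = 0.0
    best = (0, 0)
    running = 0.0
    start = 0
    for i, q in enumerate(read.quals):
        running += error_prob_cutoff - 10.0 ** (-q / 10.0)
        if running <= 0.0:
            running = 0.0
            start = i + 1
        elif running > best_score:
            best_score = running
            best = (start, i + 1)
    return read.trim_to(*best)


def demultiplex(
    reads: Iterable[Read],
    entries: Sequence[SampleSheetEntry],
    locus_defs: Sequence[LocusDef],
    params: DemuxParams = DemuxParams(),
) -> tuple[list[DemuxAssignment], LibraryQualityReport]:
    """Route every read to an (individual, locus) bin or a discard reason.

    Rules run in the order length -> mean quality -> MID -> primer -> quality
    trim -> length re-check. Reverse-orientation inserts are
    reverse-complemented into forward orientation so that downstream pileups
    are single-stranded. The returned ledger is sorted by read id, so the
    output is identical no matter how the input was ordered.
    """
    mid_index = build_mid_index(entries)
    report = LibraryQualityReport()
    ledger: list[DemuxAssignment] = []

    def discard(read: Read, reason: str) -> DemuxAssignment:
        report.discarded_by_reason[reason] += 1
        return DemuxAssignment(read.read_id, "discarded", discard_reason=reason)

    for read in reads:
        report.total_reads += 1
        bin_start = (len(read) // 50) * 50
        report.length_histogram[bin_start] = report.length_histogram.get(bin_start, 0) + 1

        if not length_filter(read, params.min_len):
            report.short_pre_trim += 1
            ledger.append(discard(read, TOO_SHORT))
            continue
        if not mean_quality_filter(read, params.min_mean_q):
            ledger.append(discard(read, LOW_MEAN_QUALITY))
            continue
        mid_hit = match_mid(read, mid_index, params)
        if mid_hit is None:
            ledger.append(discard(read, MID_MISMATCH))
            continue
        entry, start, end = mid_hit
        locus, orientation, reason = match_primer(read.bases[start:end], locus_defs)
        if reason is not None:
            ledger.append(discard(read, reason))
            continue
        p5 = locus.fwd_primer if orientation == FORWARD else locus.rev_primer
        p3 = locus.rev_primer if orientation == FORWARD else locus.fwd_primer
        insert = read.slice(start + len(p5), end - len(p3))
        insert = quality_trim(insert, params.trim_cutoff)
        if len(insert) < params.min_len:
            report.short_post_trim += 1
            ledger.append(discard(read, TOO_SHORT))
            continue
        if orientation == REVERSE:
            insert = insert.reverse_complement()
        report.kept_reads += 1
        ledger.append(
            DemuxAssignment(
                read_id=read.read_id,
                status="kept",
                individual_id=entry.individual_id,
                locus_id=locus.locus_id,
                orientation=orientation,
                trimmed_read=insert,
            )
        )

    ledger.sort(key=lambda a: a.read_id)
    return ledger, report


def bin_reads(ledger: Sequence[DemuxAssignment]) -> dict[tuple[str, str], list[Read]]:
    """Group kept, trimmed reads into (individual, locus) bins, sorted by id."""
    bins: dict[tuple[str, str], list[Read]] = {}
    for a in ledger:
        if a.status == "kept":
            bins.setdefault((a.individual_id, a.locus_id), []).append(a.trimmed_read)
    for reads in bins.values():
        reads.sort(key=lambda r: r.read_id)
    return bins


def ledger_counts(ledger: Sequence[DemuxAssignment]) -> Counter:
    """Tally of ledger statuses/reasons, for logging and conservation checks."""
    return Counter(
        a.discard_reason if a.status == "discarded" else "kept" for a in ledger
    )
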