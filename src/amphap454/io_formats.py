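"""Readers, writers and validated record types for the pipeline's file formats.

The pipeline touches four tabular/sequence formats:

* FASTQ (Sanger Phred+33) or a FASTA + QUAL pair — the sequencing reads;
* a tab-delimited sample sheet mapping MID barcodes to individuals
  (columns ``mid``, ``individual``, ``population``, ``species``);
* a tab-delimited locus table of template-specific primers
  (columns ``locus``, ``fwd_primer``, ``rev_primer``, ``min_len``, ``max_len``);
* a FASTA of called alleles whose headers encode
  ``locus|population|individual|allele_index|support``.

Native 454 flowgram (SFF) files are deliberately out of scope: every rule the
caller applies operates on basecalls and per-base Phred qualities only, so
FASTQ/FASTA+QUAL is the ingest contract. Quality encoding is fixed to
Phred+33; scores above 60 are rejected loudly as a likely +64 dialect rather
than auto-detected.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import PairedFastaQualIterator
from Bio.SeqRecord import SeqRecord

DNA_BASES = frozenset("ACGTN")

#: IUPAC degeneracy codes -> the set of concrete bases each matches.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

MAX_PHRED = 60

#: Recommended amplified-product design range (bp); outside it we warn only.
DESIGN_RANGE = (400, 600)


class FormatError(ValueError):
    """Malformed input file (bad record, bad header, invalid field)."""


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, bases over {A,C,G,T,N}, Phred scores.

    ``clip5``/``clip3`` record how many bases quality trimming removed from
    each end. They matter to the pileup stage: an *untrimmed* end of an
    amplicon read observed the template end (both barcodes were required at
    demultiplexing), so its alignment end gaps are informative "no base
    here" votes, whereas a trimmed end simply stopped observing.
    """

    read_id: str
    bases: str
    quals: tuple[int, ...]
    clip5: int = field(default=0, compare=False)
    clip3: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        object.__setattr__(self, "quals", tuple(int(q) for q in self.quals))
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        bad = set(self.bases) - DNA_BASES
        if bad:
            raise FormatError(f"read {self.read_id!r}: non-DNA characters {sorted(bad)}")
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise FormatError(
                    f"read {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}] "
                    "(is this Phred+64 encoded?)"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        if not self.quals:
            return 0.0
        return sum(self.quals) / len(self.quals)

    def slice(self, start: int, stop: int) -> "Read":
        return Read(self.read_id, self.bases[start:stop], self.quals[start:stop],
                    self.clip5, self.clip3)

    def trim_to(self, start: int, stop: int) -> "Read":
        """Like :meth:`slice`, but records the removed ends as clips."""
        stop = max(start, min(stop, len(self.bases)))
        return Read(
            self.read_id, self.bases[start:stop], self.quals[start:stop],
            self.clip5 + start, self.clip3 + (len(self.bases) - stop),
        )

    def reverse_complement(self) -> "Read":
        rc = str(Seq(self.bases).reverse_complement())
        return Read(self.read_id, rc, self.quals[::-1], self.clip3, self.clip5)


@dataclass(frozen=True)
class SampleSheetEntry:
    """One multiplexed sample: MID barcode -> individual/population/species."""

    mid: str
    individual_id: str
    population_id: str
    species_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mid", self.mid.upper())
        if len(self.mid) < 6:
            raise FormatError(f"MID {self.mid!r} shorter than 6 bp")
        bad = set(self.mid) - frozenset("ACGT")
        if bad:
            raise FormatError(f"MID {self.mid!r}: non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class LocusDef:
    """A template-specific primer pair and the expected amplicon size range.

    Primers may contain IUPAC degeneracy codes (common when one pair must
    amplify across divergent exon sequences). ``min_len``/``max_len`` bound the
    full amplified product, primers included.
    """

    locus_id: str
    fwd_primer: str
    rev_primer: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd_primer", self.fwd_primer.upper())
        object.__setattr__(self, "rev_primer", self.rev_primer.upper())
        for name, p in (("forward", self.fwd_primer), ("reverse", self.rev_primer)):
            if not p:
                raise FormatError(f"locus {self.locus_id!r}: empty {name} primer")
            bad = set(p) - set(IUPAC)
            if bad:
                raise FormatError(
                    f"locus {self.locus_id!r}: {name} primer has non-IUPAC "
                    f"characters {sorted(bad)}"
                )
        if self.min_len > self.max_len:
            raise FormatError(f"locus {self.locus_id!r}: min_len > max_len")
        if self.min_len < DESIGN_RANGE[0] or self.max_len > DESIGN_RANGE[1]:
            warnings.warn(
                f"locus {self.locus_id!r}: amplicon range "
                f"[{self.min_len}, {self.max_len}] outside the recommended "
                f"{DESIGN_RANGE[0]}-{DESIGN_RANGE[1]} bp design window",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AlleleRecord:
    """One called allele of one individual, with its supporting read count."""

    locus_id: str
    population_id: str
    individual_id: str
    allele_seq: str
    supporting_reads: int

    def __post_init__(self) -> None:
        if self.supporting_reads < 1:
            raise FormatError("supporting_reads must be >= 1")


def _record_to_read(rec: SeqRecord) -> Read:
    clip5 = clip3 = 0
    for token in rec.description.split():
        if token.startswith("c5="):
            clip5 = int(token[3:])
        elif token.startswith("c3="):
            clip3 = int(token[3:])
    try:
        return Read(rec.id, str(rec.seq),
                    tuple(rec.letter_annotations["phred_quality"]), clip5, clip3)
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise FormatError(f"record {rec.id!r}: {exc}") from exc


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a Sanger (Phred+33) FASTQ file.

    Malformed records (base/quality length mismatch, quality characters
    outside the Sanger range) abort parsing with a :class:`FormatError`
    naming the offending record.
    """
    last_id = "<start of file>"
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            last_id = rec.id
            yield _record_to_read(rec)
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ near record {last_id!r}: {exc}") from exc


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path) -> Iterator[Read]:
    """Stream reads from a paired FASTA + QUAL file (the 454 export format)."""
    with open(fasta_path) as fh_seq, open(qual_path) as fh_qual:
        try:
            for rec in PairedFastaQualIterator(fh_seq, fh_qual):
                yield _record_to_read(rec)
        except ValueError as exc:
            raise FormatError(f"malformed FASTA/QUAL pair: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Sanger FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            desc = f"c5={r.clip5} c3={r.clip3}" if (r.clip5 or r.clip3) else ""
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description=desc)
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


SAMPLE_SHEET_COLUMNS = ("mid", "individual", "population", "species")
LOCUS_TABLE_COLUMNS = ("locus", "fwd_primer", "rev_primer", "min_len", "max_len")


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected header {required}")
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        return [row for row in reader if any((v or "").strip() for v in row.values())]


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Load and validate a tab-delimited sample sheet.

    MIDs must be unique within each (population, species) pool; a duplicate is
    an error because demultiplexing would be ambiguous.
    """
    entries = [
        SampleSheetEntry(
            mid=row["mid"].strip(),
            individual_id=row["individual"].strip(),
            population_id=row["population"].strip(),
            species_id=row["species"].strip(),
        )
        for row in _read_tsv(path, SAMPLE_SHEET_COLUMNS)
    ]
    seen: dict[tuple[str, str, str], str] = {}
    for e in entries:
        key = (e.population_id, e.species_id, e.mid)
        if key in seen:
            raise FormatError(
                f"duplicate MID {e.mid!r} within pool "
                f"({e.population_id}, {e.species_id}): individuals "
                f"{seen[key]!r} and {e.individual_id!r}"
            )
        seen[key] = e.individual_id
    return entries


def read_locus_table(path: str | Path) -> list[LocusDef]:
    """Load and validate a tab-delimited locus/primer table."""
    defs = []
    seen = set()
    for row in _read_tsv(path, LOCUS_TABLE_COLUMNS):
        try:
            d = LocusDef(
                locus_id=row["locus"].strip(),
                fwd_primer=row["fwd_primer"].strip(),
                rev_primer=row["rev_primer"].strip(),
                min_len=int(row["min_len"]),
                max_len=int(row["max_len"]),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: bad locus row {row!r}: {exc}") from exc
        if d.locus_id in seen:
            raise FormatError(f"duplicate locus id {d.locus_id!r}")
        seen.add(d.locus_id)
        defs.append(d)
    return defs


def write_alleles(
    records: Sequence[AlleleRecord], path: str | Path, allow_empty: bool = False
) -> None:
    """Write called alleles as FASTA.

    Headers encode ``locus|population|individual|allele_index|support`` where
    the allele index numbers the alleles of one individual at one locus in
    input order (1-based). The encoding round-trips through
    :func:`read_alleles`.
    """
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty allele FASTA without allow_empty")
    index: dict[tuple[str, str, str], int] = {}
    with open(path, "w") as fh:
        for rec in records:
            key = (rec.locus_id, rec.population_id, rec.individual_id)
            index[key] = index.get(key, 0) + 1
            header = "|".join(
                [rec.locus_id, rec.population_id, rec.individual_id,
                 str(index[key]), str(rec.supporting_reads)]
            )
            fh.write(f">{header}\n{rec.allele_seq}\n")


def read_alleles(path: str | Path) -> list[AlleleRecord]:
    """Read an allele FASTA written by :func:`write_alleles`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 5:
            raise FormatError(f"allele header {rec.description!r} not locus|pop|ind|idx|support")
        locus, pop, ind, _idx, support = parts
        out.append(AlleleRecord(locus, pop, ind, str(rec.seq).upper(), int(support)))
    return out


def iupac_match(pattern: str, segment: str) -> bool:
    """True iff ``segment`` matches the IUPAC ``pattern`` base-for-base.

    Zero mismatches are tolerated; an uncalled (N) read base matches only a
    wildcard (N) pattern position, never a concrete primer base.
    """
    if len(pattern) != len(segment):
        return False
    return all(p == "N" or s in IUPAC[p] for p, s in zip(pattern, segment))


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, IUPAC codes included."""
    return str(Seq(seq).reverse_complement())
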