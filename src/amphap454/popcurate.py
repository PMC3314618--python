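"""Population-level allele curation and the pipeline's summary statistics.

After genotyping, the alleles of all individuals of one population are pooled
per locus for a final round of error checking. The one editing rule applied
at this level targets the dominant residual pyrosequencing artifact: an
allele observed exactly once in a population ("singleton" — one allele copy,
not one read) that differs from an established allele (count >= 2) by nothing
but a single one-base insertion/deletion inside a homopolymer run is far more
likely a sequencing artifact than a real variant, and is edited to match.

This module also computes the summary statistics reported for a sequencing
run: per-locus coverage means and >=1x / >=5x fractions, unique-allele and
heterozygote counts per locus and species, and the allelic support ratio at
heterozygous loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .haplotyper import CALLED, GenotypeCall, _make_aligner


@dataclass
class AlleleEdit:
    """Log entry for one singleton correction."""

    locus_id: str
    population_id: str
    singleton_seq: str
    corrected_to: str
    partner_count: int


@dataclass
class PopulationAlleleTable:
    """Allele spectrum of one locus in one population.

    ``alleles`` maps allele sequence -> count of allele copies across the
    successfully called diploid individuals (so counts sum to 2x the number
    of called individuals).
    """

    locus_id: str
    population_id: str
    alleles: dict = field(default_factory=dict)
    edits: list = field(default_factory=list)

    @property
    def total_copies(self) -> int:
        return sum(self.alleles.values())

    @property
    def n_unique(self) -> int:
        return sum(1 for c in self.alleles.values() if c > 0)


def build_allele_table(
    calls: Iterable[GenotypeCall], locus_id: str, population_id: str
) -> PopulationAlleleTable:
    """Pool both allele copies of every called genotype at one locus."""
    table = PopulationAlleleTable(locus_id, population_id)
    for call in calls:
        if call.status != CALLED or call.locus_id != locus_id:
            continue
        for seq in (call.allele1_seq, call.allele2_seq):
            table.alleles[seq] = table.alleles.get(seq, 0) + 1
    return table


def _single_homopolymer_indel(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` differ by exactly one length-1 indel that sits
    inside a homopolymer run (run length >= 2 in the longer sequence).

    The test aligns the pair globally (same scoring as the pileup stage) and
    demands zero substitutions and a single one-base gap whose base repeats
    an adjacent base of the longer sequence — a lone-base insertion next to a
    different base is not homopolymer context and is not eligible.
    """
    if abs(len(a) - len(b)) != 1:
        return False
    longer, shorter = (a, b) if len(a) > len(b) else (b, a)
    aligner = _make_aligner()
    aln = aligner.align(longer, shorter)[0]
    top, bottom = str(aln[0]), str(aln[1])
    gaps = [i for i, (x, y) in enumerate(zip(top, bottom)) if x == "-" or y == "-"]
    if len(gaps) != 1:
        return False
    subs = sum(1 for x, y in zip(top, bottom) if x != y and x != "-" and y != "-")
    if subs != 0:
        return False
    i = gaps[0]
    if top[i] == "-":  # the gap must be in the shorter sequence
        return False
    base = top[i]
    left = top[i - 1] if i > 0 else None
    right = top[i + 1] if i + 1 < len(top) else None
    return base in (left, right)


def singleton_correction(table: PopulationAlleleTable) -> PopulationAlleleTable:
    """Edit singleton alleles that differ from an established allele by one
    homopolymer indel.

    Eligibility is judged against the pre-correction table (singleton = count
    exactly 1; partners = count >= 2), and singletons are processed in
    deterministic (lexicographic) order, so the result is independent of the
    order allele records arrived in. Among multiple eligible partners the
    highest-count one wins, ties lexicographically. Total allele-copy count
    is conserved; the number of unique alleles can only shrink.
    """
    before = dict(table.alleles)
    partners = sorted(
        (seq for seq, c in before.items() if c >= 2),
        key=lambda s: (-before[s], s),
    )
    out = PopulationAlleleTable(table.locus_id, table.population_id,
                                dict(before), list(table.edits))
    for singleton in sorted(s for s, c in before.items() if c == 1):
        for partner in partners:
            if _single_homopolymer_indel(singleton, partner):
                out.alleles[partner] = out.alleles.get(partner, 0) + 1
                out.alleles[singleton] -= 1
                if out.alleles[singleton] == 0:
                    del out.alleles[singleton]
                out.edits.append(
                    AlleleEdit(
                        table.locus_id, table.population_id,
                        singleton, partner, before[partner],
                    )
                )
                break
    return out


def allele_proportion(allele1_cov: int, total_cov: int) -> float:
    """Fraction of a bin's coverage carried by allele 1."""
    if total_cov <= 0:
        raise ValueError("total coverage must be positive")
    if not 0 < allele1_cov <= total_cov:
        raise ValueError("allele coverage must be in (0, total]")
    return allele1_cov / total_cov


@dataclass
class AllelicRatioStats:
    """Support imbalance between the two alleles of heterozygous calls."""

    n_het: int
    mean_ratio: float            # mean of support1/support2 (>= 1 each)
    ratios: list = field(default_factory=list)


def allelic_ratio_stats(calls: Iterable[GenotypeCall]) -> AllelicRatioStats:
    """Mean major:minor read-support ratio over heterozygous calls."""
    ratios = [
        c.allele1_support / c.allele2_support
        for c in calls
        if c.is_het and c.allele2_support > 0
    ]
    mean = float(np.mean(ratios)) if ratios else float("nan")
    return AllelicRatioStats(len(ratios), mean, ratios)


@dataclass
class DiversitySummary:
    """Run-level summary: coverage, allele and heterozygote counts."""

    per_locus_species: pd.DataFrame   # locus, species, unique_alleles, heterozygotes, n_called
    mean_coverage: float
    per_locus_mean_coverage: dict
    frac_ge_1x: float
    frac_ge_5x: float
    mean_het_ratio: float


def diversity_summary(
    calls: Sequence[GenotypeCall],
    species_of_individual: Optional[dict] = None,
    tables: Optional[Sequence[PopulationAlleleTable]] = None,
) -> DiversitySummary:
    """Summarise a genotyped run.

    Coverage fractions are computed over every *attempted* bin: a bin that
    yielded no reads still counts (as 0x) in the >=1x / >=5x denominators.
    Unique-allele counts use the curated tables when given, else the raw
    calls. Heterozygote = a called genotype whose two alleles differ.
    """
    species_of_individual = species_of_individual or {}
    cov = np.array([c.coverage for c in calls], dtype=float)
    mean_cov = float(cov.mean()) if cov.size else float("nan")
    frac1 = float((cov >= 1).mean()) if cov.size else float("nan")
    frac5 = float((cov >= 5).mean()) if cov.size else float("nan")

    per_locus: dict[str, list[float]] = {}
    for c in calls:
        per_locus.setdefault(c.locus_id, []).append(c.coverage)
    per_locus_mean = {k: float(np.mean(v)) for k, v in per_locus.items()}

    curated_unique: dict[str, int] = {}
    if tables is not None:
        for t in tables:
            curated_unique[t.locus_id] = curated_unique.get(t.locus_id, 0) + t.n_unique

    rows = []
    groups: dict[tuple[str, str], list[GenotypeCall]] = {}
    for c in calls:
        sp = species_of_individual.get(c.individual_id, "all")
        groups.setdefault((c.locus_id, sp), []).append(c)
    for (locus, sp), grp in sorted(groups.items()):
        called = [c for c in grp if c.status == CALLED]
        if locus in curated_unique:
            unique = curated_unique[locus]
        else:
            unique = len({s for c in called for s in (c.allele1_seq, c.allele2_seq)})
        rows.append(
            {
                "locus": locus,
                "species": sp,
                "unique_alleles": unique,
                "heterozygotes": sum(1 for c in called if c.is_het),
                "n_called": len(called),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["locus", "species", "unique_alleles", "heterozygotes", "n_called"]
    )
    ratio = allelic_ratio_stats(calls)
    return DiversitySummary(
        per_locus_species=frame,
        mean_coverage=mean_cov,
        per_locus_mean_coverage=per_locus_mean,
        frac_ge_1x=frac1,
        frac_ge_5x=frac5,
        mean_het_ratio=ratio.mean_ratio,
    )
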