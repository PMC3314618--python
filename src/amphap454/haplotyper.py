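"""Diploid genotype calling from one individual's clonal amplicon reads.

Because each read derives from a single template molecule (emulsion PCR is
clonal amplification), a read *is* a haplotype observation. Genotyping one
(individual, locus) bin therefore reduces to:

1. **Pileup** — star alignment: the highest mean-quality read seeds the
   contig; every other read is globally aligned to it (match +1, mismatch -2,
   gap open -4, gap extend -1, free end gaps) and merged column-wise.
2. **Column calls** — a column is heterozygous when its plurality symbol
   falls strictly below 75% of the column depth; gaps count in the depth.
3. **Homopolymer arbitration** — length variation of a same-base run is the
   dominant pyrosequencing error mode, so runs whose observed lengths vary
   via alignment gaps are not treated as heterozygous. Three criteria decide
   the run length: (a) a length class supported by >=75% of spanning reads
   wins outright; (b) otherwise the class whose reads have the higher mean
   quality across the run wins; (c) quality ties break toward the shorter
   run. Below 10x coverage the quality criterion decides alone.
4. **Phasing** — reads are keyed by their symbol vector across heterozygous
   sites; the two most common keys become the two allelic states.
5. **Chimera removal** — reads whose key mixes the two allelic states
   (matching allele 1 at >=1 differing site and allele 2 at another) are PCR
   template-switching artifacts and are removed.
6. Allele sequences are re-derived as the within-class column consensus,
   with per-class homopolymer re-arbitration.

Exactly two alleles are ever emitted (diploid assumption); third-ranked
haplotypes are surfaced in a QC side channel, never called.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io_formats import LocusDef, Read

GAP = "-"
NOCOV = ""  # column not covered by the read (outside its aligned span)
SYMBOLS = ("A", "C", "G", "T", "N", GAP)

CALLED = "called"
FAILED_NO_READS = "failed_no_reads"
FAILED_LOW_COVERAGE = "failed_low_coverage"

#: star-alignment scores; fixed defaults, overridable for experimentation
ALIGN_SCORES = {"match": 1, "mismatch": -2, "open": -4, "extend": -1}


def _make_aligner(scores: dict = ALIGN_SCORES) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores["match"]
    aligner.mismatch_score = scores["mismatch"]
    aligner.open_gap_score = scores["open"]
    aligner.extend_gap_score = scores["extend"]
    # free end gaps: reads may start/stop anywhere on the seed
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # attribute names before the insertion/deletion renaming
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


@dataclass
class PileupColumn:
    """Symbol and quality tallies for one alignment column."""

    counts: dict
    qual_sums: dict

    @property
    def depth(self) -> int:
        """Non-N coverage of the column (gaps included, Ns excluded)."""
        return sum(c for s, c in self.counts.items() if s != "N")


@dataclass
class Pileup:
    """Column-wise aligned read stack for one (individual, locus) bin.

    ``matrix[i, j]`` holds read i's symbol at column j: a base, ``-`` for a
    gap inside the read's span, or ``""`` where the read does not reach.
    """

    locus_id: str
    individual_id: str
    read_ids: list[str]
    matrix: np.ndarray          # (n_reads, n_cols) of unicode symbols
    quals: np.ndarray           # (n_reads, n_cols) int, -1 where no base

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def _tallies(self) -> tuple[dict, dict]:
        """Per-symbol count and quality-sum vectors over columns (cached)."""
        cached = getattr(self, "_tally_cache", None)
        if cached is not None:
            return cached
        qpos = np.where(self.quals > 0, self.quals, 0)
        counts = {}
        qsums = {}
        for s in SYMBOLS:
            hit = self.matrix == s
            counts[s] = hit.sum(axis=0)
            qsums[s] = (qpos * hit).sum(axis=0)
        object.__setattr__(self, "_tally_cache", (counts, qsums))
        return counts, qsums

    def column(self, j: int) -> PileupColumn:
        counts, qsums = self._tallies()
        return PileupColumn(
            {s: int(counts[s][j]) for s in SYMBOLS if counts[s][j]},
            {s: int(qsums[s][j]) for s in SYMBOLS if counts[s][j]},
        )

    def columns(self) -> list[PileupColumn]:
        cached = getattr(self, "_column_cache", None)
        if cached is None:
            cached = [self.column(j) for j in range(self.n_columns)]
            object.__setattr__(self, "_column_cache", cached)
        return cached


@dataclass(frozen=True)
class HetSite:
    """One column called heterozygous (<75% plurality consensus)."""

    column_index: int
    major_symbol: str
    minor_symbol: str
    major_count: int
    minor_count: int
    is_indel: bool
    is_homopolymer: bool


@dataclass
class HomopolymerCall:
    """Arbitration record for one length-variable same-base run."""

    flank_position: int               # first pileup column of the run
    base: str
    candidate_lengths: list[int]
    counts_per_length: dict
    mean_quality_per_length: dict
    chosen_length: int
    decision_basis: str               # majority | quality | both


@dataclass
class GenotypeCall:
    """The diploid call for one (individual, locus) bin."""

    locus_id: str
    individual_id: str
    status: str
    allele1_seq: str = ""
    allele2_seq: str = ""
    coverage: int = 0
    het_sites: list = field(default_factory=list)
    allele1_support: int = 0
    allele2_support: int = 0
    chimeric_reads_removed: int = 0
    unassigned_reads: int = 0
    homopolymer_calls: list = field(default_factory=list)
    #: QC side channel: (key, count) of haplotype keys ranked third or lower
    minor_haplotypes: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def is_het(self) -> bool:
        return self.status == CALLED and self.allele1_seq != self.allele2_seq


def _align_to_seed(aligner: Align.PairwiseAligner, seed: str, query: str) -> tuple[str, str]:
    aln = aligner.align(seed, query)[0]
    return str(aln[0]), str(aln[1])


def build_pileup(reads: Sequence[Read], locus: LocusDef, individual_id: str = "") -> Pileup:
    """Star-align a read bin into a pileup.

    The seed is the longest read (ties: higher mean quality, then smaller
    read id), so the result is deterministic for a given read set regardless
    of input order. Length wins over quality because a quality-trimmed seed
    truncates the column space: template ends observed by full-span reads
    would surface as end-junction insertions and masquerade as indel
    variation.
    """
    if not reads:
        raise ValueError("cannot build a pileup from zero reads")
    order = sorted(reads, key=lambda r: (-len(r), -r.mean_quality, r.read_id))
    seed = order[0]
    others = sorted(order[1:], key=lambda r: r.read_id)
    aligner = _make_aligner()

    L = len(seed)
    # per-read: symbol at each seed position, and insertions keyed by the seed
    # position they follow (-1 = before the seed start)
    per_read: list[tuple[Read, dict, dict]] = []
    max_ins: dict[int, int] = {}

    for r in others:
        s_aln, q_aln = _align_to_seed(aligner, seed.bases, r.bases)
        sym: dict[int, tuple[str, int]] = {}
        ins: dict[int, list[tuple[str, int]]] = {}
        si = -1
        qi = 0
        qpos: list[Optional[int]] = []   # per alignment col: read index or None
        scol: list[int] = []             # per alignment col: seed pos (or -1 ins)
        for a, b in zip(s_aln, q_aln):
            if a != "-":
                si += 1
            if b != "-":
                qpos.append(qi)
                qi += 1
            else:
                qpos.append(None)
            scol.append(si if a != "-" else -2)  # -2 marks an insertion col
        # read span within the alignment (exclude end gaps)
        nz = [k for k, p in enumerate(qpos) if p is not None]
        lo, hi = nz[0], nz[-1]
        si = -1
        for k, (a, b) in enumerate(zip(s_aln, q_aln)):
            if a != "-":
                si += 1
            if k < lo or k > hi:
                continue
            if a != "-":
                if b != "-":
                    sym[si] = (b, r.quals[qpos[k]])
                else:
                    sym[si] = (GAP, -1)
            else:  # insertion relative to the seed, after seed position si
                if b != "-":
                    ins.setdefault(si, []).append((b, r.quals[qpos[k]]))
        for pos, bases in ins.items():
            max_ins[pos] = max(max_ins.get(pos, 0), len(bases))
        per_read.append((r, sym, ins))

    # column layout: [ins after -1] seed0 [ins after 0] seed1 ...
    col_of_seed: dict[int, int] = {}
    ins_start: dict[int, int] = {}
    ncols = 0
    for pos in range(-1, L):
        if pos >= 0:
            col_of_seed[pos] = ncols
            ncols += 1
        if pos in max_ins:
            ins_start[pos] = ncols
            ncols += max_ins[pos]

    n = len(reads)
    matrix = np.full((n, ncols), NOCOV, dtype="<U1")
    quals = np.full((n, ncols), -1, dtype=np.int16)
    read_ids = [seed.read_id] + [r.read_id for r, _, _ in per_read]

    # seed row
    for pos in range(L):
        j = col_of_seed[pos]
        matrix[0, j] = seed.bases[pos]
        quals[0, j] = seed.quals[pos]
    for pos, start in ins_start.items():
        # the seed votes "no base" at interior junctions always, and at the
        # template-end junctions only if that end of it was not trimmed away
        if (pos == -1 and seed.clip5 > 0) or (pos == L - 1 and seed.clip3 > 0):
            continue
        for j in range(start, start + max_ins[pos]):
            matrix[0, j] = GAP

    for i, (r, sym, ins) in enumerate(per_read, start=1):
        if not sym and not ins:
            continue
        covered = sorted(sym) if sym else []
        s_lo = covered[0] if covered else L
        s_hi = covered[-1] if covered else -1
        # an untrimmed read end observed the template end: everything between
        # its alignment end and the template end is an informative gap
        informative5 = r.clip5 == 0
        informative3 = r.clip3 == 0
        for pos, (s, q) in sym.items():
            j = col_of_seed[pos]
            matrix[i, j] = s
            quals[i, j] = q
        if informative5:
            for pos in range(0, s_lo):
                matrix[i, col_of_seed[pos]] = GAP
        if informative3:
            for pos in range(max(s_hi + 1, 0), L):
                matrix[i, col_of_seed[pos]] = GAP
        for pos, start in ins_start.items():
            bases = ins.get(pos, [])
            width = max_ins[pos]
            # the read informs the junction between seed positions pos and
            # pos+1 iff it covers both sides, it has inserted bases there, or
            # the junction lies beyond an untrimmed (template-observing) end
            spans = (
                (s_lo <= pos < s_hi)
                or pos in ins
                or (pos < s_lo and informative5)
                or (pos >= s_hi and informative3)
            )
            for k in range(width):
                j = start + k
                if k < len(bases):
                    matrix[i, j] = bases[k][0]
                    quals[i, j] = bases[k][1]
                elif spans:
                    matrix[i, j] = GAP
    return Pileup(locus.locus_id, individual_id, read_ids, matrix, quals)


_SYMBOL_ORDER = {s: k for k, s in enumerate((GAP, "A", "C", "G", "T", "N"))}


def call_column(col: PileupColumn, het_threshold: float = 0.75):
    """Call one column: heterozygous iff the plurality fraction is < threshold.

    Returns ``(symbol, None)`` for a homozygous column or ``(major, minor)``
    for a heterozygous one. N never participates; gaps count in the depth.
    Ties are broken deterministically (gap first, then alphabetically).
    """
    depth = col.depth
    if depth < 1:
        raise ValueError("cannot call a zero-depth column")
    ranked = sorted(
        ((s, c) for s, c in col.counts.items() if s != "N" and c > 0),
        key=lambda sc: (-sc[1], _SYMBOL_ORDER[sc[0]]),
    )
    major, major_count = ranked[0]
    if major_count / depth >= het_threshold or len(ranked) == 1:
        return major, None
    return major, ranked[1][0]


def _plurality_base(col: PileupColumn, purity: float = 0.75) -> Optional[str]:
    """Most frequent concrete base of a column (gaps/N excluded), or None when
    a credible second base is present.

    The mixed-column gate keeps genuinely heterozygous columns (a variant
    base inside or beside a run) out of homopolymer regions, so run-length
    arbitration cannot erase a real allelic difference. Credibility is
    judged against the full column depth, gaps included — the same
    denominator the heterozygosity rule uses — so a stray miscalled base or
    two among mostly-gap insertion columns does not split a run.
    """
    ranked = sorted(
        ((s, c) for s, c in col.counts.items() if s in "ACGT" and c > 0),
        key=lambda sc: (-sc[1], sc[0]),
    )
    if not ranked:
        return None
    if len(ranked) > 1 and ranked[1][1] >= (1.0 - purity) * col.depth:
        return None
    return ranked[0][0]


def find_homopolymer_regions(pileup: Pileup, purity: float = 0.75) -> list[tuple[int, int, str]]:
    """Locate same-base runs whose observed length varies through gaps.

    Returns ``(start_col, end_col_exclusive, base)`` for maximal runs of
    columns sharing one pure plurality base, spanning >= 2 columns, in which
    at least one spanning read carries an alignment gap. Substitution-only
    variation never triggers a region (a true heterozygous base adjacent to a
    run aligns as a mismatch, not a gap, under the gap-averse scoring), and a
    mixed-identity column splits a run rather than joining it.
    """
    cols = pileup.columns()
    bases = [_plurality_base(c, purity) for c in cols]
    regions = []
    j = 0
    while j < pileup.n_columns:
        b = bases[j]
        if b is None:
            j += 1
            continue
        k = j
        while k < pileup.n_columns and bases[k] == b:
            k += 1
        if k - j >= 2:
            block = pileup.matrix[:, j:k]
            spanning = ~np.any(block == NOCOV, axis=1)
            if np.any(block[spanning] == GAP):
                regions.append((j, k, b))
        j = k
    return regions


def resolve_homopolymer(
    pileup: Pileup,
    region: tuple[int, int, str],
    het_threshold: float = 0.75,
    min_majority_cov: int = 10,
    read_mask: Optional[np.ndarray] = None,
) -> HomopolymerCall:
    """Arbitrate the length of one homopolymer run.

    ``read_mask`` restricts the vote to a subset of reads (used when
    re-deriving each allele from its own read class after phasing).
    """
    j0, j1, base = region
    block = pileup.matrix[:, j0:j1]
    qblock = pileup.quals[:, j0:j1]
    if read_mask is None:
        valid = ~np.any(block == NOCOV, axis=1)
    else:
        valid = np.asarray(read_mask, dtype=bool) & ~np.any(block == NOCOV, axis=1)

    nongap = (block != GAP) & (block != NOCOV)
    ells = nongap.sum(axis=1)
    qpos = np.where(qblock >= 0, qblock, 0)
    qcnt = (nongap & (qblock >= 0)).sum(axis=1)
    qsum = (qpos * (nongap & (qblock >= 0))).sum(axis=1)

    lengths: dict[int, int] = {}
    qual_obs: dict[int, list[float]] = {}
    for i in np.flatnonzero(valid):
        ell = int(ells[i])
        lengths[ell] = lengths.get(ell, 0) + 1
        if qcnt[i]:
            qual_obs.setdefault(ell, []).append(float(qsum[i]) / float(qcnt[i]))
        else:
            # a zero-length observation has no bases in the run; use the
            # nearest covered flanking base quality as its confidence
            flank = []
            if j0 > 0 and pileup.quals[i, j0 - 1] >= 0:
                flank.append(float(pileup.quals[i, j0 - 1]))
            if j1 < pileup.n_columns and pileup.quals[i, j1] >= 0:
                flank.append(float(pileup.quals[i, j1]))
            qual_obs.setdefault(ell, []).append(
                float(np.mean(flank)) if flank else 0.0
            )

    if not lengths:
        return HomopolymerCall(j0, base, [], {}, {}, 0, "quality")

    depth = sum(lengths.values())
    mean_q = {ell: float(np.mean(v)) for ell, v in qual_obs.items()}
    candidates = sorted(lengths)

    def by_quality() -> int:
        return min(candidates, key=lambda ell: (-mean_q.get(ell, 0.0), ell))

    if depth < min_majority_cov:
        chosen, basis = by_quality(), "quality"
    else:
        majority = [ell for ell, c in lengths.items() if c / depth >= het_threshold]
        if majority:
            chosen = majority[0]
            basis = "both" if chosen == by_quality() else "majority"
        else:
            chosen, basis = by_quality(), "quality"
    return HomopolymerCall(j0, base, candidates, dict(lengths), mean_q, chosen, basis)


def _consensus_sequence(
    pileup: Pileup,
    regions: Sequence[tuple[int, int, str]],
    hp_calls: Sequence[HomopolymerCall],
    het_threshold: float,
    min_majority_cov: int,
    read_mask: Optional[np.ndarray] = None,
    overrides: Optional[dict] = None,
) -> str:
    """Column-plurality consensus, with homopolymer regions emitted at their
    arbitrated length and explicit per-column symbol overrides (het sites)."""
    rows = np.arange(pileup.n_reads) if read_mask is None else np.flatnonzero(read_mask)
    region_at = {}
    for reg in regions:
        for j in range(reg[0], reg[1]):
            region_at[j] = reg
    hp_len = {reg[0]: None for reg in regions}
    global_len = {call.flank_position: call.chosen_length for call in hp_calls}
    if read_mask is None:
        hp_len.update(global_len)
    else:
        # re-derivation within one phased read class: trust the class only
        # when it has its own clear majority (a genuinely allele-specific run
        # length); otherwise inherit the full-depth arbitration rather than
        # let a couple of miscalled flows in a small class decide
        for reg in regions:
            call = resolve_homopolymer(
                pileup, reg, het_threshold, min_majority_cov, read_mask
            )
            chosen = global_len.get(reg[0], 0)
            if call.candidate_lengths:
                depth = sum(call.counts_per_length.values())
                length, count = max(
                    call.counts_per_length.items(), key=lambda lc: (lc[1], -lc[0])
                )
                if count / depth >= het_threshold:
                    chosen = length
            hp_len[reg[0]] = chosen

    sub = pileup.matrix[rows]
    subq = np.where(pileup.quals[rows] > 0, pileup.quals[rows], 0)
    sym_list = [s for s in SYMBOLS if s != "N"]
    cnt = np.stack([(sub == s).sum(axis=0) for s in sym_list])
    qs = np.stack([(subq * (sub == s)).sum(axis=0) for s in sym_list])
    # count first; equal counts (tiny read classes) resolve by summed
    # quality, then by a fixed symbol order for determinism (the stack order
    # is the symbol order, and argmax takes the first maximum)
    pref = {s: len(sym_list) - _SYMBOL_ORDER[s] for s in sym_list}
    order = np.array([pref[s] for s in sym_list])[:, None]
    score = cnt.astype(np.int64) * 10**9 + qs.astype(np.int64) * 10 + order
    best = np.argmax(score, axis=0)
    covered = cnt.sum(axis=0) > 0

    out: list[str] = []
    j = 0
    while j < pileup.n_columns:
        if j in region_at and region_at[j][0] == j:
            j0, j1, base = region_at[j]
            out.append(base * (hp_len[j0] or 0))
            j = j1
            continue
        if overrides and j in overrides:
            s = overrides[j]
        elif covered[j]:
            s = sym_list[int(best[j])]
        else:
            j += 1
            continue
        if s != GAP:
            out.append(s)
        j += 1
    return "".join(out)


def _read_key(pileup: Pileup, i: int, sites: Sequence[HetSite]) -> tuple:
    return tuple(pileup.matrix[i, s.column_index] for s in sites)


def phase_reads(
    pileup: Pileup,
    het_sites: Sequence[HetSite],
) -> tuple[Optional[tuple], Optional[tuple], dict, list]:
    """Sort reads by their het-site symbol vectors; pick the two top keys.

    Returns ``(key1, key2, assignments, minor_keys)`` where ``assignments``
    maps read index -> 1, 2 or 0 (unassigned), and ``minor_keys`` lists
    (key, count) for complete keys ranked third or lower. Reads that do not
    span every het site are keyed on the sites they span and assigned only
    when consistent with exactly one of the two chosen keys. ``key1`` is None
    when fewer than two distinct complete keys exist (caller falls back to a
    homozygous call).
    """
    n = pileup.n_reads
    keys = [_read_key(pileup, i, het_sites) for i in range(n)]
    complete = [k for k in keys if NOCOV not in k]
    counts = Counter(complete)
    if len(counts) < 2:
        return None, None, {}, []
    ranked = sorted(counts.items(), key=lambda kc: (-kc[1], kc[0]))
    key1, key2 = ranked[0][0], ranked[1][0]
    minor = ranked[2:]

    assignments: dict[int, int] = {}
    for i, k in enumerate(keys):
        if NOCOV not in k:
            assignments[i] = 1 if k == key1 else 2 if k == key2 else 0
        else:
            m1 = all(a == b for a, b in zip(k, key1) if a != NOCOV)
            m2 = all(a == b for a, b in zip(k, key2) if a != NOCOV)
            assignments[i] = 1 if (m1 and not m2) else 2 if (m2 and not m1) else 0
    return key1, key2, assignments, minor


def chimeric_read_indices(
    pileup: Pileup, het_sites: Sequence[HetSite], key1: tuple, key2: tuple
) -> list[int]:
    """Indices of reads that recombine the two allelic states.

    A read is chimeric iff, over the het sites where the two alleles differ,
    its symbols match allele 1 at >= 1 site and allele 2 at >= 1 other site —
    the signature of PCR template switching between the two true templates.
    Only reads spanning all het sites are judged; homozygous bins (no
    differing sites) never yield chimeras.
    """
    diff = [d for d in range(len(het_sites)) if key1[d] != key2[d]]
    if len(diff) < 2:
        return []
    out = []
    for i in range(pileup.n_reads):
        k = _read_key(pileup, i, het_sites)
        if NOCOV in k:
            continue
        hits1 = any(k[d] == key1[d] for d in diff)
        hits2 = any(k[d] == key2[d] for d in diff)
        only1 = all(k[d] == key1[d] for d in diff)
        only2 = all(k[d] == key2[d] for d in diff)
        if hits1 and hits2 and not only1 and not only2:
            out.append(i)
    return out


def genotype_bin(
    reads: Sequence[Read],
    locus: LocusDef,
    individual_id: str = "",
    het_threshold: float = 0.75,
    min_homopolymer_cov: int = 10,
    min_coverage: int = 1,
    min_het_depth: int = 4,
) -> GenotypeCall:
    """Full diploid call for one demultiplexed (individual, locus) bin."""
    call = GenotypeCall(locus.locus_id, individual_id, FAILED_NO_READS)
    if not reads:
        return call
    call.coverage = len(reads)
    if len(reads) < min_coverage:
        call.status = FAILED_LOW_COVERAGE
        return call

    pileup = build_pileup(reads, locus, individual_id)
    regions = find_homopolymer_regions(pileup)
    region_cols = {j for reg in regions for j in range(reg[0], reg[1])}
    call.homopolymer_calls = [
        resolve_homopolymer(pileup, reg, het_threshold, min_homopolymer_cov)
        for reg in regions
    ]

    het_sites: list[HetSite] = []
    cols = pileup.columns()
    for j, col in enumerate(cols):
        # the <75% rule needs a minimally informative column: contig edges
        # covered by a couple of reads cannot witness heterozygosity
        if col.depth < max(1, min_het_depth) or j in region_cols:
            continue
        major, minor = call_column(col, het_threshold)
        if minor is not None:
            het_sites.append(
                HetSite(
                    column_index=j,
                    major_symbol=major,
                    minor_symbol=minor,
                    major_count=col.counts.get(major, 0),
                    minor_count=col.counts.get(minor, 0),
                    is_indel=(GAP in (major, minor)),
                    is_homopolymer=False,
                )
            )
    call.het_sites = het_sites

    def homozygous_call() -> GenotypeCall:
        seq = _consensus_sequence(
            pileup, regions, call.homopolymer_calls, het_threshold, min_homopolymer_cov
        )
        call.allele1_seq = call.allele2_seq = seq
        call.allele1_support = call.allele2_support = pileup.n_reads
        call.status = CALLED if seq else FAILED_LOW_COVERAGE
        return call

    if not het_sites or pileup.n_reads < 2:
        return homozygous_call()

    key1, key2, assignments, minor = phase_reads(pileup, het_sites)
    if key1 is None:
        call.warnings.append("inconsistent het sites; fell back to homozygous call")
        return homozygous_call()

    chim = set(chimeric_read_indices(pileup, het_sites, key1, key2))
    call.chimeric_reads_removed = len(chim)
    class1 = np.array(
        [assignments.get(i) == 1 and i not in chim for i in range(pileup.n_reads)]
    )
    class2 = np.array(
        [assignments.get(i) == 2 and i not in chim for i in range(pileup.n_reads)]
    )
    # sequence re-derivation masks additionally take unassigned reads whose
    # key is strictly closer to one allelic state (a lone miscalled site must
    # not cost a read's evidence at every other column); supports stay exact
    mask1, mask2 = class1.copy(), class2.copy()
    for i in range(pileup.n_reads):
        if assignments.get(i) != 0 or i in chim:
            continue
        k = _read_key(pileup, i, het_sites)
        if NOCOV in k:
            continue
        d1 = sum(a != b for a, b in zip(k, key1))
        d2 = sum(a != b for a, b in zip(k, key2))
        if d1 < d2:
            mask1[i] = True
        elif d2 < d1:
            mask2[i] = True
    call.minor_haplotypes = [(k, c) for k, c in minor]
    if not class1.any() or not class2.any():
        call.warnings.append("a phased class lost all reads; fell back to homozygous call")
        return homozygous_call()

    ov1 = {s.column_index: k for s, k in zip(het_sites, key1)}
    ov2 = {s.column_index: k for s, k in zip(het_sites, key2)}
    seq1 = _consensus_sequence(
        pileup, regions, call.homopolymer_calls, het_threshold,
        min_homopolymer_cov, read_mask=mask1, overrides=ov1,
    )
    seq2 = _consensus_sequence(
        pileup, regions, call.homopolymer_calls, het_threshold,
        min_homopolymer_cov, read_mask=mask2, overrides=ov2,
    )
    s1, s2 = int(class1.sum()), int(class2.sum())
    # allele 1 is the better-supported state; support ties break toward the
    # lexicographically smaller sequence
    if s2 > s1 or (s2 == s1 and seq2 < seq1):
        seq1, seq2, s1, s2 = seq2, seq1, s2, s1
    call.allele1_seq, call.allele2_seq = seq1, seq2
    call.allele1_support, call.allele2_support = s1, s2
    call.unassigned_reads = int(
        sum(1 for i in range(pileup.n_reads) if assignments.get(i) == 0 and i not in chim)
    )
    call.status = CALLED
    return call


def majority_confidence_exact(k_reads: int, p_correct: float) -> float:
    """Closed-form P(majority of ``k_reads`` clonal reads is correct).

    With per-read correctness ``p``, the majority of an odd sample of k reads
    is correct with probability sum_{i>k/2} C(k,i) p^i (1-p)^(k-i). Kept here
    (next to the caller it justifies) as the exact reference for the
    binomial-tail implementation in the design/cost module.
    """
    from math import comb

    if k_reads % 2 == 0:
        raise ValueError("majority is undefined for an even read count")
    return float(
        sum(
            comb(k_reads, i) * p_correct**i * (1 - p_correct) ** (k_reads - i)
            for i in range(k_reads // 2 + 1, k_reads + 1)
        )
    )
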