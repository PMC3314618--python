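"""Synthetic multiplexed amplicon pyrosequencing libraries with ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a multiplexed design — two species, five intron loci each, twenty
  individuals per species per sequencing region, every individual labelled by
  a MID barcode carried on both fusion primers;
* diploid genotypes drawn from per-locus allele pools whose frequencies are
  tuned so realized heterozygosity converges to a configured per-species
  value (one high-diversity and one low-diversity species by default);
* reads laid out adaptor-MID-primer-insert-rc(primer)-rc(MID)-adaptor,
  sequenced off either strand, with coverage per (individual, locus) bin
  drawn from a negative binomial around a 70.7x mean;
* a pyrosequencing-flavoured error model: a mostly-high-quality base error
  process (mean per-base substitution rate 1% concentrated in a small
  fraction of low-quality bases, so mean read quality stays above the Q30
  filter, as in real base-called data), homopolymer run-length errors whose
  probability grows with run length, single-crossover PCR chimeras at 12.5%
  of reads in heterozygous bins with a 13:9 allelic-ratio skew, and a
  configurable contamination fraction of short truncated junk reads;
* Phred qualities emitted from the same per-base error probabilities that
  drive the substitution process, so the mean-quality filter stays
  meaningful.

Every emitted read joins to exactly one truth row, and identical config +
seed reproduces the library byte for byte.

What the generator does *not* model: flowgram-level chemistry, emPCR
duplicate structure, cross-talk between gasket regions, or allelic
homopolymer-length polymorphism (allele pools diverge by substitutions
only — see the methods note for why).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    IUPAC,
    LocusDef,
    Read,
    SampleSheetEntry,
    reverse_complement,
    write_fastq,
)
from .demux import ADAPTOR_A, ADAPTOR_B

BASES = np.array(list("ACGT"))

#: Species-specific exon-primed intron-crossing primer panel for the two
#: sea-star study species (five nuclear loci each; the degenerate codes in
#: the second species' EFA1a/GPI pairs are real design features and exercise
#: IUPAC-aware matching).
DEFAULT_PANEL: dict[str, list[tuple[str, str, str]]] = {
    "Pexi": [
        ("ATPSa", "TTTGCACCAGTGACCTTTTG", "GCCCTTTGAGCTACAGTTCG"),
        ("EFA1a", "AAAGGAAGCCGCTGAGGTGAGT", "CGATGACGGTGCAGTAATACC"),
        ("GPI", "GCCAAGCACTTTGTTGCCTT", "TCCCAGAAGGGAAACATGTTATCCTTGTCG"),
        ("TBP", "TGTCAAGCAGTGCAACATTTC", "GCTCCCTGATCCGCATAATA"),
        ("TP", "TTGGCTTATCCAGCGTTTCT", "ATTCTCGCCCACTCAGTGAC"),
    ],
    "Mcal": [
        ("ATPSa", "CGTGTCTTTTGCGGGTAAAC", "AATGATGTTGGCACTTTTCG"),
        ("EFA1a", "AGTTAACCCAGTCACCAAGAGTCAWA", "GGACCAAGTAGAAGGATTGCCCTC"),
        ("GPI", "GTGGCCCTGTCAACCAACG", "TCCCARAARGGAAACATGTTWTCC"),
        ("TBP", "TGTTTCAAGCAATACAAAAAGGTT", "GCACATTTGGCAACAGAAAT"),
        ("TP", "TGGCTCAAGTGGCTTATGTTC", "ATGCAGCCCACCCTGATTAC"),
    ],
}


@dataclass
class SimConfig:
    """Study conditions for one simulated sequencing run.

    Defaults are the conditions of the multiplexed sea-star design this
    package models: 20 individuals for each of 2 species at 5 loci per
    region, 70.7x mean bin coverage, ~1% mean per-base substitution error,
    12.5% chimeric reads at heterozygous bins with a 13:9 allelic-ratio
    skew, and amplicons of 400-600 bp.
    """

    seed: int
    n_populations: int = 1
    n_individuals: int = 20
    n_species: int = 2
    n_loci: int = 5
    amplicon_len_range: tuple[int, int] = (400, 600)
    allele_pool_size: int = 6
    allele_divergence: float = 0.01
    heterozygosity: tuple[float, ...] = (0.5, 0.05)
    mean_coverage: float = 70.7
    coverage_dispersion: float = 8.0
    substitution_rate: float = 0.01
    # error mass is stratified by read, as on the real platform: a junk-read
    # fraction (failed beads, mixed signals) carries high error and is mostly
    # removed by the quality filters, while ordinary reads are much cleaner;
    # the overall mean per-base substitution rate stays at substitution_rate
    junk_read_fraction: float = 0.10
    junk_error_rate: float = 0.06
    homopolymer_coeff: float = 0.02
    homopolymer_cap: float = 0.5
    chimera_rate: float = 0.125
    allelic_skew: float = 13 / 22
    short_read_fraction: float = 0.05
    short_len_range: tuple[int, int] = (30, 149)
    mid_length: int = 10
    use_default_panel: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory: simulations must be reproducible")
        for name in (
            "allele_divergence", "substitution_rate", "chimera_rate",
            "allelic_skew", "short_read_fraction", "homopolymer_cap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for h in self.heterozygosity:
            if not 0.0 <= h <= 1.0:
                raise ValueError("heterozygosity values must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.allele_pool_size < 1:
            raise ValueError("allele_pool_size must be >= 1")


@dataclass
class SimTruth:
    """Everything the pipeline's output can be checked against."""

    config: SimConfig
    sample_sheet: list          # list[SampleSheetEntry]
    locus_defs: list            # list[LocusDef]
    species_of_locus: dict      # locus_id -> species_id
    species_of_individual: dict  # individual_id -> species_id
    mids: dict                  # (population, individual) -> MID
    pools: dict                 # (species, locus_id) -> list of insert seqs
    genotypes: pd.DataFrame     # population, individual, species, locus, allele1/2 ...
    reads: Optional[pd.DataFrame] = None   # per-read provenance, filled by simulate_reads

    def genotype_of(self, individual_id: str, locus_id: str) -> tuple[str, str]:
        g = self.genotypes
        row = g[(g["individual"] == individual_id) & (g["locus"] == locus_id)]
        if row.empty:
            raise KeyError((individual_id, locus_id))
        r = row.iloc[0]
        return r["allele1_seq"], r["allele2_seq"]


def _random_mids(rng: np.random.Generator, n: int, length: int, min_dist: int = 3) -> list[str]:
    """Draw ``n`` distinct barcodes with pairwise Hamming distance >= min_dist."""
    mids: list[str] = []
    arrs: list[np.ndarray] = []
    guard = 0
    while len(mids) < n:
        guard += 1
        if guard > 100000:
            raise RuntimeError("could not generate enough well-separated MIDs")
        cand = rng.integers(0, 4, size=length)
        if all(int(np.sum(cand != prev)) >= min_dist for prev in arrs):
            arrs.append(cand)
            mids.append("".join(BASES[cand]))
    return mids


def _random_insert(rng: np.random.Generator, length: int, n_runs: int = 3) -> str:
    """Random DNA with a few seeded homopolymer runs (pyrosequencing's
    favourite substrate)."""
    seq = list(BASES[rng.integers(0, 4, size=length)])
    for _ in range(n_runs):
        run_len = int(rng.integers(4, 8))
        pos = int(rng.integers(0, max(1, length - run_len)))
        base = seq[pos]
        for k in range(run_len):
            seq[pos + k] = base
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply ``n_subs`` substitutions at distinct random positions."""
    s = list(seq)
    if n_subs <= 0:
        return seq
    pos = rng.choice(len(s), size=min(n_subs, len(s)), replace=False)
    for p in pos:
        old = s[p]
        choices = [b for b in "ACGT" if b != old]
        s[p] = choices[int(rng.integers(0, 3))]
    return "".join(s)


def _pool_frequencies(k: int, het: float) -> np.ndarray:
    """Allele frequencies (one common allele + k-1 equifrequent rare ones)
    whose expected heterozygosity 1 - sum(p^2) equals ``het``.

    Solves (1 + 1/(k-1)) q^2 - (2/(k-1)) q + (1/(k-1) - 1 + het) = 0 for the
    common-allele frequency q; het is capped at the maximum 1 - 1/k
    achievable with k equifrequent alleles.
    """
    if k == 1 or het <= 0:
        return np.array([1.0] + [0.0] * (k - 1))
    het = min(het, 1.0 - 1.0 / k - 1e-9)
    a = 1.0 + 1.0 / (k - 1)
    b = -2.0 / (k - 1)
    c = 1.0 / (k - 1) - 1.0 + het
    disc = b * b - 4 * a * c
    q = (-b + np.sqrt(disc)) / (2 * a)
    rest = (1.0 - q) / (k - 1)
    return np.array([q] + [rest] * (k - 1))


def default_locus_panel(config: SimConfig) -> tuple[list[LocusDef], dict[str, str]]:
    """Locus definitions (species-qualified ids) and their species map."""
    defs: list[LocusDef] = []
    species_of: dict[str, str] = {}
    species_names = list(DEFAULT_PANEL)[: config.n_species]
    lo, hi = config.amplicon_len_range
    for sp in species_names:
        for name, fwd, rev in DEFAULT_PANEL[sp][: config.n_loci]:
            locus_id = f"{name}_{sp}"
            defs.append(LocusDef(locus_id, fwd, rev, lo, hi))
            species_of[locus_id] = sp
    return defs, species_of


def _synthetic_panel(config: SimConfig, rng: np.random.Generator) -> tuple[list[LocusDef], dict[str, str]]:
    """Random primer panel for configurations larger than the default one."""
    defs: list[LocusDef] = []
    species_of: dict[str, str] = {}
    lo, hi = config.amplicon_len_range
    for s in range(config.n_species):
        sp = f"SP{s + 1}"
        for l in range(config.n_loci):
            fwd = "".join(BASES[rng.integers(0, 4, size=20)])
            rev = "".join(BASES[rng.integers(0, 4, size=20)])
            locus_id = f"L{l + 1}_{sp}"
            defs.append(LocusDef(locus_id, fwd, rev, lo, hi))
            species_of[locus_id] = sp
    return defs, species_of


def simulate_genotypes(config: SimConfig) -> SimTruth:
    """Draw the design (MIDs, loci, allele pools) and every true genotype.

    Per species x locus, an ancestral intron is mutated into a pool of
    ``allele_pool_size`` alleles (substitution-only divergence); each
    individual draws two alleles i.i.d. from pool frequencies tuned to the
    species' configured heterozygosity.
    """
    rng = np.random.default_rng(config.seed)
    if config.use_default_panel and config.n_species <= len(DEFAULT_PANEL) and all(
        config.n_loci <= len(v) for v in DEFAULT_PANEL.values()
    ):
        locus_defs, species_of_locus = default_locus_panel(config)
    else:
        locus_defs, species_of_locus = _synthetic_panel(config, rng)
    species_names = sorted(set(species_of_locus.values()), key=list(species_of_locus.values()).index)

    het_of_species = {
        sp: config.heterozygosity[i % len(config.heterozygosity)]
        for i, sp in enumerate(species_names)
    }

    # allele pools per (species, locus): substitution-only divergence so every
    # pool member has the same length (see module docstring)
    pools: dict[tuple[str, str], list[str]] = {}
    freqs: dict[tuple[str, str], np.ndarray] = {}
    defs_by_id = {d.locus_id: d for d in locus_defs}
    for locus_id, sp in species_of_locus.items():
        d = defs_by_id[locus_id]
        target = int(rng.integers(config.amplicon_len_range[0], config.amplicon_len_range[1] + 1))
        insert_len = max(50, target - len(d.fwd_primer) - len(d.rev_primer))
        ancestor = _random_insert(rng, insert_len)
        pool = [ancestor]
        for _ in range(config.allele_pool_size - 1):
            n_subs = max(1, int(rng.poisson(config.allele_divergence * insert_len)))
            pool.append(_mutate(rng, ancestor, n_subs))
        pools[(sp, locus_id)] = pool
        freqs[(sp, locus_id)] = _pool_frequencies(len(pool), het_of_species[sp])

    sample_sheet: list[SampleSheetEntry] = []
    mids: dict[tuple[str, str], str] = {}
    species_of_individual: dict[str, str] = {}
    rows = []
    for p in range(config.n_populations):
        pop = f"P{p + 1:02d}"
        pop_mids = _random_mids(
            rng, config.n_individuals * len(species_names), config.mid_length
        )
        it = iter(pop_mids)
        for sp in species_names:
            for i in range(config.n_individuals):
                ind = f"{pop}_{sp}_{i + 1:02d}"
                mid = next(it)
                sample_sheet.append(SampleSheetEntry(mid, ind, pop, sp))
                mids[(pop, ind)] = mid
                species_of_individual[ind] = sp
                for locus_id, lsp in species_of_locus.items():
                    if lsp != sp:
                        continue
                    f = freqs[(sp, locus_id)]
                    a1, a2 = rng.choice(len(f), size=2, p=f)
                    pool = pools[(sp, locus_id)]
                    rows.append(
                        {
                            "population": pop,
                            "individual": ind,
                            "species": sp,
                            "locus": locus_id,
                            "allele1_idx": int(a1),
                            "allele2_idx": int(a2),
                            "allele1_seq": pool[int(a1)],
                            "allele2_seq": pool[int(a2)],
                            "is_het": pool[int(a1)] != pool[int(a2)],
                        }
                    )
    genotypes = pd.DataFrame(rows)
    return SimTruth(
        config=config,
        sample_sheet=sample_sheet,
        locus_defs=locus_defs,
        species_of_locus=species_of_locus,
        species_of_individual=species_of_individual,
        mids=mids,
        pools={k: list(v) for k, v in pools.items()},
        genotypes=genotypes,
    )


def _concretize_primer(rng: np.random.Generator, primer: str) -> str:
    """Replace IUPAC degeneracies by concrete bases, as degenerate-oligo
    synthesis does molecule by molecule."""
    out = []
    for ch in primer:
        opts = sorted(IUPAC[ch])
        out.append(opts[int(rng.integers(0, len(opts)))] if len(opts) > 1 else ch)
    return "".join(out)


def _homopolymer_errors(
    rng: np.random.Generator, seq: str, coeff: float, cap: float
) -> tuple[str, int, list[int]]:
    """Perturb run lengths: each run of length L >= 2 gains or loses one base
    with probability min(cap, coeff * (L - 1)).

    Also returns the output positions of every *miscalled* run: a mis-read
    flow leaves an ambiguous signal, so the basecaller emits those bases with
    depressed quality, which is exactly the signal the caller's quality
    criterion exploits.
    """
    if coeff <= 0:
        return seq, 0, []
    out: list[str] = []
    n_events = 0
    err_positions: list[int] = []
    pos = 0
    for base, group in itertools.groupby(seq):
        run = len(list(group))
        hit = run >= 2 and rng.random() < min(cap, coeff * (run - 1))
        if hit:
            run += 1 if rng.random() < 0.5 else -1
            n_events += 1
            err_positions.extend(range(pos, pos + run))
        out.append(base * run)
        pos += run
    return "".join(out), n_events, err_positions


# per-base quality/error model: a small fraction of low-quality bases carries
# most of the substitution error, keeping mean read quality above Q30 at a 1%
# mean substitution rate (as in real base-called pyrosequencing data)
_Q_GOOD = np.arange(30, 41)
_Q_BAD = np.arange(2, 11)
_E_GOOD = float(np.mean(10.0 ** (-_Q_GOOD / 10.0)))
_E_BAD = float(np.mean(10.0 ** (-_Q_BAD / 10.0)))


def _bad_base_fraction(rate: float) -> float:
    if rate <= _E_GOOD:
        return 0.0
    return min(1.0, (rate - _E_GOOD) / (_E_BAD - _E_GOOD))


def _apply_base_errors(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    bad_frac: Optional[float] = None,
    depressed: Optional[Sequence[int]] = None,
) -> tuple[str, np.ndarray, int]:
    """Assign per-base qualities and substitute bases at their own error
    probability. ``depressed`` positions (miscalled homopolymer flows) get
    mid-range quality (Q10-20). Returns (bases, quals, n_substitutions)."""
    n = len(seq)
    if rate <= 0 and bad_frac is None:
        # a noise-free read: maximal quality, no substitutions
        quals = np.full(n, int(_Q_GOOD[-1]))
        if depressed is not None and len(depressed):
            idx = np.asarray([p for p in depressed if 0 <= p < n], dtype=int)
            if idx.size:
                quals[idx] = rng.integers(10, 21, size=idx.size)
        return seq, quals.astype(int), 0
    pi = _bad_base_fraction(rate) if bad_frac is None else bad_frac
    bad = rng.random(n) < pi
    quals = np.where(
        bad,
        rng.integers(_Q_BAD[0], _Q_BAD[-1] + 1, size=n),
        rng.integers(_Q_GOOD[0], _Q_GOOD[-1] + 1, size=n),
    )
    if depressed is not None and len(depressed):
        idx = np.asarray([p for p in depressed if 0 <= p < n], dtype=int)
        if idx.size:
            quals[idx] = rng.integers(10, 21, size=idx.size)
    e = 10.0 ** (-quals / 10.0)
    hit = rng.random(n) < e
    out = list(seq)
    n_subs = 0
    for i in np.flatnonzero(hit):
        old = out[i]
        if old not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != old]
        out[i] = choices[int(rng.integers(0, 3))]
        n_subs += 1
    return "".join(out), quals.astype(int), n_subs


def _make_chimera(rng: np.random.Generator, a: str, b: str) -> str:
    """Single template-switch crossover between the two allelic templates."""
    L = min(len(a), len(b))
    k = int(rng.integers(1, L)) if L > 1 else 1
    if rng.random() < 0.5:
        a, b = b, a
    return a[:k] + b[k:]


def simulate_reads(truth: SimTruth) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Emit reads for every (individual, locus) bin of every population.

    Returns one read list per population (regions are sequenced as separate
    files) and the per-read truth table. Fills ``truth.reads`` in place.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 454]))
    defs_by_id = {d.locus_id: d for d in truth.locus_defs}
    reads_by_pop: dict[str, list[Read]] = {}
    truth_rows = []
    serial = 0

    m = config.mean_coverage
    k = config.coverage_dispersion
    p_nb = k / (k + m)

    for _, g in truth.genotypes.iterrows():
        pop = g["population"]
        d = defs_by_id[g["locus"]]
        mid = truth.mids[(pop, g["individual"])]
        coverage = int(rng.negative_binomial(k, p_nb))
        alleles = (g["allele1_seq"], g["allele2_seq"])
        is_het = bool(g["is_het"])
        for _ in range(coverage):
            serial += 1
            read_id = f"r{serial:07d}"
            if is_het:
                allele_idx = 1 if rng.random() < config.allelic_skew else 2
            else:
                allele_idx = 1
            insert = alleles[allele_idx - 1]
            is_chimera = False
            if is_het and rng.random() < config.chimera_rate:
                insert = _make_chimera(rng, alleles[0], alleles[1])
                is_chimera = True
                allele_idx = 0
            insert, n_hp, hp_pos = _homopolymer_errors(
                rng, insert, config.homopolymer_coeff, config.homopolymer_cap
            )
            fwd = _concretize_primer(rng, d.fwd_primer)
            rev = _concretize_primer(rng, d.rev_primer)
            template = (
                ADAPTOR_A + mid + fwd + insert
                + reverse_complement(rev) + reverse_complement(mid)
                + reverse_complement(ADAPTOR_B)
            )
            offset = len(ADAPTOR_A) + len(mid) + len(fwd)
            depressed = [offset + p for p in hp_pos]
            orientation = "forward"
            if rng.random() < 0.5:
                template = reverse_complement(template)
                orientation = "reverse"
                depressed = [len(template) - 1 - p for p in depressed]
            is_truncated = rng.random() < config.short_read_fraction
            if is_truncated:
                cut = int(rng.integers(config.short_len_range[0], config.short_len_range[1] + 1))
                template = template[:cut]
                bases, quals, n_subs = _apply_base_errors(
                    rng, template, config.substitution_rate, bad_frac=0.4
                )
            else:
                # read-stratified error: junk reads carry most of the error
                # mass, ordinary reads get the residual rate; stratification
                # switches off when the configured rate is too small to split
                jf, jr = config.junk_read_fraction, config.junk_error_rate
                resid = (config.substitution_rate - jf * jr) / max(1e-9, 1.0 - jf)
                if jf <= 0 or resid < _E_GOOD:
                    rate = config.substitution_rate
                elif rng.random() < jf:
                    rate = jr
                else:
                    rate = resid
                bases, quals, n_subs = _apply_base_errors(
                    rng, template, rate, depressed=depressed
                )
            reads_by_pop.setdefault(pop, []).append(Read(read_id, bases, tuple(quals)))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "population": pop,
                    "individual": g["individual"],
                    "locus": g["locus"],
                    "allele_index": allele_idx,   # 0 marks a chimera
                    "is_chimera": is_chimera,
                    "is_truncated": is_truncated,
                    "orientation": orientation,
                    "n_substitutions": n_subs,
                    "n_homopolymer_events": n_hp,
                }
            )

    for pop, reads in reads_by_pop.items():
        idx = rng.permutation(len(reads))
        reads_by_pop[pop] = [reads[i] for i in idx]
    truth.reads = pd.DataFrame(truth_rows)
    return reads_by_pop, truth.reads


def degrade_library(
    reads: Sequence[Read],
    short_frac: float,
    seed: int,
    short_len_range: tuple[int, int] = (30, 149),
) -> list[Read]:
    """Replace a fraction of reads with short, low-quality truncations — the
    failure mode of a library contaminated by unpurified short products."""
    if not 0.0 <= short_frac <= 1.0:
        raise ValueError("short_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[Read] = []
    for r in reads:
        if rng.random() < short_frac:
            cut = int(rng.integers(short_len_range[0], short_len_range[1] + 1))
            bases = r.bases[:cut]
            quals = tuple(int(q) for q in rng.integers(2, 16, size=len(bases)))
            out.append(Read(r.read_id, bases, quals))
        else:
            out.append(r)
    return out


def write_simulation(
    truth: SimTruth, reads_by_pop: dict[str, list[Read]], out_dir: str | Path
) -> dict[str, Path]:
    """Write FASTQ per population plus sample sheet, locus table and truth
    tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pops = sorted(reads_by_pop)
    for pop in pops:
        name = "reads.fastq" if len(pops) == 1 else f"reads_{pop}.fastq"
        p = out / name
        write_fastq(reads_by_pop[pop], p)
        paths[f"reads:{pop}"] = p

    p = out / "samples.tsv"
    with open(p, "w") as fh:
        fh.write("mid\tindividual\tpopulation\tspecies\n")
        for e in truth.sample_sheet:
            fh.write(f"{e.mid}\t{e.individual_id}\t{e.population_id}\t{e.species_id}\n")
    paths["samples"] = p

    p = out / "loci.tsv"
    with open(p, "w") as fh:
        fh.write("locus\tfwd_primer\trev_primer\tmin_len\tmax_len\n")
        for d in truth.locus_defs:
            fh.write(f"{d.locus_id}\t{d.fwd_primer}\t{d.rev_primer}\t{d.min_len}\t{d.max_len}\n")
    paths["loci"] = p

    p = out / "truth_genotypes.tsv"
    truth.genotypes.to_csv(p, sep="\t", index=False)
    paths["truth_genotypes"] = p
    if truth.reads is not None:
        p = out / "truth_reads.tsv"
        truth.reads.to_csv(p, sep="\t", index=False)
        paths["truth_reads"] = p
    return paths


def simulate_library(config: SimConfig) -> tuple[SimTruth, dict[str, list[Read]]]:
    """Convenience: genotypes + reads in one call."""
    truth = simulate_genotypes(config)
    reads_by_pop, _ = simulate_reads(truth)
    return truth, reads_by_pop
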