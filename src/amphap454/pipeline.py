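"""End-to-end orchestration: simulate -> demux -> call -> curate -> stats.

The pipeline stages are pure functions of their declared inputs; this module
chains them, serialises the intermediate tables, and (when run on simulated
data) scores the calls against the generator's truth. Configuration is a
single YAML file with one section per stage; unknown keys are rejected and
the resolved configuration is written next to the outputs so every run is
reproducible from its artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import demux as dx
from . import sim454
from .haplotyper import CALLED, GenotypeCall, genotype_bin
from .io_formats import AlleleRecord, LocusDef, write_alleles, write_fastq
from .popcurate import (
    PopulationAlleleTable,
    allelic_ratio_stats,
    build_allele_table,
    diversity_summary,
    singleton_correction,
)


@dataclass
class CallParams:
    """Tunables of the genotyping stage."""

    het_threshold: float = 0.75
    min_homopolymer_cov: int = 10
    min_coverage: int = 1
    min_het_depth: int = 4


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run (one YAML section per stage)."""

    seed: int = 1
    out_dir: str = "amphap454_run"
    simulate: sim454.SimConfig = None  # type: ignore[assignment]
    demux: dx.DemuxParams = field(default_factory=dx.DemuxParams)
    call: CallParams = field(default_factory=CallParams)

    def __post_init__(self) -> None:
        if self.simulate is None:
            self.simulate = sim454.SimConfig(seed=self.seed)


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_pipeline_config(source: str | Path | dict) -> PipelineConfig:
    """Parse a pipeline YAML (or pre-parsed dict); strict about unknown keys."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    top_known = {"seed", "out_dir", "simulate", "demux", "call"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    seed = int(data.get("seed", 1))
    sim_section = dict(data.get("simulate", {}))
    sim_section.setdefault("seed", seed)
    return PipelineConfig(
        seed=seed,
        out_dir=str(data.get("out_dir", "amphap454_run")),
        simulate=_build_section(sim454.SimConfig, sim_section, "simulate"),
        demux=_build_section(dx.DemuxParams, dict(data.get("demux", {})), "demux"),
        call=_build_section(CallParams, dict(data.get("call", {})), "call"),
    )


def dump_resolved_config(cfg: PipelineConfig, path: str | Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": cfg.seed,
                "out_dir": cfg.out_dir,
                "simulate": clean(cfg.simulate),
                "demux": clean(cfg.demux),
                "call": clean(cfg.call),
            },
            fh,
            sort_keys=False,
        )


GENOTYPE_COLUMNS = [
    "individual", "locus", "status", "coverage", "allele1", "allele2",
    "support1", "support2", "n_het_sites", "n_chimeras_removed",
]


def calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    rows = [
        {
            "individual": c.individual_id,
            "locus": c.locus_id,
            "status": c.status,
            "coverage": c.coverage,
            "allele1": c.allele1_seq,
            "allele2": c.allele2_seq,
            "support1": c.allele1_support,
            "support2": c.allele2_support,
            "n_het_sites": len(c.het_sites),
            "n_chimeras_removed": c.chimeric_reads_removed,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def call_bins(
    bins: dict[tuple[str, str], list],
    locus_defs: Sequence[LocusDef],
    attempted: Optional[Sequence[tuple[str, str]]] = None,
    params: CallParams = CallParams(),
) -> list[GenotypeCall]:
    """Genotype every (individual, locus) bin.

    ``attempted`` lists the bins the design tried to sequence; bins that
    received no reads become failed calls with zero coverage, so coverage
    fractions downstream are computed over the whole design.
    """
    defs = {d.locus_id: d for d in locus_defs}
    keys = sorted(set(bins) | set(attempted or []))
    calls = []
    for ind, locus_id in keys:
        reads = bins.get((ind, locus_id), [])
        calls.append(
            genotype_bin(
                reads,
                defs[locus_id],
                individual_id=ind,
                het_threshold=params.het_threshold,
                min_homopolymer_cov=params.min_homopolymer_cov,
                min_coverage=params.min_coverage,
                min_het_depth=params.min_het_depth,
            )
        )
    return calls


def curate_calls(
    calls: Sequence[GenotypeCall], population_of: dict[str, str]
) -> tuple[list[GenotypeCall], list[PopulationAlleleTable]]:
    """Population-level singleton correction, applied back onto the calls.

    Returns corrected copies of the calls plus the per-(locus, population)
    allele tables after correction.
    """
    groups: dict[tuple[str, str], list[GenotypeCall]] = {}
    for c in calls:
        pop = population_of.get(c.individual_id, "pop")
        groups.setdefault((c.locus_id, pop), []).append(c)

    tables = []
    remap: dict[tuple[str, str, str], str] = {}
    for (locus_id, pop), grp in sorted(groups.items()):
        table = build_allele_table(grp, locus_id, pop)
        corrected = singleton_correction(table)
        tables.append(corrected)
        for e in corrected.edits:
            remap[(locus_id, pop, e.singleton_seq)] = e.corrected_to

    out = []
    for c in calls:
        pop = population_of.get(c.individual_id, "pop")
        c2 = dataclasses.replace(
            c,
            allele1_seq=remap.get((c.locus_id, pop, c.allele1_seq), c.allele1_seq),
            allele2_seq=remap.get((c.locus_id, pop, c.allele2_seq), c.allele2_seq),
        )
        out.append(c2)
    return out, tables


def evaluate_recovery(
    calls: Sequence[GenotypeCall], truth: sim454.SimTruth
) -> dict:
    """Score calls against simulated truth.

    A bin is recovered when it was called and its unordered allele pair
    equals the true pair exactly; failed bins count as missed.
    """
    by_key = {(c.individual_id, c.locus_id): c for c in calls}
    n = 0
    exact = 0
    failed = 0
    for _, g in truth.genotypes.iterrows():
        n += 1
        c = by_key.get((g["individual"], g["locus"]))
        if c is None or c.status != CALLED:
            failed += 1
            continue
        want = frozenset((g["allele1_seq"], g["allele2_seq"]))
        got = frozenset((c.allele1_seq, c.allele2_seq))
        if want == got:
            exact += 1
    return {
        "n_bins": n,
        "n_exact": exact,
        "n_failed": failed,
        "recovery": exact / n if n else float("nan"),
    }


def truth_unique_alleles(truth: sim454.SimTruth) -> dict[str, int]:
    """Realized (not pool-size) unique-allele count per locus in the truth."""
    out: dict[str, set] = {}
    for _, g in truth.genotypes.iterrows():
        out.setdefault(g["locus"], set()).update((g["allele1_seq"], g["allele2_seq"]))
    return {k: len(v) for k, v in sorted(out.items())}


def run_all(cfg: PipelineConfig, write_outputs: bool = True) -> dict:
    """simulate -> demux (per region) -> call -> curate -> stats.

    Returns a summary dict; when ``write_outputs`` is set, all intermediate
    and final artifacts are written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        dump_resolved_config(cfg, out / "resolved_config.yaml")

    truth, reads_by_pop = sim454.simulate_library(cfg.simulate)
    if write_outputs:
        sim454.write_simulation(truth, reads_by_pop, out / "sim")

    entries_by_pop: dict[str, list] = {}
    for e in truth.sample_sheet:
        entries_by_pop.setdefault(e.population_id, []).append(e)

    all_ledgers = []
    reports = {}
    bins: dict[tuple[str, str], list] = {}
    for pop in sorted(reads_by_pop):
        ledger, report = dx.demultiplex(
            reads_by_pop[pop], entries_by_pop[pop], truth.locus_defs, cfg.demux
        )
        all_ledgers.extend(ledger)
        reports[pop] = report
        for key, rs in dx.bin_reads(ledger).items():
            bins.setdefault(key, []).extend(rs)

    attempted = [
        (g["individual"], g["locus"]) for _, g in truth.genotypes.iterrows()
    ]
    calls = call_bins(bins, truth.locus_defs, attempted, cfg.call)

    population_of = {e.individual_id: e.population_id for e in truth.sample_sheet}
    curated, tables = curate_calls(calls, population_of)

    summary_stats = diversity_summary(
        curated, truth.species_of_individual, tables
    )
    ratio = allelic_ratio_stats(curated)
    recovery = evaluate_recovery(curated, truth)

    total = sum(r.total_reads for r in reports.values())
    kept = sum(r.kept_reads for r in reports.values())
    summary = {
        "n_reads_total": total,
        "n_reads_kept": kept,
        "kept_fraction": kept / total if total else float("nan"),
        "n_bins_attempted": len(attempted),
        "mean_coverage": summary_stats.mean_coverage,
        "frac_ge_1x": summary_stats.frac_ge_1x,
        "frac_ge_5x": summary_stats.frac_ge_5x,
        "n_het_calls": ratio.n_het,
        "mean_het_allelic_ratio": summary_stats.mean_het_ratio,
        "genotype_recovery": recovery["recovery"],
        "n_failed_bins": recovery["n_failed"],
        "unique_alleles_called": {
            t.locus_id: t.n_unique for t in sorted(tables, key=lambda t: t.locus_id)
        },
        "unique_alleles_truth": truth_unique_alleles(truth),
    }

    if write_outputs:
        calls_to_frame(calls).to_csv(out / "genotypes.tsv", sep="\t", index=False)
        calls_to_frame(curated).to_csv(out / "genotypes_curated.tsv", sep="\t", index=False)
        with open(out / "ledger.tsv", "w") as fh:
            fh.write("read_id\tstatus\tindividual\tlocus\torientation\tdiscard_reason\n")
            for a in all_ledgers:
                fh.write(
                    f"{a.read_id}\t{a.status}\t{a.individual_id or ''}\t"
                    f"{a.locus_id or ''}\t{a.orientation or ''}\t{a.discard_reason or ''}\n"
                )
        with open(out / "library_quality.json", "w") as fh:
            json.dump({p: json.loads(r.to_json()) for p, r in reports.items()}, fh, indent=2)
        alleles = [
            AlleleRecord(c.locus_id, population_of.get(c.individual_id, "pop"),
                         c.individual_id, seq, support)
            for c in curated
            if c.status == CALLED
            for seq, support in ((c.allele1_seq, max(c.allele1_support, 1)),
                                 (c.allele2_seq, max(c.allele2_support, 1)))
        ]
        write_alleles(alleles, out / "alleles.fasta", allow_empty=True)
        with open(out / "edits.log", "w") as fh:
            fh.write("locus\tpopulation\tsingleton\tcorrected_to\tpartner_count\n")
            for t in tables:
                for e in t.edits:
                    fh.write(
                        f"{e.locus_id}\t{e.population_id}\t{e.singleton_seq}\t"
                        f"{e.corrected_to}\t{e.partner_count}\n"
                    )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    return summary
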