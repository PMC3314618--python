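"""Closed-form experiment-design and cost arithmetic.

The multiplexed-amplicon design sequences ``n_loci`` loci for ``n_individuals``
individuals of ``n_species`` species in each of ``n_populations`` populations,
with two tagged fusion primers (forward + reverse) synthesized per
individual x species x locus. These few formulas answer the planning
questions: how many primers must be synthesized, how many individual-locus
sequencing targets the design contains, what the same targets would cost by
direct Sanger sequencing (with an optional cloned fraction for heterozygotes
that cannot be resolved from mixed chromatograms), and how confidently a
simple majority of k clonal reads recovers the true sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom


@dataclass
class DesignSpec:
    """Counts defining one multiplexed sequencing design."""

    n_individuals: int = 20
    n_species: int = 2
    n_loci: int = 5
    n_populations: int = 16
    mass_target_ng: float = 0.5   # per-amplicon mass pooled into a library

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_species", "n_loci", "n_populations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class CostScenario:
    """Parameters of the Sanger-vs-pyrosequencing cost comparison.

    Direct Sanger sequencing reads every target in both directions
    (``reads_per_direct_locus`` = 2, forward + reverse). A fraction
    ``frac_cloned`` of targets additionally needs cloning to separate the two
    alleles, at ``cloning_cost_per_sample`` plus ``reads_per_clone`` extra
    Sanger reads each — the cloned scenarios keep the full direct-sequencing
    cost and add cloning on top. The pyrosequencing alternative is priced as
    tagged-primer synthesis plus one full sequencing plate.
    """

    n_loci_total: int = 3200
    sanger_price_per_read: float = 4.00
    reads_per_direct_locus: int = 2
    frac_cloned: float = 0.0
    reads_per_clone: int = 5
    cloning_cost_per_sample: float = 12.50
    primer_cost: float = 125.0
    primer_cost_454: float = 12137.0
    plate_cost_454: float = 12423.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_cloned <= 1.0:
            raise ValueError("frac_cloned must lie in [0, 1]")
        for name in (
            "sanger_price_per_read", "cloning_cost_per_sample", "primer_cost",
            "primer_cost_454", "plate_cost_454",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def primer_count(d: DesignSpec) -> int:
    """Tagged primers to synthesize: 2 per individual x species x locus."""
    return 2 * d.n_individuals * d.n_species * d.n_loci


def loci_count(d: DesignSpec) -> int:
    """Individual-locus sequencing targets across the whole design."""
    return d.n_populations * d.n_individuals * d.n_species * d.n_loci


def sanger_cost(s: CostScenario) -> float:
    """Total cost of Sanger sequencing all targets, cloning a fraction."""
    direct = s.n_loci_total * s.reads_per_direct_locus * s.sanger_price_per_read
    cloned = s.frac_cloned * s.n_loci_total * (
        s.cloning_cost_per_sample + s.reads_per_clone * s.sanger_price_per_read
    )
    return s.primer_cost + direct + cloned


def cost_454(s: CostScenario) -> float:
    """Total cost of the multiplexed pyrosequencing alternative."""
    return s.primer_cost_454 + s.plate_cost_454


def pooling_volume(conc_ng_per_ul: float, mass_target_ng: float = 0.5) -> float:
    """Volume (uL) of one quantified PCR product to pool for an equimolar
    library, given its concentration (ng/uL) and the per-amplicon mass
    target."""
    if conc_ng_per_ul <= 0:
        raise ValueError("concentration must be positive")
    return mass_target_ng / conc_ng_per_ul


def majority_confidence(k_reads: int, p_correct: float) -> float:
    """P(a strict majority of ``k_reads`` clonal reads carries the true
    sequence), per-read correctness ``p_correct``.

    Requires an odd k: with an even sample a majority can tie and the
    quantity is undefined without a tie-break convention.
    """
    if k_reads % 2 == 0:
        raise ValueError("k_reads must be odd (majority undefined for even samples)")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    # P(X > k/2) for X ~ Binomial(k, p)
    return float(binom.sf(k_reads // 2, k_reads, p_correct))
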