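"""Demultiplexing: filters, barcode/primer matching, trimming, the ledger."""

import numpy as np
import pytest

from amphap454 import demux as dx
from amphap454.io_formats import LocusDef, Read, SampleSheetEntry, reverse_complement
from amphap454.sim454 import SimConfig, simulate_library

from conftest import make_read


class TestLengthFilter:
    @pytest.mark.parametrize("n,keep", [(149, False), (150, True), (400, True)])
    def test_below_threshold_is_strict(self, n, keep):
        assert dx.length_filter(make_read("A" * n)) is keep


class TestMeanQualityFilter:
    def test_exactly_thirty_is_kept(self):
        assert dx.mean_quality_filter(make_read("A" * 200, 30))

    def test_just_below_thirty_discarded(self):
        assert not dx.mean_quality_filter(make_read("A" * 200, 29))

    def test_alternating_20_40_mean_30_kept(self):
        quals = [20, 40] * 100
        assert dx.mean_quality_filter(make_read("A" * 200, quals))


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        r = make_read("ACGT" * 50, 40)
        assert dx.quality_trim(r).bases == r.bases

    def test_low_quality_tail_removed(self):
        r = make_read("ACGT" * 10 + "A" * 20, [40] * 40 + [2] * 20)
        t = dx.quality_trim(r)
        assert t.bases == "ACGT" * 10
        assert (t.clip5, t.clip3) == (0, 20)

    def test_hopeless_read_trims_to_empty_then_fails_length(self):
        r = make_read("A" * 200, 2)
        t = dx.quality_trim(r)
        assert len(t) == 0
        assert not dx.length_filter(t)

    def test_matches_bruteforce_interval_maximisation(self, rng):
        # independent oracle: score every contiguous interval directly
        def brute(read, cutoff=0.05):
            scores = [cutoff - 10 ** (-q / 10) for q in read.quals]
            best, best_iv = 0.0, (0, 0)
            for i in range(len(scores)):
                total = 0.0
                for j in range(i, len(scores)):
                    total += scores[j]
                    if total > best:
                        best, best_iv = total, (i, j + 1)
            return read.bases[best_iv[0]:best_iv[1]]

        for _ in range(50):
            n = int(rng.integers(1, 40))
            quals = [int(q) for q in rng.integers(2, 41, size=n)]
            r = make_read("".join(rng.choice(list("ACGT"), n)), quals)
            assert dx.quality_trim(r).bases == brute(r)

    def test_hand_computed_toy(self):
        # per-base scores: Q40 -> +0.0499, Q2 -> -0.581; best interval is the
        # three consecutive Q40s at 4..6 (0.150), beating the pair at 0..1
        r = make_read("AACCGGTTAA", [40, 40, 2, 2, 40, 40, 40, 2, 2, 2])
        assert dx.quality_trim(r).bases == "GGT"


def _entries():
    return [
        SampleSheetEntry("ACGAGTGCGT", "A01", "P1", "S1"),
        SampleSheetEntry("ACGCTCGACA", "A02", "P1", "S1"),
    ]


def _wrap(mid: str, payload: str, mid3: str | None = None, adaptors=True) -> str:
    mid3 = mid if mid3 is None else mid3
    s = mid + payload + reverse_complement(mid3)
    if adaptors:
        s = dx.ADAPTOR_A + s + reverse_complement(dx.ADAPTOR_B)
    return s


class TestMatchMid:
    def test_same_mid_both_ends_identifies_individual(self):
        idx = dx.build_mid_index(_entries())
        r = make_read(_wrap("ACGAGTGCGT", "A" * 60))
        entry, start, end = dx.match_mid(r, idx)
        assert entry.individual_id == "A01"
        assert r.bases[start:end] == "A" * 60

    def test_mid_at_five_prime_only_is_a_mismatch(self):
        idx = dx.build_mid_index(_entries())
        r = make_read(dx.ADAPTOR_A + "ACGAGTGCGT" + "A" * 60)
        assert dx.match_mid(r, idx) is None

    def test_two_different_individuals_mids_is_a_mismatch(self):
        idx = dx.build_mid_index(_entries())
        r = make_read(_wrap("ACGAGTGCGT", "A" * 60, mid3="ACGCTCGACA"))
        assert dx.match_mid(r, idx) is None

    def test_adaptorless_read_starting_at_mid_is_tolerated(self):
        idx = dx.build_mid_index(_entries())
        r = make_read(_wrap("ACGAGTGCGT", "A" * 60, adaptors=False))
        assert dx.match_mid(r, idx)[0].individual_id == "A01"

    def test_one_edit_mode_recovers_single_substitution(self):
        idx = dx.build_mid_index(_entries())
        bad = "TCGAGTGCGT"  # one substitution in A01's barcode
        r = make_read(dx.ADAPTOR_A + bad + "A" * 60
                      + reverse_complement("ACGAGTGCGT") + reverse_complement(dx.ADAPTOR_B))
        assert dx.match_mid(r, idx) is None
        loose = dx.DemuxParams(mid_edits=1)
        assert dx.match_mid(r, idx, loose)[0].individual_id == "A01"

    def test_shared_mid_across_individuals_rejected(self):
        entries = [
            SampleSheetEntry("ACGAGTGCGT", "A01", "P1", "S1"),
            SampleSheetEntry("ACGAGTGCGT", "B01", "P1", "S2"),
        ]
        with pytest.raises(Exception, match="unique"):
            dx.build_mid_index(entries)


ATPS_FWD = "TTTGCACCAGTGACCTTTTG"
ATPS_REV = "GCCCTTTGAGCTACAGTTCG"


class TestMatchPrimer:
    def _loci(self):
        return [
            LocusDef("ATPSa", ATPS_FWD, ATPS_REV, 400, 600),
            LocusDef("TP", "TTGGCTTATCCAGCGTTTCT", "ATTCTCGCCCACTCAGTGAC", 400, 600),
        ]

    def test_forward_orientation(self):
        seg = ATPS_FWD + "A" * 100 + reverse_complement(ATPS_REV)
        locus, orientation, reason = dx.match_primer(seg, self._loci())
        assert (locus.locus_id, orientation, reason) == ("ATPSa", "forward", None)

    def test_reverse_orientation(self):
        seg = ATPS_REV + "T" * 100 + reverse_complement(ATPS_FWD)
        locus, orientation, reason = dx.match_primer(seg, self._loci())
        assert (locus.locus_id, orientation) == ("ATPSa", "reverse")

    def test_single_substitution_in_primer_is_absent(self):
        seg = ("A" + ATPS_FWD[1:]) + "A" * 100 + reverse_complement(ATPS_REV)
        locus, orientation, reason = dx.match_primer(seg, self._loci())
        assert reason == dx.PRIMER_ABSENT

    def test_degenerate_primer_matches_every_expansion(self):
        loci = [LocusDef("L1", "ACWTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 400, 600)]
        for b in "AT":
            seg = f"AC{b}TACGTACGTACGTACGT" + "G" * 80 + reverse_complement(loci[0].rev_primer)
            assert dx.match_primer(seg, loci)[0].locus_id == "L1"

    def test_two_matching_loci_is_ambiguous(self):
        loci = [
            LocusDef("L1", "ACNTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 400, 600),
            LocusDef("L2", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 400, 600),
        ]
        seg = "ACGTACGTACGTACGTACGT" + "G" * 80 + reverse_complement("TGCATGCATGCATGCATGCA")
        assert dx.match_primer(seg, loci)[2] == dx.AMBIGUOUS


class TestDemultiplex:
    def test_error_free_library_fully_recovered(self, tiny_sim_config):
        cfg = SimConfig(seed=tiny_sim_config.seed, n_individuals=3, n_loci=2,
                        mean_coverage=20, substitution_rate=0.0,
                        homopolymer_coeff=0.0, chimera_rate=0.0,
                        short_read_fraction=0.0)
        truth, reads_by_pop = simulate_library(cfg)
        reads = reads_by_pop["P01"]
        ledger, report = dx.demultiplex(reads, truth.sample_sheet, truth.locus_defs)
        counts = dx.ledger_counts(ledger)
        # partition conservation
        assert report.total_reads == len(reads)
        assert report.kept_reads + sum(report.discarded_by_reason.values()) == len(reads)
        # every kept read binned to its true individual and locus
        by_id = truth.reads.set_index("read_id")
        kept = [a for a in ledger if a.status == "kept"]
        assert counts["kept"] == len(reads)  # no noise: nothing discarded
        for a in kept:
            row = by_id.loc[a.read_id]
            assert (a.individual_id, a.locus_id) == (row["individual"], row["locus"])
            assert a.orientation == row["orientation"]

    def test_reverse_reads_are_delivered_in_forward_orientation(self, tiny_sim_config):
        cfg = SimConfig(seed=11, n_individuals=2, n_loci=1, n_species=1,
                        mean_coverage=10, substitution_rate=0.0,
                        homopolymer_coeff=0.0, chimera_rate=0.0,
                        short_read_fraction=0.0, heterozygosity=(0.0,))
        truth, reads_by_pop = simulate_library(cfg)
        ledger, _ = dx.demultiplex(reads_by_pop["P01"], truth.sample_sheet, truth.locus_defs)
        for a in ledger:
            assert a.status == "kept"
            want, _ = truth.genotype_of(a.individual_id, a.locus_id)
            assert a.trimmed_read.bases == want

    def test_all_short_reads_discarded_with_conserved_totals(self):
        reads = [make_read("A" * 100, read_id=f"r{i}") for i in range(10)]
        ledger, report = dx.demultiplex(reads, _entries(), [])
        assert report.total_reads == 10
        assert report.discarded_by_reason[dx.TOO_SHORT] == 10
        assert all(a.discard_reason == dx.TOO_SHORT for a in ledger)

    def test_empty_input(self):
        ledger, report = dx.demultiplex([], _entries(), [])
        assert ledger == [] and report.total_reads == 0

    def test_ledger_is_order_independent(self, tiny_sim_config):
        truth, reads_by_pop = simulate_library(tiny_sim_config)
        reads = list(reads_by_pop["P01"])
        l1, _ = dx.demultiplex(reads, truth.sample_sheet, truth.locus_defs)
        l2, _ = dx.demultiplex(reads[::-1], truth.sample_sheet, truth.locus_defs)
        assert l1 == l2

    def test_report_json_tallies(self, tiny_sim_config):
        import json

        truth, reads_by_pop = simulate_library(tiny_sim_config)
        _, report = dx.demultiplex(reads_by_pop["P01"], truth.sample_sheet, truth.locus_defs)
        payload = json.loads(report.to_json())
        assert payload["total_reads"] == report.total_reads
        assert sum(payload["length_histogram"].values()) == report.total_reads
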