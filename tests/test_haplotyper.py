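"""Diploid calling: pileups, the 75% rule, homopolymers, phasing, chimeras."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amphap454 import haplotyper as hp
from amphap454.io_formats import LocusDef, Read

from conftest import make_read

LOCUS = LocusDef("LOC", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 400, 600)


def reads_from(template: str, n: int, q: int = 35, prefix: str = "r") -> list:
    return [make_read(template, q, read_id=f"{prefix}{i:03d}") for i in range(n)]


def pileup_from_rows(rows: list[str], quals: list[list[int]] | None = None) -> hp.Pileup:
    """Build a Pileup directly from aligned row strings ('.' = not covered)."""
    n, m = len(rows), len(rows[0])
    matrix = np.full((n, m), hp.NOCOV, dtype="<U1")
    q = np.full((n, m), -1, dtype=np.int16)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            if ch == ".":
                continue
            matrix[i, j] = ch
            q[i, j] = quals[i][j] if quals else (35 if ch != "-" else -1)
    return hp.Pileup("LOC", "I1", [f"r{i}" for i in range(n)], matrix, q)


class TestBuildPileup:
    def test_identical_reads_give_uniform_depth(self):
        p = hp.build_pileup(reads_from("ACGTTTGCAGT" * 4, 5), LOCUS)
        assert p.n_reads == 5
        for col in p.columns():
            assert col.depth == 5
            assert len(col.counts) == 1

    def test_single_substitution_gives_exactly_one_mixed_column(self):
        t = "ACGTTTGCAGTACGTTTGCAGT"
        other = t[:10] + "A" + t[11:]
        reads = reads_from(t, 2) + [make_read(other, 35, read_id="x")]
        p = hp.build_pileup(reads, LOCUS)
        mixed = [c for c in p.columns() if len([s for s in c.counts if c.counts[s]]) > 1]
        assert len(mixed) == 1
        assert mixed[0].counts == {"A": 1, t[10]: 2}

    def test_staggered_reads_depth_equals_overlap(self):
        t = "ACGTTTGCAGTACGTTTGCAGTAAAT"
        # clipped reads: cover [0,20), [3,26), [6,26) of the template
        reads = [
            make_read(t[:20], 35, read_id="a", clip3=6),
            make_read(t[3:], 35, read_id="b", clip5=3),
            make_read(t[6:], 30, read_id="c", clip5=6),
        ]
        p = hp.build_pileup(reads, LOCUS)
        depths = [c.depth for c in p.columns()]
        expect = [1] * 3 + [2] * 3 + [3] * 14 + [2] * 6
        assert depths == expect

    def test_deterministic_under_input_permutation(self, rng):
        t = "ACGTTTGCAGTACGTTTGCAGT"
        reads = [make_read(t if i % 3 else t[:15] + "G" + t[16:], int(30 + i % 9),
                           read_id=f"r{i}") for i in range(9)]
        p1 = hp.build_pileup(reads, LOCUS)
        p2 = hp.build_pileup(list(reversed(reads)), LOCUS)
        assert p1.read_ids == p2.read_ids
        assert (p1.matrix == p2.matrix).all()


class TestCallColumn:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 76, "C": 24}, ("A", None)),
            ({"A": 74, "C": 26}, ("A", "C")),
            ({"A": 75, "C": 25}, ("A", None)),  # boundary: "below 75%" is strict
            ({"A": 10}, ("A", None)),
            ({"A": 40, "-": 60}, ("-", "A")),
        ],
    )
    def test_threshold_rule(self, counts, expected):
        col = hp.PileupColumn(counts, {s: 0 for s in counts})
        assert hp.call_column(col) == expected

    def test_n_does_not_participate(self):
        col = hp.PileupColumn({"A": 3, "N": 97}, {"A": 0, "N": 0})
        assert hp.call_column(col) == ("A", None)

    @given(
        st.dictionaries(
            st.sampled_from(["A", "C", "G", "T", "-"]),
            st.integers(min_value=0, max_value=200),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0)
    )
    @settings(max_examples=300, deadline=None)
    def test_boundary_law_matches_bruteforce(self, counts):
        col = hp.PileupColumn(dict(counts), {s: 0 for s in counts})
        major, minor = hp.call_column(col)
        depth = sum(counts.values())
        is_het_brute = max(counts.values()) / depth < 0.75
        assert (minor is not None) == is_het_brute


class TestResolveHomopolymer:
    def _run_pileup(self, lengths: dict[int, int], quals: dict[int, int], base="A",
                    width=None, flank_q=35):
        width = width or max(lengths)
        rows, qrows = [], []
        for ell, n in sorted(lengths.items()):
            for _ in range(n):
                rows.append("C" + base * ell + "-" * (width - ell) + "G")
                qrows.append([flank_q] + [quals[ell]] * ell + [-1] * (width - ell) + [flank_q])
        return pileup_from_rows(rows, qrows), (1, 1 + width, base)

    def test_majority_class_wins_at_depth(self):
        p, reg = self._run_pileup({7: 46, 8: 4}, {7: 30, 8: 30})
        call = hp.resolve_homopolymer(p, reg)
        assert (call.chosen_length, call.decision_basis) == (7, "both")

    def test_below_ten_reads_quality_decides_alone(self):
        p, reg = self._run_pileup({5: 4, 6: 4}, {5: 32, 6: 25})
        call = hp.resolve_homopolymer(p, reg)
        assert (call.chosen_length, call.decision_basis) == (5, "quality")

    def test_quality_tie_breaks_toward_shorter_run(self):
        p, reg = self._run_pileup({4: 10, 5: 10}, {4: 30, 5: 30})
        call = hp.resolve_homopolymer(p, reg)
        assert call.chosen_length == 4

    def test_no_majority_at_depth_falls_to_quality(self):
        p, reg = self._run_pileup({4: 8, 5: 6}, {4: 20, 5: 38})
        call = hp.resolve_homopolymer(p, reg)
        assert (call.chosen_length, call.decision_basis) == (5, "quality")


def _het_pileup(keys: list[tuple], copies: list[int]):
    """Two-het-site toy pileup: sites at columns 1 and 3."""
    rows = []
    for key, n in zip(keys, copies):
        for _ in range(n):
            rows.append(f"C{key[0]}G{key[1]}T")
    return pileup_from_rows(rows)


class TestPhaseReads:
    def test_two_sites_top_two_keys(self):
        p = _het_pileup([("A", "C"), ("G", "T"), ("A", "T")], [40, 35, 5])
        sites = [
            hp.HetSite(1, "A", "G", 45, 35, False, False),
            hp.HetSite(3, "C", "T", 40, 40, False, False),
        ]
        k1, k2, assignments, minor = hp.phase_reads(p, sites)
        assert (k1, k2) == (("A", "C"), ("G", "T"))
        counts = Counter(assignments.values())
        assert counts[1] == 40 and counts[2] == 35
        assert minor == [(("A", "T"), 5)]

    def test_single_site_supports(self):
        p = _het_pileup([("A", "C"), ("G", "C")], [12, 9])
        sites = [hp.HetSite(1, "A", "G", 12, 9, False, False)]
        k1, k2, assignments, _ = hp.phase_reads(p, sites)
        assert k1 == ("A",) and k2 == ("G",)
        assert Counter(assignments.values()) == {1: 12, 2: 9}

    def test_fewer_than_two_keys_flags_fallback(self):
        p = _het_pileup([("A", "C")], [8])
        sites = [hp.HetSite(1, "A", "G", 8, 0, False, False)]
        assert hp.phase_reads(p, sites)[0] is None

    def test_partial_reads_assigned_when_unambiguous(self):
        rows = ["CAGCT"] * 6 + ["CGGTT"] * 5 + [".AGC.", ".GGT.", ".NGN."]
        p = pileup_from_rows(rows)
        sites = [
            hp.HetSite(1, "A", "G", 7, 6, False, False),
            hp.HetSite(3, "C", "T", 7, 6, False, False),
        ]
        k1, k2, assignments, _ = hp.phase_reads(p, sites)
        assert assignments[11] == 1   # spans both sites: A..C
        assert assignments[12] == 2
        assert assignments[13] == 0   # N at both sites: consistent with neither

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_agrees_with_exhaustive_enumeration(self, data):
        n_sites = data.draw(st.integers(1, 3))
        n_reads = data.draw(st.integers(2, 12))
        keys = [
            tuple(data.draw(st.sampled_from("ACGT")) for _ in range(n_sites))
            for _ in range(n_reads)
        ]
        if len(set(keys)) < 2:
            return
        rows = ["".join(f"C{s}" for s in key) + "G" for key in keys]
        p = pileup_from_rows(rows)
        sites = [hp.HetSite(2 * j + 1, "A", "C", 1, 1, False, False) for j in range(n_sites)]
        k1, k2, _, minor = hp.phase_reads(p, sites)
        # oracle: full enumeration of key frequencies with the same tie rule
        ranked = sorted(Counter(keys).items(), key=lambda kc: (-kc[1], kc[0]))
        assert (k1, k2) == (ranked[0][0], ranked[1][0])
        assert minor == ranked[2:]


class TestChimeras:
    def test_recombinant_key_removed(self):
        p = _het_pileup([("A", "C"), ("G", "T"), ("A", "T")], [10, 8, 2])
        sites = [
            hp.HetSite(1, "A", "G", 12, 8, False, False),
            hp.HetSite(3, "C", "T", 10, 10, False, False),
        ]
        idx = hp.chimeric_read_indices(p, sites, ("A", "C"), ("G", "T"))
        assert len(idx) == 2
        for i in idx:
            assert (p.matrix[i, 1], p.matrix[i, 3]) == ("A", "T")

    def test_parental_keys_retained(self):
        p = _het_pileup([("A", "C"), ("G", "T")], [10, 8])
        sites = [
            hp.HetSite(1, "A", "G", 10, 8, False, False),
            hp.HetSite(3, "C", "T", 10, 8, False, False),
        ]
        assert hp.chimeric_read_indices(p, sites, ("A", "C"), ("G", "T")) == []

    def test_single_differing_site_cannot_yield_chimeras(self):
        p = _het_pileup([("A", "C"), ("G", "C")], [10, 8])
        sites = [hp.HetSite(1, "A", "G", 10, 8, False, False)]
        assert hp.chimeric_read_indices(p, sites, ("A",), ("G",)) == []


class TestGenotypeBin:
    def test_homozygote_thirty_clean_reads(self):
        t = "ACGTTTGCAGTA" * 10
        call = hp.genotype_bin(reads_from(t, 30), LOCUS, "I1")
        assert call.status == hp.CALLED
        assert call.allele1_seq == call.allele2_seq == t
        assert call.coverage == 30
        assert not call.is_het

    def test_heterozygote_with_chimeras_recovered(self, rng):
        a1 = "ACGTTTGCAGTA" * 8
        a2 = a1[:20] + "T" + a1[21:60] + "G" + a1[61:]  # two het sites
        reads = []
        for i in range(60):  # 13:9-like skew
            reads.append(make_read(a1 if i % 22 < 13 else a2, 35, read_id=f"r{i:03d}"))
        for i in range(8):   # single-crossover artifacts
            k = int(rng.integers(25, 55))
            reads.append(make_read(a1[:k] + a2[k:], 35, read_id=f"c{i:03d}"))
        call = hp.genotype_bin(reads, LOCUS, "I1")
        assert call.is_het
        assert {call.allele1_seq, call.allele2_seq} == {a1, a2}
        # every crossover fell between the two het sites, so every artifact
        # read carries allele1's first site and allele2's second
        assert call.chimeric_reads_removed == 8
        assert call.allele1_support >= call.allele2_support

    def test_empty_bin(self):
        call = hp.genotype_bin([], LOCUS, "I1")
        assert call.status == hp.FAILED_NO_READS

    def test_support_tie_breaks_to_lexicographically_smaller_allele(self):
        a1 = "TTTTACGTACGTACGT"
        a2 = "ATTTACGTACGTACGT"
        reads = reads_from(a1, 10, prefix="a") + reads_from(a2, 10, prefix="b")
        call = hp.genotype_bin(reads, LOCUS, "I1")
        assert call.allele1_seq == a2  # A... < T...
        assert call.allele1_support == call.allele2_support == 10

    def test_homopolymer_error_reads_do_not_break_homozygote(self):
        t = "ACGT" + "A" * 6 + "CGTTTGCAGT" * 5
        good = reads_from(t, 18)
        slipped = [make_read("ACGT" + "A" * 7 + "CGTTTGCAGT" * 5,
                             [35] * 4 + [14] * 7 + [35] * 50, read_id="hp1")]
        call = hp.genotype_bin(good + slipped, LOCUS, "I1")
        assert call.status == hp.CALLED
        assert call.allele1_seq == call.allele2_seq == t

    def test_chimera_removal_never_alters_clean_allele_sequences(self):
        a1 = "ACGTTTGCAGTA" * 8
        a2 = a1[:20] + "T" + a1[21:60] + "G" + a1[61:]
        clean = [make_read(a1 if i < 14 else a2, 35, read_id=f"r{i:03d}") for i in range(24)]
        with_chim = clean + [make_read(a1[:40] + a2[40:], 35, read_id="chi")]
        c0 = hp.genotype_bin(clean, LOCUS, "I1")
        c1 = hp.genotype_bin(with_chim, LOCUS, "I1")
        assert {c0.allele1_seq, c0.allele2_seq} == {c1.allele1_seq, c1.allele2_seq}
        assert c1.chimeric_reads_removed == 1


class TestMajorityClosedForm:
    def test_matches_binomial_tail_to_1e12(self):
        from amphap454.design_cost import majority_confidence

        for k in (1, 3, 5, 7, 9):
            for p in (0.0, 0.1, 0.5, 0.9, 0.97, 1.0):
                assert hp.majority_confidence_exact(k, p) == pytest.approx(
                    majority_confidence(k, p), abs=1e-12
                )
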