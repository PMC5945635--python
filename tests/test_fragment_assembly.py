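"""Suffix-prefix overlaps, circular layout search, consensus, overlap accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitobipart.fragment_assembly import (
    AssemblyLayout,
    FragmentSet,
    Overlap,
    assemble_circle,
    find_overlaps,
    least_rotation,
    overlap_report,
    reverse_complement,
    rotations_equal,
)
from mitobipart.reference import OVERLAP_LENGTHS_BP


def brute_force_overlap(a: str, b: str, min_overlap: int, max_mismatch: int):
    """Independent all-suffix/all-prefix scan."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        mm = sum(x != y for x, y in zip(a[-k:], b[:k]))
        if mm <= max_mismatch:
            return (k, mm)
    return None


class TestFindOverlaps:
    def test_simple_pair(self):
        fs = FragmentSet([("f1", "ACGTAC"), ("f2", "TACGGA")])
        table, _ = find_overlaps(fs, min_overlap=3, try_reverse_complement=False)
        assert table == [Overlap("f1", "f2", 3, 0)]

    def test_no_overlap_below_threshold(self):
        fs = FragmentSet([("f1", "AAAACCCC"), ("f2", "GGGGTTTT")])
        table, _ = find_overlaps(fs, min_overlap=3, try_reverse_complement=False)
        assert table == []

    def test_simulated_circle_yields_one_cycle(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, junctions = simulate_amplicons(chroms[0], 4, (122, 398), seed=5)
        table, _ = find_overlaps(fs, min_overlap=50)
        got = {(o.source, o.target): o.length for o in table}
        expected = {(j["source"], j["target"]): j["overlap"] for j in junctions}
        assert got == expected  # exactly the 4 planted junctions, correct lengths

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_agrees_with_brute_force(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=80))
        b = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=80))
        min_ov = data.draw(st.integers(1, 6))
        max_mm = data.draw(st.integers(0, 2))
        fs = FragmentSet([("a", a), ("b", b)])
        table, _ = find_overlaps(fs, min_ov, max_mm, try_reverse_complement=False)
        hit = next(((o.length, o.mismatches) for o in table if o.source == "a"), None)
        assert hit == brute_force_overlap(a, b, min_ov, max_mm)

    def test_reverse_complement_co_orientation(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, _ = simulate_amplicons(chroms[1], 4, (122, 398), seed=9)
        flipped = [
            (fid, reverse_complement(seq) if i == 2 else seq)
            for i, (fid, seq) in enumerate(fs.fragments)
        ]
        layout = assemble_circle(FragmentSet(flipped))
        assert layout.closed
        assert rotations_equal(layout.consensus, chroms[1].sequence) or rotations_equal(
            layout.consensus, reverse_complement(chroms[1].sequence)
        )


class TestAssembleCircle:
    def test_round_trip_four_fragments(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, _ = simulate_amplicons(chroms[0], 4, (122, 398), seed=1)
        layout = assemble_circle(fs)
        assert layout.closed
        assert layout.consensus_length == chroms[0].length
        assert rotations_equal(layout.consensus, chroms[0].sequence)

    def test_consensus_length_conservation(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        for n in (2, 5, 7):
            fs, _ = simulate_amplicons(chroms[0], n, (122, 398), seed=n)
            layout = assemble_circle(fs)
            total = sum(len(s) for _, s in fs.fragments)
            assert layout.consensus_length == total - sum(
                o.length for o in layout.junction_overlaps
            )

    def test_two_rotations_of_full_circle(self):
        rng = np.random.default_rng(0)
        circle = "".join(rng.choice(list("ACGT"), size=400))
        rot = circle[150:] + circle[:150]
        # each fragment is one full rotation: suffix of one is prefix of the other
        layout = assemble_circle(
            FragmentSet([("r1", circle), ("r2", rot)]), min_overlap=50
        )
        assert layout.closed

    def test_abutting_fragments_cannot_close(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, _ = simulate_amplicons(chroms[0], 3, (0, 0), seed=2)
        layout = assemble_circle(fs, min_overlap=50)
        assert not layout.closed

    def test_one_junction_below_threshold_reports_open_path(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, junctions = simulate_amplicons(chroms[0], 3, (122, 398), seed=4)
        # truncate one fragment's tail below the overlap threshold
        frags = [
            (fid, seq[:-junctions[i]["overlap"]] if i == 0 else seq)
            for i, (fid, seq) in enumerate(fs.fragments)
        ]
        layout = assemble_circle(FragmentSet(frags), min_overlap=50)
        assert not layout.closed
        assert len(layout.order) == 3  # best open path still chains everything

    def test_planted_mismatches_within_tolerance(self, synthetic_genome):
        from mitobipart.synthetic_data import simulate_amplicons

        chroms, _, _ = synthetic_genome
        fs, junctions = simulate_amplicons(chroms[0], 4, (150, 300), seed=6)
        frags = []
        for i, (fid, seq) in enumerate(fs.fragments):
            if i == 1:  # plant one mismatch inside this fragment's suffix overlap
                pos = len(seq) - junctions[1]["overlap"] // 2
                base = "A" if seq[pos] != "A" else "C"
                seq = seq[:pos] + base + seq[pos + 1 :]
            frags.append((fid, seq))
        layout = assemble_circle(FragmentSet(frags), min_overlap=50, max_mismatch=1)
        assert layout.closed
        diffs = sum(
            x != y
            for x, y in zip(least_rotation(layout.consensus), least_rotation(chroms[0].sequence))
        )
        assert diffs <= 1


class TestOverlapReport:
    def test_published_overlap_accounting(self):
        """The 14 printed confirmation overlaps total 3,655 bp, range 122-398."""
        rep = overlap_report(extra_confirmations=OVERLAP_LENGTHS_BP)
        assert rep["total_overlap"] == 3655
        assert rep["min"] == 122
        assert rep["max"] == 398
        assert rep["n_overlaps"] == 14

    def test_single_junction(self):
        layout = AssemblyLayout(["f1"], [Overlap("f1", "f1", 100, 0)], "A" * 10, True)
        rep = overlap_report(layout)
        assert (rep["total_overlap"], rep["min"], rep["max"]) == (100, 100, 100)

    def test_empty(self):
        rep = overlap_report()
        assert rep["total_overlap"] == 0 and rep["min"] is None and rep["max"] is None


class TestRotations:
    @pytest.mark.parametrize("s,expected", [("bca", "abc"), ("aab", "aab"), ("baa", "aab")])
    def test_least_rotation(self, s, expected):
        assert least_rotation(s) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60), st.integers(0, 59))
    def test_rotations_equal_under_any_shift(self, s, shift):
        shift %= len(s)
        assert rotations_equal(s, s[shift:] + s[:shift])
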