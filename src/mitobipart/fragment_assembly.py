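"""Overlap-layout verification of circular amplicon assemblies.

Given a set of overlapping fragment sequences (e.g. Sanger-sequenced long-PCR
products), finds suffix-prefix overlaps, searches for a circular layout (a
Hamiltonian cycle in the overlap digraph), builds the consensus, and reports
junction-overlap statistics. A closed layout — every adjacent pair, including
last back to first, overlapping at or above threshold — is the assembly-level
evidence that the molecule is circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np


@dataclass
class FragmentSet:
    """Named fragment sequences destined for one circular molecule."""

    fragments: list[tuple[str, str]]  # (id, sequence)
    kind: str = "long-PCR"

    def __post_init__(self) -> None:
        if any(not seq for _id, seq in self.fragments):
            raise ValueError("empty fragment sequence")
        ids = [fid for fid, _ in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate fragment ids")
        self.fragments = [(fid, seq.upper()) for fid, seq in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class Overlap:
    """Longest qualifying suffix(i) -> prefix(j) match."""

    source: str
    target: str
    length: int
    mismatches: int


@dataclass
class AssemblyLayout:
    """An ordered circular (or best open) layout of fragments."""

    order: list[str]
    junction_overlaps: list[Overlap]
    consensus: str
    closed: bool

    @property
    def consensus_length(self) -> int:
        return len(self.consensus)


def _suffix_prefix_overlap(
    a: str, b: str, min_overlap: int, max_mismatch: int
) -> Optional[tuple[int, int]]:
    """Longest qualifying overlap of a's suffix with b's prefix, as (length, mismatches)."""
    cap = min(len(a), len(b))
    if cap < min_overlap:
        return None
    if max_mismatch == 0:
        # KMP failure function over b + sentinel + a: the final value is the
        # longest prefix of b that is also a suffix of a.
        s = b + "\x00" + a
        fail = [0] * len(s)
        k = 0
        for i in range(1, len(s)):
            while k and s[i] != s[k]:
                k = fail[k - 1]
            if s[i] == s[k]:
                k += 1
            fail[i] = k
        return (k, 0) if k >= min_overlap else None
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for k in range(cap, min_overlap - 1, -1):
        mm = int(np.count_nonzero(aa[-k:] != bb[:k]))
        if mm <= max_mismatch:
            return (k, mm)
    return None


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def find_overlaps(
    fs: FragmentSet,
    min_overlap: int = 50,
    max_mismatch: int = 0,
    try_reverse_complement: bool = True,
) -> tuple[list[Overlap], FragmentSet]:
    """All qualifying pairwise suffix-prefix overlaps (longest per ordered pair).

    When ``try_reverse_complement`` is set, fragments are first co-oriented:
    any fragment whose reverse complement overlaps the current layout better
    than the given strand is flipped (Sanger reads arrive in both
    orientations). Returns the overlap table and the possibly re-oriented
    fragment set; self-pairs are never reported.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    frags = list(fs.fragments)
    if try_reverse_complement and len(frags) > 1:
        frags = _co_orient(frags, min_overlap, max_mismatch)
    oriented = FragmentSet(fragments=frags, kind=fs.kind)
    table: list[Overlap] = []
    for fid_a, seq_a in frags:
        for fid_b, seq_b in frags:
            if fid_a == fid_b:
                continue
            hit = _suffix_prefix_overlap(seq_a, seq_b, min_overlap, max_mismatch)
            if hit:
                table.append(Overlap(fid_a, fid_b, hit[0], hit[1]))
    return table, oriented


def _score(frags, min_overlap, max_mismatch) -> int:
    total = 0
    for i, (fa, a) in enumerate(frags):
        for j, (fb, b) in enumerate(frags):
            if i == j:
                continue
            hit = _suffix_prefix_overlap(a, b, min_overlap, max_mismatch)
            if hit:
                total += hit[0]
    return total


def _co_orient(frags, min_overlap, max_mismatch):
    """Greedy strand assignment: flip any fragment whose flip raises total overlap."""
    frags = list(frags)
    improved = True
    passes = 0
    while improved and passes < 3:
        improved = False
        passes += 1
        base = _score(frags, min_overlap, max_mismatch)
        for idx, (fid, seq) in enumerate(frags):
            trial = list(frags)
            trial[idx] = (fid, reverse_complement(seq))
            if _score(trial, min_overlap, max_mismatch) > base:
                frags = trial
                base = _score(frags, min_overlap, max_mismatch)
                improved = True
    return frags


def least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm), for canonical circles."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def rotations_equal(a: str, b: str) -> bool:
    """True iff two circular sequences are equal up to rotation."""
    return len(a) == len(b) and least_rotation(a) == least_rotation(b)


def _cycle_overlaps(order, by_pair):
    out = []
    for idx, fid in enumerate(order):
        nxt = order[(idx + 1) % len(order)]
        ov = by_pair.get((fid, nxt))
        if ov is None:
            return None
        out.append(ov)
    return out


def assemble_circle(
    fs: FragmentSet,
    min_overlap: int = 50,
    max_mismatch: int = 0,
    try_reverse_complement: bool = True,
    canonical_rotation: bool = False,
) -> AssemblyLayout:
    """Search for a circular layout of the fragments and build its consensus.

    For up to 12 fragments the Hamiltonian-cycle search is exhaustive (the
    first fragment is fixed to break rotational symmetry) and maximises total
    junction overlap; beyond that a greedy longest-overlap-first chaining is
    used (ties by lexicographic fragment id). The consensus drops each
    junction's overlap once; at mismatching overlap columns the upstream
    fragment's base is kept (deterministic two-sequence tie-break). If no
    cycle exists, the best open path is returned with ``closed=False``.

    With ``canonical_rotation`` the consensus is reported as its
    lexicographically least rotation (only meaningful for closed layouts).
    """
    table, oriented = find_overlaps(fs, min_overlap, max_mismatch, try_reverse_complement)
    by_pair = {(o.source, o.target): o for o in table}
    seqs = dict(oriented.fragments)
    ids = [fid for fid, _ in oriented.fragments]

    best_cycle: Optional[list[str]] = None
    best_total = -1
    if 2 <= len(ids) <= 12:
        first = ids[0]
        for rest in permutations(ids[1:]):
            order = [first, *rest]
            ovs = _cycle_overlaps(order, by_pair)
            if ovs is None:
                continue
            total = sum(o.length for o in ovs)
            if total > best_total:
                best_total = total
                best_cycle = order
    elif len(ids) > 12:
        best_cycle = _greedy_cycle(ids, by_pair)
        if best_cycle is not None and _cycle_overlaps(best_cycle, by_pair) is None:
            best_cycle = None

    if best_cycle is not None:
        ovs = _cycle_overlaps(best_cycle, by_pair)
        pieces = []
        for idx, fid in enumerate(best_cycle):
            drop = ovs[idx].length  # overlap with the next fragment
            pieces.append(seqs[fid][: len(seqs[fid]) - drop])
        consensus = "".join(pieces)
        if canonical_rotation and consensus:
            consensus = least_rotation(consensus)
        return AssemblyLayout(order=best_cycle, junction_overlaps=ovs, consensus=consensus, closed=True)

    # no cycle: best open path by greedy longest-overlap chaining
    order, ovs = _best_open_path(ids, by_pair)
    consensus = ""
    if order:
        consensus = seqs[order[0]]
        for idx in range(1, len(order)):
            ov = by_pair[(order[idx - 1], order[idx])]
            consensus += seqs[order[idx]][ov.length :]
    return AssemblyLayout(order=order, junction_overlaps=ovs, consensus=consensus, closed=False)


def _greedy_cycle(ids, by_pair):
    if not ids:
        return None
    order = [sorted(ids)[0]]
    remaining = set(ids) - {order[0]}
    while remaining:
        cands = [
            (by_pair[(order[-1], j)].length, j)
            for j in remaining
            if (order[-1], j) in by_pair
        ]
        if not cands:
            return None
        cands.sort(key=lambda t: (-t[0], t[1]))
        order.append(cands[0][1])
        remaining.discard(cands[0][1])
    return order if (order[-1], order[0]) in by_pair else None


def _best_open_path(ids, by_pair):
    """Greedy longest-overlap-first path through as many fragments as possible."""
    edges = sorted(by_pair.values(), key=lambda o: (-o.length, o.source, o.target))
    best_order: list[str] = [ids[0]] if ids else []
    best_ovs: list = []
    for start in sorted(ids):
        order = [start]
        ovs = []
        used = {start}
        while True:
            nxt = next(
                (e for e in edges if e.source == order[-1] and e.target not in used), None
            )
            if nxt is None:
                break
            order.append(nxt.target)
            used.add(nxt.target)
            ovs.append(nxt)
        if len(order) > len(best_order):
            best_order, best_ovs = order, ovs
    return best_order, best_ovs


def overlap_report(
    layout: Optional[AssemblyLayout] = None,
    extra_confirmations: Sequence[int] = (),
) -> dict:
    """Totals over junction overlaps plus independent confirmation overlaps.

    ``extra_confirmations`` carries overlap lengths from independently
    amplified fragments (partial-gene amplicons confirming long-PCR
    junctions) that are not part of the layout itself.
    """
    lengths = [o.length for o in layout.junction_overlaps] if layout else []
    lengths += list(extra_confirmations)
    if not lengths:
        return {"total_overlap": 0, "min": None, "max": None, "n_overlaps": 0,
                "n_fragments": len(layout.order) if layout else 0}
    return {
        "total_overlap": sum(lengths),
        "min": min(lengths),
        "max": max(lengths),
        "n_overlaps": len(lengths),
        "n_fragments": len(layout.order) if layout else 0,
    }
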