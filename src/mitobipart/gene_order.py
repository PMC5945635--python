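"""Circular gene-order comparison: shared-cluster (conserved block) detection.

A genome's gene order is a circular (or linear) sequence of signed gene
labels. Two orders share a cluster when at least two genes are contiguous and
identically ordered in both; clusters are reported strictly maximal (not
extendable in either direction in both orders). Comparing a multi-chromosome
genome against another taxon is done chromosome by chromosome.

Gene names are normalised through an editable alias table before comparison —
mismatched naming conventions (COI vs cox1, one-letter tRNA figure labels)
are the dominant practical failure mode of such comparisons. The leucine and
serine tRNA paralogs (L1/L2, S1/S2, distinguished by anticodon) are kept
distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from mitobipart.genome_model import GeneClass, GenomeAnnotation

#: default alias table: common synonyms and one-letter tRNA labels -> canonical
DEFAULT_ALIASES: dict[str, str] = {
    "coi": "cox1",
    "coii": "cox2",
    "coiii": "cox3",
    "co1": "cox1",
    "co2": "cox2",
    "co3": "cox3",
    "cytb": "cob",
    "cob": "cob",
    "nd1": "nad1",
    "nd2": "nad2",
    "nd3": "nad3",
    "nd4": "nad4",
    "nd4l": "nad4l",
    "nd5": "nad5",
    "nd6": "nad6",
    "12s": "rrns",
    "16s": "rrnl",
    "srrna": "rrns",
    "lrrna": "rrnl",
}
# one-letter tRNA labels as used in circular-map figures
for _letter in "ACDEFGHIKMNPQRTVWY":
    DEFAULT_ALIASES[_letter.lower()] = f"trn{_letter.lower()}"
for _iso in ("l1", "l2", "s1", "s2"):
    DEFAULT_ALIASES[_iso] = f"trn{_iso}"


def normalize_gene_name(name: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Canonical lower-case gene label, resolving aliases."""
    table = DEFAULT_ALIASES if aliases is None else aliases
    low = name.strip().lower()
    return table.get(low, low)


@dataclass
class GeneOrder:
    """Ordered, signed gene labels of one chromosome or genome."""

    label: str
    genes: list[str]  # signed names: leading '-' marks minus strand
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene order {self.label!r} is empty")

    def normalized(self, aliases: Optional[dict[str, str]] = None) -> list[tuple[str, int]]:
        """(canonical name, sign) pairs."""
        out = []
        for g in self.genes:
            sign = -1 if g.startswith("-") else 1
            out.append((normalize_gene_name(g.lstrip("+-"), aliases), sign))
        return out

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SharedCluster:
    """A maximal run of genes contiguous and identically ordered in two orders."""

    genes: list[str]
    start_a: int  # 0-based start index in order a
    start_b: int  # 0-based start index in order b (of the block as listed in b)
    orientation: str = "same"  # "same" | "reversed"

    @property
    def length(self) -> int:
        return len(self.genes)


def order_from_annotation(
    a: GenomeAnnotation,
    include_classes: frozenset = frozenset({GeneClass.PCG, GeneClass.TRNA, GeneClass.RRNA}),
) -> GeneOrder:
    """Linearize an annotation into a gene order (NCRs excluded by default)."""
    genes = [
        ("-" if f.strand == "-" else "") + f.gene_name
        for f in a.features
        if f.gene_class in include_classes
    ]
    if not genes:
        raise ValueError(f"annotation {a.chromosome.id!r} yields an empty gene order")
    return GeneOrder(label=a.chromosome.id, genes=genes, circular=a.chromosome.is_circular)


def _runs(
    sa: list[tuple[str, int]],
    sb: list[tuple[str, int]],
    circ_a: bool,
    circ_b: bool,
    min_len: int,
) -> list[tuple[int, int, int]]:
    """Maximal match runs between two signed sequences as (start_a, start_b, length).

    Seeds at every matching position pair whose diagonal predecessor does not
    match (so each reported run is left-maximal), extends forward maximally,
    and caps the length at ``min(len(sa), len(sb))``. When both orders are
    circular, a fully matching torus line (no mismatch anywhere along the
    periodic diagonal — e.g. an order against a rotation of itself) has no
    seed and is detected separately, contributing one capped run.
    """
    import math

    n, m = len(sa), len(sb)
    cap = min(n, m)
    runs: list[tuple[int, int, int]] = []

    def emit(i: int, j: int, raw_len: int) -> None:
        # a raw diagonal run longer than the shorter order is reported as its
        # length-cap windows: each window uses distinct positions in both orders
        if raw_len <= cap:
            if raw_len >= min_len:
                runs.append((i, j, raw_len))
        elif cap >= min_len:
            for t in range(raw_len - cap + 1):
                runs.append(((i + t) % n, (j + t) % m, cap))

    if circ_a and circ_b:
        g = math.gcd(n, m)
        period = n * m // g
        for d in range(g):
            if all(sa[t % n] == sb[(d + t) % m] for t in range(period)):
                # fully matching torus line: every length-cap window along it
                if cap >= min_len:
                    for t in range(period):
                        runs.append((t % n, (d + t) % m, cap))
    hard_cap = (n * m // math.gcd(n, m)) if (circ_a and circ_b) else n + m
    for i in range(n):
        for j in range(m):
            if sa[i] != sb[j]:
                continue
            has_pred = (i > 0 or circ_a) and (j > 0 or circ_b)
            if has_pred and sa[(i - 1) % n] == sb[(j - 1) % m]:
                continue  # not a left end of the run
            length = 1
            while length < hard_cap:
                ni, nj = i + length, j + length
                if ni >= n:
                    if not circ_a:
                        break
                    ni %= n
                if nj >= m:
                    if not circ_b:
                        break
                    nj %= m
                if sa[ni] != sb[nj]:
                    break
                length += 1
            emit(i, j, length)
    return runs


def shared_clusters(
    order_a: GeneOrder,
    order_b: GeneOrder,
    allow_reversal: bool = False,
    min_len: int = 2,
    aliases: Optional[dict[str, str]] = None,
) -> list[SharedCluster]:
    """All maximal shared gene clusters of length >= ``min_len`` between two orders.

    Matching honours each order's circularity (a block may wrap the listed
    origin) and gene strand. With ``allow_reversal`` the comparison is also
    run against order b reversed with flipped strands, reporting those blocks
    with ``orientation="reversed"`` — moot for all-same-strand mitogenomes,
    relevant for general taxa.

    Maximality is strict and global: a reported block's gene string is not a
    contiguous substring of any other reported block of the same orientation
    (repeated labels can seed runs that longer runs elsewhere subsume), and
    identical gene strings from different seeds are reported once.
    """
    sa = order_a.normalized(aliases)
    sb = order_b.normalized(aliases)
    cap = min(len(sa), len(sb))
    # (signed normalized tuple, cluster) candidates, then global maximality filter
    candidates: list[tuple[tuple, SharedCluster]] = []
    for i, j, length in _runs(sa, sb, order_a.circular, order_b.circular, min_len):
        genes = [order_a.genes[(i + t) % len(sa)].lstrip("+-") for t in range(length)]
        key = tuple(sa[(i + t) % len(sa)] for t in range(length))
        candidates.append(
            (key, SharedCluster(genes=genes, start_a=i, start_b=j, orientation="same"))
        )
    if allow_reversal:
        rb = [(name, -sign) for name, sign in reversed(sb)]
        m = len(sb)
        for i, j, length in _runs(sa, rb, order_a.circular, order_b.circular, min_len):
            genes = [order_a.genes[(i + t) % len(sa)].lstrip("+-") for t in range(length)]
            key = tuple(sa[(i + t) % len(sa)] for t in range(length))
            start_b = (m - 1 - (j + length - 1)) % m
            candidates.append(
                (key, SharedCluster(genes=genes, start_a=i, start_b=start_b, orientation="reversed"))
            )

    def contained(short: tuple, long: tuple, long_is_full_circle: bool) -> bool:
        if len(short) > len(long):
            return False
        haystack = long * 2 if long_is_full_circle else long
        return any(
            haystack[k : k + len(short)] == short for k in range(len(haystack) - len(short) + 1)
        )

    candidates.sort(key=lambda kc: (-kc[1].length, kc[1].start_a, kc[1].start_b, kc[1].orientation))
    kept: list[tuple[tuple, SharedCluster]] = []
    both_circular = order_a.circular and order_b.circular
    for key, cluster in candidates:
        redundant = any(
            k_cl.orientation == cluster.orientation
            and contained(key, k_key, both_circular and len(k_key) == cap)
            for k_key, k_cl in kept
        )
        if not redundant:
            kept.append((key, cluster))
    return [c for _, c in kept]


def cluster_summary(clusters: Sequence[SharedCluster]) -> dict[str, int]:
    """Totals over a cluster list: count, genes covered, longest block."""
    return {
        "n_clusters": len(clusters),
        "genes_covered": sum(c.length for c in clusters),
        "longest_cluster": max((c.length for c in clusters), default=0),
    }


# ---------------------------------------------------------------------------
# Gene-order text format: one genome per line, "label: g1 g2 -g3 ...",
# a '*' suffix on the label marking a linear (non-circular) order.
# ---------------------------------------------------------------------------

def parse_gene_orders(text: str) -> dict[str, GeneOrder]:
    orders: dict[str, GeneOrder] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'label: gene gene ...'")
        label, _, rest = line.partition(":")
        label = label.strip()
        circular = True
        if label.endswith("*"):
            circular = False
            label = label[:-1].strip()
        genes = rest.split()
        if not genes:
            raise ValueError(f"line {lineno}: no genes listed for {label!r}")
        orders[label] = GeneOrder(label=label, genes=genes, circular=circular)
    return orders
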