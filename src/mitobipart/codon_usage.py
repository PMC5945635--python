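"""Codon counting over protein-coding genes and nucleotide-bias statistics.

Counts complete codons only — a trailing 1–2 nt incomplete termination codon
is excluded, since a partial triplet has no defensible codon assignment.
Percentages are rounded half-up to one decimal, the precision at which such
tables are conventionally printed.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable as _BioCodonTable

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (Python's round() is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def translation_table(table_id: int = 5):
    """Biopython codon table for an NCBI genetic code (default 5, invertebrate mt)."""
    return _BioCodonTable.unambiguous_dna_by_id[table_id]


@dataclass
class CodonUsageTable:
    """Codon counts and relative frequencies (% of all counted codons)."""

    group: str
    counts: Counter = field(default_factory=Counter)
    #: codons skipped because they contained an N
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, codon: str) -> float:
        """Relative frequency of one codon in percent, to one decimal."""
        if self.total == 0:
            return 0.0
        return round_half_up(100.0 * self.counts.get(codon, 0) / self.total)

    def frequencies(self) -> dict[str, float]:
        return {c: self.frequency(c) for c in sorted(self.counts)}


def count_codons(
    genes: Sequence[tuple[str, str]],
    group: str = "all",
    include_incomplete_terminal: bool = False,
    exclude_stop_codons: bool = False,
    table_id: int = 5,
) -> CodonUsageTable:
    """Tally codons over a set of coding sequences.

    Parameters
    ----------
    genes : sequence of (name, coding sequence)
        Sequences are read on the annotated coding strand, frame starting at
        base 1 of each gene.
    include_incomplete_terminal : bool
        When True, a trailing partial triplet is counted as its 1–2 literal
        bases padded to nothing — retained only for sensitivity analyses;
        default drops the partial triplet.
    exclude_stop_codons : bool
        Drop complete termination codons of the genetic code ``table_id``
        from the tally.
    """
    table = CodonUsageTable(group=group)
    stops = set(translation_table(table_id).stop_codons) if exclude_stop_codons else set()
    for _name, seq in genes:
        seq = seq.upper()
        n_complete = len(seq) // 3
        for i in range(n_complete):
            codon = seq[3 * i : 3 * i + 3]
            if "N" in codon:
                table.ambiguous += 1
                continue
            if codon in stops:
                continue
            table.counts[codon] += 1
        if include_incomplete_terminal and len(seq) % 3:
            tail = seq[3 * n_complete :]
            if "N" not in tail:
                table.counts[tail] += 1
    return table


def rich_fraction(table: CodonUsageTable, base: str, min_copies: int) -> float:
    """Summed relative frequency (%) of codons with >= ``min_copies`` of ``base``.

    With ``base="T", min_copies=2`` this is the T-rich codon fraction; with
    ``base="C", min_copies=2`` the C-rich fraction.
    """
    base = base.upper()
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    if min_copies not in (1, 2, 3):
        raise ValueError(f"min_copies must be 1, 2 or 3, got {min_copies}")
    if table.total == 0:
        return 0.0
    hits = sum(n for codon, n in table.counts.items() if codon.count(base) >= min_copies)
    return round_half_up(100.0 * hits / table.total)


def top_codons(table: CodonUsageTable, k: int) -> list[tuple[str, float]]:
    """The ``k`` most frequent codons with their percentages; ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(codon, table.frequency(codon)) for codon, _ in ranked[:k]]


def at_content(seq: str) -> float:
    """A+T content of a sequence in percent (N bases excluded), to one decimal."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    effective = len(seq) - seq.count("N")
    if effective == 0:
        raise ValueError("sequence contains only N")
    return round_half_up(100.0 * (seq.count("A") + seq.count("T")) / effective)


def usage_rows(table: CodonUsageTable, table_id: int = 5) -> list[dict]:
    """Full 64-row usage listing: codon, amino acid (or ``*``), count, percent."""
    code = translation_table(table_id)
    rows = []
    for codon in ALL_CODONS:
        aa = "*" if codon in code.stop_codons else code.forward_table.get(codon, "?")
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "count": table.counts.get(codon, 0),
                "percent": table.frequency(codon),
            }
        )
    return rows
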