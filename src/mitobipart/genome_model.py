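"""Core data model: circular chromosomes, feature annotations, and their I/O.

Coordinates are 1-based and fully inclusive throughout, matching the convention
of published mitochondrial annotation tables (a gene at 1–1536 spans 1536 nt).
Features are stored unwrapped (``start <= end``); only subsequence extraction
understands wrap-around on a circular chromosome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

_VALID_BASES = frozenset("ACGTN")


class GeneClass(str, Enum):
    """Functional class of an annotated feature."""

    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    NCR = "NCR"


def infer_gene_class(name: str) -> GeneClass:
    """Infer a feature's class from standard mitochondrial naming conventions.

    ``trn*`` names are tRNAs, ``rrn*`` are rRNAs, ``NCR*`` are non-coding
    regions, and everything else is treated as a protein-coding gene.
    """
    low = name.lower()
    if low.startswith("trn"):
        return GeneClass.TRNA
    if low.startswith("rrn"):
        return GeneClass.RRNA
    if low.startswith("ncr"):
        return GeneClass.NCR
    return GeneClass.PCG


class GeneTableError(ValueError):
    """Raised for malformed or internally inconsistent gene tables."""


@dataclass(frozen=True)
class CircularChromosome:
    """A (usually circular) mitochondrial chromosome.

    Parameters
    ----------
    id : str
        Chromosome label, e.g. ``"chromosome_I"``.
    length : int
        Declared length in nucleotides; must be positive.
    sequence : str, optional
        Nucleotide sequence over ``{A, C, G, T, N}``. When present its length
        must equal ``length``.
    is_circular : bool
        Whether coordinates wrap across the origin (default ``True``).
    """

    id: str
    length: int
    sequence: Optional[str] = None
    is_circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id!r}: length must be positive, got {self.length}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise ValueError(
                    f"chromosome {self.id!r}: sequence length {len(seq)} != declared length {self.length}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {self.id!r}: invalid characters in sequence: {sorted(bad)}"
                )


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated gene or non-coding region, in 1-based inclusive coordinates."""

    gene_name: str
    gene_class: GeneClass
    start: int
    end: int
    strand: str = "+"
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_name}: end ({self.end}) < start ({self.start}); "
                "wrap-around features are not supported"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_name}: strand must be '+' or '-', got {self.strand!r}")
        if self.anticodon is not None and len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_name}: anticodon must be 3 nt, got {self.anticodon!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """An ordered feature set on one chromosome.

    Features are kept sorted by ascending start coordinate.
    """

    chromosome: CircularChromosome
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.gene_name))

    def by_class(self, gene_class: GeneClass) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.gene_class == gene_class]

    def get(self, gene_name: str) -> FeatureAnnotation:
        for f in self.features:
            if f.gene_name == gene_name:
                return f
        raise KeyError(f"no feature named {gene_name!r} on {self.chromosome.id}")


def feature_length(f: FeatureAnnotation) -> int:
    """Length of a feature in nucleotides (``end - start + 1``)."""
    return f.end - f.start + 1


def extract_subsequence(chrom: CircularChromosome, start: int, end: int) -> str:
    """Extract the subsequence at 1-based inclusive ``[start, end]``.

    When ``end < start`` on a circular chromosome the extraction wraps across
    the origin, returning ``length - start + 1 + end`` nucleotides.
    """
    if chrom.sequence is None:
        raise ValueError(f"chromosome {chrom.id!r} has no sequence")
    if not (1 <= start <= chrom.length) or not (1 <= end <= chrom.length):
        raise ValueError(
            f"positions ({start}, {end}) out of range for chromosome of length {chrom.length}"
        )
    if end >= start:
        return chrom.sequence[start - 1 : end]
    if not chrom.is_circular:
        raise ValueError(
            f"wrap-around extraction ({start}, {end}) requested on non-circular {chrom.id!r}"
        )
    return chrom.sequence[start - 1 :] + chrom.sequence[:end]


def feature_sequence(chrom: CircularChromosome, f: FeatureAnnotation) -> str:
    """Sequence of a feature on its coding strand (reverse-complemented for '-')."""
    seq = extract_subsequence(chrom, f.start, f.end)
    if f.strand == "-":
        comp = str.maketrans("ACGTN", "TGCAN")
        seq = seq.translate(comp)[::-1]
    return seq


@dataclass(frozen=True)
class Violation:
    """One validation failure; data, not an exception."""

    feature: Optional[str]
    rule: str
    detail: str


def validate_annotation(a: GenomeAnnotation) -> list[Violation]:
    """Check an annotation against the model's invariants.

    Returns an empty list iff all invariants hold. Checks:

    - every feature lies within ``[1, chromosome length]``
    - no two features share identical (name, start, end)
    - gene class is consistent with the name-prefix convention
    - minus-strand features are flagged (all-same-strand is the norm in
      chromadorean nematode mitogenomes)
    """
    violations: list[Violation] = []
    L = a.chromosome.length
    seen: set[tuple[str, int, int]] = set()
    for f in a.features:
        if f.end > L:
            violations.append(
                Violation(f.gene_name, "within_chromosome", f"end {f.end} > chromosome length {L}")
            )
        key = (f.gene_name, f.start, f.end)
        if key in seen:
            violations.append(Violation(f.gene_name, "duplicate_row", f"repeated row {key}"))
        seen.add(key)
        expected = infer_gene_class(f.gene_name)
        if f.gene_class != expected:
            violations.append(
                Violation(
                    f.gene_name,
                    "class_name_consistency",
                    f"class {f.gene_class.value} inconsistent with name (expected {expected.value})",
                )
            )
        if f.strand == "-":
            violations.append(
                Violation(f.gene_name, "minus_strand", "feature on minus strand (flagged, not fatal)")
            )
    return violations


# ---------------------------------------------------------------------------
# Gene-table TSV I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "gene",
    "start",
    "end",
    "length",
    "class",
    "start_codon",
    "stop_codon",
    "strand",
    "anticodon",
    "intergenic",
}

_CLASS_ALIASES = {
    "pcg": GeneClass.PCG,
    "trna": GeneClass.TRNA,
    "rrna": GeneClass.RRNA,
    "ncr": GeneClass.NCR,
}


def parse_gene_table(
    table_text: str,
    chromosome_length: Optional[int] = None,
    chromosome_id: str = "chromosome",
    sequence: Optional[str] = None,
) -> GenomeAnnotation:
    """Parse a gene-coordinate table (TSV or whitespace-separated) into an annotation.

    The table needs columns ``gene``, ``start``, ``end``; optional columns are
    ``length`` (cross-checked against ``end - start + 1``), ``class``,
    ``start_codon``, ``stop_codon``, ``strand``, ``anticodon`` and
    ``intergenic`` (ignored here; recomputed by the stats stage). A header row
    is recognised when the first non-comment line starts with ``gene``;
    otherwise columns are taken positionally as gene/start/end[/length].
    ``#``-prefixed lines are comments.

    When ``chromosome_length`` is omitted it defaults to the maximum feature
    end (or the sequence length when a sequence is given).
    """
    header: Optional[list[str]] = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        parts = [p.strip() for p in parts if p.strip() != ""]
        if header is None and parts[0].lower() == "gene":
            unknown = set(p.lower() for p in parts) - _TABLE_COLUMNS
            if unknown:
                raise GeneTableError(f"line {lineno}: unknown columns {sorted(unknown)}")
            header = [p.lower() for p in parts]
            continue
        rows.append((lineno, parts))

    if header is None:
        header = ["gene", "start", "end", "length"]

    features: list[FeatureAnnotation] = []
    for lineno, parts in rows:
        if len(parts) < 3:
            raise GeneTableError(f"line {lineno}: expected at least gene/start/end, got {parts!r}")
        rec = dict(zip(header, parts))
        name = rec.get("gene")
        if name is None:
            raise GeneTableError(f"line {lineno}: missing gene name")
        try:
            start = int(rec["start"])
            end = int(rec["end"])
        except (KeyError, ValueError) as exc:
            raise GeneTableError(f"line {lineno}: bad start/end in {parts!r}") from exc
        cls_text = rec.get("class")
        if cls_text:
            try:
                gene_class = _CLASS_ALIASES[cls_text.lower()]
            except KeyError:
                raise GeneTableError(f"line {lineno}: unknown gene class {cls_text!r}") from None
        else:
            gene_class = infer_gene_class(name)
        try:
            feat = FeatureAnnotation(
                gene_name=name,
                gene_class=gene_class,
                start=start,
                end=end,
                strand=rec.get("strand", "+") or "+",
                anticodon=rec.get("anticodon") or None,
                start_codon=(rec.get("start_codon") or None),
                stop_codon=(rec.get("stop_codon") or None),
            )
        except ValueError as exc:
            raise GeneTableError(f"line {lineno}: {exc}") from exc
        if rec.get("length"):
            declared = int(rec["length"])
            if declared != feat.length:
                raise GeneTableError(
                    f"gene {name}: declared length {declared} != span {feat.length} "
                    f"({start}-{end})"
                )
        features.append(feat)

    if chromosome_length is None:
        if sequence is not None:
            chromosome_length = len(sequence)
        elif features:
            chromosome_length = max(f.end for f in features)
        else:
            raise GeneTableError("cannot infer chromosome length from an empty table")
    chrom = CircularChromosome(id=chromosome_id, length=chromosome_length, sequence=sequence)
    return GenomeAnnotation(chromosome=chrom, features=features)


def render_gene_table(a: GenomeAnnotation) -> str:
    """Serialize an annotation back to the gene-table TSV dialect."""
    lines = ["gene\tstart\tend\tlength\tclass\tstart_codon\tstop_codon\tstrand"]
    for f in a.features:
        lines.append(
            "\t".join(
                [
                    f.gene_name,
                    str(f.start),
                    str(f.end),
                    str(f.length),
                    f.gene_class.value,
                    f.start_codon or "",
                    f.stop_codon or "",
                    f.strand,
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O (via Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path_or_handle) -> dict[str, str]:
    """Read a (multi-)FASTA file into ``{record id: uppercase sequence}``."""
    records = SeqIO.parse(path_or_handle, "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_fasta(sequences: dict[str, str], handle, circular: bool = False) -> None:
    """Write sequences as FASTA; circular molecules are marked in the description."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for name, seq in sequences.items():
            desc = " circular=true" if circular else ""
            handle.write(f">{name}{desc}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
    finally:
        if close:
            handle.close()


_GENBANK_CLASS = {"CDS": GeneClass.PCG, "tRNA": GeneClass.TRNA, "rRNA": GeneClass.RRNA}


def read_genbank(path_or_handle) -> list[GenomeAnnotation]:
    """Read GenBank flat file(s), mapping CDS/tRNA/rRNA features to annotations.

    Feature names are taken from the ``gene`` qualifier (falling back to
    ``product``); coordinates are converted to 1-based inclusive. Compound
    (joined) locations are not supported and raise.
    """
    annotations = []
    for rec in SeqIO.parse(path_or_handle, "genbank"):
        seq = str(rec.seq).upper() if len(rec.seq) else None
        topology = rec.annotations.get("topology", "circular")
        chrom = CircularChromosome(
            id=rec.id, length=len(rec.seq), sequence=seq, is_circular=topology == "circular"
        )
        feats = []
        for feat in rec.features:
            if feat.type not in _GENBANK_CLASS:
                continue
            if len(feat.location.parts) != 1:
                raise ValueError(f"{rec.id}: compound location on {feat.type} not supported")
            name = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
            feats.append(
                FeatureAnnotation(
                    gene_name=name,
                    gene_class=_GENBANK_CLASS[feat.type],
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                )
            )
        annotations.append(GenomeAnnotation(chromosome=chrom, features=feats))
    return annotations


def rotate_chromosome(chrom: CircularChromosome, new_origin: int) -> CircularChromosome:
    """Return the chromosome rotated so 1-based ``new_origin`` becomes position 1."""
    if chrom.sequence is None:
        raise ValueError("rotation requires a sequence")
    if not chrom.is_circular:
        raise ValueError("cannot rotate a non-circular chromosome")
    if not 1 <= new_origin <= chrom.length:
        raise ValueError(f"origin {new_origin} out of range")
    seq = chrom.sequence[new_origin - 1 :] + chrom.sequence[: new_origin - 1]
    return replace(chrom, sequence=seq)
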