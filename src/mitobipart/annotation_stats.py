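"""Structural bookkeeping over gene annotations.

Reproduces the arithmetic of a mitochondrial genome-organization table:
intergenic spacing around the circle, chromosome-length closure, detection of
long non-coding regions (NCRs), gene-class inventories across chromosomes,
and start/stop codon inference including incomplete termination codons.

Spacing convention: ``start(next) - end(current) - 1``, so abutting genes
score 0 and a 1-nt shared base scores -1. Negative values denote overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from mitobipart.genome_model import (
    CircularChromosome,
    FeatureAnnotation,
    GeneClass,
    GenomeAnnotation,
    feature_length,
    feature_sequence,
)

#: Canonical metazoan mitochondrial gene inventory (13 PCGs incl. atp8,
#: 22 tRNAs, 2 rRNAs). Most nematodes lack atp8.
CANONICAL_PCGS = frozenset(
    ["atp6", "atp8", "cob", "cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6"]
)

#: Start codons observed for invertebrate mitochondrial PCGs; the default set
#: is the one used by the chromadorean nematodes this model targets.
DEFAULT_START_CODONS = frozenset(["ATT", "ATA", "ATG"])


@dataclass(frozen=True)
class SpacingRecord:
    """Spacer between two adjacent features on a circular chromosome."""

    upstream_gene: str
    downstream_gene: str
    spacing: int
    wraps_origin: bool = False
    #: set when the overlap implied by a negative spacing exceeds the shorter
    #: of the two features — almost certainly an annotation error
    violation: bool = False


@dataclass
class GeneInventory:
    """Gene counts by class, per chromosome and deduplicated across chromosomes."""

    per_chromosome: dict[str, dict[GeneClass, int]] = field(default_factory=dict)
    distinct: dict[GeneClass, int] = field(default_factory=dict)
    duplicated_across: list[str] = field(default_factory=list)
    duplicated_within: dict[str, list[str]] = field(default_factory=dict)
    missing_canonical: list[str] = field(default_factory=list)

    def total_features(self, chromosome_id: str) -> int:
        return sum(self.per_chromosome[chromosome_id].values())


@dataclass(frozen=True)
class CodonCall:
    """Inferred initiation/termination codons for a protein-coding gene."""

    gene: str
    start_codon: str
    stop_codon: str  # "TAA" | "TAG" | "TGA" | "TA" | "T"
    complete: bool
    start_codon_allowed: bool = True


class ClosureError(ValueError):
    """Chromosome-length closure disagreement."""


def intergenic_spacings(a: GenomeAnnotation) -> list[SpacingRecord]:
    """Spacer after each feature, in coordinate order, including the wrap junction.

    For *n* features on a circular chromosome exactly *n* records are
    returned; the last record wraps the origin back to the first feature. On a
    non-circular chromosome *n - 1* records are returned.
    """
    feats = a.features
    if not feats:
        raise ValueError("annotation has no features")
    records: list[SpacingRecord] = []
    for up, down in zip(feats, feats[1:]):
        spacing = down.start - up.end - 1
        records.append(
            SpacingRecord(
                up.gene_name,
                down.gene_name,
                spacing,
                violation=spacing < 0 and -spacing > min(feature_length(up), feature_length(down)),
            )
        )
    if a.chromosome.is_circular:
        first, last = feats[0], feats[-1]
        spacing = first.start + a.chromosome.length - last.end - 1
        records.append(
            SpacingRecord(
                last.gene_name,
                first.gene_name,
                spacing,
                wraps_origin=True,
                violation=spacing < 0
                and -spacing > min(feature_length(last), feature_length(first)),
            )
        )
    return records


def closure_length(a: GenomeAnnotation, wrap_spacing: int) -> int:
    """Close the circle: last feature end plus the printed wrap-around spacer.

    When the chromosome's length is independently declared the two values must
    agree, otherwise :class:`ClosureError` is raised.
    """
    if not a.features:
        raise ValueError("annotation has no features")
    last_end = max(f.end for f in a.features)
    implied = last_end + wrap_spacing
    if a.chromosome.length is not None and a.chromosome.length != implied:
        raise ClosureError(
            f"{a.chromosome.id}: closure length {implied} (last end {last_end} + wrap "
            f"{wrap_spacing}) disagrees with declared length {a.chromosome.length}"
        )
    return implied


def detect_ncrs(a: GenomeAnnotation, min_len: int = 200, prefix: str = "NCR") -> list[FeatureAnnotation]:
    """Detect non-coding regions as inter-gene gaps of at least ``min_len`` nt.

    Only gene features (PCG/tRNA/rRNA) bound the gaps; NCR-class rows already
    present in the annotation are ignored, so detection works identically
    whether or not the table lists its NCRs. Detected regions are named
    ``NCR1``, ``NCR2``, ... in coordinate order, with coordinates
    ``(upstream end + 1, downstream start - 1)``. A gap spanning the circle's
    origin is not reported (rotate the chromosome to expose it).
    """
    genes = [f for f in a.features if f.gene_class != GeneClass.NCR]
    ncrs: list[FeatureAnnotation] = []
    for up, down in zip(genes, genes[1:]):
        gap = down.start - up.end - 1
        if gap >= min_len:
            ncrs.append(
                FeatureAnnotation(
                    gene_name=f"{prefix}{len(ncrs) + 1}",
                    gene_class=GeneClass.NCR,
                    start=up.end + 1,
                    end=down.start - 1,
                )
            )
    return ncrs


def gene_inventory(
    annotations: Sequence[GenomeAnnotation],
    canonical_pcgs: Iterable[str] = CANONICAL_PCGS,
) -> GeneInventory:
    """Count genes per chromosome and across the genome.

    ``duplicated_across`` lists gene names annotated on two or more
    chromosomes; ``missing_canonical`` lists canonical mitochondrial PCGs
    absent from the whole genome (flags e.g. the usual nematode *atp8* loss).
    NCR features are excluded from all counts.
    """
    inv = GeneInventory()
    name_chroms: dict[str, set[str]] = {}
    names_by_class: dict[GeneClass, set[str]] = {c: set() for c in GeneClass}
    for a in annotations:
        counts = {c: 0 for c in (GeneClass.PCG, GeneClass.TRNA, GeneClass.RRNA)}
        seen_here: dict[str, int] = {}
        for f in a.features:
            if f.gene_class == GeneClass.NCR:
                continue
            counts[f.gene_class] += 1
            names_by_class[f.gene_class].add(f.gene_name)
            name_chroms.setdefault(f.gene_name, set()).add(a.chromosome.id)
            seen_here[f.gene_name] = seen_here.get(f.gene_name, 0) + 1
        inv.per_chromosome[a.chromosome.id] = counts
        within = sorted(n for n, c in seen_here.items() if c > 1)
        if within:
            inv.duplicated_within[a.chromosome.id] = within
    inv.distinct = {
        c: len(names_by_class[c]) for c in (GeneClass.PCG, GeneClass.TRNA, GeneClass.RRNA)
    }
    inv.duplicated_across = sorted(n for n, chroms in name_chroms.items() if len(chroms) >= 2)
    present = {n.lower() for n in name_chroms}
    inv.missing_canonical = sorted(g for g in canonical_pcgs if g.lower() not in present)
    return inv


def infer_codons(
    chrom: CircularChromosome,
    f: FeatureAnnotation,
    allowed_starts: Iterable[str] = DEFAULT_START_CODONS,
    check_internal_stops: bool = False,
    stop_codons: Iterable[str] = ("TAA", "TAG"),
) -> CodonCall:
    """Infer the initiation and termination codon of a protein-coding gene.

    The start codon is the first 3 nt. The termination codon depends on the
    span modulo 3: a full trailing triplet for span % 3 == 0; an incomplete
    ``"TA"`` for remainder 2; an incomplete ``"T"`` for remainder 1 (both
    completed to TAA by post-transcriptional polyadenylation). Trailing bases
    inconsistent with that convention raise ``ValueError``.
    """
    if f.gene_class != GeneClass.PCG:
        raise ValueError(f"{f.gene_name}: codon inference applies to PCGs only")
    seq = feature_sequence(chrom, f)
    if len(seq) < 6:
        raise ValueError(f"{f.gene_name}: span {len(seq)} too short for a coding gene")
    start = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        stop = seq[-3:]
        complete = True
    elif rem == 1:
        stop = seq[-1:]
        complete = False
        if stop != "T":
            raise ValueError(
                f"{f.gene_name}: trailing base {stop!r} violates the incomplete-stop "
                "convention (must be T)"
            )
    else:
        stop = seq[-2:]
        complete = False
        if stop != "TA":
            raise ValueError(
                f"{f.gene_name}: trailing bases {stop!r} violate the incomplete-stop "
                "convention (must be TA)"
            )
    if check_internal_stops:
        stops = set(stop_codons)
        coding_end = len(seq) - rem - (3 if rem == 0 else 0)
        for i in range(3, coding_end, 3):
            if seq[i : i + 3] in stops:
                raise ValueError(f"{f.gene_name}: internal in-frame stop at codon {i // 3 + 1}")
    return CodonCall(
        gene=f.gene_name,
        start_codon=start,
        stop_codon=stop,
        complete=complete,
        start_codon_allowed=start in set(allowed_starts),
    )


def trna_size_range(
    annotations: Sequence[GenomeAnnotation],
) -> tuple[int, int, str, str]:
    """Min and max tRNA gene length across chromosomes, with the genes attaining them.

    Ties are broken by the first tRNA (in chromosome and coordinate order)
    attaining the extreme. Raises ``ValueError`` when no tRNA is annotated.
    """
    trnas = [
        (feature_length(f), f.gene_name)
        for a in annotations
        for f in a.features
        if f.gene_class == GeneClass.TRNA
    ]
    if not trnas:
        raise ValueError("no tRNA features in the annotations")
    min_len, min_gene = min(trnas, key=lambda t: t[0])
    max_len, max_gene = max(trnas, key=lambda t: t[0])
    return min_len, max_len, min_gene, max_gene


def length_conservation(a: GenomeAnnotation) -> tuple[int, int]:
    """Check Σ feature lengths + Σ spacings == chromosome length.

    Returns ``(implied length, declared length)``; NCRs listed as features are
    counted once (as features — their bounding gaps are then zero).
    """
    total = sum(feature_length(f) for f in a.features)
    total += sum(r.spacing for r in intergenic_spacings(a))
    return total, a.chromosome.length
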