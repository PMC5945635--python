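"""Duplicated-gene detection and cross-copy divergence analysis.

Genes annotated on more than one chromosome of a multipartite mitogenome are
compared positionally (the copies carry equal annotated spans, so the
comparison is ungapped), every mismatch is expanded into a substitution
record, and coding substitutions are classified synonymous or nonsynonymous
under the invertebrate mitochondrial genetic code (NCBI translation table 5:
ATA=Met, TGA=Trp, AGA/AGG=Ser). For tRNA genes, the structural impact of a
substitution is assessed against a dot-bracket secondary structure, with G·U
wobble counted as a preserved stem pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import seq3

from mitobipart.codon_usage import round_half_up, translation_table
from mitobipart.genome_model import FeatureAnnotation, GenomeAnnotation, feature_length

#: base pairs preserved in a tRNA stem: Watson-Crick plus G·U wobble
PRESERVED_PAIRS = frozenset(["AT", "TA", "GC", "CG", "GT", "TG"])


@dataclass(frozen=True)
class SubstitutionRecord:
    """One nucleotide difference between two gene copies."""

    position: int  # 1-based within the gene
    base_a: str
    base_b: str
    codon_index: Optional[int] = None  # 1-based codon number (coding frame)
    codon_position: Optional[int] = None  # 1, 2 or 3 within the codon
    codon_a: Optional[str] = None
    codon_b: Optional[str] = None
    aa_a: Optional[str] = None
    aa_b: Optional[str] = None
    effect: Optional[str] = None  # "synonymous" | "nonsynonymous" | structural note


@dataclass
class DuplicatePair:
    """A gene present on two chromosomes, with its cross-copy divergence."""

    gene_name: str
    chromosome_a: str
    chromosome_b: str
    span_nt: int
    identity_percent: float
    substitutions: list[SubstitutionRecord] = field(default_factory=list)


def find_duplicates(annotations: Sequence[GenomeAnnotation]) -> list[str]:
    """Gene names annotated on at least two chromosomes, sorted.

    NCR features are ignored. Genes repeated *within* one chromosome do not
    qualify by themselves (see ``find_within_chromosome_duplicates``).
    """
    chroms_by_name: dict[str, set[str]] = {}
    for a in annotations:
        for f in a.features:
            if f.gene_class.value == "NCR":
                continue
            chroms_by_name.setdefault(f.gene_name, set()).add(a.chromosome.id)
    return sorted(n for n, c in chroms_by_name.items() if len(c) >= 2)


def duplicate_multiplicity(annotations: Sequence[GenomeAnnotation]) -> dict[str, int]:
    """Total copy count across chromosomes for each cross-chromosome duplicate."""
    dups = set(find_duplicates(annotations))
    counts: dict[str, int] = {}
    for a in annotations:
        for f in a.features:
            if f.gene_name in dups:
                counts[f.gene_name] = counts.get(f.gene_name, 0) + 1
    return counts


def find_within_chromosome_duplicates(annotations: Sequence[GenomeAnnotation]) -> dict[str, list[str]]:
    """Genes with multiple copies on a single chromosome, keyed by chromosome id."""
    out: dict[str, list[str]] = {}
    for a in annotations:
        seen: dict[str, int] = {}
        for f in a.features:
            seen[f.gene_name] = seen.get(f.gene_name, 0) + 1
        dups = sorted(n for n, c in seen.items() if c > 1)
        if dups:
            out[a.chromosome.id] = dups
    return out


def duplicated_span(annotations: Sequence[GenomeAnnotation], gene_names: Sequence[str]) -> int:
    """Total nucleotides of the duplicated block, counting one copy per gene.

    Each named gene must be present on at least two chromosomes with equal
    annotated length (the ungapped-comparison precondition); unequal copy
    lengths raise ``ValueError``.
    """
    total = 0
    for name in gene_names:
        lengths = [
            feature_length(f)
            for a in annotations
            for f in a.features
            if f.gene_name == name
        ]
        if len(lengths) < 2:
            raise ValueError(f"gene {name!r} is not duplicated across the annotations")
        if len(set(lengths)) != 1:
            raise ValueError(
                f"gene {name!r}: copies have unequal lengths {lengths}; gapped comparison unsupported"
            )
        total += lengths[0]
    return total


def classify_coding_substitution(
    codon_a: str, codon_b: str, table_id: int = 5
) -> tuple[str, str, str]:
    """Translate two codons and classify the change as synonymous or nonsynonymous.

    Returns three-letter amino acids (``Ter`` for a stop). The default genetic
    code is table 5 (invertebrate mitochondrial).
    """
    code = translation_table(table_id)
    aas = []
    for codon in (codon_a.upper(), codon_b.upper()):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid codon {codon!r}: must be 3 unambiguous bases")
        aas.append("*" if codon in code.stop_codons else code.forward_table[codon])
    effect = "synonymous" if aas[0] == aas[1] else "nonsynonymous"
    name = lambda aa: "Ter" if aa == "*" else seq3(aa)
    return name(aas[0]), name(aas[1]), effect


def compare_copies(
    seq_a: str,
    seq_b: str,
    frame: str = "coding",
    table_id: int = 5,
    gene_name: str = "",
    chromosome_a: str = "a",
    chromosome_b: str = "b",
) -> DuplicatePair:
    """Ungapped positional comparison of two equal-length gene copies.

    ``frame="coding"`` expands each mismatch with codon context and a
    synonymous/nonsynonymous call; ``frame="trna"`` (or any non-coding frame)
    records the bare base change. Identity is ``100 x matches / length``,
    rounded half-up to one decimal.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal copy lengths {len(seq_a)} != {len(seq_b)}")
    if not seq_a:
        raise ValueError("empty sequences")
    if frame == "coding" and len(seq_a) < 3:
        raise ValueError("coding-frame comparison requires length >= 3")
    subs: list[SubstitutionRecord] = []
    for i, (x, y) in enumerate(zip(seq_a, seq_b)):
        if x == y:
            continue
        pos = i + 1
        if frame == "coding" and i + 3 - i % 3 <= len(seq_a):
            ci = i // 3
            codon_a = seq_a[3 * ci : 3 * ci + 3]
            codon_b = seq_b[3 * ci : 3 * ci + 3]
            aa_a, aa_b, effect = classify_coding_substitution(codon_a, codon_b, table_id)
            subs.append(
                SubstitutionRecord(
                    position=pos,
                    base_a=x,
                    base_b=y,
                    codon_index=ci + 1,
                    codon_position=i % 3 + 1,
                    codon_a=codon_a,
                    codon_b=codon_b,
                    aa_a=aa_a,
                    aa_b=aa_b,
                    effect=effect,
                )
            )
        else:
            subs.append(SubstitutionRecord(position=pos, base_a=x, base_b=y))
    matches = len(seq_a) - len(subs)
    identity = round_half_up(100.0 * matches / len(seq_a))
    return DuplicatePair(
        gene_name=gene_name,
        chromosome_a=chromosome_a,
        chromosome_b=chromosome_b,
        span_nt=len(seq_a),
        identity_percent=identity,
        substitutions=subs,
    )


def _pair_table(structure: str) -> dict[int, int]:
    """0-based partner index per paired position from a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: unmatched ')' at {i + 1}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at {i + 1}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unmatched '(' at {stack[-1] + 1}")
    return pairs


@dataclass(frozen=True)
class StructureImpact:
    """Structural consequence of one substitution in a structured RNA."""

    position: int  # 1-based
    context: str  # "paired" | "loop"
    pairing_preserved: bool
    partner_position: Optional[int] = None


def trna_structure_impact(seq_a: str, seq_b: str, structure: str) -> list[StructureImpact]:
    """Assess each substitution between two tRNA copies against a secondary structure.

    The structure (dot-bracket, same length as the sequences) is taken as that
    of copy A. A substitution in a loop always preserves structure; at a
    paired position, pairing is preserved iff the new base still forms a
    Watson-Crick or G·U pair with copy A's partner base.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("unequal sequence lengths")
    if len(structure) != len(seq_a):
        raise ValueError("structure length does not match sequence length")
    pairs = _pair_table(structure)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    out: list[StructureImpact] = []
    for i, (x, y) in enumerate(zip(seq_a, seq_b)):
        if x == y:
            continue
        if i in pairs:
            j = pairs[i]
            partner = seq_b[j] if seq_b[j] != seq_a[j] else seq_a[j]
            preserved = (y + partner) in PRESERVED_PAIRS
            out.append(
                StructureImpact(
                    position=i + 1, context="paired", pairing_preserved=preserved, partner_position=j + 1
                )
            )
        else:
            out.append(StructureImpact(position=i + 1, context="loop", pairing_preserved=True))
    return out


def analyse_duplicates(
    annotations: Sequence[GenomeAnnotation], table_id: int = 5
) -> list[DuplicatePair]:
    """Full duplicate analysis over annotated chromosomes with sequences.

    For every gene on >= 2 chromosomes, extracts both copies and runs
    :func:`compare_copies` in the frame appropriate to the gene class.
    """
    from mitobipart.genome_model import GeneClass, feature_sequence

    pairs: list[DuplicatePair] = []
    for name in find_duplicates(annotations):
        copies = [
            (a, f)
            for a in annotations
            for f in a.features
            if f.gene_name == name
        ]
        (ann_a, f_a), (ann_b, f_b) = copies[0], copies[1]
        frame = "coding" if f_a.gene_class == GeneClass.PCG else "trna"
        pair = compare_copies(
            feature_sequence(ann_a.chromosome, f_a),
            feature_sequence(ann_b.chromosome, f_b),
            frame=frame,
            table_id=table_id,
            gene_name=name,
            chromosome_a=ann_a.chromosome.id,
            chromosome_b=ann_b.chromosome.id,
        )
        pairs.append(pair)
    return pairs
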