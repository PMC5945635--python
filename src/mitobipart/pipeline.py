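"""One-shot analysis pipeline: validate -> stats -> inventory -> codon usage ->
duplicates -> gene order -> assembly, aggregated into a JSON-serialisable report.

Stages that lack their inputs (no sequences, no fragments) are marked
``skipped``, not failed. Reports are deterministic: all randomness is seeded
and recorded in the provenance block, and re-running on identical inputs and
configuration yields byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from mitobipart import __version__
from mitobipart.annotation_stats import (
    detect_ncrs,
    gene_inventory,
    infer_codons,
    intergenic_spacings,
    length_conservation,
    trna_size_range,
)
from mitobipart.codon_usage import at_content, count_codons, rich_fraction, top_codons
from mitobipart.duplication_analysis import analyse_duplicates, duplicated_span, find_duplicates
from mitobipart.fragment_assembly import FragmentSet, assemble_circle, overlap_report
from mitobipart.gene_order import (
    GeneOrder,
    cluster_summary,
    order_from_annotation,
    shared_clusters,
)
from mitobipart.genome_model import (
    GeneClass,
    GenomeAnnotation,
    feature_sequence,
    validate_annotation,
)

DEFAULT_CONFIG = {
    "ncr_min_len": 200,
    "min_overlap": 50,
    "max_mismatch": 0,
    "allow_reversal": False,
    "strict_validation": True,
    "exclude_stop_codons": False,
    "table_id": 5,
}


class ValidationAbort(RuntimeError):
    """Raised when validation violations exceed the configured severity."""


@dataclass
class AnalysisReport:
    """Aggregated results of every pipeline stage, JSON round-trippable."""

    stats: dict = field(default_factory=dict)
    inventory: dict = field(default_factory=dict)
    codon_usage: dict = field(default_factory=dict)
    duplicates: dict = field(default_factory=dict)
    gene_order: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def run_full_report(
    annotations: Sequence[GenomeAnnotation],
    orders: Optional[dict[str, GeneOrder]] = None,
    fragment_sets: Optional[dict[str, FragmentSet]] = None,
    config: Optional[dict] = None,
    seed: int = 0,
) -> AnalysisReport:
    """Run every applicable stage over the annotated chromosomes.

    Parameters
    ----------
    annotations
        One annotation per chromosome; sequences optional (sequence-dependent
        stages are skipped without them).
    orders
        Additional gene orders (other taxa) to compare chromosome-by-chromosome.
    fragment_sets
        Amplicon fragment sets keyed by chromosome id, assembled and checked
        for circular closure.
    """
    if not annotations:
        raise ValueError("at least one annotated chromosome is required")
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    report = AnalysisReport()
    report.provenance = {
        "tool": "mitobipart",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "chromosomes": [a.chromosome.id for a in annotations],
    }

    # validation gate
    for a in annotations:
        violations = validate_annotation(a)
        fatal = [v for v in violations if v.rule in ("within_chromosome", "duplicate_row")]
        report.validation[a.chromosome.id] = [asdict(v) for v in violations]
        if cfg["strict_validation"] and fatal:
            raise ValidationAbort(
                f"{a.chromosome.id}: rule {fatal[0].rule!r} violated: {fatal[0].detail}"
            )

    # per-chromosome structural stats
    for a in annotations:
        spacings = intergenic_spacings(a)
        implied, declared = length_conservation(a)
        ncrs = detect_ncrs(a, min_len=cfg["ncr_min_len"])
        block = {
            "length": a.chromosome.length,
            "n_features": len(a.features),
            "spacings": [asdict(s) for s in spacings],
            "conservation": {"implied_length": implied, "declared_length": declared},
            "ncrs": [
                {"name": n.gene_name, "start": n.start, "end": n.end, "length": n.length}
                for n in ncrs
            ],
        }
        if a.chromosome.sequence is not None:
            calls = []
            for f in a.by_class(GeneClass.PCG):
                call = infer_codons(a.chromosome, f)
                calls.append(asdict(call))
            block["codon_calls"] = calls
            block["ncr_at_content"] = {
                n.gene_name: at_content(feature_sequence(a.chromosome, n)) for n in ncrs
            }
        report.stats[a.chromosome.id] = block

    # inventory
    inv = gene_inventory(annotations)
    report.inventory = {
        "per_chromosome": {
            cid: {c.value: n for c, n in counts.items()}
            for cid, counts in inv.per_chromosome.items()
        },
        "distinct": {c.value: n for c, n in inv.distinct.items()},
        "duplicated_across": inv.duplicated_across,
        "duplicated_within": inv.duplicated_within,
        "missing_canonical": inv.missing_canonical,
    }
    try:
        mn, mx, mn_gene, mx_gene = trna_size_range(annotations)
        report.inventory["trna_size_range"] = {
            "min": mn, "max": mx, "min_gene": mn_gene, "max_gene": mx_gene,
        }
    except ValueError:
        report.inventory["trna_size_range"] = None

    # codon usage (needs sequences)
    for a in annotations:
        if a.chromosome.sequence is None:
            report.codon_usage[a.chromosome.id] = {"skipped": "no sequence"}
            continue
        genes = [
            (f.gene_name, feature_sequence(a.chromosome, f))
            for f in a.by_class(GeneClass.PCG)
        ]
        table = count_codons(
            genes,
            group=a.chromosome.id,
            exclude_stop_codons=cfg["exclude_stop_codons"],
            table_id=cfg["table_id"],
        )
        report.codon_usage[a.chromosome.id] = {
            "total_codons": table.total,
            "top3": top_codons(table, 3),
            "t_rich_percent": rich_fraction(table, "T", 2),
            "c_rich_percent": rich_fraction(table, "C", 2),
        }

    # duplicates
    dup_names = find_duplicates(annotations)
    report.duplicates = {"genes": dup_names}
    if dup_names:
        report.duplicates["span_nt"] = duplicated_span(annotations, dup_names)
        if all(a.chromosome.sequence is not None for a in annotations):
            pairs = analyse_duplicates(annotations, table_id=cfg["table_id"])
            report.duplicates["pairs"] = [
                {
                    "gene": p.gene_name,
                    "identity_percent": p.identity_percent,
                    "n_substitutions": len(p.substitutions),
                    "substitutions": [asdict(s) for s in p.substitutions],
                }
                for p in pairs
            ]
        else:
            report.duplicates["pairs"] = {"skipped": "no sequences"}

    # gene order
    chrom_orders = {a.chromosome.id: order_from_annotation(a) for a in annotations}
    report.gene_order = {"orders": {cid: o.genes for cid, o in chrom_orders.items()}}
    comparisons = {}
    ids = list(chrom_orders)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cl = shared_clusters(
                chrom_orders[ids[i]], chrom_orders[ids[j]], allow_reversal=cfg["allow_reversal"]
            )
            comparisons[f"{ids[i]}|{ids[j]}"] = {
                "clusters": [asdict(c) for c in cl],
                "summary": cluster_summary(cl),
            }
    for label, other in (orders or {}).items():
        for cid, mine in chrom_orders.items():
            cl = shared_clusters(mine, other, allow_reversal=cfg["allow_reversal"])
            comparisons[f"{cid}|{label}"] = {
                "clusters": [asdict(c) for c in cl],
                "summary": cluster_summary(cl),
            }
    report.gene_order["comparisons"] = comparisons

    # assembly
    for cid, fs in (fragment_sets or {}).items():
        layout = assemble_circle(
            fs, min_overlap=cfg["min_overlap"], max_mismatch=cfg["max_mismatch"]
        )
        report.assembly[cid] = {
            "closed": layout.closed,
            "order": layout.order,
            "consensus_length": layout.consensus_length,
            "overlap_report": overlap_report(layout),
        }
    if not fragment_sets:
        report.assembly = {"skipped": "no fragments"}

    return report


def render_table1(a: GenomeAnnotation) -> str:
    """Render an annotation in the layout of a genome-organization table.

    Columns: gene, positions, number of nucleotides, initiation/termination
    codons, intergenic spacer (printed after its gene; the last row carries
    the wrap-around spacer).
    """
    lines = ["gene\tpositions\tnt\tcodons\tintergenic"]
    if not a.features:
        return lines[0] + "\n"
    spacings = intergenic_spacings(a)
    spacing_after = {i: s.spacing for i, s in enumerate(spacings)}
    for i, f in enumerate(a.features):
        codons = ""
        if f.gene_class == GeneClass.PCG and (f.start_codon or f.stop_codon):
            codons = f"{f.start_codon or '?'}/{f.stop_codon or '?'}"
        spacing = spacing_after.get(i, "")
        lines.append(
            f"{f.gene_name}\t{f.start}–{f.end}\t{f.length}\t{codons}\t{spacing}"
        )
    return "\n".join(lines) + "\n"
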