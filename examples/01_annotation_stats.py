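"""Annotation arithmetic on the published two-chromosome gene tables.

Parses the transcribed coordinate tables of the bipartite *Ruizia karukerae*
mitogenome and reproduces the structural bookkeeping: intergenic spacers,
circular closure, non-coding-region detection and the genome-wide inventory.
"""

from mitobipart.annotation_stats import (
    closure_length,
    detect_ncrs,
    gene_inventory,
    intergenic_spacings,
    trna_size_range,
)
from mitobipart.genome_model import GeneClass
from mitobipart.reference import load_reference_annotations

chr1, chr2 = load_reference_annotations()

for ann, wrap in ((chr1, 13), (chr2, 12)):
    spacings = intergenic_spacings(ann)
    overlaps = [s for s in spacings if s.spacing < 0]
    print(f"{ann.chromosome.id}: {len(ann.features)} features, "
          f"closure {closure_length(ann, wrap)} nt "
          f"({len(overlaps)} overlapping junctions, "
          f"largest spacer {max(s.spacing for s in spacings)} nt)")
    for ncr in detect_ncrs(ann, min_len=200):
        print(f"  non-coding region {ncr.start}-{ncr.end} ({ncr.length} nt)")

inv = gene_inventory([chr1, chr2])
mn, mx, mn_gene, mx_gene = trna_size_range([chr1, chr2])
print(f"distinct genes: {inv.distinct[GeneClass.PCG]} PCGs, "
      f"{inv.distinct[GeneClass.TRNA]} tRNAs, {inv.distinct[GeneClass.RRNA]} rRNAs; "
      f"missing canonical: {inv.missing_canonical}")
print(f"duplicated on both chromosomes: {inv.duplicated_across}")
print(f"tRNA sizes: {mn} nt ({mn_gene}) to {mx} nt ({mx_gene})")

# The closure lengths are the chromosome sizes implied by the last feature
# plus the wrap-around spacer; they must (and do) equal the declared lengths.
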