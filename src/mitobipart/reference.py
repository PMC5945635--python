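"""Published reference data for the *Ruizia karukerae* bipartite mitogenome.

Transcriptions of the printed genome-organization table (gene coordinates,
spans, start/stop codons and intergenic spacers for both circular
chromosomes) and the printed amplicon-overlap confirmation lengths. These are
the study's published inputs; sequences themselves live in GenBank under
accessions MF509850 (chromosome I) and MF509851 (chromosome II) and are not
bundled.

The ``intergenic`` column holds the spacer printed *after* each feature
(negative = overlap with the next feature); the final row's value is the
wrap-around spacer back to the first feature of the circle.
"""

CHROMOSOME_I_LENGTH = 7659
CHROMOSOME_II_LENGTH = 7647

TABLE1_CHROMOSOME_I = """\
# R. karukerae mitochondrial chromosome I (7,659 nt, circular)
gene\tstart\tend\tlength\tclass\tstart_codon\tstop_codon\tintergenic
cox1\t1\t1536\t1536\tPCG\tATT\tTAA\t-2
trnC\t1535\t1590\t56\ttRNA\t\t\t2
trnE\t1593\t1648\t56\ttRNA\t\t\t0
rrnS\t1649\t2338\t690\trRNA\t\t\t0
trnS2\t2339\t2393\t55\ttRNA\t\t\t12
trnD\t2406\t2461\t56\ttRNA\t\t\t106
trnG\t2568\t2623\t56\ttRNA\t\t\t-1
cox2\t2623\t3312\t690\tPCG\tATA\tTAA\t-1
trnH\t3312\t3365\t54\ttRNA\t\t\t0
rrnL\t3366\t4306\t941\trRNA\t\t\t0
nad3\t4307\t4642\t336\tPCG\tATT\tTAA\t-1
nad5\t4642\t6223\t1582\tPCG\tATA\tT\t0
trnA\t6224\t6278\t55\ttRNA\t\t\t19
nad6\t6298\t6771\t474\tPCG\tATA\tTAA\t29
trnS1\t6801\t6865\t65\ttRNA\t\t\t0
NCR1\t6866\t7336\t471\tNCR\t\t\t0
nad4l\t7337\t7588\t252\tPCG\tATT\tTAA\t5
trnW\t7594\t7646\t53\ttRNA\t\t\t13
"""

TABLE1_CHROMOSOME_II = """\
# R. karukerae mitochondrial chromosome II (7,647 nt, circular)
gene\tstart\tend\tlength\tclass\tstart_codon\tstop_codon\tintergenic
nad1\t1\t861\t861\tPCG\tATT\tTAA\t2
atp6\t864\t1442\t579\tPCG\tATG\tTAG\t1
trnK\t1444\t1504\t61\ttRNA\t\t\t0
trnL2\t1505\t1559\t55\ttRNA\t\t\t1
nad2\t1561\t2449\t889\tPCG\tATA\tT\t0
trnI\t2450\t2509\t60\ttRNA\t\t\t0
trnR\t2510\t2563\t54\ttRNA\t\t\t-1
trnQ\t2563\t2617\t55\ttRNA\t\t\t-1
trnF\t2617\t2670\t54\ttRNA\t\t\t1
cob\t2672\t3760\t1089\tPCG\tATG\tTAG\t0
trnL1\t3761\t3815\t55\ttRNA\t\t\t-3
cox3\t3813\t4560\t748\tPCG\tATA\tT\t0
trnT\t4561\t4617\t57\ttRNA\t\t\t0
nad4\t4618\t5844\t1227\tPCG\tATA\tTAA\t-2
trnM\t5843\t5901\t59\ttRNA\t\t\t-1
trnD\t5901\t5956\t56\ttRNA\t\t\t106
trnG\t6063\t6118\t56\ttRNA\t\t\t-1
cox2\t6118\t6807\t690\tPCG\tATA\tTAA\t-1
trnH\t6807\t6860\t54\ttRNA\t\t\t57
trnV\t6918\t6987\t70\ttRNA\t\t\t0
NCR2\t6988\t7476\t489\tNCR\t\t\t0
trnP\t7477\t7529\t53\ttRNA\t\t\t-1
trnN\t7529\t7583\t55\ttRNA\t\t\t-2
trnY\t7582\t7635\t54\ttRNA\t\t\t12
"""

#: Printed sizes (bp) of the overlapping regions between partial-gene
#: amplicons and the ends of the long PCR fragments, both chromosomes
#: (8 confirmations on chromosome I, 6 on chromosome II).
OVERLAP_LENGTHS_BP = [395, 237, 122, 266, 307, 345, 309, 348, 146, 163, 163, 232, 398, 224]

#: Genes annotated on both chromosomes.
DUPLICATED_GENES = ["cox2", "trnD", "trnG", "trnH"]


def load_reference_annotations():
    """Parse both transcribed chromosome tables into ``GenomeAnnotation`` objects."""
    from mitobipart.genome_model import parse_gene_table

    chr1 = parse_gene_table(
        TABLE1_CHROMOSOME_I, chromosome_length=CHROMOSOME_I_LENGTH, chromosome_id="chromosome_I"
    )
    chr2 = parse_gene_table(
        TABLE1_CHROMOSOME_II, chromosome_length=CHROMOSOME_II_LENGTH, chromosome_id="chromosome_II"
    )
    return chr1, chr2


def reference_intergenic_column(table_text: str) -> dict[tuple[str, int], int]:
    """Printed intergenic spacers keyed by (gene name, start) in table order."""
    out = {}
    for line in table_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("gene\t"):
            continue
        parts = line.split("\t")
        out[(parts[0], int(parts[1]))] = int(parts[7])
    return out
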