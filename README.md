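# mitobipart

Structural analysis of **multipartite circular mitochondrial genomes** —
mitogenomes split across two or more small circles instead of the canonical
single 14–20 kb chromosome, as found in a handful of nematodes, rotifers and
lice. The package grew out of the analyses used to establish the bipartite
mitogenome of the millipede-parasitic nematode *Ruizia karukerae* (two
circles of 7,659 and 7,647 nt sharing a duplicated `cox2 + trnD/trnG/trnH`
block; GenBank MF509850/MF509851) and turns them into a tested, reusable
pipeline for anyone annotating or verifying an unusual mitochondrial genome
architecture.

It is a library first: the importable API plus the narrative scripts in
`examples/` are the main interface, and a thin `mitobipart` CLI wraps the
same functions for shell use.

## What it computes

Coordinates are 1-based inclusive throughout, matching published annotation
tables (a gene at 1–1536 spans 1,536 nt).

- **Annotation arithmetic** (`annotation_stats`) — intergenic spacers
  (`start(next) − end(current) − 1`; negative = overlap), circular closure
  (last feature end + wrap-around spacer must equal the chromosome length),
  detection of non-coding regions as inter-gene gaps ≥ 200 nt, gene-class
  inventories across chromosomes, and start/stop codon inference including
  the incomplete terminators `T`/`TA` completed by polyadenylation.
- **Codon-usage bias** (`codon_usage`) — codon counts over coding genes,
  top-k codons, A+T content, and the T-rich (≥ 2 T per triplet) / C-rich
  (≥ 2 C) fractions used to describe nematode mtDNA composition bias.
- **Duplicated-gene divergence** (`duplication_analysis`) — genes annotated
  on ≥ 2 chromosomes, ungapped cross-copy identity
  (`100 × matches / length`), per-site substitution records classified
  synonymous/nonsynonymous under the invertebrate mitochondrial code (NCBI
  table 5: ATA=Met, TGA=Trp, AGA/AGG=Ser), and stem/loop impact of tRNA
  substitutions against dot-bracket structures (G·U wobble preserved).
- **Gene-order clusters** (`gene_order`) — circular gene orders linearized
  from annotations and strictly maximal shared clusters (conserved adjacency
  blocks ≥ 2 genes) between chromosomes or taxa, with alias normalization
  for one-letter tRNA labels and common gene-name synonyms.
- **Assembly verification** (`fragment_assembly`) — suffix–prefix overlap
  detection, Hamiltonian-cycle layout search, and the closure arithmetic
  (consensus = Σ fragments − Σ junction overlaps) that certifies a circular
  molecule from overlapping long-PCR amplicons.
- **Synthetic genomes** (`synthetic_data`) — a generator emitting bipartite
  genomes with the reference layout (T-biased composition, negative spacers,
  one long NCR per circle, a duplicated block with exactly *k* planted
  substitutions) plus amplicon sets, with full ground truth for testing
  every stage.
- **Pipeline** (`pipeline`) — all stages in one deterministic,
  JSON-round-trippable report.

## Worked example

```python
from mitobipart.reference import load_reference_annotations
from mitobipart.annotation_stats import closure_length, detect_ncrs, gene_inventory
from mitobipart.gene_order import order_from_annotation, shared_clusters
from mitobipart.genome_model import GeneClass

chr1, chr2 = load_reference_annotations()   # transcribed published tables
print(closure_length(chr1, 13), closure_length(chr2, 12))
print([ (n.start, n.end, n.length) for n in detect_ncrs(chr1) ])
inv = gene_inventory([chr1, chr2])
print(inv.distinct[GeneClass.PCG], inv.duplicated_across)
(cluster,) = shared_clusters(order_from_annotation(chr1), order_from_annotation(chr2))
print("-".join(cluster.genes))
```

prints

```
7659 7647
[(6866, 7336, 471)]
12 ['cox2', 'trnD', 'trnG', 'trnH']
trnD-trnG-cox2-trnH
```

— the two circular chromosome lengths implied by closing each circle, the
471-nt non-coding region on chromosome I, the 12 distinct protein-coding
genes with the four genes duplicated on both circles, and the one gene-order
cluster the chromosomes share (exactly the duplicated block). Running
`python examples/03_duplicated_genes.py` additionally shows a planted
nonsynonymous substitution recovered at 99.9% cross-copy identity and the
TAT→TCT (Tyr→Ser) classification under the invertebrate mitochondrial code;
the other `examples/` scripts cover codon bias, assembly closure and the
full synthetic round trip.

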