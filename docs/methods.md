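# Methods

## Scope and data model

The package analyses annotated circular mitochondrial chromosomes. It does
not predict genes or fold tRNAs: annotations (coordinate tables, GenBank
features) and secondary structures (dot-bracket strings) are inputs, and the
package's job is the arithmetic, comparison and verification built on top of
them. Coordinates are 1-based and fully inclusive, the convention of
published mitogenome organization tables; features are stored unwrapped
(`start ≤ end`) because published tables place the origin between features,
and only subsequence extraction supports wrap-around. The origin of each
circle is treated as arbitrary; chromosomes can be rotated, and circular
consensus sequences compare equal up to rotation.

Ambiguity codes other than N are rejected at parse time: the codon-level
logic downstream (stop detection, substitution classification) is defined
over unambiguous bases only.

## Annotation arithmetic

**Intergenic spacing** is `start(next) − end(current) − 1`, so abutting
genes score 0 and a shared base scores −1. This is the only convention
consistent with every spacer cell of the reference tables (e.g. a gene
starting on its upstream neighbour's final base prints −1). The spacer
after the last feature wraps the origin: `start(first) + L − end(last) − 1`.
On a circular chromosome with *n* features there are exactly *n* spacers,
and Σ feature lengths + Σ spacers = chromosome length exactly — the
conservation identity used as a validation gate.

**Non-coding regions** are inter-gene gaps ≥ `min_len` (default 200 nt).
The default separates the two regimes seen in compact nematode mtDNA:
spacers up to ~100 nt are ordinary intergenic sequence, while the one long
gap per chromosome (hundreds of nt, presumed to contain control elements)
is the NCR. Detection ignores NCR-class rows already present in the input,
so it behaves identically whether or not a table lists its NCRs; NCRs are
numbered NCR1, NCR2… in coordinate order, genome-wide sequential by
default. A gap spanning the listed origin is not reported — rotate the
chromosome to expose it. Detection is monotone in the threshold: raising
`min_len` never adds a region.

**Codon calls.** The start codon is the first triplet, validated against a
configurable allowed set (default {ATT, ATA, ATG}, the set observed in
chromadorean nematodes; GTG/TTG can be admitted for other taxa). The stop
is read from the span modulo 3: a full trailing triplet (span ≡ 0), an
incomplete `TA` (≡ 2) or `T` (≡ 1), the latter two completed to TAA by
post-transcriptional polyadenylation. Trailing bases inconsistent with that
convention are an error, not a silent call. An optional scan flags internal
in-frame stops.

## Codon usage

Only complete triplets are counted; a trailing 1–2 nt incomplete terminator
is excluded because a partial triplet has no defensible codon assignment
(a flag restores the literal tail for sensitivity analyses). Codons
containing N are tallied separately, not counted. Complete stop codons are
counted by default, with a flag to exclude them. "T-rich" means ≥ 2 T per
triplet and "C-rich" ≥ 2 C; the copy-number threshold is a parameter, so a
strict > 2 reading is also computable. Percentages round half-up to one
decimal, the precision such tables are printed at (Python's built-in
banker's rounding would turn 99.855 into 99.8 rather than the conventional
99.9).

## Duplicated genes

Cross-chromosome duplicates are genes annotated on ≥ 2 chromosomes;
within-chromosome repeats are reported separately. Copy comparison is
ungapped and positional — duplicated copies in the genomes this targets
carry equal annotated spans, and a banded-alignment fallback is out of
scope (unequal spans raise). Identity is `100 × matches / length`, half-up
to one decimal. Coding substitutions carry codon context and a
synonymous/nonsynonymous call under NCBI translation table 5 (invertebrate
mitochondrial; configurable by table id). The genetic-code data comes from
Biopython's table registry; the classification itself is checked in the
test suite against an exhaustive 64×64 oracle built directly from that
registry.

tRNA substitutions are assessed against a dot-bracket structure taken as
copy A's fold: loop substitutions always preserve structure; at a paired
position the new base must still form a Watson–Crick or G·U pair with the
partner base (G·U wobble counts as preserved — standard tRNA stem
chemistry).

## Gene-order clusters

Gene orders are signed circular (or linear) label sequences; names pass
through an editable alias table (one-letter tRNA figure labels, COI-style
synonyms; L1/L2 and S1/S2 kept distinct) because mismatched naming is the
dominant practical failure mode of cross-paper comparisons. Shared clusters
are runs of ≥ 2 genes contiguous and identically ordered in both inputs,
honouring each order's circularity.

Maximality is strict and global: a reported block is not a contiguous
substring of any longer reported block, and identical blocks found at
several seeds are reported once. (Overlapping sub-blocks of a longer
cluster are thus never listed separately; with repeated labels this is a
genuine design choice, and the one this package makes.) Degenerate periodic
cases — an order compared against a rotation of itself, repeated-label
periodic orders — are detected as fully matching circular diagonals and
reported as a single full-length cluster. Reversal matching (the block
reversed with flipped strands) is available behind a flag, default off,
since the target genomes encode all genes on one strand. The implementation
is tested for equivalence against a brute-force enumerate-all-rotations
oracle on randomized orders.

## Fragment assembly

Overlaps are exact-or-near suffix–prefix matches (exact matching uses a
KMP border computation; with mismatches allowed, a vectorized scan from the
longest candidate down). Defaults are `min_overlap=50`, `max_mismatch=0`:
amplicon-confirmation overlaps in this setting are ≥ 100 nt and were
checked for identity, so exact matching is the honest default and both
knobs are configurable. Fragments are first co-oriented greedily (flipping
any fragment whose reverse complement raises total overlap), since Sanger
reads arrive in both orientations.

The circular layout is a Hamiltonian cycle in the overlap digraph —
exhaustive search (first fragment fixed, total overlap maximised) for
≤ 12 fragments, which covers any realistic amplicon design; greedy
longest-overlap-first beyond, with ties broken by fragment id. The
consensus drops each junction overlap once, keeping the upstream fragment's
base at mismatching overlap columns (a deterministic tie-break between two
sequences). `consensus length = Σ fragment lengths − Σ junction overlaps`
holds exactly for mismatch-free inputs. When no cycle exists the best open
path is reported with `closed=false`. Canonical output rotation is the
lexicographically least (Booth's algorithm).

## Synthetic genomes

The generator's defaults are the study conditions of the reference genome:
two circles of 7,659 and 7,647 nt with the published feature layout
(17 + 23 genes, one NCR of 471/489 nt, spacers from −3 to 106 nt), a
duplicated block `cox2, trnD, trnG, trnH` copied verbatim between circles,
and nucleotide weights T 0.40 / A 0.31 / G 0.17 / C 0.12 — chosen once to
give the strong T bias and ~70% A+T typical of chromadorean nematode
mtDNA. Coding genes get a valid start codon, stop-free middle codons
(sampled from the weighted nucleotide model with rejection of TAA/TAG),
and a complete or incomplete stop matching the span modulo 3; features
overlapping a coding gene inherit its fixed bases. tRNA/rRNA/NCR tracts and
spacers are i.i.d. under the composition weights.

Exactly *k* substitutions are planted into the second chromosome's block
copy at uniformly chosen positions, honouring an optional
synonymous/nonsynonymous constraint, never falling in a coding gene's first
or last codon and never creating an in-frame stop (both copies are assumed
functional). Unsatisfiable constraints fail after bounded retries rather
than degrading silently. Amplicon simulation tiles a circle with *n*
fragments whose junction overlaps are drawn uniformly from a configurable
range; cut spacing is checked against the maximum overlap so each planted
junction is the unique qualifying overlap. Everything is deterministic per
seed.

What the generator does **not** emulate: real codon-frequency profiles
(composition is i.i.d. nucleotide-level, so absolute codon percentages
differ from any real genome even though rank structure and bias direction
match), structure-aware tRNA/rRNA sequence, sequencing error, and
evolutionary divergence over time (single-snapshot only). Passing
round-trip tests therefore demonstrates correctness of the arithmetic and
the recovery logic under the stated structural conditions, not performance
on noisy real reads.

## Problem sizes and determinism

Tests and the acceptance script run at the reference scale: ~7.6 kb
circles, 4–7 amplicons, up to 20 generation seeds and 10 full round-trip
trials — sizes at which the exhaustive layout search and brute-force test
oracles are exact. All randomness flows from explicit seeds; reports and
generated genomes are byte-identical across reruns with the same inputs.

## Known limitations

- No gapped comparison of duplicated copies, no dN/dS, and no inference of
  duplication mechanism.
- No rearrangement distances (breakpoint/DCJ) or ancestral gene-order
  reconstruction; cluster detection only.
- NCR detection cannot report a gap spanning the listed origin.
- The maximal shared non-genic region between chromosomes (beyond annotated
  genes) is not delimited; duplicate analysis is annotation-driven.
- Verifying published full-sequence statistics (codon percentages, NCR A+T
  content of the deposited chromosomes) requires fetching the GenBank
  records; the package computes these statistics from any provided
  FASTA/GenBank input but ships no sequence data.
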