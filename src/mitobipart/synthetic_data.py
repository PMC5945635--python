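"""Synthetic bipartite mitogenome generator with planted ground truth.

Emulates the structure of a two-chromosome nematode mitochondrial genome:
two circles of ~7.6 kb, a duplicated block (one protein-coding gene plus
three tRNA genes) shared between the chromosomes with a configurable number
of planted substitutions, T-biased nucleotide composition, short or negative
intergenic spacers, one long non-coding region per chromosome, and
overlapping amplicon fragments tiling each circle. Every generated genome
carries a :class:`TruthRecord` so each analysis stage can be checked against
planted truth.

Protein-coding genes receive a valid start codon, no internal in-frame stop
under the invertebrate mitochondrial code, and a complete or incomplete stop
consistent with the gene span modulo 3. Coding sequence is sampled codon by
codon from a weighted nucleotide model with rejection of stop triplets —
simpler than a per-codon frequency model and enough to reproduce the T-rich
codon bias qualitatively. tRNA/rRNA/NCR tracts and spacers are i.i.d. under
the same composition weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from mitobipart.annotation_stats import intergenic_spacings
from mitobipart.codon_usage import translation_table
from mitobipart.genome_model import (
    CircularChromosome,
    FeatureAnnotation,
    GeneClass,
    GenomeAnnotation,
    extract_subsequence,
)

#: default composition: strongly T-biased, as in chromadorean nematode mtDNA
DEFAULT_WEIGHTS = {"T": 0.40, "A": 0.31, "G": 0.17, "C": 0.12}

_STOPS = ("TAA", "TAG")  # table 5 termination codons
_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Raised when a spec's constraints cannot be satisfied."""


@dataclass(frozen=True)
class FeaturePlan:
    """Planned feature: name, class, span and (for PCGs) codon policy."""

    name: str
    gene_class: GeneClass
    length: int
    start_codon: Optional[str] = None  # PCGs; default ATT
    stop_codon: Optional[str] = None  # "TAA"|"TAG"|"TA"|"T"; default fits span % 3


@dataclass
class ChromosomePlan:
    """Feature layout of one circular chromosome.

    ``spacings[i]`` is the spacer after feature ``i`` (negative = overlap);
    the last entry is the wrap-around spacer closing the circle.
    """

    id: str
    features: list[FeaturePlan]
    spacings: list[int]

    def __post_init__(self) -> None:
        if len(self.spacings) != len(self.features):
            raise ValueError(
                f"{self.id}: need one spacing per feature (incl. wrap), got "
                f"{len(self.spacings)} for {len(self.features)} features"
            )

    def positions(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) per feature."""
        out = []
        pos = 1
        for plan, spacing in zip(self.features, self.spacings):
            start, end = pos, pos + plan.length - 1
            out.append((start, end))
            pos = end + spacing + 1
        return out

    @property
    def length(self) -> int:
        (_, last_end) = self.positions()[-1]
        return last_end + self.spacings[-1]


@dataclass
class GenomeSpec:
    """Full specification of a synthetic bipartite genome."""

    chromosomes: list[ChromosomePlan]
    duplicated_block: list[str] = field(default_factory=list)
    k_substitutions: int = 0
    substitution_type: str = "any"  # "any" | "synonymous" | "nonsynonymous"
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substitution_type not in ("any", "synonymous", "nonsynonymous"):
            raise ValueError(f"bad substitution_type {self.substitution_type!r}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("composition weights must be positive")
        if self.duplicated_block:
            for chrom in self.chromosomes[:2]:
                names = {f.name for f in chrom.features}
                missing = set(self.duplicated_block) - names
                if missing:
                    raise ValueError(
                        f"duplicated block genes {sorted(missing)} absent from {chrom.id}"
                    )
        block_len = sum(
            f.length
            for f in (self.chromosomes[0].features if self.chromosomes else [])
            if f.name in self.duplicated_block
        )
        if self.duplicated_block and self.k_substitutions > block_len:
            raise ValueError("k_substitutions exceeds duplicated block length")


@dataclass(frozen=True)
class PlantedSubstitution:
    """Ground truth for one planted cross-copy difference."""

    gene: str
    position_in_gene: int  # 1-based
    base_a: str  # chromosome carrying the original copy
    base_b: str  # chromosome carrying the mutated copy
    effect: Optional[str]  # synonymous | nonsynonymous (PCG) | None (tRNA)


@dataclass
class TruthRecord:
    """Everything the generator knows that the pipeline must recover."""

    sequences: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, GenomeAnnotation] = field(default_factory=dict)
    substitutions: list[PlantedSubstitution] = field(default_factory=list)
    fragment_junctions: dict[str, list[dict]] = field(default_factory=dict)


def _sample_bases(rng: np.random.Generator, n: int, weights: dict[str, float]) -> list[str]:
    p = np.array([weights[b] for b in "ACGT"], dtype=float)
    p /= p.sum()
    return [str(b) for b in rng.choice(_BASES, size=n, p=p)]


def _fill_codon(
    rng: np.random.Generator,
    fixed: list[Optional[str]],
    weights: dict[str, float],
    forbid_stop: bool,
) -> list[str]:
    """Sample a 3-nt codon honouring pre-fixed bases; reject stop triplets."""
    for _ in range(200):
        codon = [
            b if b is not None else _sample_bases(rng, 1, weights)[0] for b in fixed
        ]
        if forbid_stop and "".join(codon) in _STOPS:
            if all(b is not None for b in fixed):
                raise GenerationError("pre-fixed codon is a stop triplet")
            continue
        return codon
    raise GenerationError("could not sample a non-stop codon in 200 tries")


def _expected_stop(length: int, requested: Optional[str]) -> str:
    rem = length % 3
    required_len = {0: 3, 1: 1, 2: 2}[rem]
    if requested is None:
        return {0: "TAA", 1: "T", 2: "TA"}[rem]
    if len(requested) != required_len:
        raise GenerationError(
            f"stop codon {requested!r} incompatible with span {length} (mod 3 = {rem})"
        )
    return requested


def _write_pcg(
    rng: np.random.Generator,
    array: list[Optional[str]],
    start: int,
    plan: FeaturePlan,
    weights: dict[str, float],
) -> None:
    """Write one protein-coding gene into the chromosome array (0-based start)."""
    L = plan.length
    start_codon = plan.start_codon or "ATT"
    stop = _expected_stop(L, plan.stop_codon)
    span = array[start : start + L]
    # start codon
    for k, base in enumerate(start_codon):
        if span[k] is not None and span[k] != base:
            raise GenerationError(
                f"{plan.name}: start codon {start_codon} conflicts with overlapping feature"
            )
        span[k] = base
    # stop (complete or incomplete, right-aligned)
    for k, base in enumerate(stop):
        idx = L - len(stop) + k
        if span[idx] is not None and span[idx] != base:
            raise GenerationError(
                f"{plan.name}: stop {stop} conflicts with overlapping feature"
            )
        span[idx] = base
    # middle codons
    n_coding = (L - (L % 3)) // 3  # complete codons incl. start (and stop when complete)
    first_middle = 1
    last_middle = n_coding - (1 if len(stop) == 3 else 0)
    for ci in range(first_middle, last_middle):
        fixed = span[3 * ci : 3 * ci + 3]
        span[3 * ci : 3 * ci + 3] = _fill_codon(rng, fixed, weights, forbid_stop=True)
    array[start : start + L] = span


def generate_bipartite_genome(
    spec: GenomeSpec,
) -> tuple[list[CircularChromosome], list[GenomeAnnotation], TruthRecord]:
    """Generate the chromosomes, annotations and ground truth for a spec.

    Deterministic for a fixed spec and seed. The duplicated block is copied
    verbatim from the first chromosome into the second, then mutated at
    exactly ``spec.k_substitutions`` uniformly chosen positions honouring the
    substitution-type constraint; substitutions never fall in a PCG's first
    or last codon and never create an in-frame stop.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthRecord()
    chromosomes: list[CircularChromosome] = []
    annotations: list[GenomeAnnotation] = []
    arrays: dict[str, list[Optional[str]]] = {}
    positions_by_chrom: dict[str, list[tuple[int, int]]] = {}

    for chrom_idx, plan in enumerate(spec.chromosomes):
        L = plan.length
        array: list[Optional[str]] = [None] * L
        positions = plan.positions()
        positions_by_chrom[plan.id] = positions

        if chrom_idx == 1 and spec.duplicated_block:
            _copy_block_and_mutate(rng, spec, arrays, positions_by_chrom, array, plan, truth)

        # protein-coding genes first: they carry the hard constraints
        for fplan, (start, _end) in zip(plan.features, positions):
            if fplan.gene_class == GeneClass.PCG:
                _write_pcg(rng, array, start - 1, fplan, spec.weights)
        # then everything else plus unclaimed gaps, i.i.d. under the weights
        free = [i for i, b in enumerate(array) if b is None]
        bases = _sample_bases(rng, len(free), spec.weights)
        for i, b in zip(free, bases):
            array[i] = b

        seq = "".join(array)  # type: ignore[arg-type]
        chrom = CircularChromosome(id=plan.id, length=L, sequence=seq)
        feats = [
            FeatureAnnotation(
                gene_name=fplan.name,
                gene_class=fplan.gene_class,
                start=s,
                end=e,
                start_codon=fplan.start_codon,
                stop_codon=fplan.stop_codon,
            )
            for fplan, (s, e) in zip(plan.features, positions)
        ]
        ann = GenomeAnnotation(chromosome=chrom, features=feats)
        chromosomes.append(chrom)
        annotations.append(ann)
        arrays[plan.id] = array
        truth.sequences[plan.id] = seq
        truth.annotations[plan.id] = ann

    return chromosomes, annotations, truth


def _copy_block_and_mutate(rng, spec, arrays, positions_by_chrom, array, plan, truth):
    """Copy the duplicated block from chromosome 1 and plant k substitutions."""
    src_plan = spec.chromosomes[0]
    src_array = arrays[src_plan.id]
    src_pos = {f.name: p for f, p in zip(src_plan.features, positions_by_chrom[src_plan.id])}
    dst_pos = {f.name: p for f, p in zip(plan.features, plan.positions())}
    plans = {f.name: f for f in plan.features}

    # spans of all PCGs on the destination chromosome: a substitution placed
    # via an overlapping tRNA must not fall inside a PCG (it would escape the
    # codon-level constraints applied to PCG-placed substitutions)
    pcg_spans = [
        dst_pos[f.name]
        for f in plan.features
        if f.gene_class == GeneClass.PCG
    ]

    def _inside_pcg(site0: int) -> bool:
        return any(s - 1 <= site0 <= e - 1 for s, e in pcg_spans)

    # candidate positions for mutation: (gene, offset within gene)
    candidates: list[tuple[str, int]] = []
    for name in spec.duplicated_block:
        s0, e0 = src_pos[name]
        s1, _e1 = dst_pos[name]
        gene_len = e0 - s0 + 1
        for off in range(gene_len):
            src_base = src_array[s0 - 1 + off]
            if src_base is None:
                raise GenerationError(f"block gene {name} not yet generated on {src_plan.id}")
            if array[s1 - 1 + off] is not None and array[s1 - 1 + off] != src_base:
                raise GenerationError(f"block gene {name} conflicts with prior content")
            array[s1 - 1 + off] = src_base
        fp = plans[name]
        if fp.gene_class == GeneClass.PCG:
            stop_len = len(_expected_stop(gene_len, fp.stop_codon))
            # exclude start codon and the (possibly incomplete) stop
            lo, hi = 3, gene_len - stop_len
            if spec.substitution_type in ("any", "synonymous", "nonsynonymous"):
                candidates.extend((name, off) for off in range(lo, hi))
        else:
            if spec.substitution_type == "any":
                candidates.extend(
                    (name, off)
                    for off in range(gene_len)
                    if not _inside_pcg(s1 - 1 + off)
                )

    k = spec.k_substitutions
    if k == 0:
        return
    if not candidates:
        raise GenerationError("no candidate positions for the requested substitution type")
    code = translation_table(5)
    chosen: list[tuple[str, int]] = []
    taken_sites: set[int] = set()  # absolute chromosome positions, to respect overlaps
    attempts = 0
    while len(chosen) < k:
        attempts += 1
        if attempts > 500 * k:
            raise GenerationError(
                f"could not place {k} {spec.substitution_type} substitutions after {attempts} tries"
            )
        name, off = candidates[int(rng.integers(len(candidates)))]
        s1 = dst_pos[name][0]
        site = s1 - 1 + off
        if site in taken_sites:
            continue
        old = array[site]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        fp = plans[name]
        effect = None
        if fp.gene_class == GeneClass.PCG:
            ci, cp = off // 3, off % 3
            codon_old = "".join(array[s1 - 1 + 3 * ci : s1 - 1 + 3 * ci + 3])
            codon_new = codon_old[:cp] + new + codon_old[cp + 1 :]
            if codon_new in _STOPS:
                continue
            aa_old = code.forward_table[codon_old]
            aa_new = code.forward_table[codon_new]
            effect = "synonymous" if aa_old == aa_new else "nonsynonymous"
            if spec.substitution_type != "any" and effect != spec.substitution_type:
                continue
        array[site] = new
        taken_sites.add(site)
        chosen.append((name, off))
        truth.substitutions.append(
            PlantedSubstitution(
                gene=name,
                position_in_gene=off + 1,
                base_a=old,
                base_b=new,
                effect=effect,
            )
        )


def simulate_amplicons(
    chrom: CircularChromosome,
    n_fragments: int,
    overlap_range: tuple[int, int],
    seed: int = 0,
) -> tuple["FragmentSet", list[dict]]:
    """Cut a circular chromosome into overlapping amplicon fragments.

    Fragments tile the circle: fragment *i* starts at cut *i* and extends
    past cut *i+1* by a junction overlap drawn uniformly from
    ``overlap_range`` (inclusive), so every base is covered at least once and
    the suffix of each fragment equals the prefix of the next. Returns the
    fragment set and the ground-truth junction list. Deterministic per seed.
    """
    from mitobipart.fragment_assembly import FragmentSet

    if chrom.sequence is None:
        raise ValueError("amplicon simulation requires a sequence")
    if n_fragments < 2:
        raise ValueError("need at least 2 fragments for circular closure")
    lo, hi = overlap_range
    if lo < 0 or hi < lo:
        raise ValueError(f"bad overlap range {overlap_range}")
    L = chrom.length
    rng = np.random.default_rng(seed)
    base_gap = L // n_fragments
    jitter = max(1, base_gap // 8)
    cuts = []
    for i in range(n_fragments):
        c = i * L // n_fragments + int(rng.integers(-jitter, jitter + 1))
        cuts.append(c % L)
    cuts[0] = 0
    cuts = sorted(set(cuts))
    if len(cuts) != n_fragments:
        raise ValueError("infeasible tiling: cut points collide; fewer fragments or larger circle")
    gaps = [(cuts[(i + 1) % n_fragments] - cuts[i]) % L for i in range(n_fragments)]
    if min(gaps) <= hi:
        raise ValueError(
            f"infeasible tiling: overlap up to {hi} exceeds inter-cut distance {min(gaps)}"
        )
    overlaps = [int(rng.integers(lo, hi + 1)) for _ in range(n_fragments)]
    doubled = chrom.sequence + chrom.sequence
    fragments = []
    junctions = []
    for i in range(n_fragments):
        start = cuts[i]
        end = cuts[(i + 1) % n_fragments]
        span = (end - start) % L + overlaps[(i + 1) % n_fragments]
        fragments.append((f"frag{i + 1}", doubled[start : start + span]))
        junctions.append(
            {
                "source": f"frag{i + 1}",
                "target": f"frag{(i + 1) % n_fragments + 1}",
                "overlap": overlaps[(i + 1) % n_fragments],
                "cut_position": end + 1,  # 1-based start of the next fragment
            }
        )
    return FragmentSet(fragments=fragments), junctions


# ---------------------------------------------------------------------------
# Spec construction helpers
# ---------------------------------------------------------------------------

def spec_from_table(a: GenomeAnnotation) -> ChromosomePlan:
    """Derive a chromosome plan reproducing an annotation's structure.

    Gene names, classes, spans, codon policies and spacings (including the
    wrap spacer) are carried over, so a genome generated from the plan has
    the same coordinate table as the input annotation.
    """
    if not a.features:
        raise ValueError("cannot derive a plan from an empty annotation")
    spacings = [r.spacing for r in intergenic_spacings(a)]
    if not a.chromosome.is_circular:
        spacings.append(0)
    feats = [
        FeaturePlan(
            name=f.gene_name,
            gene_class=f.gene_class,
            length=f.length,
            start_codon=f.start_codon,
            stop_codon=f.stop_codon,
        )
        for f in a.features
    ]
    return ChromosomePlan(id=a.chromosome.id, features=feats, spacings=spacings)


def reference_bipartite_spec(
    k_substitutions: int = 3,
    substitution_type: str = "any",
    seed: int = 0,
    weights: Optional[dict[str, float]] = None,
) -> GenomeSpec:
    """A spec mirroring the published two-chromosome annotation tables.

    Two circles of 7,659 and 7,647 nt, 17 + 23 genes plus one long NCR each,
    duplicated block {cox2, trnD, trnG, trnH}, printed spacings and codon
    assignments.
    """
    from mitobipart.reference import DUPLICATED_GENES, load_reference_annotations

    chr1, chr2 = load_reference_annotations()
    return GenomeSpec(
        chromosomes=[spec_from_table(chr1), spec_from_table(chr2)],
        duplicated_block=list(DUPLICATED_GENES),
        k_substitutions=k_substitutions,
        substitution_type=substitution_type,
        weights=dict(weights or DEFAULT_WEIGHTS),
        seed=seed,
    )
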