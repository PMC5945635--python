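"""Generator correctness: determinism, structural fidelity, planted truth."""

import pytest

from mitobipart.annotation_stats import (
    detect_ncrs,
    infer_codons,
    length_conservation,
)
from mitobipart.codon_usage import translation_table
from mitobipart.duplication_analysis import analyse_duplicates, find_duplicates
from mitobipart.genome_model import GeneClass, feature_sequence, validate_annotation
from mitobipart.synthetic_data import (
    ChromosomePlan,
    FeaturePlan,
    GenerationError,
    GenomeSpec,
    generate_bipartite_genome,
    reference_bipartite_spec,
    simulate_amplicons,
    spec_from_table,
)


class TestGenerateBipartiteGenome:
    def test_determinism_byte_identical(self):
        a = generate_bipartite_genome(reference_bipartite_spec(3, seed=7))
        b = generate_bipartite_genome(reference_bipartite_spec(3, seed=7))
        assert [c.sequence for c in a[0]] == [c.sequence for c in b[0]]
        assert a[2].substitutions == b[2].substitutions

    def test_seed_changes_output(self):
        a = generate_bipartite_genome(reference_bipartite_spec(3, seed=7))
        b = generate_bipartite_genome(reference_bipartite_spec(3, seed=8))
        assert [c.sequence for c in a[0]] != [c.sequence for c in b[0]]

    def test_reference_spec_reproduces_table_structure(self, synthetic_genome):
        chroms, anns, _ = synthetic_genome
        assert [c.length for c in chroms] == [7659, 7647]
        for ann in anns:
            assert validate_annotation(ann) == []
            implied, declared = length_conservation(ann)
            assert implied == declared
        assert len(detect_ncrs(anns[0])) == 1 and len(detect_ncrs(anns[1])) == 1

    def test_pcgs_have_valid_codons_and_no_internal_stops(self, synthetic_genome):
        chroms, anns, _ = synthetic_genome
        for ann in anns:
            for f in ann.by_class(GeneClass.PCG):
                call = infer_codons(ann.chromosome, f, check_internal_stops=True)
                assert call.start_codon_allowed
                assert call.stop_codon == f.stop_codon

    def test_duplicate_block_recovery(self, synthetic_genome):
        chroms, anns, truth = synthetic_genome
        assert find_duplicates(anns) == ["cox2", "trnD", "trnG", "trnH"]

    @pytest.mark.parametrize("k", [0, 1, 3, 6])
    def test_exactly_k_substitutions_planted_and_recovered(self, k):
        spec = reference_bipartite_spec(k, seed=100 + k)
        chroms, anns, truth = generate_bipartite_genome(spec)
        assert len(truth.substitutions) == k
        pairs = {p.gene_name: p for p in analyse_duplicates(anns)}
        recovered = [
            (p.gene_name, s.position)
            for p in pairs.values()
            for s in p.substitutions
        ]
        planted = [(t.gene, t.position_in_gene) for t in truth.substitutions]
        assert sorted(recovered) == sorted(planted)
        # identity arithmetic: 100 * (L - k_gene) / L per gene
        for gene, pair in pairs.items():
            k_gene = sum(1 for t in truth.substitutions if t.gene == gene)
            expected = round(100 * (pair.span_nt - k_gene) / pair.span_nt, 1)
            assert pair.identity_percent == pytest.approx(expected, abs=0.05)

    def test_substitution_effects_match_pipeline_classification(self):
        spec = reference_bipartite_spec(5, seed=31)
        _, anns, truth = generate_bipartite_genome(spec)
        pairs = {p.gene_name: p for p in analyse_duplicates(anns)}
        for t in truth.substitutions:
            if t.effect is None:
                continue
            sub = next(
                s for s in pairs[t.gene].substitutions if s.position == t.position_in_gene
            )
            assert sub.effect == t.effect

    @pytest.mark.parametrize("constraint", ["synonymous", "nonsynonymous"])
    def test_typed_substitutions_honour_constraint(self, constraint):
        spec = reference_bipartite_spec(2, substitution_type=constraint, seed=17)
        _, anns, truth = generate_bipartite_genome(spec)
        assert all(t.effect == constraint for t in truth.substitutions)
        assert all(t.gene == "cox2" for t in truth.substitutions)  # typed subs are coding

    def test_k_zero_copies_identical(self):
        _, anns, truth = generate_bipartite_genome(reference_bipartite_spec(0, seed=2))
        assert truth.substitutions == []
        for p in analyse_duplicates(anns):
            assert p.identity_percent == 100.0

    def test_unsatisfiable_block_raises(self):
        spec = reference_bipartite_spec(0, seed=1)
        spec.duplicated_block = ["nad9"]
        with pytest.raises(ValueError, match="nad9"):
            GenomeSpec(
                chromosomes=spec.chromosomes,
                duplicated_block=["nad9"],
                k_substitutions=1,
            )


class TestSimulateAmplicons:
    def test_fragment_length_conservation(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        fs, junctions = simulate_amplicons(chroms[0], 4, (122, 398), seed=3)
        total_overlap = sum(j["overlap"] for j in junctions)
        assert sum(len(s) for _, s in fs.fragments) == chroms[0].length + total_overlap

    def test_two_fragments_fixed_overlap(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        fs, _ = simulate_amplicons(chroms[0], 2, (100, 100), seed=1)
        assert sum(len(s) for _, s in fs.fragments) == chroms[0].length + 200

    def test_every_base_covered(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        chrom = chroms[1]
        fs, junctions = simulate_amplicons(chrom, 5, (122, 398), seed=8)
        doubled = chrom.sequence + chrom.sequence
        covered = [False] * chrom.length
        starts = {j["source"]: None for j in junctions}
        pos = 0
        for fid, seq in fs.fragments:
            idx = doubled.find(seq)
            assert idx >= 0
            for p in range(idx, idx + len(seq)):
                covered[p % chrom.length] = True
        assert all(covered)

    def test_determinism(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        a, _ = simulate_amplicons(chroms[0], 4, (122, 398), seed=11)
        b, _ = simulate_amplicons(chroms[0], 4, (122, 398), seed=11)
        assert a.fragments == b.fragments

    def test_infeasible_tiling_raises(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        with pytest.raises(ValueError, match="infeasible"):
            simulate_amplicons(chroms[0], 30, (300, 398), seed=1)

    def test_minimum_two_fragments(self, synthetic_genome):
        chroms, _, _ = synthetic_genome
        with pytest.raises(ValueError):
            simulate_amplicons(chroms[0], 1, (122, 398), seed=1)


class TestSpecFromTable:
    def test_reference_round_trip(self, reference_annotations):
        plan = spec_from_table(reference_annotations[0])
        assert len(plan.features) == 18
        assert plan.length == 7659
        ncr = next(f for f in plan.features if f.gene_class == GeneClass.NCR)
        assert ncr.length == 471

    def test_generate_then_rederive_is_idempotent(self, synthetic_genome):
        _, anns, _ = synthetic_genome
        for ann in anns:
            plan = spec_from_table(ann)
            assert [(f.name, f.length) for f in plan.features] == [
                (f.gene_name, f.length) for f in ann.features
            ]
            assert plan.length == ann.chromosome.length

    def test_empty_annotation_raises(self):
        from mitobipart.genome_model import CircularChromosome, GenomeAnnotation

        with pytest.raises(ValueError):
            spec_from_table(GenomeAnnotation(CircularChromosome("c", 10), []))


def test_plan_spacing_arity_enforced():
    with pytest.raises(ValueError, match="one spacing per feature"):
        ChromosomePlan(
            id="c",
            features=[FeaturePlan("cox1", GeneClass.PCG, 300)],
            spacings=[1, 2],
        )
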