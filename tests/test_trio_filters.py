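"""Segregation classifiers, annotation predicates, and the filter cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ann, gt, make_duo, make_trio
from triokin.errors import ConfigurationError, PhaseUndeterminedError
from triokin.trio_filters import (cascade_counts, classify_dominant,
                                  classify_recessive, find_compound_het,
                                  is_deleterious_in_silico, is_nonsynonymous,
                                  is_rare)


def keys(matrix, indices):
    return {matrix.variants[i].key for i in indices}


class TestClassifyRecessive:
    def test_trio_textbook_pattern_returned(self):
        m = make_trio([("1/1", "0/1", "0/1")])
        assert classify_recessive(m) == keys(m, [0])

    def test_unaffected_parent_homozygote_excluded(self):
        m = make_trio([("1/1", "1/1", "0/1")])
        assert classify_recessive(m) == set()

    def test_affected_parent_homozygote_not_excluded_but_not_het(self):
        # exclusion lifts for an affected parent, yet the trio rule still
        # demands both parents het, so the variant is not returned
        m = make_trio([("1/1", "1/1", "0/1")], affected_mother=True)
        assert classify_recessive(m) == set()

    def test_child_not_homozygous_not_returned(self):
        m = make_trio([("0/1", "0/1", "0/1")])
        assert classify_recessive(m) == set()

    def test_missing_parent_genotype_disqualifies(self):
        m = make_trio([("1/1", "./.", "0/1")])
        assert classify_recessive(m) == set()

    def test_duo_child_hom_parent_het_returned(self):
        m = make_duo([("1/1", "0/1"), ("1/1", "1/1"), ("1/1", "0/0")])
        assert classify_recessive(m) == keys(m, [0])

    def test_no_parents_is_configuration_error(self):
        from triokin.variant_model import GenotypeMatrix, Sample, VariantRecord
        m = GenotypeMatrix(
            variants=[VariantRecord(chrom="1", pos=1, ref="A", alt="T")],
            samples=[Sample("C", "child", affected=True)],
            genotypes=[[gt("1/1")]])
        with pytest.raises(ConfigurationError):
            classify_recessive(m)

    def test_hemizygous_x_duo(self):
        # male child hemizygous alt counts as homozygous-equivalent
        m = make_duo([("1", "0/1"), ("1", "1/1"), ("0", "0/1")], chrom="X")
        assert classify_recessive(m) == keys(m, [0])


class TestClassifyDominant:
    def test_de_novo_textbook(self):
        m = make_trio([("0/1", "0/0", "0/0")])
        assert classify_dominant(m, "de_novo") == keys(m, [0])

    def test_de_novo_carrier_parent_disqualifies(self):
        m = make_trio([("0/1", "0/1", "0/0"), ("0/1", "./.", "0/0")])
        assert classify_dominant(m, "de_novo") == set()

    def test_affected_parent_transmission(self):
        m = make_trio([("0/1", "0/1", "0/0"),   # from affected mother: yes
                       ("0/1", "0/0", "0/1"),   # from unaffected father: no
                       ("0/1", "0/1", "0/1")],  # unaffected father carrier: no
                      affected_mother=True)
        assert classify_dominant(m, "affected_parent") == keys(m, [0])

    def test_homozygous_child_never_dominant(self):
        m = make_trio([("1/1", "0/0", "0/0")], affected_mother=True)
        assert classify_dominant(m, "de_novo") == set()
        assert classify_dominant(m, "affected_parent") == set()

    def test_affected_parent_mode_needs_affected_parent(self):
        m = make_trio([("0/1", "0/0", "0/0")])
        with pytest.raises(ConfigurationError):
            classify_dominant(m, "affected_parent")

    def test_unknown_mode_rejected(self):
        m = make_trio([("0/1", "0/0", "0/0")])
        with pytest.raises(ConfigurationError):
            classify_dominant(m, "recessive")


class TestFindCompoundHet:
    def test_trans_pair_found(self):
        m = make_trio([("0/1", "0/1", "0/0"), ("0/1", "0/0", "0/1")])
        pairs = find_compound_het(m)
        assert set(pairs) == {"G1"}
        assert pairs["G1"] == [tuple(sorted(keys(m, [0, 1])))]

    def test_cis_by_origin_not_paired(self):
        m = make_trio([("0/1", "0/1", "0/0"), ("0/1", "0/1", "0/0")])
        assert find_compound_het(m) == {}

    def test_different_genes_never_paired(self):
        anns = [ann(gene="G1"), ann(gene="G2")]
        m = make_trio([("0/1", "0/1", "0/0"), ("0/1", "0/0", "0/1")],
                      annotations=anns)
        assert find_compound_het(m) == {}

    def test_pair_with_parental_homozygote_excluded(self):
        m = make_trio([("0/1", "1/1", "0/0"), ("0/1", "0/0", "0/1")])
        assert find_compound_het(m) == {}

    def test_biparental_variant_not_a_member(self):
        m = make_trio([("0/1", "0/1", "0/1"), ("0/1", "0/0", "0/1")])
        assert find_compound_het(m) == {}

    def test_duo_raises_phase_undetermined(self):
        m = make_duo([("0/1", "0/1")])
        with pytest.raises(PhaseUndeterminedError):
            find_compound_het(m)

    def test_symmetric_in_pair_order_and_all_pairs_reported(self):
        # two maternal + one paternal member -> exactly the 2 trans pairs
        m = make_trio([("0/1", "0/1", "0/0"),
                       ("0/1", "0/1", "0/0"),
                       ("0/1", "0/0", "0/1")])
        pairs = find_compound_het(m)["G1"]
        assert len(pairs) == 2
        assert all(p[0] <= p[1] for p in pairs)
        paternal = m.variants[2].key
        assert all(paternal in p for p in pairs)


class TestPredicates:
    @pytest.mark.parametrize("consequence, impact, expected", [
        ("missense_variant", "MODERATE", True),
        ("stop_gained", "HIGH", True),
        ("frameshift_variant", "HIGH", True),
        ("synonymous_variant", "LOW", False),
        ("intron_variant", "MODIFIER", False),
        ("3_prime_UTR_variant", "MODIFIER", False),
        ("intergenic_variant", "MODIFIER", False),
        ("splice_acceptor_variant", "HIGH", True),
        ("synonymous_variant&splice_acceptor_variant", "LOW", True),
        ("splice_region_variant", "LOW", False),
        ("splice_region_variant", "MODERATE", True),
        ("made_up_term", "MODERATE", False),
        ("", "MODERATE", False),
    ])
    def test_is_nonsynonymous(self, consequence, impact, expected):
        assert is_nonsynonymous(ann(consequence=consequence,
                                    impact=impact)) is expected

    @pytest.mark.parametrize("sift, polyphen, impact, expected", [
        ("deleterious", "possibly_damaging", "MODERATE", True),
        ("tolerated", "benign", "MODERATE", False),
        ("missing", "missing", "HIGH", True),
        ("deleterious_low_confidence", "benign", "LOW", True),
        ("tolerated_low_confidence", "benign", "MODERATE", False),
        ("missing", "probably_damaging", "LOW", True),
        ("missing", "missing", "MODERATE", False),
    ])
    def test_is_deleterious_in_silico(self, sift, polyphen, impact, expected):
        assert is_deleterious_in_silico(
            ann(sift=sift, polyphen=polyphen, impact=impact)) is expected

    @pytest.mark.parametrize("gmaf, threshold, expected", [
        (0.0016, 0.01, True),    # known rare variant
        (0.408, 0.01, False),    # common polymorphism
        (None, 0.01, True),      # novel: missing treated as rare
        (0.01, 0.01, False),     # strict inequality
        (0.0099, 0.01, True),
    ])
    def test_is_rare(self, gmaf, threshold, expected):
        assert is_rare(ann(gmaf=gmaf), threshold, "GLOBAL") is expected

    def test_is_rare_unknown_population_rejected(self):
        with pytest.raises(ConfigurationError):
            is_rare(ann(gmaf=0.1), 0.01, "AFR")
        with pytest.raises(ConfigurationError):
            is_rare(ann(gmaf=0.1), 0.0, "GLOBAL")

    @settings(max_examples=100, derandomize=True)
    @given(maf=st.one_of(st.none(), st.floats(0, 1)),
           t1=st.floats(0.001, 1.0), t2=st.floats(0.001, 1.0))
    def test_is_rare_monotone_in_threshold(self, maf, t1, t2):
        lo, hi = sorted((t1, t2))
        a = ann(gmaf=maf)
        if is_rare(a, lo, "GLOBAL"):
            assert is_rare(a, hi, "GLOBAL")


class TestCascade:
    def test_empty_matrix_all_zero(self):
        m = make_trio([])
        c = cascade_counts(m)
        assert (c.total_variants, c.recessive_homozygous, c.rare,
                c.nonsynonymous, c.deleterious_in_silico) == (0, 0, 0, 0, 0)

    def test_all_het_children_zero_ladder(self):
        m = make_trio([("0/1", "0/1", "0/1")] * 5)
        c = cascade_counts(m)
        assert c.total_variants == 5
        assert c.recessive_homozygous == 0 == c.deleterious_in_silico

    def test_snp_indel_partition(self):
        from triokin.variant_model import VariantRecord
        m = make_trio([("0/1", "0/0", "0/0"), ("0/1", "0/0", "0/0"),
                       ("0/0", "0/1", "0/0")])
        m.variants[1] = VariantRecord(chrom="1", pos=1001, ref="A", alt="ATT",
                                      annotation=ann())
        c = cascade_counts(m)
        # third variant not carried by the child -> not counted
        assert (c.total_variants, c.snps, c.indels) == (2, 1, 1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_cascade_monotone_on_random_matrices(self, data):
        gts = ("0/0", "0/1", "1/1", "./.")
        n = data.draw(st.integers(1, 25))
        rows = [(data.draw(st.sampled_from(gts)),
                 data.draw(st.sampled_from(gts)),
                 data.draw(st.sampled_from(gts))) for _ in range(n)]
        anns = [ann(gmaf=data.draw(st.one_of(st.none(), st.floats(0, 0.5))),
                    consequence=data.draw(st.sampled_from(
                        ("missense_variant", "synonymous_variant",
                         "stop_gained", "intron_variant"))),
                    sift=data.draw(st.sampled_from(("deleterious", "tolerated",
                                                    "missing"))))
                for _ in range(n)]
        c = cascade_counts(make_trio(rows, annotations=anns))
        assert (c.recessive_homozygous >= c.rare >= c.nonsynonymous
                >= c.deleterious_in_silico)
        assert c.total_variants == c.snps + c.indels
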