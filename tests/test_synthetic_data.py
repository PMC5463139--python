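"""Statistical and structural properties of the synthetic generator."""

import numpy as np
import pytest
from scipy import stats

from triokin.errors import CapacityError, ConfigurationError
from triokin.pedigree import pedigree_for_kinship, sibling_parents
from triokin.synthetic_data import (GeneInterval, InjectionSpec, LabelModel,
                                    SpectrumParams, annotate_sites,
                                    estimate_kinship, gene_drop,
                                    matrix_from_gene_drop, simulate_family,
                                    simulate_parent_pair, simulate_spectrum,
                                    tile_gene_model, write_family_vcf)
from triokin.variant_model import normalize_chrom, read_family_vcf


class TestSpectrum:
    def test_all_rare_construction(self):
        sp = SpectrumParams(n_sites=100, rare_fraction=1.0,
                            rare_maf_range=(1e-4, 1e-2))
        sites = simulate_spectrum(sp, np.random.default_rng(0))
        assert len(sites) == 100
        assert all(s.annotation.maf["GLOBAL"] < 0.01 for s in sites)

    def test_chromosome_weights_respected(self):
        sp = SpectrumParams(n_sites=50, chromosome_weights={"1": 1.0})
        sites = simulate_spectrum(sp, np.random.default_rng(0))
        assert {s.chrom for s in sites} == {"1"}

    def test_positions_strictly_increasing_within_chromosome(self):
        sites = simulate_spectrum(SpectrumParams(n_sites=2000),
                                  np.random.default_rng(1))
        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        for pos in by_chrom.values():
            assert all(a < b for a, b in zip(pos, pos[1:]))

    def test_empirical_rare_fraction_binomial(self):
        sp = SpectrumParams(n_sites=10_000, rare_fraction=0.7,
                            rare_maf_range=(1e-4, 9e-3))
        sites = simulate_spectrum(sp, np.random.default_rng(2))
        n_rare = sum(s.annotation.maf["GLOBAL"] < 0.01 for s in sites)
        assert stats.binomtest(n_rare, 10_000, 0.7).pvalue > 1e-4

    def test_eur_is_bounded_perturbation_of_global(self):
        sp = SpectrumParams(n_sites=500, eur_noise=0.2)
        sites = simulate_spectrum(sp, np.random.default_rng(3))
        for s in sites:
            g, e = s.annotation.maf["GLOBAL"], s.annotation.maf["EUR"]
            assert 0.0 < e < 1.0
            assert 0.79 * g <= e <= 1.21 * g

    def test_indel_fraction_and_determinism(self):
        sp = SpectrumParams(n_sites=2000, indel_fraction=0.1)
        a = simulate_spectrum(sp, np.random.default_rng(7))
        b = simulate_spectrum(sp, np.random.default_rng(7))
        assert [r.key for r in a] == [r.key for r in b]
        n_indel = sum(not s.is_snp for s in a)
        assert stats.binomtest(n_indel, 2000, 0.1).pvalue > 1e-4


class TestGeneModelAndLabels:
    def test_interval_lookup_assigns_gene(self):
        sites = simulate_spectrum(SpectrumParams(n_sites=300),
                                  np.random.default_rng(0))
        model = tile_gene_model(sites)
        annotated = annotate_sites(sites, model, rng=np.random.default_rng(1))
        by_pos = {(iv.chrom, p): iv.gene for iv in model
                  for p in ()}  # lookup done per site below
        for s in annotated:
            inside = [iv.gene for iv in model
                      if iv.chrom == normalize_chrom(s.chrom)
                      and iv.start <= s.pos <= iv.end]
            if inside:
                assert s.annotation.gene == inside[0]
            else:
                assert s.annotation.gene == ""
                assert s.annotation.consequence == "intergenic_variant"

    def test_overlapping_intervals_rejected(self):
        sites = simulate_spectrum(SpectrumParams(n_sites=10),
                                  np.random.default_rng(0))
        bad = [GeneInterval("A", "1", 1, 10 ** 9),
               GeneInterval("B", "1", 5, 10 ** 9)]
        with pytest.raises(ConfigurationError):
            annotate_sites(sites, bad)

    def test_forced_deleterious_labels(self):
        from triokin.trio_filters import is_deleterious_in_silico
        sites = simulate_spectrum(SpectrumParams(n_sites=200),
                                  np.random.default_rng(0))
        model = tile_gene_model(sites, intergenic_every=0)
        lm = LabelModel(consequence_probs=(("missense_variant", "MODERATE", 1.0),),
                        sift_deleterious_prob=1.0, polyphen_damaging_prob=1.0)
        annotated = annotate_sites(sites, model, lm, np.random.default_rng(1))
        genic = [s for s in annotated if s.annotation.gene]
        assert genic
        assert all(is_deleterious_in_silico(s.annotation) for s in genic)

    def test_label_frequencies_match_configuration(self):
        sites = simulate_spectrum(SpectrumParams(n_sites=10_000),
                                  np.random.default_rng(5))
        model = tile_gene_model(sites, intergenic_every=0)
        annotated = annotate_sites(sites, model, LabelModel(),
                                   np.random.default_rng(6))
        genic = [s for s in annotated if s.annotation.gene]
        counts = {}
        for s in genic:
            counts[s.annotation.consequence] = counts.get(
                s.annotation.consequence, 0) + 1
        probs = {c: w for c, _, w in LabelModel().consequence_probs}
        total = sum(probs.values())
        observed = [counts.get(c, 0) for c in probs]
        expected = [len(genic) * w / total for w in probs.values()]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert chi2 < stats.chi2.ppf(0.9999, df=len(probs) - 1)


class TestGeneDrop:
    def _sites(self, n=3000, seed=0, x_weight=False):
        weights = dict(SpectrumParams().chromosome_weights)
        sp = SpectrumParams(n_sites=n, chromosome_weights=weights)
        return simulate_spectrum(sp, np.random.default_rng(seed))

    def test_mendelian_consistency(self):
        sites = self._sites()
        ped = pedigree_for_kinship(0.25, child=True, child_sex="M")
        dropped = gene_drop(ped, sites, np.random.default_rng(1))
        for i, site in enumerate(sites):
            c = dropped["child"][i]
            m = dropped["mother"][i]
            f = dropped["father"][i]
            assert c.alleles[0] in m.alleles  # maternal allele really maternal
            if c.ploidy == 2:
                if normalize_chrom(site.chrom) == "X":
                    assert c.alleles[1] == f.alleles[0]  # father's single X
                else:
                    assert c.alleles[1] in f.alleles

    def test_founder_hwe(self):
        """Founder genotype frequencies match (1-p)^2, 2p(1-p), p^2."""
        sp = SpectrumParams(n_sites=20_000, rare_fraction=0.0,
                            chromosome_weights={"1": 1.0})
        sites = simulate_spectrum(sp, np.random.default_rng(2))
        dropped = gene_drop(pedigree_for_kinship(0.0, child=False), sites,
                            np.random.default_rng(3))
        p = np.array([s.annotation.maf["EUR"] for s in sites])
        dos = np.array([g.n_alt for g in dropped["father"]])
        # bin sites by frequency and chi-square the pooled genotype counts
        chi2 = 0.0
        dof = 0
        for lo, hi in ((0.01, 0.1), (0.1, 0.3), (0.3, 0.5)):
            sel = (p >= lo) & (p < hi)
            if sel.sum() < 100:
                continue
            pbar = p[sel]
            exp = np.array([np.sum((1 - pbar) ** 2),
                            np.sum(2 * pbar * (1 - pbar)),
                            np.sum(pbar ** 2)])
            obs = np.array([(dos[sel] == k).sum() for k in (0, 1, 2)])
            chi2 += float(np.sum((obs - exp) ** 2 / exp))
            dof += 2
        assert dof >= 4
        assert chi2 < stats.chi2.ppf(0.999, df=dof)

    def test_unrelated_parents_independent(self):
        """Chi-square independence of parental carrier status.

        A narrow frequency band keeps per-site carrier probability uniform;
        pooling heterogeneous frequencies would fake an association."""
        sp = SpectrumParams(n_sites=10_000, rare_fraction=1.0,
                            rare_maf_range=(0.05, 0.051),
                            chromosome_weights={"1": 1.0})
        sites = simulate_spectrum(sp, np.random.default_rng(4))
        dropped = gene_drop(pedigree_for_kinship(0.0, child=False), sites,
                            np.random.default_rng(5))
        fa = np.array([g.carrier for g in dropped["father"]])
        mo = np.array([g.carrier for g in dropped["mother"]])
        table = np.array([[np.sum(fa & mo), np.sum(fa & ~mo)],
                          [np.sum(~fa & mo), np.sum(~fa & ~mo)]])
        assert stats.chi2_contingency(table).pvalue > 1e-4

    def test_sibling_parents_share_excess_rare_alleles(self):
        """Carrier co-occurrence for sibling parents exceeds the HWE
        expectation 1-(1-p)^2 used for unrelated individuals."""
        sp = SpectrumParams(n_sites=10_000, rare_fraction=1.0,
                            rare_maf_range=(1e-3, 1e-2),
                            chromosome_weights={"1": 1.0})
        sites = simulate_spectrum(sp, np.random.default_rng(6))
        dropped = gene_drop(sibling_parents(child=False), sites,
                            np.random.default_rng(7))
        fa = np.array([g.carrier for g in dropped["father"]])
        mo = np.array([g.carrier for g in dropped["mother"]])
        p = np.array([s.annotation.maf["EUR"] for s in sites])
        shared = np.sum(fa & mo)
        hwe_expected = np.sum((1 - (1 - p[fa]) ** 2))
        assert shared > 2 * hwe_expected

    def test_forced_transmission(self):
        from triokin.variant_model import Annotation, VariantRecord
        from triokin.pedigree import Member, PedigreeSpec
        # deterministic: 1/1 x 0/0 parents -> child always 0/1
        site = VariantRecord(chrom="1", pos=10, ref="A", alt="T",
                             annotation=Annotation(maf={"EUR": 0.999999}))
        site0 = VariantRecord(chrom="1", pos=20, ref="A", alt="T",
                              annotation=Annotation(maf={"EUR": 1e-6}))
        ped = pedigree_for_kinship(0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            dropped = gene_drop(ped, [site, site0], rng)
            if dropped["father"][0].hom_alt and dropped["mother"][0].hom_ref:
                assert dropped["child"][0].het

    def test_kinship_realism(self):
        """Dosage-correlation kinship estimates match the declared label."""
        sp = SpectrumParams(n_sites=25_000, rare_fraction=0.2,
                            chromosome_weights={str(c): 1.0
                                                for c in range(1, 23)})
        rng = np.random.default_rng(11)
        sites = simulate_spectrum(sp, rng)
        for phi in (0.0, 1 / 16, 0.25):
            ped = pedigree_for_kinship(phi, child=False)
            dropped = gene_drop(ped, sites, rng)
            m = matrix_from_gene_drop(sites, dropped, family_id="K")
            est = estimate_kinship(m, "father", "mother")
            assert est == pytest.approx(phi, abs=0.02)

    def test_full_determinism(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        m1, _ = simulate_family(kinship=1 / 64, rng=rng1)
        m2, _ = simulate_family(kinship=1 / 64, rng=rng2)
        assert [r.key for r in m1.variants] == [r.key for r in m2.variants]
        assert m1.genotypes == m2.genotypes


class TestInjection:
    def test_manifest_matches_spec_counts(self, injected_family):
        _, manifest = injected_family
        by_class = manifest.groupby("truth_class").size().to_dict()
        assert by_class["compound_het_member"] == 4
        assert sum(v for k, v in by_class.items()
                   if k.startswith("recessive")) == 10
        assert sum(v for k, v in by_class.items()
                   if k.startswith("panel_hit")) == 3

    def test_zero_spec_identity(self):
        rng = np.random.default_rng(3)
        matrix, _ = simulate_family(rng=rng)
        from triokin.synthetic_data import inject_ground_truth
        spec = InjectionSpec(recessive_total=0, recessive_rare=0,
                             recessive_nonsynonymous=0, recessive_deleterious=0,
                             compound_het_pairs=0, de_novo=0, panel_hits={})
        injected, manifest = inject_ground_truth(matrix, spec,
                                                 np.random.default_rng(0),
                                                 neutralize=False)
        assert manifest.empty
        assert injected.genotypes == matrix.sorted_copy().genotypes

    def test_capacity_error(self):
        rng = np.random.default_rng(4)
        matrix, _ = simulate_family(spectrum=SpectrumParams(n_sites=10), rng=rng)
        from triokin.synthetic_data import inject_ground_truth
        with pytest.raises(CapacityError):
            inject_ground_truth(matrix, InjectionSpec(recessive_total=50,
                                                      recessive_rare=0,
                                                      recessive_nonsynonymous=0,
                                                      recessive_deleterious=0),
                                np.random.default_rng(0))

    def test_nested_ladder_validated(self):
        with pytest.raises(ConfigurationError):
            InjectionSpec(recessive_total=2, recessive_rare=3)

    def test_de_novo_injection_recovered(self):
        from triokin.trio_filters import classify_dominant
        rng = np.random.default_rng(8)
        spec = InjectionSpec(de_novo=3)
        matrix, manifest = simulate_family(rng=rng, inject=spec)
        got = classify_dominant(matrix, "de_novo")
        want = {tuple(r) for r in
                manifest.loc[manifest.truth_class == "de_novo",
                             ["chrom", "pos", "ref", "alt"]].itertuples(index=False)}
        assert got == want


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path, injected_family):
        matrix, _ = injected_family
        path = tmp_path / "fam.vcf"
        write_family_vcf(matrix, path)
        roles = {s.sample_id: s.role for s in matrix.samples}
        back = read_family_vcf(path, roles, family_id=matrix.family_id)
        assert [r.key for r in back.variants] == [r.key for r in matrix.variants]
        assert back.genotypes == matrix.genotypes
        # annotations survive the CSQ round trip
        for a, b in zip(matrix.variants, back.variants):
            assert a.annotation.gene == b.annotation.gene
            assert a.annotation.consequence == b.annotation.consequence
            assert a.annotation.sift == b.annotation.sift
            g1, g2 = a.annotation.maf["GLOBAL"], b.annotation.maf["GLOBAL"]
            assert (g1 is None) == (g2 is None)
            if g1 is not None:
                assert g2 == pytest.approx(g1, rel=1e-4)

    def test_sample_order_matches_declaration(self, tmp_path):
        matrix, _ = simulate_family(spectrum=SpectrumParams(n_sites=50),
                                    rng=np.random.default_rng(1))
        path = write_family_vcf(matrix, tmp_path / "f.vcf")
        header = [l for l in path.read_text().splitlines()
                  if l.startswith("#CHROM")][0]
        assert header.split("\t")[9:] == [s.sample_id for s in matrix.samples]

    def test_multiallelic_emission_splits_back(self, tmp_path):
        """Two alts written on one line are split back into the two
        injected records with remapped genotypes."""
        from conftest import gt
        from triokin.variant_model import (Annotation, GenotypeMatrix, Sample,
                                           VariantRecord)
        maf = {"GLOBAL": 0.1, "EUR": 0.1}
        variants = [
            VariantRecord(chrom="1", pos=500, ref="G", alt="A",
                          annotation=Annotation(maf=maf)),
            VariantRecord(chrom="1", pos=500, ref="G", alt="T",
                          annotation=Annotation(maf=maf)),
        ]
        samples = [Sample("S1", "child", affected=True),
                   Sample("S2", "mother")]
        grid = [[gt("0/1"), gt("0/0")], [gt("0/1"), gt("1/1")]]
        m = GenotypeMatrix(variants=variants, samples=samples, genotypes=grid)
        path = write_family_vcf(m, tmp_path / "multi.vcf",
                                merge_multiallelic=True)
        body = [l for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert len(body) == 1 and "A,T" in body[0]
        back = read_family_vcf(path, {"S1": "child", "S2": "mother"})
        assert [r.key for r in back.variants] == [r.key for r in m.variants]
        # multi-allelic merge canonicalises unphased allele order
        got = [[tuple(sorted(g.alleles)) for g in row] for row in back.genotypes]
        want = [[tuple(sorted(g.alleles)) for g in row] for row in grid]
        assert got == want

    def test_empty_vcf_header_only(self, tmp_path):
        from triokin.variant_model import GenotypeMatrix, Sample
        m = GenotypeMatrix(variants=[], samples=[Sample("S1", "child")],
                           genotypes=[])
        path = write_family_vcf(m, tmp_path / "empty.vcf")
        back = read_family_vcf(path, {"S1": "child"})
        assert back.n_variants == 0
        assert [s.sample_id for s in back.samples] == ["S1"]
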