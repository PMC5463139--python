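"""Synthetic annotated family exomes with controlled pedigree structure.

Generates everything the pipeline consumes, at desk scale and fully
deterministic under a seed:

* a site-frequency spectrum with a heavy rare tail (two-component mixture:
  a log-uniform rare band and a bounded unimodal common component), with a
  GLOBAL frequency and a noisily concordant EUR frequency per site;
* founder genotypes in Hardy-Weinberg equilibrium and Mendelian gene
  dropping through explicit pedigrees (including consanguineous parent
  pairs), with sexed X-chromosome transmission;
* categorical annotation labels (gene symbol by genomic interval,
  consequence/impact/SIFT/PolyPhen);
* injected ground-truth variants realising each filter class exactly, with
  a truth manifest for end-to-end assertions;
* a VCF writer emitting the same CSQ dialect the reader parses.

Sites are simulated without linkage disequilibrium.  The sharing statistic
samples one variant per chromosome precisely to blunt LD effects, so
unlinked sites are a faithful null for it; this is a documented limitation
for anything LD-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import CapacityError, ConfigurationError, PedigreeError
from .panel_filter import BUILTIN_GENE_SETS, GeneSet, builtin_gene_sets
from .pedigree import PedigreeSpec, pedigree_for_kinship
from .trio_filters import is_nonsynonymous, is_rare
from .variant_model import (Annotation, AnnotationConfig,
                            DEFAULT_ANNOTATION_CONFIG, Genotype,
                            GenotypeMatrix, Sample, VariantRecord,
                            karyotype_sort_key, normalize_chrom)

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: site allocation across chr1-22 and X, proportional to approximate
#: protein-coding gene content per chromosome
DEFAULT_CHROMOSOME_WEIGHTS: Mapping[str, float] = {
    "1": 2000, "2": 1200, "3": 1000, "4": 750, "5": 900, "6": 1000,
    "7": 900, "8": 700, "9": 800, "10": 700, "11": 1300, "12": 1000,
    "13": 300, "14": 600, "15": 600, "16": 800, "17": 1200, "18": 270,
    "19": 1400, "20": 500, "21": 200, "22": 400, "X": 800,
}

#: chromosome placement for the built-in panel genes (used by the tiled
#: gene model so panel scans have realistically located targets)
PANEL_GENE_CHROM: Mapping[str, str] = {
    "ATP8B1": "18", "ABCB11": "2", "ABCB4": "7", "TJP2": "9", "BAAT": "9",
    "CYP7A1": "8", "CYP7B1": "8", "HSD3B7": "16", "AKR1D1": "7",
    "AKR1C1": "10", "RXRA": "9", "SLC27A5": "19",
    "ABCC2": "10", "ABCC4": "13", "NR1H4": "12", "SLC10A1": "14",
    "SLCO1B1": "12",
    "CYP2C19": "10", "CYP2C9": "10", "KRT8": "12", "KRT18": "12",
    "NAT2": "8", "SERPINA1": "14",
    "APOB": "2", "LMF1": "16", "MTTP": "4", "PEMT": "17", "PNPLA3": "22",
}


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumParams:
    """Parameters of the simulated site-frequency spectrum.

    The rare component is log-uniform on ``rare_maf_range``; the common
    component is a Beta(*common_beta*) rescaled onto (0.01, 0.5).  ``EUR``
    frequencies are the ``GLOBAL`` draw times a bounded multiplicative
    noise factor in ``[1 - eur_noise, 1 + eur_noise]``, clipped to (0, 1),
    so population-selection code paths see genuinely discordant panels.
    """

    n_sites: int = 5000
    rare_fraction: float = 0.95
    rare_maf_range: tuple = (4e-3, 1e-2)
    common_beta: tuple = (2.0, 5.0)
    chromosome_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_WEIGHTS))
    indel_fraction: float = 0.025
    eur_noise: float = 0.2

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise ConfigurationError("rare_fraction must be in [0,1]")
        lo, hi = self.rare_maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("rare_maf_range must satisfy 0 < lo < hi < 1")


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_spectrum(params: SpectrumParams = SpectrumParams(),
                      rng=None) -> list:
    """Simulate annotated-but-unlabelled sites: positions strictly increasing
    within each chromosome, GLOBAL and EUR frequencies per site."""
    rng = _rng(rng)
    chroms = sorted(params.chromosome_weights, key=karyotype_sort_key)
    w = np.array([params.chromosome_weights[c] for c in chroms], dtype=float)
    counts = rng.multinomial(params.n_sites, w / w.sum())
    records = []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        pos = np.cumsum(rng.integers(100, 50_000, size=n)) + 10_000
        is_rare_site = rng.random(n) < params.rare_fraction
        lo, hi = params.rare_maf_range
        rare = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        a, b = params.common_beta
        common = 0.01 + rng.beta(a, b, size=n) * 0.49
        gmaf = np.where(is_rare_site, rare, common)
        noise = rng.uniform(1.0 - params.eur_noise, 1.0 + params.eur_noise, size=n)
        eur = np.clip(gmaf * noise, 1e-6, 0.999)
        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        is_indel = rng.random(n) < params.indel_fraction
        ins_len = rng.integers(1, 4, size=n)
        for i in range(n):
            ref = _BASES[ref_idx[i]]
            alt = _BASES[(ref_idx[i] + alt_shift[i]) % 4]
            if is_indel[i]:
                tail = "".join(_BASES[(ref_idx[i] + j) % 4]
                               for j in range(1, ins_len[i] + 1))
                if i % 2 == 0:
                    alt = ref + tail      # insertion
                else:
                    ref, alt = ref + tail, ref  # deletion
            records.append(VariantRecord(
                chrom=chrom, pos=int(pos[i]), ref=ref, alt=alt,
                annotation=Annotation(maf={"GLOBAL": float(gmaf[i]),
                                           "EUR": float(eur[i])}),
            ))
    return records


# ---------------------------------------------------------------------------
# Gene model + labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int
    end: int


def tile_gene_model(sites: Sequence[VariantRecord],
                    sites_per_gene: int = 25,
                    intergenic_every: int = 10) -> list:
    """Deterministically tile consecutive sites into gene intervals.

    Panel genes are placed on their real chromosomes; remaining blocks get
    filler symbols.  Every ``intergenic_every``-th block is left intergenic
    so the gene-absent code path is exercised.
    """
    by_chrom: dict = {}
    for s in sites:
        by_chrom.setdefault(normalize_chrom(s.chrom), []).append(s)
    panel_queue: dict = {}
    for gene, chrom in PANEL_GENE_CHROM.items():
        panel_queue.setdefault(chrom, []).append(gene)
    intervals = []
    for chrom in sorted(by_chrom, key=karyotype_sort_key):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        queue = list(panel_queue.get(chrom, []))
        block_i = 0
        for start in range(0, len(chrom_sites), sites_per_gene):
            block = chrom_sites[start:start + sites_per_gene]
            block_i += 1
            if intergenic_every and block_i % intergenic_every == 0:
                continue
            gene = queue.pop(0) if queue else f"GENE{chrom}_{block_i:03d}"
            intervals.append(GeneInterval(gene=gene, chrom=chrom,
                                          start=block[0].pos, end=block[-1].pos))
    return intervals


def _validate_gene_model(intervals: Sequence[GeneInterval]) -> None:
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ConfigurationError(
                    f"overlapping gene intervals on chr{chrom}: "
                    f"{a.gene} and {b.gene}"
                )


@dataclass
class LabelModel:
    """Categorical distribution of annotation labels for genic sites.

    ``consequence_probs`` lists (consequence, impact, weight); SIFT and
    PolyPhen labels are drawn only for missense sites, deleterious/damaging
    with the given probabilities (split between the two damaging tiers).
    """

    consequence_probs: tuple = (
        ("missense_variant", "MODERATE", 0.42),
        ("synonymous_variant", "LOW", 0.40),
        ("intron_variant", "MODIFIER", 0.06),
        ("3_prime_UTR_variant", "MODIFIER", 0.05),
        ("splice_region_variant", "LOW", 0.03),
        ("frameshift_variant", "HIGH", 0.02),
        ("stop_gained", "HIGH", 0.01),
        ("splice_acceptor_variant", "HIGH", 0.01),
    )
    sift_deleterious_prob: float = 0.25
    polyphen_damaging_prob: float = 0.25


def annotate_sites(sites: Sequence[VariantRecord],
                   gene_model: Sequence[GeneInterval],
                   label_model: LabelModel = LabelModel(),
                   rng=None) -> list:
    """Assign gene symbols by interval and draw annotation labels."""
    rng = _rng(rng)
    _validate_gene_model(gene_model)
    by_chrom: dict = {}
    for iv in gene_model:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    weights = np.array([w for _, _, w in label_model.consequence_probs])
    weights = weights / weights.sum()
    out = []
    for site in sites:
        chrom = normalize_chrom(site.chrom)
        gene = ""
        for iv in by_chrom.get(chrom, ()):
            if iv.start <= site.pos <= iv.end:
                gene = iv.gene
                break
        if not gene:
            ann = replace(site.annotation, gene="",
                          consequence="intergenic_variant", impact="MODIFIER",
                          sift="missing", polyphen="missing")
            out.append(site.with_annotation(ann))
            continue
        k = int(rng.choice(len(weights), p=weights))
        consequence, impact, _ = label_model.consequence_probs[k]
        sift = polyphen = "missing"
        if consequence == "missense_variant":
            sift = ("deleterious" if rng.random() < label_model.sift_deleterious_prob
                    else "tolerated")
            if rng.random() < label_model.polyphen_damaging_prob:
                polyphen = ("probably_damaging" if rng.random() < 0.5
                            else "possibly_damaging")
            else:
                polyphen = "benign"
        ann = replace(site.annotation, gene=gene, consequence=consequence,
                      impact=impact, sift=sift, polyphen=polyphen)
        out.append(site.with_annotation(ann))
    return out


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def gene_drop(pedigree: PedigreeSpec, sites: Sequence[VariantRecord],
              rng=None, population: str = "EUR") -> dict:
    """Drop founder alleles through the pedigree; returns role -> [Genotype].

    Founder haplotypes are independent Bernoulli(MAF) draws (HWE); each
    transmission passes one uniformly chosen allele from each parent.
    X transmission respects sex: fathers pass their single X to daughters
    only; sons are hemizygous for a maternal allele.
    """
    rng = _rng(rng)
    n = len(sites)
    p = np.array([s.annotation.maf_of(population) for s in sites], dtype=float)
    if np.any(np.isnan(p)):
        raise ConfigurationError("all sites need a MAF for gene dropping")
    is_x = np.array([normalize_chrom(s.chrom) == "X" for s in sites])
    haps: dict = {}
    for mid in pedigree.topological_order():
        m = pedigree.members[mid]
        if m.is_founder:
            hm = rng.random(n) < p
            hp = rng.random(n) < p
        else:
            mhm, mhp = haps[m.mother]
            fhm, fhp = haps[m.father]
            hm = np.where(rng.random(n) < 0.5, mhm, mhp)
            hp = np.where(rng.random(n) < 0.5, fhm, fhp)
        if m.sex == "M":
            # single X: mirror the maternal allele into the paternal slot so
            # a daughter always receives the father's one X
            hp = np.where(is_x, hm, hp)
        haps[mid] = (hm, hp)
    out = {}
    for role, mid in pedigree.target_samples.items():
        hm, hp = haps[mid]
        male = pedigree.members[mid].sex == "M"
        gts = []
        for i in range(n):
            if is_x[i] and male:
                gts.append(Genotype.haploid(int(hm[i])))
            else:
                gts.append(Genotype.diploid(int(hm[i]), int(hp[i])))
        out[role] = gts
    return out


def matrix_from_gene_drop(sites: Sequence[VariantRecord],
                          genotypes_by_role: Mapping[str, Sequence[Genotype]],
                          family_id: str = "FAM",
                          affected: Optional[Mapping[str, bool]] = None) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from gene-dropped role genotypes."""
    affected = affected or {}
    roles = [r for r in ("child", "mother", "father") if r in genotypes_by_role]
    samples = [Sample(sample_id=f"{family_id}_{r}", role=r,
                      affected=affected.get(r, r == "child")) for r in roles]
    grid = [[genotypes_by_role[r][i] for r in roles] for i in range(len(sites))]
    return GenotypeMatrix(variants=list(sites), samples=samples,
                          genotypes=grid, family_id=family_id)


def estimate_kinship(matrix: GenotypeMatrix, role_a: str, role_b: str,
                     population: str = "EUR", min_maf: float = 0.05) -> float:
    """Moment estimate of kinship from common-variant genotype correlation.

    Dosages are standardised per site by the population frequency,
    z = (d - 2p) / sqrt(2 p (1 - p)), so heterogeneous frequencies do not
    inflate the estimate; E[z_a z_b] = 2 phi, hence phi_hat is half the mean
    cross-product.  Uses autosomal diploid sites with MAF >= *min_maf*.
    """
    ia, ib = matrix.role_index(role_a), matrix.role_index(role_b)
    za, zb = [], []
    for vi, rec in enumerate(matrix.variants):
        if normalize_chrom(rec.chrom) == "X":
            continue
        maf = rec.annotation.maf_of(population)
        if maf is None or maf < min_maf:
            continue
        ga, gb = matrix.genotypes[vi][ia], matrix.genotypes[vi][ib]
        if ga.is_missing or gb.is_missing or ga.ploidy != 2 or gb.ploidy != 2:
            continue
        sd = np.sqrt(2.0 * maf * (1.0 - maf))
        za.append((ga.n_alt - 2.0 * maf) / sd)
        zb.append((gb.n_alt - 2.0 * maf) / sd)
    if len(za) < 2:
        raise ConfigurationError("not enough common sites to estimate kinship")
    return float(np.mean(np.array(za) * np.array(zb)) / 2.0)


# ---------------------------------------------------------------------------
# Ground-truth injection
# ---------------------------------------------------------------------------

@dataclass
class InjectionSpec:
    """How many ground-truth variants to plant per filter class.

    The recessive ladder is nested: of ``recessive_total`` homozygous-
    recessive variants, ``recessive_rare`` are rare, of which
    ``recessive_nonsynonymous`` are protein-altering, of which
    ``recessive_deleterious`` are predicted deleterious.
    """

    recessive_total: int = 10
    recessive_rare: int = 4
    recessive_nonsynonymous: int = 3
    recessive_deleterious: int = 2
    compound_het_pairs: int = 2
    de_novo: int = 0
    panel_hits: Mapping[str, int] = field(default_factory=lambda: {
        "cholestatic_disease": 1,
        "bile_acid_metabolism": 1,
        "bile_secretion_transport": 1,
    })
    rare_maf: float = 0.001
    common_maf: float = 0.2

    def __post_init__(self):
        if not (self.recessive_total >= self.recessive_rare
                >= self.recessive_nonsynonymous >= self.recessive_deleterious >= 0):
            raise ConfigurationError("recessive ladder counts must be nested")


def _ann_with(ann: Annotation, maf: float, consequence: str, impact: str,
              sift: str, polyphen: str) -> Annotation:
    return replace(ann, consequence=consequence, impact=impact, sift=sift,
                   polyphen=polyphen, maf={"GLOBAL": maf, "EUR": maf})


def inject_ground_truth(matrix: GenotypeMatrix, spec: InjectionSpec,
                        rng=None,
                        gene_sets: Optional[Sequence[GeneSet]] = None,
                        rarity_threshold: float = 0.01,
                        neutralize: bool = True):
    """Overwrite genotypes/annotations to realise each class exactly.

    Returns ``(new_matrix, manifest)`` where the manifest maps every
    injected variant to its ground-truth class.  With ``neutralize=True``
    (the default for exact-recovery fixtures) background sites that would
    confound a class are rewritten: spontaneous recessive-homozygote
    patterns become het/het/het trios, potential compound-het partners are
    made biparental, and rare nonsynonymous background hits inside panel
    genes are relabelled synonymous.  All rewrites stay Mendelian-consistent.
    """
    rng = _rng(rng)
    gene_sets = list(gene_sets) if gene_sets is not None else builtin_gene_sets()
    panel_union = {g for gs in gene_sets for g in gs.genes}
    ci = matrix.role_index("child")
    mi = matrix.role_index("mother")
    fi = matrix.role_index("father")
    if ci is None or mi is None or fi is None:
        raise ConfigurationError("injection requires a full trio matrix")
    unaffected_cols = [j for j, s in enumerate(matrix.samples)
                       if not s.affected]

    variants = list(matrix.variants)
    grid = [list(row) for row in matrix.genotypes]

    def autosomal_diploid(vi: int) -> bool:
        return (normalize_chrom(variants[vi].chrom) != "X"
                and all(g.ploidy == 2 for g in grid[vi]))

    pool = [vi for vi in range(len(variants)) if autosomal_diploid(vi)]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    taken: set = set()
    manifest_rows = []

    def take(predicate, what: str) -> int:
        for vi in pool:
            if vi in taken:
                continue
            if predicate(vi):
                taken.add(vi)
                return vi
        raise CapacityError(f"no remaining site available for {what}")

    def record(vi: int, truth_class: str, detail: str = "") -> None:
        rec = variants[vi]
        manifest_rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alt, "gene": rec.annotation.gene,
            "truth_class": truth_class, "detail": detail,
        })

    def not_panel(vi: int) -> bool:
        return variants[vi].annotation.gene.upper() not in panel_union

    # --- recessive ladder ------------------------------------------------
    n_common = spec.recessive_total - spec.recessive_rare
    n_rare_syn = spec.recessive_rare - spec.recessive_nonsynonymous
    n_tolerated = spec.recessive_nonsynonymous - spec.recessive_deleterious
    ladder = (
        [("recessive_common", spec.common_maf, "missense_variant", "MODERATE",
          "tolerated", "benign")] * n_common
        + [("recessive_rare_synonymous", spec.rare_maf, "synonymous_variant",
            "LOW", "missing", "missing")] * n_rare_syn
        + [("recessive_rare_nonsyn_tolerated", spec.rare_maf,
            "missense_variant", "MODERATE", "tolerated", "benign")] * n_tolerated
        + [("recessive_rare_nonsyn_deleterious", spec.rare_maf,
            "missense_variant", "MODERATE", "deleterious",
            "probably_damaging")] * spec.recessive_deleterious
    )
    for truth_class, maf, csq, impact, sift, poly in ladder:
        vi = take(not_panel, truth_class)
        variants[vi] = variants[vi].with_annotation(
            _ann_with(variants[vi].annotation, maf, csq, impact, sift, poly))
        grid[vi][ci] = Genotype.diploid(1, 1)
        grid[vi][mi] = Genotype.diploid(0, 1)
        grid[vi][fi] = Genotype.diploid(0, 1)
        record(vi, truth_class)

    # --- compound-het pairs (one gene per pair, in trans by origin) ------
    by_gene: dict = {}
    for vi in pool:
        if vi in taken or not not_panel(vi):
            continue
        gene = variants[vi].annotation.gene
        if gene:
            by_gene.setdefault(gene, []).append(vi)
    pair_genes = [g for g, vs in by_gene.items() if len(vs) >= 2]
    if len(pair_genes) < spec.compound_het_pairs:
        raise CapacityError("not enough multi-site genes for compound-het pairs")
    for pair_i in range(spec.compound_het_pairs):
        gene = pair_genes[pair_i]
        v1, v2 = by_gene[gene][:2]
        for vi, carrier_col in ((v1, mi), (v2, fi)):
            taken.add(vi)
            variants[vi] = variants[vi].with_annotation(
                _ann_with(variants[vi].annotation, spec.rare_maf,
                          "missense_variant", "MODERATE", "tolerated", "benign"))
            grid[vi][ci] = Genotype.diploid(0, 1)
            grid[vi][mi] = Genotype.diploid(0, 1) if carrier_col == mi else Genotype.diploid(0, 0)
            grid[vi][fi] = Genotype.diploid(0, 1) if carrier_col == fi else Genotype.diploid(0, 0)
            record(vi, "compound_het_member", detail=f"pair{pair_i + 1}")

    # --- de novo ---------------------------------------------------------
    for i in range(spec.de_novo):
        vi = take(not_panel, "de_novo")
        variants[vi] = variants[vi].with_annotation(
            _ann_with(variants[vi].annotation, spec.rare_maf,
                      "missense_variant", "MODERATE", "deleterious",
                      "probably_damaging"))
        grid[vi][ci] = Genotype.diploid(0, 1)
        grid[vi][mi] = Genotype.diploid(0, 0)
        grid[vi][fi] = Genotype.diploid(0, 0)
        record(vi, "de_novo")

    # --- panel hits (child het, one carrier parent, distinct genes) ------
    # genes belonging to several categories would be reported once per
    # category, so exact-recovery hits are planted in single-category genes
    categories_of: dict = {}
    for gs in gene_sets:
        for g in gs.genes:
            categories_of.setdefault(g, set()).add(gs.category)
    used_panel_genes: set = set()
    for category, count in spec.panel_hits.items():
        cat_genes = {g for g, cats in categories_of.items()
                     if cats == {category}}
        if count and not cat_genes:
            raise ConfigurationError(
                f"no single-category gene available for {category!r}")
        for i in range(count):
            def in_category(vi: int, _genes=cat_genes) -> bool:
                g = variants[vi].annotation.gene.upper()
                return g in _genes and g not in used_panel_genes
            vi = take(in_category, f"panel hit in {category}")
            used_panel_genes.add(variants[vi].annotation.gene.upper())
            variants[vi] = variants[vi].with_annotation(
                _ann_with(variants[vi].annotation, spec.rare_maf,
                          "missense_variant", "MODERATE", "tolerated", "benign"))
            carrier = mi if rng.random() < 0.5 else fi
            grid[vi][ci] = Genotype.diploid(0, 1)
            grid[vi][mi] = Genotype.diploid(0, 1) if carrier == mi else Genotype.diploid(0, 0)
            grid[vi][fi] = Genotype.diploid(0, 1) if carrier == fi else Genotype.diploid(0, 0)
            record(vi, f"panel_hit:{category}")

    # --- background neutralisation ---------------------------------------
    if neutralize:
        for vi in range(len(variants)):
            if vi in taken:
                continue
            child = grid[vi][ci]
            # spontaneous recessive-homozygote pattern
            if child.hom_alt:
                if child.ploidy == 2:
                    grid[vi][ci] = Genotype.diploid(0, 1)
                else:
                    grid[vi][ci] = Genotype.haploid(0)
                for j in (mi, fi):
                    g = grid[vi][j]
                    if g.ploidy == 2:
                        grid[vi][j] = Genotype.diploid(0, 1)
                child = grid[vi][ci]
            # potential compound-het partner: make it biparental
            gene = variants[vi].annotation.gene
            if gene and child.het:
                gm, gf = grid[vi][mi], grid[vi][fi]
                if not gm.is_missing and not gf.is_missing:
                    if gm.carrier != gf.carrier:
                        if not gm.carrier and gm.ploidy == 2:
                            grid[vi][mi] = Genotype.diploid(0, 1)
                        elif not gf.carrier:
                            grid[vi][fi] = (Genotype.diploid(0, 1)
                                            if gf.ploidy == 2 else Genotype.haploid(1))
            # rare nonsynonymous background inside a panel gene
            ann = variants[vi].annotation
            if (gene and gene.upper() in panel_union and grid[vi][ci].carrier
                    and is_nonsynonymous(ann)
                    and (is_rare(ann, rarity_threshold, "GLOBAL")
                         or is_rare(ann, rarity_threshold, "EUR"))):
                variants[vi] = variants[vi].with_annotation(
                    replace(ann, consequence="synonymous_variant",
                            impact="LOW", sift="missing", polyphen="missing"))

    manifest = pd.DataFrame(
        manifest_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "truth_class", "detail"],
    )
    new_matrix = GenotypeMatrix(variants=variants, samples=list(matrix.samples),
                                genotypes=grid, family_id=matrix.family_id)
    return new_matrix.sorted_copy(), manifest.sort_values(
        ["truth_class", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# High-level family simulation
# ---------------------------------------------------------------------------

def simulate_family(
    kinship: float = 0.0,
    spectrum: SpectrumParams = None,
    label_model: LabelModel = None,
    inject: Optional[InjectionSpec] = None,
    rng=None,
    family_id: str = "FAM1",
    child_sex: str = "F",
    duo: bool = False,
    annotate: bool = True,
):
    """One call from pedigree to (GenotypeMatrix, truth manifest or None).

    ``kinship`` selects the parent-pair relationship (0, 1/64, 1/16, 1/4);
    ``duo=True`` drops the father from the emitted samples (mother-child
    duo, as when only one parent is available).
    """
    rng = _rng(rng)
    spectrum = spectrum or SpectrumParams()
    sites = simulate_spectrum(spectrum, rng)
    if annotate:
        model = tile_gene_model(sites)
        sites = annotate_sites(sites, model, label_model or LabelModel(), rng)
    ped = pedigree_for_kinship(kinship, child=True, child_sex=child_sex)
    dropped = gene_drop(ped, sites, rng)
    if duo:
        dropped = {r: g for r, g in dropped.items() if r != "father"}
    matrix = matrix_from_gene_drop(sites, dropped, family_id=family_id)
    manifest = None
    if inject is not None:
        matrix, manifest = inject_ground_truth(matrix, inject, rng)
    return matrix, manifest


def simulate_cohort(
    family_kinships: Sequence[float],
    spectrum: SpectrumParams = None,
    label_model: LabelModel = None,
    rng=None,
    duo_families: Sequence[int] = (),
    child_sexes: Optional[Sequence[str]] = None,
    annotate: bool = True,
    family_prefix: str = "FAM",
):
    """Several families gene-dropped over one shared site panel.

    Mimics a jointly called cohort: every family's matrix covers the same
    (chrom, pos, ref, alt) keys, so cross-family comparisons (the
    inter-family father baseline) have overlapping variants.  Families whose
    index appears in *duo_families* are emitted without the father.
    Returns ``(sites, [GenotypeMatrix, ...])``.
    """
    rng = _rng(rng)
    spectrum = spectrum or SpectrumParams()
    sites = simulate_spectrum(spectrum, rng)
    if annotate:
        model = tile_gene_model(sites)
        sites = annotate_sites(sites, model, label_model or LabelModel(), rng)
    matrices = []
    for i, phi in enumerate(family_kinships):
        sex = child_sexes[i] if child_sexes else "F"
        ped = pedigree_for_kinship(phi, child=True, child_sex=sex)
        dropped = gene_drop(ped, sites, rng)
        if i in duo_families:
            dropped = {r: g for r, g in dropped.items() if r != "father"}
        matrices.append(matrix_from_gene_drop(
            sites, dropped, family_id=f"{family_prefix}{i + 1}"))
    return sites, matrices


def simulate_parent_pair(kinship: float = 0.0,
                         spectrum: SpectrumParams = None,
                         rng=None, family_id: str = "PAIR") -> GenotypeMatrix:
    """A father+mother pair (no child, no labels) for the sharing statistic."""
    rng = _rng(rng)
    spectrum = spectrum or SpectrumParams()
    sites = simulate_spectrum(spectrum, rng)
    ped = pedigree_for_kinship(kinship, child=False)
    dropped = gene_drop(ped, sites, rng)
    return matrix_from_gene_drop(sites, dropped, family_id=family_id)


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

def _csq_block(rec: VariantRecord, config: AnnotationConfig) -> str:
    a = rec.annotation
    inverse_maf = {col: pop for pop, col in config.maf_fields.items()}
    parts = []
    for name in config.csq_fields:
        if name == "Allele":
            parts.append(rec.alt)
        elif name == "SYMBOL":
            parts.append(a.gene)
        elif name == "Consequence":
            parts.append(a.consequence)
        elif name == "IMPACT":
            parts.append("" if a.impact == "UNKNOWN" else a.impact)
        elif name == "HGVSp":
            parts.append(a.protein_change)
        elif name == "SIFT":
            parts.append("" if a.sift == "missing" else a.sift)
        elif name == "PolyPhen":
            parts.append("" if a.polyphen == "missing" else a.polyphen)
        elif name in inverse_maf:
            f = a.maf.get(inverse_maf[name])
            parts.append("" if f is None else f"{f:.6g}")
        else:
            parts.append("")
    return "|".join(parts)


def write_family_vcf(matrix: GenotypeMatrix, path: Union[str, Path],
                     config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG,
                     merge_multiallelic: bool = False) -> Path:
    """Write the family as VCF 4.2 with the CSQ dialect the reader parses.

    With ``merge_multiallelic=True``, consecutive records sharing
    (chrom, pos, ref) are emitted as one multi-allelic line (per-sample alt
    counts must fit the ploidy); used to exercise split-on-ingest.
    """
    path = Path(path)
    m = matrix.sorted_copy()
    chroms = []
    for rec in m.variants:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        f'##INFO=<ID={config.csq_tag},Number=.,Type=String,Description='
        f'"Consequence annotations. Format: {"|".join(config.csq_fields)}">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    sample_ids = [s.sample_id for s in m.samples]
    lines.append("#" + "\t".join(
        ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        + sample_ids))

    groups: list = []
    for vi, rec in enumerate(m.variants):
        key = (rec.chrom, rec.pos, rec.ref)
        if merge_multiallelic and groups and groups[-1][0] == key:
            groups[-1][1].append(vi)
        else:
            groups.append([key, [vi]])

    for (chrom, pos, ref), vis in groups:
        alts = [m.variants[vi].alt for vi in vis]
        csq = ",".join(_csq_block(m.variants[vi], config) for vi in vis)
        gts = []
        for j in range(len(m.samples)):
            per_alt = [m.genotypes[vi][j] for vi in vis]
            if len(vis) == 1:
                gts.append(per_alt[0].vcf_string())  # preserve allele order
                continue
            if any(g.is_missing for g in per_alt):
                gts.append("/".join("." * per_alt[0].ploidy)
                           if per_alt[0].ploidy > 1 else ".")
                continue
            ploidy = per_alt[0].ploidy
            alleles = []
            for k, g in enumerate(per_alt, start=1):
                alleles.extend([k] * g.n_alt)
            if len(alleles) > ploidy:
                raise ValueError(
                    f"cannot merge {chrom}:{pos}: alt alleles exceed ploidy")
            alleles = [0] * (ploidy - len(alleles)) + alleles
            gts.append("/".join(str(a) for a in sorted(alleles)))
        variant_id = m.variants[vis[0]].id or "."
        lines.append("\t".join(
            [chrom, str(pos), variant_id, ref, ",".join(alts), ".", "PASS",
             f"{config.csq_tag}={csq}", "GT"] + gts))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_roles_yaml(matrix: GenotypeMatrix, path: Union[str, Path]) -> Path:
    """Emit the sample-id -> role map (plus affected flags) as YAML."""
    path = Path(path)
    payload = {
        "family_id": matrix.family_id,
        "roles": {s.sample_id: s.role for s in matrix.samples},
        "affected": {s.sample_id: bool(s.affected) for s in matrix.samples},
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    return path
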