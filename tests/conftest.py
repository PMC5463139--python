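"""Shared test fixtures and small builders."""

import numpy as np
import pytest

from triokin.variant_model import (Annotation, Genotype, GenotypeMatrix,
                                   Sample, VariantRecord)


def gt(s: str) -> Genotype:
    """Parse '0/1', './.', '1' (haploid), '.' (haploid missing)."""
    alleles = tuple(None if a == "." else int(a) for a in s.split("/"))
    return Genotype(alleles)


def ann(gene="G1", consequence="missense_variant", impact="MODERATE",
        sift="missing", polyphen="missing", gmaf=None, eur=None,
        protein_change="") -> Annotation:
    return Annotation(gene=gene, consequence=consequence, impact=impact,
                      sift=sift, polyphen=polyphen,
                      maf={"GLOBAL": gmaf, "EUR": eur},
                      protein_change=protein_change)


def make_trio(rows, annotations=None, chrom="1", affected_mother=False,
              affected_father=False, family_id="T1") -> GenotypeMatrix:
    """Build a trio matrix from [(child, mother, father), ...] GT strings.

    Variants are placed at consecutive positions on *chrom* (a list of
    chroms is also accepted) with default annotations unless given.
    """
    chroms = chrom if isinstance(chrom, (list, tuple)) else [chrom] * len(rows)
    annotations = annotations or [ann()] * len(rows)
    variants = [
        VariantRecord(chrom=chroms[i], pos=1000 + i, ref="A", alt="T",
                      annotation=annotations[i])
        for i in range(len(rows))
    ]
    samples = [
        Sample("C", "child", affected=True),
        Sample("M", "mother", affected=affected_mother),
        Sample("F", "father", affected=affected_father),
    ]
    grid = [[gt(c), gt(m), gt(f)] for c, m, f in rows]
    return GenotypeMatrix(variants=variants, samples=samples, genotypes=grid,
                          family_id=family_id)


def make_duo(rows, annotations=None, chrom="1", parent_role="mother",
             family_id="D1") -> GenotypeMatrix:
    """[(child, parent), ...] GT strings -> child + one parent matrix."""
    annotations = annotations or [ann()] * len(rows)
    variants = [
        VariantRecord(chrom=chrom, pos=1000 + i, ref="A", alt="T",
                      annotation=annotations[i])
        for i in range(len(rows))
    ]
    samples = [Sample("C", "child", affected=True), Sample("P", parent_role)]
    grid = [[gt(c), gt(p)] for c, p in rows]
    return GenotypeMatrix(variants=variants, samples=samples, genotypes=grid,
                          family_id=family_id)


@pytest.fixture(scope="session")
def injected_family():
    """A gene-dropped trio with the default ground-truth injection."""
    from triokin.synthetic_data import InjectionSpec, simulate_family

    matrix, manifest = simulate_family(rng=np.random.default_rng(1),
                                       inject=InjectionSpec(),
                                       family_id="FIX1")
    return matrix, manifest
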