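"""Segregation classification and the rarity/deleteriousness filter cascade.

Implements the inheritance-model filters applied per family (recessive
homozygous, dominant in two modes, compound heterozygous), the annotation
predicates (nonsynonymous, deleterious in silico, rare), and the monotone
count ladder summarising how many of the child's recessive-homozygous
variants survive each successive filter.

Conventions shared by every classifier:

* a variant found homozygous-alternate in an *unaffected* parent is never
  reported, regardless of any other criterion;
* a missing genotype disqualifies a variant from any positive call
  (conservative false-negative bias rather than imputation);
* hemizygous alt genotypes count as homozygous-equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

from .errors import ConfigurationError, PhaseUndeterminedError
from .variant_model import Annotation, GenotypeMatrix

log = logging.getLogger(__name__)

SEGREGATION_LABELS = (
    "recessive_homozygous", "dominant", "compound_het_member", "de_novo",
    "unclassified", "excluded_parental_homozygote",
)

#: consequence terms considered protein-altering
PROTEIN_ALTERING_TERMS = frozenset({
    "missense_variant", "stop_gained", "stop_lost", "start_lost",
    "frameshift_variant", "inframe_insertion", "inframe_deletion",
    "protein_altering_variant", "incomplete_terminal_codon_variant",
    "transcript_ablation", "transcript_amplification",
})
#: splice terms that rescue an otherwise excluded variant unconditionally
SPLICE_STRONG_TERMS = frozenset({
    "splice_donor_variant", "splice_acceptor_variant",
})
#: splice_region only counts when the annotator rated the site >= MODERATE,
#: so LOW-impact near-splice synonymous calls do not flood the reports
SPLICE_REGION_TERMS = frozenset({"splice_region_variant"})

_KNOWN_EXCLUDED_TERMS = frozenset({
    "synonymous_variant", "stop_retained_variant", "start_retained_variant",
    "intron_variant", "intergenic_variant", "upstream_gene_variant",
    "downstream_gene_variant", "5_prime_utr_variant", "3_prime_utr_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant", "non_coding_transcript_variant",
    "non_coding_transcript_exon_variant", "regulatory_region_variant",
    "tf_binding_site_variant", "mature_mirna_variant", "nmd_transcript_variant",
    "coding_sequence_variant",
})

_warned_terms: set = set()


# ---------------------------------------------------------------------------
# Annotation predicates
# ---------------------------------------------------------------------------

def is_nonsynonymous(annotation: Annotation) -> bool:
    """True iff the consequence is protein-altering or splice-affecting.

    Synonymous, intronic, UTR and other non-coding/MODIFIER terms are
    excluded; splice donor/acceptor always rescue, splice_region rescues
    only at impact >= MODERATE.
    """
    terms = {t.strip() for t in annotation.consequence.split("&") if t.strip()}
    if not terms:
        return False
    if terms & PROTEIN_ALTERING_TERMS:
        return True
    if terms & SPLICE_STRONG_TERMS:
        return True
    if terms & SPLICE_REGION_TERMS and annotation.impact in ("MODERATE", "HIGH"):
        return True
    for t in terms:
        if (t not in _KNOWN_EXCLUDED_TERMS and t not in SPLICE_REGION_TERMS
                and t not in _warned_terms):
            _warned_terms.add(t)
            log.warning("unknown consequence term %r treated as not protein-altering", t)
    return False


def is_deleterious_in_silico(annotation: Annotation) -> bool:
    """Deleterious by SIFT, or damaging by PolyPhen, or annotator impact HIGH.

    Missing predictors contribute False (they cannot rescue a variant).
    """
    return (
        annotation.sift in ("deleterious", "deleterious_low_confidence")
        or annotation.polyphen in ("probably_damaging", "possibly_damaging")
        or annotation.impact == "HIGH"
    )


def is_rare(annotation: Annotation, threshold: float, population: str) -> bool:
    """MAF in *population* missing (novel -> rare) or strictly below *threshold*."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigurationError(f"rarity threshold must be in (0,1], got {threshold}")
    maf = annotation.maf_of(population)
    return maf is None or maf < threshold


# ---------------------------------------------------------------------------
# Segregation classifiers
# ---------------------------------------------------------------------------

def _require_child(matrix: GenotypeMatrix) -> int:
    i = matrix.role_index("child")
    if i is None:
        raise ConfigurationError("matrix has no child sample")
    return i


def _parental_homozygote(matrix: GenotypeMatrix, vi: int) -> bool:
    """True if any unaffected parent is hom_alt at variant *vi*."""
    for sample, col in matrix.parents:
        gt = matrix.genotypes[vi][col]
        if not sample.affected and gt.hom_alt:
            return True
    return False


def classify_recessive(matrix: GenotypeMatrix) -> set:
    """Variant keys consistent with autosomal-recessive inheritance.

    Trio: child hom_alt and both parents het.  Duo: child hom_alt and the
    available parent a carrier but not hom_alt.  Variants hom_alt in an
    unaffected parent are excluded; missing parental genotypes disqualify.
    """
    ci = _require_child(matrix)
    parents = matrix.parents
    if not parents:
        raise ConfigurationError(
            "recessive classification needs at least one parent; "
            "use single-sample reporting for parent-less data"
        )
    out = set()
    for vi, rec in enumerate(matrix.variants):
        child = matrix.genotypes[vi][ci]
        if not child.hom_alt:
            continue
        gts = [matrix.genotypes[vi][col] for _, col in parents]
        if any(g.is_missing for g in gts):
            continue
        if _parental_homozygote(matrix, vi):
            continue
        if len(parents) == 2:
            if all(g.het for g in gts):
                out.add(rec.key)
        else:
            g = gts[0]
            if g.carrier and not g.hom_alt:
                out.add(rec.key)
    return out


def classify_dominant(matrix: GenotypeMatrix, mode: str = "de_novo") -> set:
    """Variant keys consistent with a dominant model.

    ``mode="de_novo"``: child het and every available parent hom_ref.
    ``mode="affected_parent"``: child het and the carriers among the parents
    are exactly the affected parent(s).  Missing parental genotypes
    disqualify; unaffected-parent homozygotes are excluded as always.
    """
    if mode not in ("de_novo", "affected_parent"):
        raise ConfigurationError(f"unknown dominant mode {mode!r}")
    ci = _require_child(matrix)
    parents = matrix.parents
    if mode == "affected_parent" and not any(s.affected for s, _ in parents):
        raise ConfigurationError(
            "dominant mode 'affected_parent' requires at least one parent "
            "flagged affected"
        )
    out = set()
    for vi, rec in enumerate(matrix.variants):
        child = matrix.genotypes[vi][ci]
        if not child.het:
            continue
        gts = [(s, matrix.genotypes[vi][col]) for s, col in parents]
        if any(g.is_missing for _, g in gts):
            continue
        if _parental_homozygote(matrix, vi):
            continue
        if mode == "de_novo":
            if all(g.hom_ref for _, g in gts):
                out.add(rec.key)
        else:
            if all((g.carrier if s.affected else g.hom_ref) for s, g in gts):
                out.add(rec.key)
    return out


def find_compound_het(matrix: GenotypeMatrix) -> Mapping[str, list]:
    """Per-gene compound-heterozygote pairs, phased by parental origin.

    A pair (v1, v2) in the same non-empty gene qualifies iff the child is
    het at both, v1 is carried by exactly one parent and v2 by exactly the
    other (in trans by origin).  Requires both parents (duo phasing is
    undetermined and raises rather than silently returning nothing).
    """
    ci = _require_child(matrix)
    parents = matrix.parents
    if len(parents) != 2:
        raise PhaseUndeterminedError(
            "compound-heterozygote phasing by parental origin requires both "
            "parents; phase is undetermined for duo input"
        )
    # gene -> list of (key, origin role) for child-het variants carried by
    # exactly one parent and not excluded
    by_gene: dict = {}
    for vi, rec in enumerate(matrix.variants):
        gene = rec.annotation.gene
        if not gene:
            continue
        child = matrix.genotypes[vi][ci]
        if not child.het:
            continue
        gts = [(s, matrix.genotypes[vi][col]) for s, col in parents]
        if any(g.is_missing for _, g in gts):
            continue
        if _parental_homozygote(matrix, vi):
            continue
        carriers = [s.role for s, g in gts if g.carrier]
        if len(carriers) != 1:
            continue
        by_gene.setdefault(gene, []).append((rec.key, carriers[0]))
    out: dict = {}
    for gene, members in by_gene.items():
        pairs = [
            tuple(sorted((k1, k2)))
            for (k1, o1), (k2, o2) in combinations(members, 2)
            if o1 != o2
        ]
        if pairs:
            out[gene] = sorted(set(pairs))
    return out


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterCascadeCounts:
    """The per-child monotone count ladder.

    Each stage filters the previous stage's survivors, so
    ``recessive_homozygous >= rare >= nonsynonymous >= deleterious_in_silico``;
    totals are over all variants present in (carried by) the child.
    """

    total_variants: int
    snps: int
    indels: int
    recessive_homozygous: int
    rare: int
    nonsynonymous: int
    deleterious_in_silico: int
    rarity_threshold: float

    def __post_init__(self):
        assert self.total_variants == self.snps + self.indels
        assert (self.recessive_homozygous >= self.rare >= self.nonsynonymous
                >= self.deleterious_in_silico)

    def to_dict(self) -> dict:
        return {
            "total_variants": self.total_variants,
            "snps": self.snps,
            "indels": self.indels,
            "recessive_homozygous": self.recessive_homozygous,
            "rare": self.rare,
            "nonsynonymous": self.nonsynonymous,
            "deleterious_in_silico": self.deleterious_in_silico,
            "rarity_threshold": self.rarity_threshold,
        }


def cascade_counts(matrix: GenotypeMatrix, threshold: float = 0.01,
                   population: str = "GLOBAL") -> FilterCascadeCounts:
    """Apply the fixed filter order recessive -> rare -> nonsynonymous ->
    deleterious and count survivors at each stage."""
    ci = _require_child(matrix)
    ann_by_key = {rec.key: rec.annotation for rec in matrix.variants}
    total = snps = 0
    for vi, rec in enumerate(matrix.variants):
        if matrix.genotypes[vi][ci].carrier:
            total += 1
            if rec.is_snp:
                snps += 1
    recessive = classify_recessive(matrix)
    rare = {k for k in recessive if is_rare(ann_by_key[k], threshold, population)}
    nonsyn = {k for k in rare if is_nonsynonymous(ann_by_key[k])}
    deleterious = {k for k in nonsyn if is_deleterious_in_silico(ann_by_key[k])}
    return FilterCascadeCounts(
        total_variants=total,
        snps=snps,
        indels=total - snps,
        recessive_homozygous=len(recessive),
        rare=len(rare),
        nonsynonymous=len(nonsyn),
        deleterious_in_silico=len(deleterious),
        rarity_threshold=threshold,
    )
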