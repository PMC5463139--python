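"""Gene-panel candidate scan.

Intersects a family's filtered variants with curated gene panels (cholestatic
disease genes, bile-acid metabolism, bile secretion/transport, other liver
disease genes, lipid metabolism) and emits categorised candidate rows in the
style of a clinical report: one row per (category, variant), with the carrier
list spelled out ("patient and father").

Gene matching is by uppercased symbol, because the panels are symbol lists
from pathway/disease databases and the annotation supplies symbols.  A small
built-in set of illustrative panels (containing the canonical hereditary-
cholestasis genes) ships with the package; real analyses should supply their
own lists, one symbol per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigurationError
from .trio_filters import is_nonsynonymous, is_rare
from .variant_model import GenotypeMatrix, karyotype_sort_key

log = logging.getLogger(__name__)

CATEGORIES = (
    "cholestatic_disease",
    "bile_acid_metabolism",
    "bile_secretion_transport",
    "liver_disease_other",
    "lipid_metabolism",
)

#: Small illustrative panels built around the canonical hereditary-cholestasis
#: and bile-handling genes; stand-ins for full pathway-database exports.
BUILTIN_GENE_SETS: Mapping[str, tuple] = {
    "cholestatic_disease": (
        "ABCB11", "ABCB4", "AKR1D1", "ATP8B1", "BAAT", "CYP7A1", "CYP7B1",
        "HSD3B7", "TJP2",
    ),
    "bile_acid_metabolism": (
        "AKR1C1", "AKR1D1", "BAAT", "CYP7A1", "CYP7B1", "HSD3B7", "RXRA",
        "SLC27A5",
    ),
    "bile_secretion_transport": (
        "ABCB11", "ABCB4", "ABCC2", "ABCC4", "NR1H4", "SLC10A1", "SLCO1B1",
    ),
    "liver_disease_other": (
        "CYP2C19", "CYP2C9", "KRT18", "KRT8", "NAT2", "SERPINA1",
    ),
    "lipid_metabolism": (
        "APOB", "LMF1", "MTTP", "PEMT", "PNPLA3",
    ),
}


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    genes: frozenset

    def __post_init__(self):
        if not self.name:
            raise ConfigurationError("gene set needs a non-empty name")
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"unknown panel category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


def builtin_gene_sets() -> list:
    return [GeneSet(name=f"builtin_{cat}", category=cat, genes=frozenset(genes))
            for cat, genes in BUILTIN_GENE_SETS.items()]


def load_gene_set(path: Union[str, Path], category: str,
                  name: Optional[str] = None) -> GeneSet:
    """Read a one-symbol-per-line gene list ('#' comments, blank lines ok)."""
    path = Path(path)
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip().upper()
            if sym:
                genes.add(sym)
    if not genes:
        log.warning("gene list %s produced an empty set", path)
    return GeneSet(name=name or path.stem, category=category,
                   genes=frozenset(genes))


def load_gene_sets(paths: Mapping[str, Union[str, Path]]) -> list:
    """Load one gene list per category from a category -> path mapping."""
    return [load_gene_set(p, category=cat) for cat, p in paths.items()]


def write_gene_lists(directory: Union[str, Path],
                     gene_sets: Optional[Iterable[GeneSet]] = None) -> dict:
    """Write gene lists (defaults to the built-ins) as plain-text files;
    returns the category -> path map suitable for load_gene_sets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for gs in (gene_sets or builtin_gene_sets()):
        p = directory / f"{gs.category}.txt"
        p.write_text("\n".join(sorted(gs.genes)) + "\n", encoding="utf-8")
        out[gs.category] = p
    return out


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------

_ROLE_PHRASE = {"child": "patient", "mother": "mother", "father": "father"}


@dataclass(frozen=True)
class CandidateRow:
    category: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str
    consequence: str
    impact: str
    sift: str
    polyphen: str
    maf: Optional[float]
    rare: bool
    whitelisted: bool
    carriers: str          # e.g. "patient and father"
    genotypes: tuple       # ((sample_id, gt string), ...)

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CandidateReport:
    family_id: str
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["category", "chrom", "pos", "ref", "alt", "gene",
                "protein_change", "consequence", "impact", "sift", "polyphen",
                "maf", "rare", "whitelisted", "carriers"]
        recs = []
        for r in sorted(self.rows, key=lambda r: (CATEGORIES.index(r.category),
                                                  karyotype_sort_key(r.chrom),
                                                  r.pos, r.ref, r.alt)):
            d = {c: getattr(r, c) for c in cols}
            d["maf"] = "." if r.maf is None else f"{r.maf:.6g}"
            for sid, gt in r.genotypes:
                d[f"GT_{sid}"] = gt
            recs.append(d)
        return pd.DataFrame(recs, columns=None if recs else cols)

    def category_counts(self) -> dict:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.rows:
            counts[r.category] += 1
        return counts


def _whitelist_match(whitelist, rec) -> bool:
    a = rec.annotation
    keys = {
        f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}",
        f"{a.gene}:{a.protein_change}" if a.gene and a.protein_change else None,
    }
    return any(w in keys for w in whitelist)


def scan_panels(
    matrix: GenotypeMatrix,
    gene_sets: Sequence[GeneSet],
    rarity_threshold: float = 0.01,
    population: str = "GLOBAL",
    whitelist: Sequence[str] = (),
) -> CandidateReport:
    """Report child-carried panel-gene variants per category.

    A variant is reported under every category whose gene set contains its
    gene, provided it is nonsynonymous, not homozygous-alternate in any
    unaffected parent, and either rare in *population* or explicitly
    whitelisted as a reportable common polymorphism (whitelist entries are
    ``chrom:pos:ref:alt`` or ``GENE:protein_change`` strings).  A gene that
    belongs to two categories is reported under both.
    """
    from .trio_filters import _parental_homozygote, _require_child

    ci = _require_child(matrix)
    report = CandidateReport(family_id=matrix.family_id)
    for vi, rec in enumerate(matrix.variants):
        ann = rec.annotation
        gene = ann.gene.upper()
        if not gene:
            continue
        child = matrix.genotypes[vi][ci]
        if not child.carrier:
            continue
        if not is_nonsynonymous(ann):
            continue
        if _parental_homozygote(matrix, vi):
            continue
        rare = is_rare(ann, rarity_threshold, population)
        whitelisted = _whitelist_match(whitelist, rec)
        if not (rare or whitelisted):
            continue
        carrier_roles = [s.role for j, s in enumerate(matrix.samples)
                         if matrix.genotypes[vi][j].carrier]
        carriers = " and ".join(_ROLE_PHRASE[r] for r in ("child", "mother", "father")
                                if r in carrier_roles)
        gts = tuple((s.sample_id, matrix.genotypes[vi][j].vcf_string())
                    for j, s in enumerate(matrix.samples))
        for gs in gene_sets:
            if gene in gs.genes:
                report.rows.append(CandidateRow(
                    category=gs.category, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=rec.alt, gene=gene,
                    protein_change=ann.protein_change,
                    consequence=ann.consequence, impact=ann.impact,
                    sift=ann.sift, polyphen=ann.polyphen,
                    maf=ann.maf.get(population),
                    rare=rare, whitelisted=whitelisted,
                    carriers=carriers, genotypes=gts,
                ))
    return report
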