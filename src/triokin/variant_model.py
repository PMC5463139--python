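"""Core variant domain model.

Bi-allelic variant records, genotypes, family genotype matrices, VCF ingest
(with multi-allelic splitting on the way in), VEP-style CSQ annotation parsing,
and TSV report writing.  Everything downstream (segregation filters, panel
scan, consanguinity statistic) operates on these types.

Coordinates are 1-based inclusive throughout (VCF convention).  The identity
key used to match a variant across samples and families is
``(chrom, pos, ref, alt)`` after multi-allelic splitting; no indel
normalisation/left-alignment is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, VcfParseError

log = logging.getLogger(__name__)

VariantKey = tuple  # (chrom, pos, ref, alt)

#: Human karyotype ordering used for every sorted output.
KARYOTYPE = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
_KORDER = {c: i for i, c in enumerate(KARYOTYPE)}

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER", "UNKNOWN")
_IMPACT_SEVERITY = {"HIGH": 4, "MODERATE": 3, "LOW": 2, "MODIFIER": 1, "UNKNOWN": 0}

SIFT_LABELS = frozenset(
    {"deleterious", "deleterious_low_confidence", "tolerated",
     "tolerated_low_confidence", "missing"}
)
POLYPHEN_LABELS = frozenset(
    {"probably_damaging", "possibly_damaging", "benign", "missing"}
)

ROLES = ("child", "mother", "father")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; 'chrX' and 'X' are the same contig."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c == "M" else c


def karyotype_sort_key(chrom: str):
    c = normalize_chrom(chrom)
    return (_KORDER.get(c, len(KARYOTYPE)), c)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    """Functional annotation bundle attached to one bi-allelic variant.

    ``maf`` maps population name (e.g. ``GLOBAL``, ``EUR``) to an allele
    frequency in [0, 1] or ``None`` when the variant is absent from that
    reference panel.  Missing (``None``) is deliberately distinct from 0.0:
    a frequency of zero is an observation, absence is not.
    """

    gene: str = ""
    consequence: str = ""
    impact: str = "UNKNOWN"
    sift: str = "missing"
    polyphen: str = "missing"
    maf: Mapping[str, Optional[float]] = field(default_factory=dict)
    protein_change: str = ""

    def __post_init__(self):
        if self.impact not in _IMPACT_SEVERITY:
            object.__setattr__(self, "impact", "UNKNOWN")
        if self.sift not in SIFT_LABELS:
            object.__setattr__(self, "sift", "missing")
        if self.polyphen not in POLYPHEN_LABELS:
            object.__setattr__(self, "polyphen", "missing")
        for pop, f in self.maf.items():
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"MAF for {pop} outside [0,1]: {f}")

    def maf_of(self, population: str) -> Optional[float]:
        """Frequency for *population*; raises if the population is unknown."""
        if population not in self.maf:
            raise ConfigurationError(
                f"unknown population {population!r}; available: "
                f"{sorted(self.maf) or 'none'}"
            )
        return self.maf[population]


EMPTY_ANNOTATION = Annotation()


# ---------------------------------------------------------------------------
# Variant record and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic variant site (post multi-allelic splitting)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: Annotation = EMPTY_ANNOTATION
    id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_annotation(self, annotation: Annotation) -> "VariantRecord":
        return replace(self, annotation=annotation)


@dataclass(frozen=True)
class Genotype:
    """Genotype of one sample at one bi-allelic site.

    ``alleles`` holds 0 (ref), 1 (alt) or ``None`` (missing) per chromosome
    copy; length is the ploidy (2 on autosomes and female X, 1 on male X).
    The classification helpers hom_ref / het / hom_alt / missing are mutually
    exclusive and exhaustive; a hemizygous alt genotype classifies as hom_alt
    (homozygous-equivalent for the exclusion and recessive rules).
    """

    alleles: tuple

    def __post_init__(self):
        if len(self.alleles) not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        for a in self.alleles:
            if a not in (0, 1, None):
                raise ValueError(f"allele index must be 0, 1 or missing, got {a}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def diploid(a: Optional[int], b: Optional[int]) -> "Genotype":
        return Genotype((a, b))

    @staticmethod
    def haploid(a: Optional[int]) -> "Genotype":
        return Genotype((a,))

    @staticmethod
    def missing_gt(ploidy: int = 2) -> "Genotype":
        return Genotype((None,) * ploidy)

    # -- classification ----------------------------------------------
    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def het(self) -> bool:
        return not self.is_missing and len(set(self.alleles)) == 2

    @property
    def hom_alt(self) -> bool:
        # hemizygous alt (ploidy 1) counts as homozygous-equivalent
        return not self.is_missing and all(a == 1 for a in self.alleles)

    @property
    def carrier(self) -> bool:
        return not self.is_missing and any(a == 1 for a in self.alleles)

    @property
    def n_alt(self) -> int:
        """Count of alt alleles among the called alleles."""
        return sum(1 for a in self.alleles if a == 1)

    def vcf_string(self) -> str:
        return "/".join("." if a is None else str(a) for a in self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.vcf_string()


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str
    affected: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")


@dataclass
class GenotypeMatrix:
    """Genotypes of one family (or parent pair) across its samples.

    Rows are variants, columns are samples.  At most one ``child``, at most
    one ``mother`` and one ``father``; parent-pair matrices without a child
    are allowed (they back the inter-family baseline statistic).
    """

    variants: list
    samples: list
    genotypes: list  # genotypes[variant_index][sample_index] -> Genotype
    family_id: str = ""

    def __post_init__(self):
        roles = [s.role for s in self.samples]
        for r in set(roles):
            if roles.count(r) > 1:
                raise ConfigurationError(f"duplicate role {r!r} in family")
        if len(self.genotypes) != len(self.variants):
            raise ValueError("genotype grid rows != number of variants")
        for row in self.genotypes:
            if len(row) != len(self.samples):
                raise ValueError("genotype grid columns != number of samples")

    # -- lookups -------------------------------------------------------
    def role_index(self, role: str) -> Optional[int]:
        for i, s in enumerate(self.samples):
            if s.role == role:
                return i
        return None

    def sample_for_role(self, role: str) -> Optional[Sample]:
        i = self.role_index(role)
        return None if i is None else self.samples[i]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def parents(self) -> list:
        """(Sample, column index) for each parent present."""
        out = []
        for role in ("mother", "father"):
            i = self.role_index(role)
            if i is not None:
                out.append((self.samples[i], i))
        return out

    def gt(self, variant_index: int, role: str) -> Genotype:
        i = self.role_index(role)
        if i is None:
            raise ConfigurationError(f"no sample with role {role!r}")
        return self.genotypes[variant_index][i]

    def sorted_copy(self) -> "GenotypeMatrix":
        order = sorted(
            range(len(self.variants)),
            key=lambda i: (karyotype_sort_key(self.variants[i].chrom),
                           self.variants[i].pos, self.variants[i].ref,
                           self.variants[i].alt),
        )
        return GenotypeMatrix(
            variants=[self.variants[i] for i in order],
            samples=list(self.samples),
            genotypes=[self.genotypes[i] for i in order],
            family_id=self.family_id,
        )


# ---------------------------------------------------------------------------
# Multi-allelic splitting
# ---------------------------------------------------------------------------

def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Sequence[Sequence[Optional[int]]],
    variant_id: Optional[str] = None,
    annotations: Optional[Sequence[Annotation]] = None,
):
    """Split a (possibly multi-allelic) site into bi-allelic records.

    One output record per alternate allele, in input ALT order.  In the
    record for allele *k* (1-based ALT index), input allele index *k* maps
    to 1 and every other non-reference index maps to 0 (reference-
    equivalent); missing alleles stay missing.  Returns a list of
    ``(VariantRecord, [Genotype per sample])``.
    """
    if not alts:
        raise ValueError("at least one alternate allele required")
    anns = annotations or [EMPTY_ANNOTATION] * len(alts)
    if len(anns) != len(alts):
        raise ValueError("annotations must align with alts")
    out = []
    for k, alt in enumerate(alts, start=1):
        rec = VariantRecord(chrom=normalize_chrom(chrom), pos=pos, ref=ref,
                            alt=alt, annotation=anns[k - 1], id=variant_id)
        gts = []
        for sample_alleles in genotypes:
            remapped = tuple(
                None if a is None else (1 if a == k else 0)
                for a in sample_alleles
            )
            gts.append(Genotype(remapped))
        out.append((rec, gts))
    return out


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Declares where annotations come from and how to read them.

    Either a VEP-style CSQ INFO field (``csq_fields`` gives the ``|``-separated
    subfield order; ``maf_fields`` maps population name to subfield name) or a
    tab-delimited sidecar keyed by chrom, pos, ref, alt.
    """

    csq_tag: str = "CSQ"
    csq_fields: tuple = (
        "Allele", "SYMBOL", "Consequence", "IMPACT", "HGVSp",
        "SIFT", "PolyPhen", "GMAF", "EUR_MAF",
    )
    maf_fields: Mapping[str, str] = field(
        default_factory=lambda: {"GLOBAL": "GMAF", "EUR": "EUR_MAF"}
    )
    sidecar: Optional[Path] = None

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AnnotationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"csq_tag", "csq_fields", "maf_fields", "sidecar"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown annotation config keys: {sorted(unknown)}"
            )
        if "csq_fields" in raw:
            raw["csq_fields"] = tuple(raw["csq_fields"])
        if raw.get("sidecar"):
            raw["sidecar"] = Path(raw["sidecar"])
        return cls(**raw)


DEFAULT_ANNOTATION_CONFIG = AnnotationConfig()


def _clean_predictor(value: str, labels: frozenset) -> str:
    """'tolerated_low_confidence(0.2)' -> 'tolerated_low_confidence'."""
    label = value.split("(")[0].strip().lower()
    return label if label in labels else "missing"


def _parse_maf(value: str, context: str) -> Optional[float]:
    v = value.strip()
    if v in ("", ".", "-", "NA"):
        return None
    try:
        f = float(v)
    except ValueError:
        log.warning("unparseable frequency %r in %s; treated as missing", v, context)
        return None
    if not (0.0 <= f <= 1.0):
        log.warning("frequency %r outside [0,1] in %s; treated as missing", v, context)
        return None
    return f


def parse_annotation(raw: Optional[str],
                     config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG) -> Annotation:
    """Parse a CSQ INFO string into an :class:`Annotation`.

    Total: never raises on arbitrary strings.  When several transcript blocks
    are present the block with the most severe impact is kept (tie -> first
    listed).  Absent/unknown fields map to missing/UNKNOWN, never to 0.0.
    """
    populations = {pop: None for pop in config.maf_fields}
    if raw is None or raw == "":
        return Annotation(maf=populations)

    best = None
    best_sev = -1
    for block in str(raw).split(","):
        parts = block.split("|")
        fields = {}
        for name, value in zip(config.csq_fields, parts):
            fields[name] = value
        impact = fields.get("IMPACT", "").strip().upper()
        if impact not in _IMPACT_SEVERITY:
            impact = "UNKNOWN"
        sev = _IMPACT_SEVERITY[impact]
        if sev > best_sev:
            best_sev = sev
            best = (fields, impact)
    fields, impact = best
    maf = {
        pop: _parse_maf(fields.get(col, ""), f"CSQ field {col}")
        for pop, col in config.maf_fields.items()
    }
    return Annotation(
        gene=fields.get("SYMBOL", "").strip(),
        consequence=fields.get("Consequence", "").strip(),
        impact=impact,
        sift=_clean_predictor(fields.get("SIFT", ""), SIFT_LABELS),
        polyphen=_clean_predictor(fields.get("PolyPhen", ""), POLYPHEN_LABELS),
        maf=maf,
        protein_change=fields.get("HGVSp", "").strip(),
    )


def load_sidecar(path: Union[str, Path],
                 config: AnnotationConfig) -> Mapping[VariantKey, Annotation]:
    """Read a tab-delimited annotation sidecar keyed by chrom,pos,ref,alt."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"sidecar {path} must contain columns {sorted(required)}"
        )
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        maf = {
            pop: _parse_maf(d.get(col, ""), f"sidecar column {col}")
            for pop, col in config.maf_fields.items()
        }
        key = (normalize_chrom(d["chrom"]), int(d["pos"]), d["ref"], d["alt"])
        out[key] = Annotation(
            gene=d.get("gene", "").strip(),
            consequence=d.get("consequence", "").strip(),
            impact=(d.get("impact", "").strip().upper() or "UNKNOWN"),
            sift=_clean_predictor(d.get("sift", ""), SIFT_LABELS),
            polyphen=_clean_predictor(d.get("polyphen", ""), POLYPHEN_LABELS),
            maf=maf,
            protein_change=d.get("protein_change", "").strip(),
        )
    return out


# ---------------------------------------------------------------------------
# VCF ingest
# ---------------------------------------------------------------------------

def _cyvcf2_genotype(gt_row) -> Genotype:
    """Convert a cyvcf2 per-sample genotype row ([a0, a1, phased]) to allele
    indices; -1 means missing."""
    alleles = tuple(None if a < 0 else int(a) for a in gt_row[:-1])
    if not alleles:
        alleles = (None, None)
    return alleles  # raw allele indices; remapped during splitting


def read_family_vcf(
    paths: Union[str, Path, Sequence[Union[str, Path]]],
    roles: Mapping[str, str],
    annotation_config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG,
    affected: Optional[Mapping[str, bool]] = None,
    family_id: str = "",
) -> GenotypeMatrix:
    """Read one family's VCF(s) into a :class:`GenotypeMatrix`.

    *paths* may be one multi-sample VCF or several per-sample VCFs; *roles*
    maps each sample id of interest to child/mother/father.  Multi-allelic
    records are split on ingest.  A sample lacking a record at a site is
    genotype-missing (an explicit 0/0 call is hom_ref); sites are matched
    across files by (chrom, pos, ref, alt).
    """
    import cyvcf2

    if isinstance(paths, (str, Path)):
        paths = [paths]
    role_values = list(roles.values())
    for r in set(role_values):
        if role_values.count(r) > 1:
            raise ConfigurationError(f"role {r!r} mapped to more than one sample")
        if r not in ROLES:
            raise ConfigurationError(f"unknown role {r!r}")
    affected = dict(affected or {})

    sidecar = (load_sidecar(annotation_config.sidecar, annotation_config)
               if annotation_config.sidecar else None)

    # variant key -> (record, {sample_id: raw allele tuple})
    sites: dict = {}
    seen_samples: list = []
    for path in paths:
        try:
            vcf = cyvcf2.VCF(str(path))
        except Exception as exc:  # pragma: no cover - cyvcf2 error paths
            raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
        file_samples = [s for s in vcf.samples if s in roles]
        for s in file_samples:
            if s not in seen_samples:
                seen_samples.append(s)
        cols = [vcf.samples.index(s) for s in file_samples]
        for lineno, v in enumerate(vcf, start=1):
            alts = list(v.ALT or [])
            if not alts:
                continue
            try:
                raw_gts = [_cyvcf2_genotype(v.genotypes[c]) for c in cols]
                csq = v.INFO.get(annotation_config.csq_tag)
                ann = parse_annotation(csq, annotation_config)
                split = split_multiallelic(
                    v.CHROM, v.POS, v.REF, alts, raw_gts,
                    variant_id=(v.ID or None),
                    annotations=[ann] * len(alts),
                )
            except (ValueError, TypeError) as exc:
                raise VcfParseError(
                    f"malformed VCF record at {path} line ~{lineno} "
                    f"({v.CHROM}:{v.POS}): {exc}"
                ) from exc
            for rec, gts in split:
                entry = sites.setdefault(rec.key, [rec, {}])
                if entry[0].annotation is EMPTY_ANNOTATION and rec.annotation is not EMPTY_ANNOTATION:
                    entry[0] = rec
                for sid, gt in zip(file_samples, gts):
                    entry[1][sid] = gt
        vcf.close()

    missing_ids = set(roles) - set(seen_samples)
    if missing_ids:
        raise ConfigurationError(
            f"sample id(s) {sorted(missing_ids)} not found in {list(map(str, paths))}"
        )

    samples = [
        Sample(sid, roles[sid], affected=affected.get(sid, roles[sid] == "child"))
        for sid in roles
    ]
    ordered = sorted(sites.values(),
                     key=lambda e: (karyotype_sort_key(e[0].chrom), e[0].pos,
                                    e[0].ref, e[0].alt))
    variants, grid = [], []
    for rec, per_sample in ordered:
        if sidecar is not None and rec.key in sidecar:
            rec = rec.with_annotation(sidecar[rec.key])
        variants.append(rec)
        grid.append([per_sample.get(s.sample_id, Genotype.missing_gt())
                     for s in samples])
    return GenotypeMatrix(variants=variants, samples=samples,
                          genotypes=grid, family_id=family_id)


# ---------------------------------------------------------------------------
# TSV report writing
# ---------------------------------------------------------------------------

def variant_table(
    records: Sequence[VariantRecord],
    genotypes: Optional[Sequence[Sequence[Genotype]]] = None,
    samples: Optional[Sequence[Sample]] = None,
    labels: Optional[Mapping[str, Sequence]] = None,
) -> pd.DataFrame:
    """Assemble the standard variant report table, karyotype-sorted."""
    pops = sorted({p for r in records for p in r.annotation.maf})
    rows = []
    for i, rec in enumerate(records):
        a = rec.annotation
        row = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
            "id": rec.id or ".",
            "gene": a.gene or ".",
            "protein_change": a.protein_change or ".",
            "consequence": a.consequence or ".",
            "impact": a.impact,
            "sift": a.sift,
            "polyphen": a.polyphen,
        }
        for pop in pops:
            f = a.maf.get(pop)
            row[f"MAF_{pop}"] = "." if f is None else f"{f:.6g}"
        if genotypes is not None and samples is not None:
            for j, s in enumerate(samples):
                row[f"GT_{s.sample_id}"] = genotypes[i][j].vcf_string()
        if labels:
            for name, values in labels.items():
                row[name] = values[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    if not rows:
        cols = ["chrom", "pos", "ref", "alt", "id", "gene", "protein_change",
                "consequence", "impact", "sift", "polyphen"]
        if samples:
            cols += [f"GT_{s.sample_id}" for s in samples]
        df = pd.DataFrame(columns=cols)
    if len(df):
        order = sorted(range(len(records)),
                       key=lambda i: (karyotype_sort_key(records[i].chrom),
                                      records[i].pos, records[i].ref,
                                      records[i].alt))
        df = df.iloc[order].reset_index(drop=True)
    return df


def write_variant_table(
    records: Sequence[VariantRecord],
    path: Union[str, Path],
    genotypes: Optional[Sequence[Sequence[Genotype]]] = None,
    samples: Optional[Sequence[Sample]] = None,
    labels: Optional[Mapping[str, Sequence]] = None,
) -> Path:
    """Write the variant report as UTF-8 TSV ('.' for missing)."""
    df = variant_table(records, genotypes, samples, labels)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
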