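"""Run orchestration: ingest -> trio filters -> panel scan -> consanguinity.

A single validated YAML/JSON config drives one or more families; outputs are
per-family TSV/JSON reports plus a cohort summary.  Re-running with the same
config and seed reproduces byte-identical payloads (timestamps are confined
to the run log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import consanguinity as consang
from . import trio_filters
from .errors import ConfigurationError, TriokinError
from .panel_filter import (CATEGORIES, builtin_gene_sets, load_gene_sets,
                           scan_panels)
from .variant_model import (AnnotationConfig, GenotypeMatrix,
                            read_family_vcf, write_variant_table)

log = logging.getLogger(__name__)


@dataclass
class FamilyConfig:
    family_id: str
    vcfs: list
    roles: Mapping[str, str]
    affected: Mapping[str, bool] = field(default_factory=dict)


@dataclass
class RunConfig:
    families: list
    output_dir: Path
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    gene_lists: Optional[Mapping[str, Path]] = None
    rarity_threshold: float = 0.01
    population: str = "GLOBAL"
    dominant_mode: str = "de_novo"
    common_whitelist: tuple = ()
    consanguinity_thresholds: tuple = consang.DEFAULT_THRESHOLDS
    consanguinity_population: str = consang.DEFAULT_POPULATION
    consanguinity_reps: int = consang.DEFAULT_REPS
    seed: int = 0


_TOP_KEYS = {
    "families", "output_dir", "annotation", "gene_lists", "rarity_threshold",
    "population", "dominant_mode", "common_whitelist", "consanguinity", "seed",
}
_CONSANG_KEYS = {"thresholds", "population", "reps"}
_FAMILY_KEYS = {"id", "vcfs", "vcf", "roles", "affected"}


def _type_error(key: str, expected: str, value) -> ConfigurationError:
    return ConfigurationError(
        f"config key {key!r}: expected {expected}, got {type(value).__name__}"
    )


def validate_config(path: Union[str, Path]) -> RunConfig:
    """Load, default and strictly validate a run config (YAML or JSON).

    Unknown keys are hard errors so typos cannot silently change behaviour.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) {sorted(unknown)}; known: {sorted(_TOP_KEYS)}"
        )
    base = path.parent

    def respath(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "families" not in raw or not isinstance(raw["families"], list) or not raw["families"]:
        raise ConfigurationError("config needs a non-empty 'families' list")
    families = []
    for fam in raw["families"]:
        unknown = set(fam) - _FAMILY_KEYS
        if unknown:
            raise ConfigurationError(f"unknown family key(s) {sorted(unknown)}")
        if "id" not in fam:
            raise ConfigurationError("each family needs an 'id'")
        vcfs = fam.get("vcfs") or ([fam["vcf"]] if fam.get("vcf") else None)
        if not vcfs:
            raise ConfigurationError(f"family {fam['id']}: needs 'vcf' or 'vcfs'")
        vcfs = [respath(v) for v in vcfs]
        for v in vcfs:
            if not v.exists():
                raise ConfigurationError(f"family {fam['id']}: missing VCF {v}")
        roles = fam.get("roles")
        if not isinstance(roles, dict) or not roles:
            raise _type_error(f"families[{fam['id']}].roles", "mapping", roles)
        role_list = list(roles.values())
        for r in set(role_list):
            if role_list.count(r) > 1:
                raise ConfigurationError(
                    f"family {fam['id']}: role {r!r} assigned to several samples")
        families.append(FamilyConfig(
            family_id=str(fam["id"]), vcfs=vcfs, roles=dict(roles),
            affected=dict(fam.get("affected") or {}),
        ))
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("family ids must be unique")

    ann = AnnotationConfig()
    if "annotation" in raw:
        a = dict(raw["annotation"])
        unknown = set(a) - {"csq_tag", "csq_fields", "maf_fields", "sidecar"}
        if unknown:
            raise ConfigurationError(f"unknown annotation key(s) {sorted(unknown)}")
        if "csq_fields" in a:
            a["csq_fields"] = tuple(a["csq_fields"])
        if a.get("sidecar"):
            a["sidecar"] = respath(a["sidecar"])
        ann = AnnotationConfig(**a)

    gene_lists = None
    if raw.get("gene_lists"):
        gene_lists = {}
        for cat, p in raw["gene_lists"].items():
            if cat not in CATEGORIES:
                raise ConfigurationError(
                    f"unknown gene list category {cat!r}; expected {CATEGORIES}")
            p = respath(p)
            if not p.exists():
                raise ConfigurationError(f"missing gene list {p}")
            gene_lists[cat] = p

    cons = dict(raw.get("consanguinity") or {})
    unknown = set(cons) - _CONSANG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown consanguinity key(s) {sorted(unknown)}")

    threshold = float(raw.get("rarity_threshold", 0.01))
    if not (0.0 < threshold <= 1.0):
        raise ConfigurationError("rarity_threshold must be in (0,1]")
    mode = raw.get("dominant_mode", "de_novo")
    if mode not in ("de_novo", "affected_parent"):
        raise ConfigurationError(f"unknown dominant_mode {mode!r}")

    return RunConfig(
        families=families,
        output_dir=respath(raw.get("output_dir", "triokin_run")),
        annotation=ann,
        gene_lists=gene_lists,
        rarity_threshold=threshold,
        population=str(raw.get("population", "GLOBAL")),
        dominant_mode=mode,
        common_whitelist=tuple(raw.get("common_whitelist") or ()),
        consanguinity_thresholds=tuple(float(t) for t in
                                       cons.get("thresholds",
                                                consang.DEFAULT_THRESHOLDS)),
        consanguinity_population=str(cons.get("population",
                                              consang.DEFAULT_POPULATION)),
        consanguinity_reps=int(cons.get("reps", consang.DEFAULT_REPS)),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _segregation_tables(matrix: GenotypeMatrix, config: RunConfig,
                        famdir: Path) -> dict:
    """Write per-inheritance-model variant TSVs; returns model -> count."""
    counts = {}
    by_key = {rec.key: vi for vi, rec in enumerate(matrix.variants)}

    def write(keys, name):
        vis = sorted(by_key[k] for k in keys)
        write_variant_table(
            [matrix.variants[vi] for vi in vis], famdir / f"{name}.tsv",
            genotypes=[matrix.genotypes[vi] for vi in vis],
            samples=matrix.samples,
        )
        counts[name] = len(vis)

    write(trio_filters.classify_recessive(matrix), "recessive")
    try:
        write(trio_filters.classify_dominant(matrix, config.dominant_mode),
              f"dominant_{config.dominant_mode}")
    except ConfigurationError as exc:
        log.warning("family %s: dominant model skipped: %s",
                    matrix.family_id, exc)
    try:
        pairs = trio_filters.find_compound_het(matrix)
        rows = []
        for gene, gene_pairs in sorted(pairs.items()):
            for i, (k1, k2) in enumerate(gene_pairs, start=1):
                for k in (k1, k2):
                    rows.append({"gene": gene, "pair": i,
                                 "chrom": k[0], "pos": k[1],
                                 "ref": k[2], "alt": k[3]})
        pd.DataFrame(rows, columns=["gene", "pair", "chrom", "pos", "ref",
                                    "alt"]).to_csv(
            famdir / "compound_het.tsv", sep="\t", index=False)
        counts["compound_het_pairs"] = sum(len(v) for v in pairs.values())
    except TriokinError as exc:
        log.warning("family %s: compound het skipped: %s", matrix.family_id, exc)
        counts["compound_het_pairs"] = None
    return counts


def run_family(matrix: GenotypeMatrix, config: RunConfig, famdir: Path,
               seed: int) -> dict:
    famdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"family_id": matrix.family_id,
                     "samples": {s.sample_id: s.role for s in matrix.samples}}

    cascade = trio_filters.cascade_counts(matrix, config.rarity_threshold,
                                          config.population)
    pd.DataFrame([cascade.to_dict()]).to_csv(
        famdir / "cascade_counts.tsv", sep="\t", index=False)
    summary["cascade"] = cascade.to_dict()

    summary["segregation_counts"] = _segregation_tables(matrix, config, famdir)

    gene_sets = (load_gene_sets(config.gene_lists) if config.gene_lists
                 else builtin_gene_sets())
    report = scan_panels(matrix, gene_sets,
                         rarity_threshold=config.rarity_threshold,
                         population=config.population,
                         whitelist=config.common_whitelist)
    report.to_frame().to_csv(famdir / "candidates.tsv", sep="\t", index=False)
    _json_dump(report.category_counts(), famdir / "category_counts.json")
    summary["panel_counts"] = report.category_counts()

    has_pair = (matrix.role_index("father") is not None
                and matrix.role_index("mother") is not None)
    if has_pair:
        rng = np.random.default_rng(seed)
        profile = consang.consanguinity_profile(
            matrix, thresholds=config.consanguinity_thresholds,
            n_reps=config.consanguinity_reps, rng=rng,
            population=config.consanguinity_population)
        _json_dump({str(t): r.to_dict() for t, r in profile.items()},
                   famdir / "consanguinity.json")
        rep_rows = []
        for t, r in profile.items():
            for i, ratio in enumerate(r.per_rep_ratios, start=1):
                rep_rows.append({"threshold": t, "repetition": i,
                                 "ratio": "NA" if ratio is None else f"{ratio:.6g}"})
        pd.DataFrame(rep_rows).to_csv(famdir / "consanguinity_reps.tsv",
                                      sep="\t", index=False)
        summary["consanguinity_pooled_ratio"] = {
            str(t): r.pooled_ratio for t, r in profile.items()}
    else:
        summary["consanguinity_pooled_ratio"] = None
        summary["consanguinity_note"] = (
            "skipped: statistic requires both parents")
    return summary


def run_pipeline(config: RunConfig,
                 matrices: Optional[Sequence[GenotypeMatrix]] = None) -> Path:
    """Run every family; returns the run directory.

    *matrices* may inject pre-built GenotypeMatrix objects (bypassing VCF
    ingest) for the same family ids; otherwise families are read from their
    configured VCFs.  Per-family failures are isolated; the run fails only
    if every family fails.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines = [f"seed={config.seed}",
                 f"config_hash={_config_hash(config)}"]
    by_id = {m.family_id: m for m in (matrices or [])}

    summaries, failures = [], []
    for i, fam in enumerate(config.families):
        seed = (config.seed * 100_003 + i) % (2 ** 31 - 1)
        try:
            matrix = by_id.get(fam.family_id)
            if matrix is None:
                matrix = read_family_vcf(fam.vcfs, fam.roles,
                                         annotation_config=config.annotation,
                                         affected=fam.affected,
                                         family_id=fam.family_id)
            summaries.append(run_family(matrix, config,
                                        out / fam.family_id, seed))
            log_lines.append(f"family {fam.family_id}: ok")
        except TriokinError as exc:
            failures.append((fam.family_id, str(exc)))
            log_lines.append(f"family {fam.family_id}: FAILED: {exc}")
            log.error("family %s failed: %s", fam.family_id, exc)

    cohort: dict = {
        "n_families": len(config.families),
        "n_failed": len(failures),
        "failures": [{"family_id": f, "error": e} for f, e in failures],
        "families": summaries,
    }
    cascades = [s["cascade"] for s in summaries]
    if cascades:
        cohort["mean_child_counts"] = {
            k: float(np.mean([c[k] for c in cascades]))
            for k in ("total_variants", "snps", "indels",
                      "recessive_homozygous", "rare", "nonsynonymous",
                      "deleterious_in_silico")
        }
    _json_dump(cohort, out / "summary.json")
    log_lines.append(f"elapsed_s={time.time() - t0:.2f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    if failures and len(failures) == len(config.families):
        raise TriokinError("all families failed; see run.log")
    return out


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
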