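"""Resampling-based consanguinity statistic from rare-variant sharing.

The idea: a parent pair that shares recent ancestry shares rare variants
identical by descent far more often than Hardy-Weinberg chance predicts.
The procedure repeatedly samples one rare variant carried by the father from
each chromosome (1-22 and X; Y excluded), checks whether the mother carries
the identical allele, and accumulates

* ``observed``  - the number of sampled variants the mother carries, and
* ``expected``  - the sum over sampled variants of the HWE probability that
  an unrelated individual carries at least one copy, ``1 - (1 - p)**2`` for
  population allele frequency ``p``.

Repeating the draw (default 100 times) at MAF cutoffs 0.01, 0.02, 0.05 and
0.1 gives a per-threshold distribution of per-repetition ratios and a pooled
ratio ``sum(observed) / sum(expected)``.  For unrelated pairs the pooled
ratio is calibrated at 1; consanguineous pairs give ratios far above 1, and
the effect strengthens as the cutoff tightens (rarer variants are more
informative about identity by descent).  Comparing fathers *between*
families provides an empirical unrelated-population baseline.

The family-level scalar is the pooled ratio rather than the mean of
per-repetition ratios: with very rare variants the per-repetition observed
count is frequently 0, making individual ratios unstable, while the pooled
estimator is defined whenever any expectation is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError
from .variant_model import (Genotype, GenotypeMatrix, Sample, VariantKey,
                            karyotype_sort_key, normalize_chrom)

DEFAULT_THRESHOLDS = (0.01, 0.02, 0.05, 0.1)
DEFAULT_POPULATION = "EUR"
DEFAULT_REPS = 100

#: chromosomes sampled: autosomes and X; Y (and anything else) excluded
SAMPLED_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)


@dataclass(frozen=True)
class SharingRepetition:
    """One draw of <=23 father-carried rare variants and its sharing tally."""

    sampled_variants: tuple
    expected: float
    observed: int

    def __post_init__(self):
        assert 0 <= self.observed <= len(self.sampled_variants)
        assert self.expected <= len(self.sampled_variants) + 1e-9

    @property
    def ratio(self) -> Optional[float]:
        return None if self.expected == 0 else self.observed / self.expected


@dataclass
class ConsanguinityResult:
    """Observed/expected sharing for one parent pair at one MAF threshold."""

    threshold: float
    n_reps: int
    repetitions: list
    label: str = ""

    def __post_init__(self):
        assert self.n_reps == len(self.repetitions)

    @property
    def total_observed(self) -> int:
        return sum(r.observed for r in self.repetitions)

    @property
    def total_expected(self) -> float:
        return sum(r.expected for r in self.repetitions)

    @property
    def pooled_ratio(self) -> Optional[float]:
        """sum(observed)/sum(expected); None when no expectation accrued."""
        e = self.total_expected
        return None if e == 0 else self.total_observed / e

    @property
    def per_rep_ratios(self) -> list:
        """observed/expected per repetition; None entries flag undefined."""
        return [r.ratio for r in self.repetitions]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "threshold": self.threshold,
            "n_reps": self.n_reps,
            "total_observed": self.total_observed,
            "total_expected": self.total_expected,
            "pooled_ratio": self.pooled_ratio,
            "per_rep_observed": [r.observed for r in self.repetitions],
            "per_rep_expected": [r.expected for r in self.repetitions],
            "per_rep_ratios": self.per_rep_ratios,
        }


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def expected_sharing_probability(maf: float) -> float:
    """HWE probability an unrelated individual carries >=1 copy: 1-(1-p)^2."""
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must be in (0,1), got {maf}")
    return 1.0 - (1.0 - maf) ** 2


def eligible_father_variants(
    matrix: GenotypeMatrix,
    threshold: float,
    population: str = DEFAULT_POPULATION,
) -> Mapping[str, list]:
    """Father-carried variants with 0 < MAF < threshold, grouped by chromosome.

    Y is excluded.  Variants with missing or zero population MAF are not
    eligible: their HWE expectation is 0 and would degenerate the ratio.
    """
    _require_parent_pair(matrix)
    fi = matrix.role_index("father")
    out: dict = {}
    for vi, rec in enumerate(matrix.variants):
        chrom = normalize_chrom(rec.chrom)
        if chrom not in SAMPLED_CHROMOSOMES:
            continue
        if not matrix.genotypes[vi][fi].carrier:
            continue
        maf = rec.annotation.maf_of(population)
        if maf is None or not (0.0 < maf < threshold):
            continue
        out.setdefault(chrom, []).append(rec.key)
    return {c: out[c] for c in sorted(out, key=karyotype_sort_key)}


def _require_parent_pair(matrix: GenotypeMatrix) -> None:
    if matrix.role_index("father") is None or matrix.role_index("mother") is None:
        raise ConfigurationError(
            "the consanguinity statistic is defined on a father+mother pair; "
            "one of the roles is absent"
        )


def run_repetition(
    eligible: Mapping[str, Sequence[VariantKey]],
    mother_carrier: Mapping[VariantKey, bool],
    maf_by_key: Mapping[VariantKey, float],
    rng: np.random.Generator,
) -> SharingRepetition:
    """Sample one variant per non-empty chromosome and tally sharing."""
    sampled = []
    for chrom in sorted(eligible, key=karyotype_sort_key):
        keys = eligible[chrom]
        if not keys:
            continue
        sampled.append(keys[int(rng.integers(len(keys)))])
    expected = float(sum(expected_sharing_probability(maf_by_key[k]) for k in sampled))
    observed = int(sum(1 for k in sampled if mother_carrier.get(k, False)))
    return SharingRepetition(sampled_variants=tuple(sampled),
                             expected=expected, observed=observed)


def consanguinity_ratio(
    matrix: GenotypeMatrix,
    threshold: float,
    n_reps: int = DEFAULT_REPS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    population: str = DEFAULT_POPULATION,
    label: str = "",
) -> ConsanguinityResult:
    """Run the full repeated-sampling procedure for one parent pair."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = eligible_father_variants(matrix, threshold, population)
    mi = matrix.role_index("mother")
    elig_keys = {k for c in eligible.values() for k in c}
    mother_carrier = {}
    maf_by_key = {}
    for vi, rec in enumerate(matrix.variants):
        if rec.key in elig_keys:
            mother_carrier[rec.key] = matrix.genotypes[vi][mi].carrier
            maf_by_key[rec.key] = rec.annotation.maf_of(population)
    reps = [run_repetition(eligible, mother_carrier, maf_by_key, rng)
            for _ in range(n_reps)]
    return ConsanguinityResult(threshold=threshold, n_reps=n_reps,
                               repetitions=reps,
                               label=label or matrix.family_id)


def consanguinity_profile(
    matrix: GenotypeMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_reps: int = DEFAULT_REPS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    population: str = DEFAULT_POPULATION,
) -> dict:
    """The statistic at every threshold (default 0.01/0.02/0.05/0.1)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return {t: consanguinity_ratio(matrix, t, n_reps=n_reps, rng=rng,
                                   population=population)
            for t in thresholds}


# ---------------------------------------------------------------------------
# Inter-family baseline
# ---------------------------------------------------------------------------

def parent_pair_matrix(father_matrix: GenotypeMatrix,
                       mother_matrix: GenotypeMatrix,
                       label: str = "") -> GenotypeMatrix:
    """Pair the father of one family ("father") with the father of another
    ("mother") over the union of their sites; absent sites are missing
    (hence non-carrier), matching how per-family call sets behave."""
    fa = father_matrix.role_index("father")
    fb = mother_matrix.role_index("father")
    if fa is None or fb is None:
        raise ConfigurationError("both matrices must contain a father sample")
    a_gt = {rec.key: father_matrix.genotypes[vi][fa]
            for vi, rec in enumerate(father_matrix.variants)}
    b_gt = {rec.key: mother_matrix.genotypes[vi][fb]
            for vi, rec in enumerate(mother_matrix.variants)}
    rec_by_key = {}
    for m in (father_matrix, mother_matrix):
        for rec in m.variants:
            if rec.key not in rec_by_key or not rec_by_key[rec.key].annotation.maf:
                rec_by_key[rec.key] = rec
    keys = sorted(rec_by_key, key=lambda k: (karyotype_sort_key(k[0]),) + k[1:])
    variants = [rec_by_key[k] for k in keys]
    grid = [[a_gt.get(k, Genotype.missing_gt()), b_gt.get(k, Genotype.missing_gt())]
            for k in keys]
    samples = [Sample("fatherA", "father"), Sample("fatherB", "mother")]
    return GenotypeMatrix(variants=variants, samples=samples, genotypes=grid,
                          family_id=label)


def interfamily_baseline(
    fathers: Sequence[GenotypeMatrix],
    threshold: float,
    n_reps: int = DEFAULT_REPS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    population: str = DEFAULT_POPULATION,
) -> list:
    """The statistic for every unordered pair of fathers from distinct
    families: the empirical unrelated-population baseline distribution."""
    if len(fathers) < 2:
        raise ConfigurationError("inter-family baseline needs >= 2 fathers")
    ids = [m.family_id for m in fathers]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(
            "fathers must come from distinct families (duplicate family_id); "
            "a father cannot be paired with himself"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    results = []
    for (i, a), (j, b) in combinations(enumerate(fathers), 2):
        label = f"{a.family_id}~{b.family_id}"
        pair = parent_pair_matrix(a, b, label=label)
        results.append(consanguinity_ratio(pair, threshold, n_reps=n_reps,
                                           rng=rng, population=population,
                                           label=label))
    return results
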