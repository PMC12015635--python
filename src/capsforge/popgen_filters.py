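"""Variant filtering cascade for marker discovery in a partially selfing population.

The cascade mirrors the screening used to pull CAPS-able candidate SNPs out
of a low-coverage population VCF:

1. :func:`basic_filter` — biallelic SNPs only, not fixed for the alternate
   allele, genotyped in enough samples, minor allele frequency above a floor.
2. :func:`hwe_exact` — the conditional exact test of Hardy–Weinberg genotype
   proportions with one-tailed deficit/excess p-values.  Heterozygote excess
   at low coverage is the signature of reads from duplicated regions
   co-mapping to one locus ("pseudo-SNPs"), so excess-leaning sites are
   screened out by :func:`excess_screen`.
3. :func:`tier_filter` — retention tiers by genotyping completeness, with a
   per-sample read-depth requirement for the thinnest tier.

:func:`inbreeding_estimate` provides the multilocus F-hat used to verify
that simulated populations reproduce their configured inbreeding level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .variant_io import MISSING, GenotypeMatrix, snp_id

__all__ = [
    "SiteStats",
    "HWEResult",
    "FilterParams",
    "site_stats",
    "site_stats_from_counts",
    "basic_filter",
    "hwe_exact",
    "hwe_null_distribution",
    "excess_screen",
    "tier_filter",
    "inbreeding_estimate",
]


@dataclass(frozen=True)
class SiteStats:
    """Genotype counts and minor-allele frequency for one biallelic site."""

    n_typed: int
    n_ref_hom: int
    n_het: int
    n_alt_hom: int
    maf: float
    minor_allele: str  # "ref" or "alt"

    def __post_init__(self) -> None:
        if self.n_ref_hom + self.n_het + self.n_alt_hom != self.n_typed:
            raise ValueError("genotype counts do not sum to n_typed")


@dataclass(frozen=True)
class HWEResult:
    """Exact-test p-values for one site.

    ``p_deficit`` is the lower tail (observed or fewer heterozygotes),
    ``p_excess`` the upper tail, ``p_hwe`` the two-sided p-value summing
    all heterozygote configurations no more probable than the observed one.
    """

    p_hwe: float
    p_deficit: float
    p_excess: float


@dataclass
class FilterParams:
    """Thresholds of the filtering cascade.

    Defaults reproduce the 22-sample study design: at least 15/22 samples
    typed, MAF >= 0.20, excess-tail screen at 0.5, full-confidence tier at
    17 typed samples, and the thin tier requiring depth >= 2 in >= 11
    samples.
    """

    min_typed: int = 15
    maf_min: float = 0.20
    excess_keep_threshold: float = 0.5
    tier_full: int = 17
    depth_min: int = 2
    depth_n_min: int = 11
    max_nonref_af: float = 0.999

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.excess_keep_threshold <= 1.0:
            raise ValueError("excess_keep_threshold must be in [0, 1]")
        if not 0.0 <= self.max_nonref_af <= 1.0:
            raise ValueError("max_nonref_af must be in [0, 1]")
        if min(self.min_typed, self.tier_full, self.depth_min, self.depth_n_min) < 0:
            raise ValueError("count thresholds must be non-negative")


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def site_stats(dosage_row: np.ndarray) -> SiteStats:
    """Genotype counts and MAF from one site's ref-allele dosage vector.

    MAF is computed over typed samples only; a 0.5 tie reports the
    alternate allele as minor.
    """
    d = np.asarray(dosage_row)
    typed = d[d != MISSING]
    if typed.size == 0:
        raise ValueError("no typed samples: site statistics undefined")
    n_ref_hom = int((typed == 2).sum())
    n_het = int((typed == 1).sum())
    n_alt_hom = int((typed == 0).sum())
    return site_stats_from_counts(n_ref_hom, n_het, n_alt_hom)


def site_stats_from_counts(n_ref_hom: int, n_het: int, n_alt_hom: int) -> SiteStats:
    n_typed = n_ref_hom + n_het + n_alt_hom
    if n_typed == 0:
        raise ValueError("no typed samples: site statistics undefined")
    ref_count = 2 * n_ref_hom + n_het
    alt_count = 2 * n_alt_hom + n_het
    maf = min(ref_count, alt_count) / (2 * n_typed)
    minor = "alt" if alt_count <= ref_count else "ref"
    return SiteStats(n_typed, n_ref_hom, n_het, n_alt_hom, maf, minor)


# ---------------------------------------------------------------------------
# basic filter
# ---------------------------------------------------------------------------


def basic_filter(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Apply the biallelic-SNP / fixed / missingness / MAF filters.

    Returns the retained matrix and, for each rejected site, a
    ``(snp_id, reason)`` pair where *reason* is the first failing rule in
    the order: indel, multiallelic, no-calls, fixed, missingness, maf.
    """
    params = params or FilterParams()
    kept: list[int] = []
    rejected: list[tuple[str, str]] = []
    for i, site in enumerate(matrix.sites):
        sid = snp_id(site.contig, site.pos, site.ref, site.alts[0])
        if not site.is_snp:
            rejected.append((sid, "indel"))
            continue
        if not site.is_biallelic:
            rejected.append((sid, "multiallelic"))
            continue
        d = matrix.dosage[i]
        typed = d[d != MISSING]
        if typed.size == 0:
            rejected.append((sid, "no_calls"))
            continue
        stats = site_stats(d)
        alt_count = 2 * stats.n_alt_hom + stats.n_het
        if alt_count / (2 * stats.n_typed) > params.max_nonref_af:
            rejected.append((sid, "fixed"))
            continue
        if stats.n_typed < params.min_typed:
            rejected.append((sid, "missingness"))
            continue
        if stats.maf < params.maf_min:
            rejected.append((sid, "maf"))
            continue
        kept.append(i)
    return matrix.subset(kept), rejected


# ---------------------------------------------------------------------------
# exact Hardy–Weinberg test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _het_log_weights(n: int, m: int) -> tuple[tuple[int, ...], np.ndarray]:
    """Support and normalized probabilities of the heterozygote count.

    Conditional on *n* diploid individuals and *m* copies of the minor
    allele, valid heterozygote counts share the parity of *m* and satisfy
    the obvious box constraints.  Weights follow the hypergeometric-type
    conditional distribution, computed in log space with ``gammaln``.
    """
    hs = [h for h in range(m % 2, min(m, 2 * n - m) + 1, 2)]
    logs = np.array(
        [
            h * np.log(2.0)
            - gammaln((m - h) / 2 + 1)
            - gammaln(h + 1)
            - gammaln((2 * n - m - h) / 2 + 1)
            for h in hs
        ]
    )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return tuple(hs), probs


def hwe_null_distribution(n: int, m: int) -> tuple[tuple[int, ...], np.ndarray]:
    """Public view of the exact null distribution of the het count."""
    hs, probs = _het_log_weights(n, m)
    return hs, probs.copy()


def hwe_exact(n_ref_hom: int, n_het: int, n_alt_hom: int) -> HWEResult:
    """Exact test of Hardy–Weinberg proportions for one biallelic site.

    Conditional on the observed allele counts, the heterozygote count is
    compared with its exact null distribution.  ``p_hwe`` sums the
    probabilities of all configurations no more probable than the observed
    one; the deficit and excess tails are plain (not mid-) p-values.
    A monomorphic site has a single configuration, so all three p-values
    are 1.
    """
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_ref_hom + n_het + n_alt_hom
    if n < 1:
        raise ValueError("need at least one typed sample")
    m = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    hs, probs = _het_log_weights(n, m)
    idx = hs.index(n_het)
    p_obs = probs[idx]
    # tolerance absorbs float noise when comparing "no more probable"
    p_hwe = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    p_deficit = float(probs[: idx + 1].sum())
    p_excess = float(probs[idx:].sum())
    return HWEResult(min(p_hwe, 1.0), min(p_deficit, 1.0), min(p_excess, 1.0))


def hwe_for_matrix(matrix: GenotypeMatrix) -> list[HWEResult]:
    """Exact-test results for every site of a (biallelic) matrix."""
    return [site_hwe(matrix.dosage[i]) for i in range(matrix.n_sites)]


def site_hwe(dosage_row: np.ndarray) -> HWEResult:
    stats = site_stats(dosage_row)
    return hwe_exact(stats.n_ref_hom, stats.n_het, stats.n_alt_hom)


# ---------------------------------------------------------------------------
# excess screen and retention tiers
# ---------------------------------------------------------------------------


def excess_screen(
    matrix: GenotypeMatrix,
    hwe: list[HWEResult],
    params: FilterParams | None = None,
) -> tuple[GenotypeMatrix, list[HWEResult], list[tuple[str, str]]]:
    """Drop sites leaning toward heterozygote excess.

    A site is retained iff ``p_excess >= excess_keep_threshold`` (inclusive
    at the boundary): any lean toward excess heterozygosity is treated as a
    duplication artifact signal, not real genotypic structure.
    """
    params = params or FilterParams()
    kept, kept_hwe, rejected = [], [], []
    for i, site in enumerate(matrix.sites):
        if hwe[i].p_excess >= params.excess_keep_threshold:
            kept.append(i)
            kept_hwe.append(hwe[i])
        else:
            sid = snp_id(site.contig, site.pos, site.ref, site.alts[0])
            rejected.append((sid, "het_excess"))
    return matrix.subset(kept), kept_hwe, rejected


@dataclass
class TierResult:
    matrix: GenotypeMatrix
    tiers: list[str]  # "A"/"B"/"C" per retained site
    rejected: list[tuple[str, str]] = field(default_factory=list)


def tier_filter(
    matrix: GenotypeMatrix,
    hwe: list[HWEResult],
    params: FilterParams | None = None,
) -> TierResult:
    """Tiered retention by genotyping completeness.

    Tier A (n_typed >= ``tier_full``): kept outright.  Tier B (one sample
    short): kept only when the deficit tail is the stronger signal
    (``p_deficit < p_excess``), as expected under selfing.  Tier C
    (n_typed == ``min_typed``): additionally requires read depth >=
    ``depth_min`` in at least ``depth_n_min`` samples; a tier-C site
    without depth data is rejected explicitly.
    """
    params = params or FilterParams()
    kept, tiers, rejected = [], [], []
    for i, site in enumerate(matrix.sites):
        sid = snp_id(site.contig, site.pos, site.ref, site.alts[0])
        stats = site_stats(matrix.dosage[i])
        if stats.n_typed >= params.tier_full:
            kept.append(i)
            tiers.append("A")
            continue
        if not hwe[i].p_deficit < hwe[i].p_excess:
            rejected.append((sid, "tier_not_deficit_leaning"))
            continue
        if stats.n_typed > params.min_typed:
            kept.append(i)
            tiers.append("B")
            continue
        # thinnest tier: depth rule
        dp = matrix.depth[i]
        if (dp == MISSING).all():
            rejected.append((sid, "tier_c_no_depth_data"))
            continue
        n_deep = int(((dp != MISSING) & (dp >= params.depth_min)).sum())
        if n_deep >= params.depth_n_min:
            kept.append(i)
            tiers.append("C")
        else:
            rejected.append((sid, "tier_c_depth"))
    return TierResult(matrix.subset(kept), tiers, rejected)


# ---------------------------------------------------------------------------
# inbreeding estimator
# ---------------------------------------------------------------------------


def inbreeding_estimate(matrix: GenotypeMatrix) -> float:
    """Multilocus inbreeding coefficient F-hat.

    ``1 - (sum of observed heterozygote counts) / (sum of expected
    heterozygote counts 2*p*q*n_typed)``, pooling all polymorphic sites.
    Raises if every site is monomorphic.
    """
    obs = 0.0
    exp = 0.0
    for i in range(matrix.n_sites):
        d = matrix.dosage[i]
        typed = d[d != MISSING]
        if typed.size == 0:
            continue
        n = typed.size
        p = float((typed == 2).sum() * 2 + (typed == 1).sum()) / (2 * n)
        q = 1.0 - p
        if p == 0.0 or q == 0.0:
            continue
        obs += float((typed == 1).sum())
        exp += 2.0 * p * q * n
    if exp == 0.0:
        raise ValueError("all sites monomorphic: F undefined")
    return 1.0 - obs / exp
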