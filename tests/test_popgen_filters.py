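"""Filtering cascade and exact Hardy-Weinberg test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsforge.popgen_filters import (
    FilterParams,
    basic_filter,
    excess_screen,
    hwe_exact,
    inbreeding_estimate,
    site_stats,
    site_stats_from_counts,
    tier_filter,
)
from capsforge.synthetic_data import simulate_genotypes
from capsforge.variant_io import MISSING, GenotypeMatrix, VariantSite


# ---------------------------------------------------------------------------
# independent oracle: full enumeration with exact rational arithmetic
# ---------------------------------------------------------------------------


def hwe_brute_force(n_ref_hom, n_het, n_alt_hom):
    """Exact-test p-values by enumerating every genotype configuration."""
    n = n_ref_hom + n_het + n_alt_hom
    m = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    weights = {}
    for h in range(m % 2, min(m, 2 * n - m) + 1, 2):
        a = (m - h) // 2
        b = (2 * n - m - h) // 2
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(a) * math.factorial(h) * math.factorial(b),
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    p_hwe = sum(p for p in probs.values() if p <= p_obs)
    p_def = sum(p for h, p in probs.items() if h <= n_het)
    p_exc = sum(p for h, p in probs.items() if h >= n_het)
    return float(p_hwe), float(p_def), float(p_exc)


@pytest.mark.parametrize(
    "counts,expected",
    [
        # hand-enumerated: n=5, minor count 3 -> het in {1, 3} with probs 1/3, 2/3
        ((0, 3, 2), (1.0, 1.0, 2 / 3)),
        ((1, 1, 3), (1 / 3, 1 / 3, 1.0)),
        ((5, 0, 0), (1.0, 1.0, 1.0)),  # monomorphic: single configuration
    ],
)
def test_hwe_exact_small_cases(counts, expected):
    res = hwe_exact(*counts)
    assert res.p_hwe == pytest.approx(expected[0], abs=1e-12)
    assert res.p_deficit == pytest.approx(expected[1], abs=1e-12)
    assert res.p_excess == pytest.approx(expected[2], abs=1e-12)


def test_hwe_exact_matches_enumeration_sweep():
    """Exhaustive agreement with the rational-arithmetic oracle, n <= 12."""
    for n in range(1, 13):
        for m in range(0, n + 1):
            for h in range(m % 2, min(m, 2 * n - m) + 1, 2):
                aa = (m - h) // 2
                bb = n - aa - h
                exp = hwe_brute_force(bb, h, aa)
                got = hwe_exact(bb, h, aa)
                assert abs(got.p_hwe - exp[0]) < 1e-10, (n, m, h)
                assert abs(got.p_deficit - exp[1]) < 1e-10
                assert abs(got.p_excess - exp[2]) < 1e-10


@given(
    st.integers(min_value=0, max_value=12),
    st.integers(min_value=0, max_value=12),
    st.integers(min_value=0, max_value=12),
)
@settings(deadline=None, max_examples=80, derandomize=True)
def test_hwe_tail_identities(aa, ab, bb):
    """Tails overlap on the observed class and bound the two-sided p-value."""
    if aa + ab + bb == 0:
        return
    res = hwe_exact(aa, ab, bb)
    assert 0.0 <= res.p_hwe <= 1.0
    assert res.p_deficit + res.p_excess >= 1.0 - 1e-12
    assert res.p_hwe <= res.p_deficit + res.p_excess


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact(-1, 2, 3)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,maf,minor",
    [
        ((5, 0, 5), 0.5, "alt"),  # tie reports the alternate allele
        ((14, 5, 1), 0.175, "alt"),  # alt count 7 of 40
        ((7, 0, 0), 0.0, "alt"),
    ],
)
def test_site_stats_counts(counts, maf, minor):
    s = site_stats_from_counts(*counts)
    assert s.maf == pytest.approx(maf)
    assert s.minor_allele == minor


def test_site_stats_ignores_missing():
    d = np.array([2, 2, 1, 0, MISSING, MISSING])
    s = site_stats(d)
    assert s.n_typed == 4
    assert s.maf == pytest.approx(3 / 8)


def test_site_stats_undefined_when_all_missing():
    with pytest.raises(ValueError):
        site_stats(np.array([MISSING, MISSING]))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _matrix(rows, samples=None, sites=None, depth=None):
    rows = np.asarray(rows, dtype=np.int8)
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    sites = sites or [
        VariantSite("c1", 10 * (i + 1), "A", ("G",)) for i in range(rows.shape[0])
    ]
    return GenotypeMatrix.from_dosage(sites, samples, rows, depth)


def test_basic_filter_reasons():
    n = 22
    sites = [
        VariantSite("c1", 10, "A", ("AT",)),  # indel
        VariantSite("c1", 20, "A", ("C", "G")),  # multiallelic
        VariantSite("c1", 30, "A", ("G",)),  # fixed alt
        VariantSite("c1", 40, "A", ("G",)),  # 14/22 typed
        VariantSite("c1", 50, "A", ("G",)),  # maf too low
        VariantSite("c1", 60, "A", ("G",)),  # keeper
    ]
    rows = np.array(
        [
            [1] * n,
            [1] * n,
            [0] * n,
            [1] * 14 + [MISSING] * 8,
            [2] * 21 + [1],
            [2] * 11 + [1] * 6 + [0] * 5,
        ],
        dtype=np.int8,
    )
    m = GenotypeMatrix.from_dosage(sites, [f"S{i}" for i in range(n)], rows)
    kept, rejected = basic_filter(m, FilterParams())
    assert [s.pos for s in kept.sites] == [60]
    assert dict((sid.split("_")[1], why) for sid, why in rejected) == {
        "10": "indel",
        "20": "multiallelic",
        "30": "fixed",
        "40": "missingness",
        "50": "maf",
    }


def test_basic_filter_boundaries_inclusive():
    """MAF exactly 0.20 and exactly min_typed samples are retained."""
    n = 20
    rows = np.array([[2] * 12 + [1] * 8], dtype=np.int8)  # maf = 8/40 = 0.2
    m = _matrix(rows)
    kept, _ = basic_filter(m, FilterParams(min_typed=15))
    assert kept.n_sites == 1
    rows2 = np.array([[2] * 9 + [1] * 6 + [MISSING] * 5], dtype=np.int8)  # 15 typed
    kept2, _ = basic_filter(_matrix(rows2), FilterParams(min_typed=15))
    assert kept2.n_sites == 1


def test_excess_screen_direction_and_boundary():
    """Excess-leaning sites go; p_excess >= 0.5 (inclusive) is retained."""
    rows = np.array(
        [
            [2] * 12 + [0] * 8,  # no hets: p_excess = 1 -> retained
            [1] * 20,  # all hets: p_excess small -> removed
        ],
        dtype=np.int8,
    )
    m = _matrix(rows)
    hwe = [hwe_exact(12, 0, 8), hwe_exact(0, 20, 0)]
    assert hwe[1].p_excess < 0.5
    kept, kept_hwe, rejected = excess_screen(m, hwe, FilterParams())
    assert kept.n_sites == 1
    assert rejected[0][1] == "het_excess"
    # boundary: construct a site with p_excess exactly 0.5 is awkward;
    # assert the rule directly at the threshold via a doctored result
    from capsforge.popgen_filters import HWEResult

    m1 = _matrix(rows[:1])
    kept_b, _, rej_b = excess_screen(m1, [HWEResult(1.0, 1.0, 0.5)], FilterParams())
    assert kept_b.n_sites == 1 and not rej_b


def test_tier_filter_rules():
    n = 22
    params = FilterParams()
    deficit_row = [2] * 9 + [0] * 8 + [1]  # 18 typed, deficit-leaning
    rows = np.array(
        [
            [2] * 9 + [1] * 9 + [0] * 4,  # 22 typed -> tier A regardless
            deficit_row + [MISSING] * 4,  # 18 typed -> A
            [2] * 8 + [0] * 7 + [1] + [MISSING] * 6,  # 16 typed, deficit -> B
            [1] * 16 + [MISSING] * 6,  # 16 typed, excess-leaning -> out
            [2] * 8 + [0] * 6 + [1] + [MISSING] * 7,  # 15 typed -> tier C rules
        ],
        dtype=np.int8,
    )
    depth = np.full(rows.shape, 5, dtype=np.int32)
    depth[rows == MISSING] = 0
    depth[4, :4] = 1  # tier-C site: only 11 samples at DP >= 2
    m = _matrix(rows, depth=depth)
    hwe = [
        hwe_exact(*_counts(r)) for r in rows
    ]
    res = tier_filter(m, hwe, params)
    assert res.tiers == ["A", "A", "B", "C"]
    assert [why for _, why in res.rejected] == ["tier_not_deficit_leaning"]
    # drop one more deep sample: 10 < 11 at depth >= 2 -> rejected
    depth[4, 4] = 1
    m2 = _matrix(rows, depth=depth)
    res2 = tier_filter(m2, hwe, params)
    assert res2.tiers == ["A", "A", "B"]
    assert ("tier_c_depth" in {w for _, w in res2.rejected})


def _counts(row):
    row = np.asarray(row)
    t = row[row != MISSING]
    return int((t == 2).sum()), int((t == 1).sum()), int((t == 0).sum())


def test_tier_c_without_depth_data_is_rejected_explicitly():
    rows = np.array([[2] * 8 + [0] * 6 + [1] + [MISSING] * 7], dtype=np.int8)
    m = _matrix(rows)  # depth all unknown
    hwe = [hwe_exact(*_counts(rows[0]))]
    res = tier_filter(m, hwe, FilterParams())
    assert res.matrix.n_sites == 0
    assert res.rejected[0][1] == "tier_c_no_depth_data"


def test_filter_composition_is_order_stable(study):
    """basic -> excess -> tier equals the conjunction applied at once."""
    from capsforge.popgen_filters import hwe_for_matrix

    params = FilterParams()
    m1, _ = basic_filter(study.matrix, params)
    hwe1 = hwe_for_matrix(m1)
    m2, hwe2, _ = excess_screen(m1, hwe1, params)
    staged = tier_filter(m2, hwe2, params)
    staged_ids = {(s.contig, s.pos) for s in staged.matrix.sites}

    conjunction = set()
    for i, site in enumerate(study.matrix.sites):
        d = study.matrix.dosage[i]
        if not (site.is_snp and site.is_biallelic):
            continue
        t = d[d != MISSING]
        if t.size == 0:
            continue
        st_ = site_stats(d)
        alt_af = (2 * st_.n_alt_hom + st_.n_het) / (2 * st_.n_typed)
        if alt_af > params.max_nonref_af or st_.n_typed < params.min_typed:
            continue
        if st_.maf < params.maf_min:
            continue
        h = hwe_exact(st_.n_ref_hom, st_.n_het, st_.n_alt_hom)
        if h.p_excess < params.excess_keep_threshold:
            continue
        if st_.n_typed >= params.tier_full:
            conjunction.add((site.contig, site.pos))
            continue
        if not h.p_deficit < h.p_excess:
            continue
        if st_.n_typed > params.min_typed:
            conjunction.add((site.contig, site.pos))
            continue
        dp = study.matrix.depth[i]
        if ((dp != MISSING) & (dp >= params.depth_min)).sum() >= params.depth_n_min:
            conjunction.add((site.contig, site.pos))
    assert staged_ids == conjunction


# ---------------------------------------------------------------------------
# inbreeding estimator
# ---------------------------------------------------------------------------


def test_inbreeding_extremes():
    all_het = _matrix(np.array([[1] * 20], dtype=np.int8))
    assert inbreeding_estimate(all_het) == pytest.approx(-1.0)
    no_het = _matrix(np.array([[2] * 10 + [0] * 10], dtype=np.int8))
    assert inbreeding_estimate(no_het) == pytest.approx(1.0)
    mono = _matrix(np.array([[2] * 20], dtype=np.int8))
    with pytest.raises(ValueError):
        inbreeding_estimate(mono)


@pytest.mark.parametrize("f", [0.0, 0.41, 0.8])
def test_inbreeding_recovery(f):
    """F-hat recovers the generative F within +-0.05 at 2000 sites x 22."""
    rng = np.random.default_rng(42)
    freqs = rng.uniform(0.2, 0.5, size=2000)
    dosage = simulate_genotypes(freqs, f, 22, rng)
    sites = [VariantSite("c", i + 1, "A", ("G",)) for i in range(2000)]
    m = GenotypeMatrix.from_dosage(sites, [f"S{i}" for i in range(22)], dosage)
    assert inbreeding_estimate(m) == pytest.approx(f, abs=0.05)
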