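import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endodorm.frequencies import (
    DegenerateSEError,
    GenotypeCounts,
    ReconstructionError,
    UndefinedFrequencyError,
    binomial_half_test,
    chi2_mendelian,
    combine_weighted,
    counts_from_frequencies,
    estimate_frequencies,
    gamete_equality_test,
    pool_counts,
    significance_stars,
    tally,
)
from endodorm.genotypes import SeedRecord

count_vectors = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) >= 1)


def _records(doses):
    return [
        SeedRecord(seed_id=str(i), locus_doses={"L": d}) for i, d in enumerate(doses)
    ]


def test_tally_counts_classes_and_missing():
    c = tally(_records([0, 0, 1, 2, 3, None]), "L")
    assert (c.n_ddd, c.n_Ddd, c.n_DDd, c.n_DDD, c.n_missing) == (2, 1, 1, 1, 1)
    assert c.N == 5
    empty = tally([], "L")
    assert empty.N == 0 and empty.n_missing == 0


@pytest.mark.parametrize(
    "counts,f_d,f_d_male,f_d_female",
    [
        # strongly selected germinated subpopulation of an endosperm locus
        ((94, 74, 50, 32), 0.624, 0.576, 0.672),
        # symmetric counts: everything at 1/2
        ((25, 25, 25, 25), 0.5, 0.5, 0.5),
        # dormancy-enhancing allele enriched among nongerminated seeds
        ((18, 28, 20, 55), 0.347, 0.314, 0.380),
    ],
)
def test_allelic_and_gametic_estimators(counts, f_d, f_d_male, f_d_female):
    est = estimate_frequencies(GenotypeCounts(*counts))
    assert round(est.F_d, 3) == f_d
    assert round(est.F_d_male, 3) == f_d_male
    assert round(est.F_d_female, 3) == f_d_female


@settings(derandomize=True, max_examples=150)
@given(count_vectors)
def test_frequency_identities(counts):
    """F_d is exactly the mean of the two gamete frequencies, and all
    frequency pairs are complementary."""
    est = estimate_frequencies(GenotypeCounts(*counts))
    assert est.F_d == pytest.approx((est.F_d_male + est.F_d_female) / 2, abs=1e-12)
    assert est.genotype_frequencies().sum() == pytest.approx(1.0)
    assert est.F_d + est.F_D == pytest.approx(1.0)
    assert est.F_d_male + est.F_D_male == pytest.approx(1.0)
    assert est.F_d_female + est.F_D_female == pytest.approx(1.0)


def test_estimators_refuse_empty_sample():
    with pytest.raises(UndefinedFrequencyError):
        estimate_frequencies(GenotypeCounts(0, 0, 0, 0))
    with pytest.raises(UndefinedFrequencyError):
        chi2_mendelian(GenotypeCounts(0, 0, 0, 0))


@settings(derandomize=True, max_examples=150)
@given(count_vectors)
def test_chi2_matches_brute_force(counts):
    obs = np.array(counts, dtype=float)
    e = obs.sum() / 4
    expected_stat = float(((obs - e) ** 2 / e).sum())
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = chi2_mendelian(GenotypeCounts(*counts))
    assert res.statistic == pytest.approx(expected_stat, abs=1e-9)
    assert res.df == 3


def test_chi2_small_sample_warns_but_computes():
    with pytest.warns(UserWarning):
        res = chi2_mendelian(GenotypeCounts(4, 4, 4, 4))
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_chi2_example_values():
    res = chi2_mendelian(GenotypeCounts(11, 11, 11, 10))
    assert res.statistic == pytest.approx(0.0698, abs=5e-4)
    assert res.p_value == pytest.approx(0.995, abs=5e-4)
    res2 = chi2_mendelian(GenotypeCounts(94, 74, 50, 32))
    assert res2.statistic == pytest.approx(35.376, abs=1e-3)


def test_binomial_half_test_published_se():
    res = binomial_half_test(0.624, 250)
    se = math.sqrt(2 * 0.624 * 0.376 / 250)
    assert se == pytest.approx(0.0433, abs=5e-5)
    assert res.statistic == pytest.approx((0.624 - 0.5) / se)
    null = binomial_half_test(0.5, 100)
    assert null.statistic == 0.0 and null.p_value == pytest.approx(1.0)
    weak = binomial_half_test(0.512, 43)
    assert abs(weak.statistic) < 1 and weak.p_value > 0.05


def test_binomial_half_test_exact_variants():
    gamete = binomial_half_test(0.6, 100, method="exact", n_trials=100)
    overall = binomial_half_test(0.6, 100, method="exact", n_trials=200)
    assert overall.p_value < gamete.p_value  # 2N trials: same fraction, more power
    with pytest.raises(DegenerateSEError):
        binomial_half_test(1.0, 50)


def test_gamete_equality():
    eq = gamete_equality_test(estimate_frequencies(GenotypeCounts(25, 25, 25, 25)))
    assert eq.statistic == 0.0 and eq.p_value == pytest.approx(1.0)
    # female-male asymmetry of a dosage-acting endosperm locus
    asym = gamete_equality_test(estimate_frequencies(GenotypeCounts(94, 74, 50, 32)))
    assert asym.p_value < 0.05
    assert asym.statistic < 0  # F_d' < F_d''


@pytest.mark.parametrize(
    "freqs,n,expected",
    [
        ((0.256, 0.256, 0.256, 0.232), 43, (11, 11, 11, 10)),
        ((0.25, 0.25, 0.25, 0.25), 100, (25, 25, 25, 25)),
        ((0.376, 0.296, 0.200, 0.128), 250, (94, 74, 50, 32)),
    ],
)
def test_counts_from_frequencies_examples(freqs, n, expected):
    c = counts_from_frequencies(freqs, n)
    assert (c.n_ddd, c.n_Ddd, c.n_DDd, c.n_DDD) == expected


def test_counts_from_frequencies_rejects_inconsistent():
    with pytest.raises(ReconstructionError):
        counts_from_frequencies((0.5, 0.5, 0.25, 0.25), 100)  # sums to 1.5
    with pytest.raises(ReconstructionError):
        # frequencies sum to 1 but no composition of 7 is within one
        # printed ulp of all four values
        counts_from_frequencies((0.35, 0.35, 0.2, 0.1), 7)


@settings(derandomize=True, max_examples=200)
@given(count_vectors.filter(lambda t: sum(t) <= 999))
def test_counts_from_frequencies_round_trip(counts):
    """Rounding counts/N to 3 decimals and reconstructing recovers the counts.

    Exact recovery is only identifiable while 1/N exceeds the printed
    resolution (N < 1000); above that two compositions can re-round to the
    same three-decimal frequencies and the weaker self-consistency property
    below applies."""
    n = sum(counts)
    freqs = tuple(math.floor(c / n * 1000 + 0.5) / 1000 for c in counts)
    rec = counts_from_frequencies(freqs, n)
    assert (rec.n_ddd, rec.n_Ddd, rec.n_DDd, rec.n_DDD) == counts


@settings(derandomize=True, max_examples=100)
@given(count_vectors.filter(lambda t: 1000 <= sum(t) <= 2000))
def test_counts_from_frequencies_self_consistent_at_large_n(counts):
    """For N >= 1000 the reconstruction still re-rounds to the printed
    frequencies even where the original counts are not identifiable."""
    n = sum(counts)
    freqs = tuple(math.floor(c / n * 1000 + 0.5) / 1000 for c in counts)
    rec = counts_from_frequencies(freqs, n)
    back = tuple(
        math.floor(c / n * 1000 + 0.5) / 1000
        for c in (rec.n_ddd, rec.n_Ddd, rec.n_DDd, rec.n_DDD)
    )
    assert all(abs(a - b) <= 1e-3 + 1e-12 for a, b in zip(back, freqs))


def test_pool_and_weighted_join():
    g = GenotypeCounts(60, 30, 48, 23)
    ng = GenotypeCounts(63, 49, 68, 54)
    pooled = pool_counts(g, ng)
    assert pooled.as_array().tolist() == [123, 79, 116, 77]
    est_g, est_ng = estimate_frequencies(g), estimate_frequencies(ng)
    # joined population summarised by frequency weighting at a 26% rate
    joined = combine_weighted(est_g, est_ng, 0.26)
    assert joined.F_d == pytest.approx(0.544, abs=1.05e-3)
    assert joined.F_d_male == pytest.approx(0.588, abs=1.05e-3)
    assert joined.F_d_female == pytest.approx(0.499, abs=1.05e-3)
    # equal weights of identical estimates are a fixed point
    same = combine_weighted(est_g, est_g, 0.5)
    assert same.F_d == pytest.approx(est_g.F_d)


def test_significance_stars_tiers():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
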