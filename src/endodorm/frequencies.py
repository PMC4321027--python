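"""Endosperm genotype / gamete frequency estimators and their test battery.

For a biallelic locus, counting the four triploid endosperm classes in a
sample of N genotyped seeds gives the genotypic frequencies
``F_ddd .. F_DDD`` and, because each endosperm is one male gamete plus a
duplicated female gamete, also the gamete-wise frequencies:

    F_d  = F_ddd + 0.5 F_Ddd + 0.5 F_DDd      (overall d-allele frequency)
    F_d' = F_ddd + F_DDd                      (male-gamete d frequency)
    F_d'' = F_ddd + F_Ddd                     (female-gamete d frequency)

with F_d = (F_d' + F_d'')/2 identically.  Genotypic frequencies are tested
against the Mendelian 1:1:1:1 expectation by Pearson chi-square (df=3), and
allelic/gametic frequencies against 0.5 by a normal-approximation binomial
test whose standard error is SE = sqrt(2 F_d F_D / N).  That SE differs from
the textbook binomial SE at both N and 2N trials; it is kept as the default
for fidelity to the published method, and exact binomial alternatives are
available behind ``method=``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .genotypes import SeedRecord

__all__ = [
    "GenotypeCounts",
    "FreqEstimates",
    "TestResult",
    "tally",
    "estimate_frequencies",
    "chi2_mendelian",
    "binomial_half_test",
    "gamete_equality_test",
    "counts_from_frequencies",
    "pool_counts",
    "combine_weighted",
    "significance_stars",
]


class UndefinedFrequencyError(ValueError):
    """Raised when a frequency or test is requested for zero genotyped seeds."""


class DegenerateSEError(ValueError):
    """Raised when the SE formula degenerates (frequency exactly 0 or 1)."""


class ReconstructionError(ValueError):
    """No integer count vector is consistent with the printed frequencies."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Seed counts for the four endosperm classes plus missing calls."""

    n_ddd: int
    n_Ddd: int
    n_DDd: int
    n_DDD: int
    n_missing: int = 0

    @property
    def N(self) -> int:
        return self.n_ddd + self.n_Ddd + self.n_DDd + self.n_DDD

    def as_array(self) -> np.ndarray:
        return np.array([self.n_ddd, self.n_Ddd, self.n_DDd, self.n_DDD], dtype=float)


@dataclass(frozen=True)
class FreqEstimates:
    """Genotypic, overall-allelic and gametic frequency estimates."""

    F_ddd: float
    F_Ddd: float
    F_DDd: float
    F_DDD: float
    F_d: float
    F_D: float
    F_d_male: float
    F_D_male: float
    F_d_female: float
    F_D_female: float
    N: int

    def genotype_frequencies(self) -> np.ndarray:
        return np.array([self.F_ddd, self.F_Ddd, self.F_DDd, self.F_DDD])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[int]
    p_value: float
    method: str
    note: str = ""


def significance_stars(p: float, alpha_tiers=(0.05, 0.01, 0.001)) -> str:
    """Star annotation at the conventional 0.05/0.01/0.001 tiers (else 'ns')."""
    if p < alpha_tiers[2]:
        return "***"
    if p < alpha_tiers[1]:
        return "**"
    if p < alpha_tiers[0]:
        return "*"
    return "ns"


def tally(records: Iterable[SeedRecord], locus: str) -> GenotypeCounts:
    """Count the four endosperm classes (and missing calls) at a locus."""
    counts = [0, 0, 0, 0]
    missing = 0
    for rec in records:
        dose = rec.dose(locus)
        if dose is None:
            missing += 1
        else:
            counts[dose] += 1
    return GenotypeCounts(*counts, n_missing=missing)


def estimate_frequencies(counts: GenotypeCounts) -> FreqEstimates:
    """Genotypic, allelic and gametic frequencies from endosperm counts."""
    n = counts.N
    if n < 1:
        raise UndefinedFrequencyError("frequencies undefined for N = 0")
    f = counts.as_array() / n
    f_ddd, f_Ddd, f_DDd, f_DDD = f
    f_d = f_ddd + 0.5 * f_Ddd + 0.5 * f_DDd
    f_d_male = f_ddd + f_DDd
    f_d_female = f_ddd + f_Ddd
    return FreqEstimates(
        F_ddd=f_ddd,
        F_Ddd=f_Ddd,
        F_DDd=f_DDd,
        F_DDD=f_DDD,
        F_d=f_d,
        F_D=1.0 - f_d,
        F_d_male=f_d_male,
        F_D_male=1.0 - f_d_male,
        F_d_female=f_d_female,
        F_D_female=1.0 - f_d_female,
        N=n,
    )


def chi2_mendelian(counts: GenotypeCounts) -> TestResult:
    """Pearson chi-square of the four classes against 1:1:1:1 (df = 3)."""
    n = counts.N
    if n < 1:
        raise UndefinedFrequencyError("chi-square undefined for N = 0")
    note = ""
    if n / 4 < 5:
        note = "expected count N/4 < 5; chi-square approximation is coarse"
        warnings.warn(note, stacklevel=2)
    observed = counts.as_array()
    stat, p = stats.chisquare(observed, f_exp=np.full(4, n / 4.0))
    return TestResult(float(stat), 3, float(p), "pearson-chi2", note)


def _published_se(freq: float, complement: float, n: int) -> float:
    return math.sqrt(2.0 * freq * complement / n)


def binomial_half_test(
    freq: float,
    n_genotyped: int,
    complement: Optional[float] = None,
    method: str = "normal",
    n_trials: Optional[int] = None,
) -> TestResult:
    """Two-sided test of a gamete or allelic frequency against 0.5.

    ``method="normal"`` (default) uses z = (freq - 0.5)/SE with the published
    SE = sqrt(2 * freq * complement / N), N the genotyped seed count.
    ``method="exact"`` runs an exact binomial test on
    successes = round(freq * n_trials); pass ``n_trials=N`` for a gamete
    frequency or ``2N`` for the overall allelic frequency.
    """
    if n_genotyped < 1:
        raise UndefinedFrequencyError("test undefined for N = 0")
    if complement is None:
        complement = 1.0 - freq
    if method == "normal":
        if freq <= 0.0 or freq >= 1.0:
            raise DegenerateSEError(
                f"SE formula degenerates at frequency {freq}; use method='exact'"
            )
        se = _published_se(freq, complement, n_genotyped)
        z = (freq - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
        return TestResult(float(z), None, float(p), "normal-approx (published SE)")
    if method == "exact":
        trials = n_trials if n_trials is not None else n_genotyped
        successes = int(round(freq * trials))
        res = stats.binomtest(successes, trials, p=0.5, alternative="two-sided")
        return TestResult(float(successes), None, float(res.pvalue), "exact-binomial")
    raise ValueError(f"unknown method {method!r}")


def gamete_equality_test(est: FreqEstimates) -> TestResult:
    """Two-sided test of equal male and female gamete d-frequencies.

    z = (F_d' - F_d'') / SE with the published SE evaluated at the overall
    allelic frequency: SE = sqrt(2 F_d F_D / N).
    """
    if est.N < 1:
        raise UndefinedFrequencyError("test undefined for N = 0")
    if est.F_d <= 0.0 or est.F_d >= 1.0:
        raise DegenerateSEError("SE degenerates when the overall F_d is 0 or 1")
    se = _published_se(est.F_d, est.F_D, est.N)
    z = (est.F_d_male - est.F_d_female) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(z), None, float(p), "gamete-equality z (published SE)")


def counts_from_frequencies(
    freqs: Sequence[float], n: int, tol: float = 1.05e-3
) -> GenotypeCounts:
    """Reconstruct the integer class counts behind printed frequencies.

    Uses the largest-remainder apportionment of ``freq * N`` as a seed and a
    bounded local search (offsets within +/-2 per class) to find the integer
    vector summing to N whose implied frequencies are all within ``tol`` of
    the printed values, preferring the smallest maximum deviation.  The
    default tolerance is one unit in the third printed decimal, which also
    absorbs summaries printed with truncation rather than rounding.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,):
        raise ValueError("expected four genotype frequencies")
    if n < 1:
        raise UndefinedFrequencyError("cannot reconstruct counts for N < 1")
    if abs(freqs.sum() - 1.0) > 4 * tol:
        raise ReconstructionError(
            f"frequencies sum to {freqs.sum():.4f}, not 1 within tolerance"
        )
    raw = freqs * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    seed = base.copy()
    for idx in order[:short]:
        seed[idx] += 1

    best: Optional[np.ndarray] = None
    best_dev = np.inf
    for offsets in itertools.product(range(-2, 3), repeat=3):
        off = np.array([*offsets, -sum(offsets)])
        cand = seed + off
        if (cand < 0).any() or cand.sum() != n:
            continue
        dev = np.abs(cand / n - freqs)
        if dev.max() <= tol and dev.max() < best_dev:
            best, best_dev = cand, dev.max()
    if best is None:
        raise ReconstructionError(
            f"no integer composition of {n} matches frequencies {freqs} "
            f"within {tol}"
        )
    return GenotypeCounts(*(int(c) for c in best))


def pool_counts(*counts: GenotypeCounts) -> GenotypeCounts:
    """Pool genotyped counts from subpopulations (e.g. germinated + non)."""
    arr = np.sum([c.as_array() for c in counts], axis=0).astype(int)
    missing = sum(c.n_missing for c in counts)
    return GenotypeCounts(*(int(x) for x in arr), n_missing=missing)


def combine_weighted(
    est_germinated: FreqEstimates,
    est_nongerminated: FreqEstimates,
    germination_rate: float,
) -> FreqEstimates:
    """Join two subpopulations summarised only by frequencies.

    Each genotype frequency is the mean of the germinated and nongerminated
    estimates weighted by (germination rate, 1 - rate); allelic and gametic
    frequencies are recomputed from the weighted genotype frequencies.  Used
    when one side is available only as a frequency summary; when both sides
    are genotyped, pool the raw counts instead (``pool_counts``).
    """
    if not 0.0 <= germination_rate <= 1.0:
        raise ValueError("germination_rate must lie in [0, 1]")
    w = germination_rate
    f = (
        w * est_germinated.genotype_frequencies()
        + (1.0 - w) * est_nongerminated.genotype_frequencies()
    )
    f_d = f[0] + 0.5 * f[1] + 0.5 * f[2]
    return FreqEstimates(
        F_ddd=f[0],
        F_Ddd=f[1],
        F_DDd=f[2],
        F_DDD=f[3],
        F_d=f_d,
        F_D=1.0 - f_d,
        F_d_male=f[0] + f[2],
        F_D_male=1.0 - (f[0] + f[2]),
        F_d_female=f[0] + f[1],
        F_D_female=1.0 - (f[0] + f[1]),
        N=est_germinated.N + est_nongerminated.N,
    )
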