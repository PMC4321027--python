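"""Decision rules classifying a dormancy locus by tissue of action.

Three rules read the frequency evidence from germinated (G), nongerminated
(NG), and joined/random samples of F2 seeds:

1. Offspring rule -- the genotypic chi-square rejects Mendelian ratios in the
   germinated subpopulation and the dormancy-reducing allele is more frequent
   among germinated than nongerminated seeds: the locus acts in an offspring
   tissue (embryo or endosperm) and responded to the germination selection.
2. Maternal rule -- no test rejects in any examined subpopulation and F_d
   stays at 0.5 throughout: genotypic variation of the offspring tissues does
   not touch germination, so the dormancy must be imposed maternally.
3. SDL rule -- Mendelian ratios are violated in the joined population or a
   random sample, where selection on germination cannot act: a segregation
   distortion locus, with the gamete side read off the male/female tests.

An offspring call is refined using two independent signatures that must
agree: (i) whether the two heterozygous endosperm classes (Ddd vs DDd, both
Dd embryos) differ in germination timing -- they do for an endosperm-dose
effect and cannot for an embryo effect -- and (ii) whether the germinated
subpopulation shows the gamete-frequency asymmetry F_d'' > F_d' that a
per-copy endosperm dose effect produces (the duplicated female gamete carries
two of the three doses).  Disagreement yields "indeterminate" with both
evidence lines reported.  Because a locus may additionally act maternally
without being detectable here (mothers are uniformly heterozygous), offspring
calls mean "offspring at least".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .frequencies import (
    FreqEstimates,
    GenotypeCounts,
    TestResult,
    binomial_half_test,
    chi2_mendelian,
    estimate_frequencies,
    gamete_equality_test,
)
from .genotypes import SeedPopulation, SeedRecord, partition_subpopulations
from .frequencies import tally

__all__ = [
    "SubpopEvidence",
    "TissueInference",
    "evaluate_counts",
    "heterozygote_curve_equivalence",
    "classify_locus",
    "classify_population",
]


@dataclass
class SubpopEvidence:
    """Frequency estimates plus the full test battery for one sample."""

    label: str
    counts: GenotypeCounts
    est: FreqEstimates
    chi2: TestResult
    fd_test: TestResult
    fd_male_test: TestResult
    fd_female_test: TestResult
    gamete_eq: TestResult


def evaluate_counts(counts: GenotypeCounts, label: str = "") -> SubpopEvidence:
    """Run the frequency estimators and tests on one set of genotype counts."""
    est = estimate_frequencies(counts)
    return SubpopEvidence(
        label=label,
        counts=counts,
        est=est,
        chi2=chi2_mendelian(counts),
        fd_test=binomial_half_test(est.F_d, est.N),
        fd_male_test=binomial_half_test(est.F_d_male, est.N),
        fd_female_test=binomial_half_test(est.F_d_female, est.N),
        gamete_eq=gamete_equality_test(est),
    )


def heterozygote_curve_equivalence(
    times_DDd: Sequence[float],
    times_Ddd: Sequence[float],
    n_nongerm_DDd: int = 0,
    n_nongerm_Ddd: int = 0,
    end_day: float = 7.0,
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    min_per_class: int = 5,
) -> TestResult:
    """Permutation test of equal germination timing in Ddd vs DDd seeds.

    Nongerminated seeds of each class are included as right-censored
    observations placed at end_day + 1 (one rank beyond the last counting
    day).  The statistic is the difference in class means of these censored
    times; its two-sided p-value comes from random relabellings of the pooled
    sample.  Identical in distribution for the two classes under an embryo
    model (both are Dd embryos), shifted by one additive dose under an
    endosperm model.
    """
    rng = np.random.default_rng() if rng is None else rng
    censored = float(end_day) + 1.0
    x = np.concatenate([np.asarray(times_DDd, float), np.full(n_nongerm_DDd, censored)])
    y = np.concatenate([np.asarray(times_Ddd, float), np.full(n_nongerm_Ddd, censored)])
    if len(x) < min_per_class or len(y) < min_per_class:
        return TestResult(
            float("nan"), None, float("nan"), "permutation",
            note=f"not evaluable: fewer than {min_per_class} seeds in a class",
        )
    observed = x.mean() - y.mean()
    pooled = np.concatenate([x, y])
    n1 = len(x)
    tiled = np.tile(pooled, (n_permutations, 1))
    perms = rng.permuted(tiled, axis=1)
    diffs = perms[:, :n1].mean(axis=1) - perms[:, n1:].mean(axis=1)
    # add-one estimator keeps p > 0 and counts the observed relabelling
    p = (np.sum(np.abs(diffs) >= abs(observed) - 1e-12) + 1) / (n_permutations + 1)
    return TestResult(float(observed), None, float(p), "permutation")


@dataclass
class TissueInference:
    tissue_call: str  # maternal | embryo | endosperm | indeterminate
    offspring_rule: Optional[bool]
    maternal_rule: Optional[bool]
    sdl_flag: Optional[bool]
    sdl_side: str  # male | female | both | none | not-evaluable
    dosage_flag: Optional[bool]
    preferential_fertilization_flag: Optional[bool]
    evidence: list[str] = field(default_factory=list)
    not_evaluable: list[str] = field(default_factory=list)


def classify_locus(
    germinated: SubpopEvidence,
    nongerminated: Optional[SubpopEvidence] = None,
    joined_or_random: Optional[SubpopEvidence] = None,
    het_equivalence: Optional[TestResult] = None,
    alpha: float = 0.05,
) -> TissueInference:
    """Apply the three decision rules and the offspring-tissue refinement."""
    evidence: list[str] = []
    not_evaluable: list[str] = []

    # Rule 1: offspring tissue
    g_distorted = bool(germinated.chi2.p_value < alpha)
    if nongerminated is not None:
        direction = bool(germinated.est.F_d > nongerminated.est.F_d)
        offspring = g_distorted and direction
        evidence.append(
            f"offspring rule: chi2(G) p={germinated.chi2.p_value:.4g}, "
            f"F_d(G)={germinated.est.F_d:.3f} vs F_d(NG)={nongerminated.est.F_d:.3f}"
        )
    else:
        offspring = g_distorted
        evidence.append(
            f"offspring rule (G only): chi2(G) p={germinated.chi2.p_value:.4g}"
        )

    # Rule 2: maternal tissue -- nothing rejects anywhere examined
    pools = [germinated] + [s for s in (nongerminated, joined_or_random) if s]
    maternal = bool(
        all(s.chi2.p_value >= alpha and s.fd_test.p_value >= alpha for s in pools)
    )
    evidence.append(
        "maternal rule: "
        + "; ".join(
            f"{s.label or 'sample'}: chi2 p={s.chi2.p_value:.3g}, "
            f"F_d={s.est.F_d:.3f} (p={s.fd_test.p_value:.3g})"
            for s in pools
        )
    )

    # Rule 3: SDL in a joined population / random sample
    sdl_flag: Optional[bool]
    dosage = bool(
        germinated.gamete_eq.p_value < alpha
        and germinated.est.F_d_female > germinated.est.F_d_male
    )
    if joined_or_random is not None:
        sdl_flag = bool(joined_or_random.chi2.p_value < alpha)
        male_dev = bool(joined_or_random.fd_male_test.p_value < alpha)
        female_dev = bool(joined_or_random.fd_female_test.p_value < alpha)
        if male_dev and female_dev:
            sdl_side = "both"
        elif male_dev:
            sdl_side = "male"
        elif female_dev:
            sdl_side = "female"
        else:
            sdl_side = "none"
        pref_fert = bool(
            male_dev
            and joined_or_random.est.F_d_male > joined_or_random.est.F_d_female
        )
        evidence.append(
            f"SDL rule: chi2(joined/random) p={joined_or_random.chi2.p_value:.4g}, "
            f"F_d'={joined_or_random.est.F_d_male:.3f}, "
            f"F_d''={joined_or_random.est.F_d_female:.3f}"
        )
    else:
        sdl_flag, sdl_side, pref_fert = None, "not-evaluable", None
        not_evaluable.append("SDL rule: no joined population or random sample")

    # Refinement of an offspring call: the two signatures must agree
    call = "indeterminate"
    if offspring:
        if het_equivalence is None or np.isnan(het_equivalence.p_value):
            not_evaluable.append(
                "endosperm/embryo refinement: heterozygote timing comparison "
                "not evaluable (offspring at least)"
            )
        else:
            curves_say_endosperm = het_equivalence.p_value < alpha
            gametes_say_endosperm = dosage
            evidence.append(
                f"refinement: heterozygote-equivalence p="
                f"{het_equivalence.p_value:.4g}; gamete asymmetry "
                f"F_d''-F_d'={germinated.est.F_d_female - germinated.est.F_d_male:+.3f} "
                f"(p={germinated.gamete_eq.p_value:.4g})"
            )
            if curves_say_endosperm and gametes_say_endosperm:
                call = "endosperm"
            elif not curves_say_endosperm and not gametes_say_endosperm:
                call = "embryo"
            else:
                evidence.append(
                    "refinement signatures disagree -> indeterminate "
                    "(offspring at least)"
                )
    elif maternal:
        call = "maternal"

    return TissueInference(
        tissue_call=call,
        offspring_rule=offspring,
        maternal_rule=maternal,
        sdl_flag=sdl_flag,
        sdl_side=sdl_side,
        dosage_flag=dosage,
        preferential_fertilization_flag=pref_fert,
        evidence=evidence,
        not_evaluable=not_evaluable,
    )


def classify_population(
    pop: SeedPopulation,
    locus: str,
    alpha: float = 0.05,
    random_sample: Optional[GenotypeCounts] = None,
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> TissueInference:
    """Assemble all evidence from one experiment and classify the locus.

    The joined population is the pooled genotyped counts of both
    subpopulations when both were genotyped, unless an external
    ``random_sample`` is supplied (which takes precedence for the SDL rule,
    mirroring the use of an ungerminated random seed sample).
    """
    from .frequencies import pool_counts

    germ_recs, nong_recs = partition_subpopulations(pop)
    g_counts = tally(germ_recs, locus)
    if g_counts.N < 1:
        raise ValueError("classification requires genotyped germinated seeds")
    g_ev = evaluate_counts(g_counts, label="G")

    ng_counts = tally(nong_recs, locus)
    ng_ev = evaluate_counts(ng_counts, label="NG") if ng_counts.N >= 1 else None

    if random_sample is not None:
        joined_ev = evaluate_counts(random_sample, label="random")
    elif ng_ev is not None:
        joined_ev = evaluate_counts(pool_counts(g_counts, ng_counts), label="G+NG")
    else:
        joined_ev = None

    het = None
    if ng_ev is not None:
        times_DDd = [r.germination_day for r in germ_recs if r.dose(locus) == 2]
        times_Ddd = [r.germination_day for r in germ_recs if r.dose(locus) == 1]
        het = heterozygote_curve_equivalence(
            times_DDd,
            times_Ddd,
            n_nongerm_DDd=ng_counts.n_DDd,
            n_nongerm_Ddd=ng_counts.n_Ddd,
            end_day=pop.end_day,
            n_permutations=n_permutations,
            rng=rng,
        )

    return classify_locus(
        g_ev,
        nongerminated=ng_ev,
        joined_or_random=joined_ev,
        het_equivalence=het,
        alpha=alpha,
    )
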