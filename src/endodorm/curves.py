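"""Cumulative germination distributions and allele-frequency trajectories.

The population curve is the running percentage of all tested seeds that have
germinated by each counting day.  Per-genotype curves express, for each
endosperm class i, the seeds of that class germinated through day j as a
percentage of the class's estimated total seed count

    T_i = (class-i seeds germinated over the whole test) + N_ng * F_ng,i

where N_ng is the total nongerminated seed count (including seeds whose
genotyping failed) and F_ng,i the class frequency among genotyped
nongerminated seeds.  The denominator is day-independent, so each curve rises
to a plateau (total germinated of class i) / T_i -- genotypes under stronger
dormancy plateau lower.  A literal day-dependent denominator (the cumulative
germinated count re-entering the denominator) is kept behind
``literal_denominator=True`` for comparison; it forces every curve toward its
own ceiling and is not used for inference.

The allele trajectory applies the frequency estimators to the seeds
germinated by each day (cumulative-to-date): a locus acting in an offspring
tissue shows the dormancy-reducing allele enriched early and decaying toward
the whole-subpopulation value, while a maternally acting locus stays flat
around 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .frequencies import FreqEstimates, estimate_frequencies, tally
from .genotypes import (
    ENDOSPERM_LABELS,
    SeedPopulation,
    SeedRecord,
    partition_subpopulations,
)

__all__ = [
    "GerminationCurve",
    "AlleleTrajectory",
    "population_curve",
    "genotype_curves",
    "allele_trajectory",
]


@dataclass
class GerminationCurve:
    days: np.ndarray
    cumulative_pct: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cumulative_pct = np.asarray(self.cumulative_pct, dtype=float)
        if np.any(np.diff(self.cumulative_pct) < -1e-9):
            raise ValueError("cumulative germination must be nondecreasing")

    @property
    def final_pct(self) -> float:
        return float(self.cumulative_pct[-1]) if self.cumulative_pct.size else 0.0


@dataclass
class AlleleTrajectory:
    days: np.ndarray
    F_d_at_day: np.ndarray
    F_d_male_at_day: np.ndarray
    F_d_female_at_day: np.ndarray
    n_at_day: np.ndarray
    locus: str


def _cumulative_counts(days_observed: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    obs = np.asarray(sorted(days_observed), dtype=float)
    return np.array([np.searchsorted(obs, d, side="right") for d in grid], dtype=float)


def population_curve(pop: SeedPopulation) -> GerminationCurve:
    """Cumulative germination percentage of all tested seeds by day."""
    if pop.n_total_tested < 1:
        raise ValueError("population curve undefined without tested seeds")
    grid = pop.counting_grid()
    germinated, _ = partition_subpopulations(pop)
    cum = _cumulative_counts([r.germination_day for r in germinated], grid)
    return GerminationCurve(
        days=np.asarray(grid),
        cumulative_pct=cum / pop.n_total_tested * 100.0,
        label=pop.experiment_id or "population",
    )


def genotype_curves(
    pop: SeedPopulation,
    locus: str,
    literal_denominator: bool = False,
) -> dict[int, GerminationCurve]:
    """Cumulative germination curve per endosperm genotype class.

    Requires genotyped seeds in both subpopulations: the class shares of the
    nongerminated pool are estimated from its genotyped members and spread
    over the full nongerminated count (missing calls included).
    """
    grid = np.asarray(pop.counting_grid())
    germinated, nongerminated = partition_subpopulations(pop)
    ng_counts = tally(nongerminated, locus)
    if ng_counts.N < 1:
        raise ValueError(
            "genotype curves need genotyped nongerminated seeds to estimate "
            "class totals (F_ng,i undefined)"
        )
    n_ng_total = len(nongerminated)  # includes missing-genotype nongerminated
    f_ng = ng_counts.as_array() / ng_counts.N

    curves: dict[int, GerminationCurve] = {}
    for dose in range(4):
        days_i = [
            r.germination_day for r in germinated if r.dose(locus) == dose
        ]
        cum = _cumulative_counts(days_i, grid)
        total_germ_i = float(len(days_i))
        if literal_denominator:
            denom = cum + n_ng_total * f_ng[dose]
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(denom > 0, cum / denom * 100.0, 0.0)
        else:
            t_i = total_germ_i + n_ng_total * f_ng[dose]
            pct = cum / t_i * 100.0 if t_i > 0 else np.zeros_like(cum)
        curves[dose] = GerminationCurve(
            days=grid, cumulative_pct=pct, label=ENDOSPERM_LABELS[dose]
        )
    return curves


def allele_trajectory(
    germinated: Iterable[SeedRecord],
    locus: str,
    grid: Optional[Sequence[float]] = None,
) -> AlleleTrajectory:
    """Allelic/gametic d-frequencies among seeds germinated by each day."""
    recs = [r for r in germinated if r.germinated]
    genotyped = [r for r in recs if r.dose(locus) is not None]
    if not genotyped:
        raise ValueError("allele trajectory needs at least one genotyped seed")
    if grid is None:
        days = sorted({r.germination_day for r in recs})
    else:
        days = list(grid)
    f_d, f_dm, f_df, n_at = [], [], [], []
    for day in days:
        subset = [r for r in genotyped if r.germination_day <= day]
        n_at.append(len(subset))
        if subset:
            est = estimate_frequencies(tally(subset, locus))
            f_d.append(est.F_d)
            f_dm.append(est.F_d_male)
            f_df.append(est.F_d_female)
        else:
            f_d.append(np.nan)
            f_dm.append(np.nan)
            f_df.append(np.nan)
    return AlleleTrajectory(
        days=np.asarray(days, dtype=float),
        F_d_at_day=np.asarray(f_d),
        F_d_male_at_day=np.asarray(f_dm),
        F_d_female_at_day=np.asarray(f_df),
        n_at_day=np.asarray(n_at),
        locus=locus,
    )
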