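"""Two-generation, two-ploidy genotype algebra of F2 seeds from a selfed F1.

An F2 seed from a self-pollinated heterozygous (``Dd``) F1 plant carries three
genetically distinct tissues:

* maternal tissues (testa, pericarp): always ``Dd`` -- the mother's genotype;
* the diploid embryo: egg (n) + one sperm (n), genotypes ``dd``/``Dd``/``DD``;
* the triploid endosperm: two genetically identical polar nuclei (n each) +
  the other sperm (n), genotypes ``ddd``/``Ddd``/``DDd``/``DDD``.

``D`` is the dormancy-enhancing allele and ``d`` the dormancy-reducing one.
Genotypes are stored as integer D-allele doses (endosperm 0-3, embryo 0-2);
letter strings such as ``"DDd"`` exist only at I/O boundaries.  Because both
offspring tissues derive from the same two gametes, the endosperm dose
determines the embryo genotype and the (male, female) gamete pair uniquely:

    endosperm dose = male_D + 2 * female_D
    embryo dose    = male_D + female_D
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ENDOSPERM_LABELS",
    "EMBRYO_LABELS",
    "GametePair",
    "SeedRecord",
    "SeedPopulation",
    "InvalidGenotypeError",
    "endosperm_label",
    "embryo_label",
    "parse_endosperm_genotype",
    "endosperm_to_embryo",
    "endosperm_to_gametes",
    "partition_subpopulations",
]

#: Endosperm genotype labels indexed by D-allele dose.
ENDOSPERM_LABELS = ("ddd", "Ddd", "DDd", "DDD")

#: Embryo genotype labels indexed by D-allele dose.
EMBRYO_LABELS = ("dd", "Dd", "DD")

#: Token used in seed tables for a missing genotype call.
NA_TOKEN = "NA"


class InvalidGenotypeError(ValueError):
    """Raised for a genotype dose or token outside the biallelic F2 model."""


def _check_endosperm_dose(dose: int) -> int:
    if dose not in (0, 1, 2, 3):
        raise InvalidGenotypeError(
            f"endosperm D-allele dose must be in {{0,1,2,3}}, got {dose!r}"
        )
    return int(dose)


@dataclass(frozen=True)
class GametePair:
    """The male and female gamete D-allele contributions behind one seed.

    The female gamete is counted twice in the endosperm (two identical polar
    nuclei) and once in the embryo.
    """

    male_D: int
    female_D: int

    def __post_init__(self) -> None:
        if self.male_D not in (0, 1) or self.female_D not in (0, 1):
            raise InvalidGenotypeError(
                f"gamete D contributions must be 0 or 1, got {self!r}"
            )

    @property
    def endosperm_dose(self) -> int:
        return self.male_D + 2 * self.female_D

    @property
    def embryo_dose(self) -> int:
        return self.male_D + self.female_D


def endosperm_label(dose: int) -> str:
    """Letter-string label (``ddd`` .. ``DDD``) for an endosperm dose."""
    return ENDOSPERM_LABELS[_check_endosperm_dose(dose)]


def embryo_label(dose: int) -> str:
    """Letter-string label (``dd`` .. ``DD``) for an embryo dose."""
    if dose not in (0, 1, 2):
        raise InvalidGenotypeError(
            f"embryo D-allele dose must be in {{0,1,2}}, got {dose!r}"
        )
    return EMBRYO_LABELS[dose]


def parse_endosperm_genotype(token: str | int | None) -> Optional[int]:
    """Parse a seed-table genotype token into an endosperm dose (or None).

    Accepts dose integers 0-3 (as int or string), the letter strings
    ``ddd``/``Ddd``/``DDd``/``DDD`` (case-sensitive: allele identity is coded
    by case), and ``NA``/empty for missing.
    """
    if token is None:
        return None
    if isinstance(token, int):
        return _check_endosperm_dose(token)
    tok = token.strip()
    if tok == "" or tok.upper() == NA_TOKEN:
        return None
    if tok in ENDOSPERM_LABELS:
        return ENDOSPERM_LABELS.index(tok)
    try:
        return _check_endosperm_dose(int(tok))
    except (ValueError, TypeError):
        pass
    raise InvalidGenotypeError(f"unrecognised endosperm genotype token {token!r}")


def endosperm_to_embryo(dose: int) -> int:
    """Embryo D-dose determined by an endosperm D-dose.

    Both heterozygous endosperms (``Ddd``, ``DDd``) map to the ``Dd`` embryo
    because egg and polar nuclei are genetically identical.
    """
    pair = endosperm_to_gametes(dose)
    return pair.embryo_dose


def endosperm_to_gametes(dose: int) -> GametePair:
    """Decompose an endosperm D-dose into its unique (male, female) gametes."""
    dose = _check_endosperm_dose(dose)
    return GametePair(male_D=dose % 2, female_D=dose // 2)


@dataclass
class SeedRecord:
    """One scored seed: per-locus endosperm dose(s) and germination outcome.

    ``germination_day`` is days since imbibition at which germination
    (radicle >3 mm) was scored, on the experiment's counting grid; ``None``
    means the seed had not germinated by the end of the test.  A missing
    genotype call at a locus is ``None`` in ``locus_doses``.
    """

    seed_id: str
    locus_doses: Mapping[str, Optional[int]]
    germination_day: Optional[float] = None
    experiment_id: str = ""

    @property
    def germinated(self) -> bool:
        return self.germination_day is not None

    def dose(self, locus: str) -> Optional[int]:
        return self.locus_doses.get(locus)

    def embryo_dose(self, locus: str) -> Optional[int]:
        d = self.locus_doses.get(locus)
        return None if d is None else endosperm_to_embryo(d)


@dataclass
class SeedPopulation:
    """A germination experiment on F2 seeds from one selfed heterozygous F1.

    ``n_total_tested`` counts all seeds placed in the test, which is the
    denominator of the population germination curve; it may exceed the number
    of scored records (contaminated seeds are dropped before analysis and
    tallied in ``n_contaminated``).
    """

    records: Sequence[SeedRecord]
    n_total_tested: int
    end_day: float = 7.0
    counting_interval: float = 1.0
    after_ripening_days: Optional[float] = None
    experiment_id: str = ""
    n_contaminated: int = 0

    def __post_init__(self) -> None:
        if self.n_total_tested < len(self.records):
            raise ValueError(
                "n_total_tested must be at least the number of scored records"
            )
        if self.end_day < 2:
            raise ValueError("the counting window starts at day 2")

    @property
    def loci(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for locus in rec.locus_doses:
                seen.setdefault(locus, None)
        return tuple(seen)

    def counting_grid(self) -> list[float]:
        """Observation days: 2, 2+interval, ... up to end_day inclusive."""
        n_steps = int(round((self.end_day - 2.0) / self.counting_interval))
        return [2.0 + k * self.counting_interval for k in range(n_steps + 1)]

    @property
    def germination_rate(self) -> float:
        n_g = sum(1 for r in self.records if r.germinated)
        return n_g / self.n_total_tested


def partition_subpopulations(
    pop: SeedPopulation,
) -> tuple[list[SeedRecord], list[SeedRecord]]:
    """Split scored seeds into (germinated, nongerminated) subpopulations.

    Germinated records are returned ordered by germination day; the two lists
    are disjoint and their union is the scored records.
    """
    germinated = sorted(
        (r for r in pop.records if r.germinated),
        key=lambda r: (r.germination_day, r.seed_id),
    )
    nongerminated = [r for r in pop.records if not r.germinated]
    return germinated, nongerminated
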