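"""Published summary statistics for the rice seed-dormancy loci.

These are the reported endosperm genotypic frequency summaries from
germination experiments on F2 seed populations segregating for the rice seed
dormancy loci SD7-1, SD1-2 and SD12 (singly or, for the last four entries,
for the digenic SD7-1 & SD12 system).  Each entry records the subpopulation
(G = germinated, NG = nongerminated, G+NG = joined, random = an ungerminated
random sample), the number of genotyped seeds N, the four printed genotype
frequencies, and the printed chi-square and d-allele frequency columns.

Printed values are inputs here: integer genotype counts are reconstructed
from frequencies and N with
:func:`endodorm.frequencies.counts_from_frequencies`, after which the whole
frequency/test battery can be recomputed and compared against the printed
columns.  Known misprints in the source table are annotated per entry and
excluded from comparisons: one chi-square statistic inconsistent with its own
printed p-value, and one female-gamete frequency inconsistent with the
printed genotype frequencies it derives from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["ReferenceRow", "REFERENCE_SUBPOPULATIONS", "reference_row"]


@dataclass(frozen=True)
class ReferenceRow:
    locus: str
    experiment: str
    subpopulation: str  # G | NG | G+NG | random
    n_genotyped: int
    freqs: tuple[float, float, float, float]  # F_ddd, F_Ddd, F_DDd, F_DDD
    chi2: Optional[float]
    chi2_decimals: int
    p: Optional[float]  # None when printed as "<0.0001"
    F_d: float
    F_d_male: Optional[float]  # None where the printed value is a misprint
    F_d_female: Optional[float]  # None where the printed value is a misprint
    misprints: tuple[str, ...] = ()


REFERENCE_SUBPOPULATIONS: tuple[ReferenceRow, ...] = (
    ReferenceRow("SD7-1", "Ex1", "G", 43, (0.256, 0.256, 0.256, 0.232),
                 0.07, 2, 0.995, 0.512, 0.512, 0.511),
    ReferenceRow("SD7-1", "Ex2", "G", 176, (0.256, 0.216, 0.307, 0.222),
                 3.68, 2, 0.298, 0.517, 0.563, 0.472),
    ReferenceRow("SD7-1", "Ex3", "G", 481, (0.262, 0.247, 0.249, 0.241),
                 0.44, 2, 0.932, 0.510, 0.511, 0.509),
    ReferenceRow("SD7-1", "Ex3", "NG", 138, (0.283, 0.232, 0.246, 0.239),
                 0.84, 2, 0.839, 0.522, 0.529, 0.514),
    ReferenceRow("SD7-1", "Ex3", "G+NG", 619, (0.267, 0.244, 0.249, 0.241),
                 0.99, 2, 0.804, 0.513, 0.515, 0.511),
    ReferenceRow("SD1-2", "Ex1", "G", 250, (0.376, 0.296, 0.200, 0.128),
                 35.4, 1, None, 0.624, 0.576, 0.672),
    # two misprints: the chi-square statistic is inconsistent with its own
    # printed p (counts give 1.38, whose upper-tail p is the printed 0.710),
    # and the printed male/female gamete frequencies (0.497/0.503) are the
    # transpose of what the printed genotype frequencies give
    # (F_d' = 0.261+0.242 = 0.503, F_d'' = 0.261+0.236 = 0.497)
    ReferenceRow("SD1-2", "Ex2", "G", 674, (0.261, 0.236, 0.242, 0.261),
                 None, 2, 0.710, 0.500, None, None,
                 misprints=("chi2", "F_d_male", "F_d_female")),
    ReferenceRow("SD1-2", "Ex3", "G", 280, (0.396, 0.300, 0.207, 0.096),
                 55.3, 1, None, 0.650, 0.604, 0.696),
    ReferenceRow("SD1-2", "Ex3", "NG", 801, (0.205, 0.236, 0.257, 0.302),
                 16.1, 1, 0.0011, 0.451, 0.462, 0.441),
    ReferenceRow("SD1-2", "Ex3", "G+NG", 1081, (0.254, 0.253, 0.244, 0.249),
                 0.26, 2, 0.967, 0.503, 0.499, 0.507),
    ReferenceRow("SD12", "Ex1", "G", 381, (0.367, 0.234, 0.257, 0.142),
                 39.4, 1, None, 0.613, 0.625, 0.601),
    ReferenceRow("SD12", "Ex2", "G", 215, (0.381, 0.195, 0.228, 0.195),
                 20.4, 1, 0.0001, 0.593, 0.609, 0.577),
    ReferenceRow("SD12", "Ex3", "G", 161, (0.372, 0.186, 0.298, 0.143),
                 21.2, 1, None, 0.615, 0.671, 0.559),
    ReferenceRow("SD12", "Ex3", "NG", 234, (0.269, 0.209, 0.291, 0.231),
                 3.77, 2, 0.286, 0.519, 0.560, 0.479),
    ReferenceRow("SD12", "Ex4", "random", 484, (0.287, 0.231, 0.285, 0.196),
                 11.3, 1, 0.0101, 0.545, 0.572, 0.519),
    # female-gamete frequency misprinted (printed genotype frequencies give
    # 0.477 + 0.181 = 0.658, not the printed 0.661)
    ReferenceRow("SD12", "digenic Ex1", "G", 436, (0.477, 0.181, 0.216, 0.126),
                 127.0, 0, None, 0.675, 0.693, None,
                 misprints=("F_d_female",)),
    ReferenceRow("SD7-1", "digenic Ex1", "G", 436, (0.225, 0.239, 0.280, 0.257),
                 2.97, 2, 0.396, 0.484, 0.504, 0.463),
    ReferenceRow("SD12", "digenic Ex2", "NG", 121, (0.149, 0.231, 0.165, 0.454),
                 29.0, 0, None, 0.347, 0.314, 0.380),
    ReferenceRow("SD7-1", "digenic Ex2", "NG", 121, (0.314, 0.256, 0.198, 0.231),
                 3.46, 2, 0.326, 0.541, 0.512, 0.570),
)


def reference_row(locus: str, experiment: str, subpopulation: str) -> ReferenceRow:
    for row in REFERENCE_SUBPOPULATIONS:
        if (row.locus, row.experiment, row.subpopulation) == (
            locus,
            experiment,
            subpopulation,
        ):
            return row
    raise KeyError((locus, experiment, subpopulation))
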