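import numpy as np
import pytest

from endodorm.genotypes import SeedPopulation, SeedRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_population(
    days_by_dose: dict[int, list[float | None]],
    locus: str = "L",
    n_total: int | None = None,
    end_day: float = 7.0,
    extra_nongerm_missing: int = 0,
) -> SeedPopulation:
    """Hand-built population: per endosperm dose, a list of germination days
    (None = nongerminated); optionally extra nongerminated seeds with a
    missing genotype call."""
    records = []
    i = 0
    for dose, days in days_by_dose.items():
        for day in days:
            records.append(
                SeedRecord(
                    seed_id=f"s{i:04d}",
                    locus_doses={locus: dose},
                    germination_day=day,
                    experiment_id="toy",
                )
            )
            i += 1
    for _ in range(extra_nongerm_missing):
        records.append(
            SeedRecord(
                seed_id=f"s{i:04d}",
                locus_doses={locus: None},
                germination_day=None,
                experiment_id="toy",
            )
        )
        i += 1
    return SeedPopulation(
        records=records,
        n_total_tested=n_total if n_total is not None else len(records),
        end_day=end_day,
        experiment_id="toy",
    )
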