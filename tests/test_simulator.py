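import numpy as np
import pytest

from endodorm.frequencies import estimate_frequencies, tally
from endodorm.genotypes import endosperm_to_gametes, partition_subpopulations
from endodorm.simulate import (
    LocusConfig,
    SimulationConfig,
    recovery_config,
    scenario_presets,
    simulate_population,
)


def test_reproducible_under_seed():
    cfg = SimulationConfig(n_seeds=200, rng_seed=77)
    a = simulate_population(cfg)
    b = simulate_population(cfg)
    assert [r.locus_doses for r in a.records] == [r.locus_doses for r in b.records]
    assert [r.germination_day for r in a.records] == [
        r.germination_day for r in b.records
    ]


def test_gamete_bookkeeping_matches_truth():
    cfg = SimulationConfig(
        n_seeds=500,
        loci=(LocusConfig(name="L", p_d_male=0.6, p_d_female=0.45),),
        rng_seed=3,
    )
    pop, truth = simulate_population(cfg, return_truth=True)
    for dose, male, female in zip(
        truth["L_dose"], truth["L_male_D"], truth["L_female_D"]
    ):
        pair = endosperm_to_gametes(int(dose))
        assert (pair.male_D, pair.female_D) == (male, female)


def test_mendelian_null_class_frequencies():
    cfg = SimulationConfig(n_seeds=4000, loci=(LocusConfig(name="L"),), rng_seed=11)
    pop = simulate_population(cfg)
    counts = tally(pop.records, "L").as_array()
    # each class ~1000; 4 sigma binomial band
    sd = np.sqrt(4000 * 0.25 * 0.75)
    assert np.all(np.abs(counts - 1000) < 4 * sd)


def test_one_sided_distortion_leaves_other_side_mendelian():
    cfg = SimulationConfig(
        n_seeds=6000,
        loci=(LocusConfig(name="L", p_d_male=0.57),),
        rng_seed=21,
    )
    pop = simulate_population(cfg)
    est = estimate_frequencies(tally(pop.records, "L"))
    se = np.sqrt(0.25 / 6000)
    assert est.F_d_male == pytest.approx(0.57, abs=4 * se)
    assert est.F_d_female == pytest.approx(0.50, abs=4 * se)


def test_maternal_mode_keeps_germinated_subpopulation_mendelian():
    cfg = scenario_presets()["sd7_1_like"]
    pop = simulate_population(cfg, rng=np.random.default_rng(31))
    germ, _ = partition_subpopulations(pop)
    est = estimate_frequencies(tally(germ, "SD7-1"))
    assert est.F_d == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / est.N))


def test_embryo_additive_enriches_d_allele_in_germinated():
    cfg = scenario_presets()["sd12_like"]
    pop = simulate_population(cfg, rng=np.random.default_rng(41))
    germ, nong = partition_subpopulations(pop)
    est_g = estimate_frequencies(tally(germ, "SD12"))
    est_ng = estimate_frequencies(tally(nong, "SD12"))
    assert est_g.F_d > 0.55 > est_ng.F_d


def test_dormant_fraction_monotonically_suppresses_germination():
    rates = []
    for q in (0.0, 0.25, 0.5, 0.75):
        cfg = SimulationConfig(
            n_seeds=2000,
            baseline_mean_time=5.0,
            dormant_fraction=q,
            rng_seed=8,  # common random numbers across the grid
        )
        rates.append(simulate_population(cfg).germination_rate)
    assert all(a >= b for a, b in zip(rates, rates[1:]))


def test_days_on_counting_grid_within_window():
    cfg = recovery_config("embryo", 0.5, n_seeds=500)
    pop = simulate_population(cfg, rng=np.random.default_rng(2))
    for rec in pop.records:
        if rec.germinated:
            day = rec.germination_day
            assert 2.0 <= day <= cfg.end_day
            steps = (day - 2.0) / cfg.counting_interval
            assert steps == pytest.approx(round(steps), abs=1e-9)


def test_genotyping_dropout_rates_by_status():
    cfg = SimulationConfig(
        n_seeds=4000,
        baseline_mean_time=7.0,
        dormant_fraction=0.2,
        genotyping_success=0.95,
        genotyping_success_nongerminated=0.5,
        rng_seed=6,
    )
    pop = simulate_population(cfg)
    germ, nong = partition_subpopulations(pop)
    miss_g = tally(germ, "L1").n_missing / len(germ)
    miss_ng = tally(nong, "L1").n_missing / len(nong)
    assert miss_g == pytest.approx(0.05, abs=0.03)
    assert miss_ng == pytest.approx(0.5, abs=0.05)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_seeds=0)
    with pytest.raises(ValueError):
        SimulationConfig(dormant_fraction=1.5)
    with pytest.raises(ValueError):
        LocusConfig(p_d_male=1.2)
    with pytest.raises(ValueError):
        LocusConfig(tissue_mode="pericarp")
    with pytest.raises(ValueError):
        SimulationConfig(end_day=1.0)


def test_presets_have_expected_modes():
    presets = scenario_presets()
    assert presets["sd7_1_like"].loci[0].tissue_mode == "maternal"
    assert presets["sd1_2_like"].loci[0].tissue_mode == "endosperm"
    assert presets["sd12_like"].loci[0].tissue_mode == "embryo"
    assert presets["sd12_like"].loci[0].p_d_male == pytest.approx(0.57)
    modes = {l.tissue_mode for l in presets["digenic_like"].loci}
    assert modes == {"maternal", "embryo"}
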