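import numpy as np
import pytest

from endodorm.effects import (
    SingularDesignError,
    code_embryo,
    code_endosperm,
    fit_effect_model,
    two_locus_anova,
)
from endodorm.genotypes import SeedRecord, partition_subpopulations
from endodorm.simulate import scenario_presets, simulate_population


@pytest.mark.parametrize(
    "dose,x,z", [(0, -1.0, -0.5), (1, 0.0, 0.5), (2, 1.0, -0.5)]
)
def test_embryo_coding(dose, x, z):
    assert code_embryo(dose) == (x, z)


@pytest.mark.parametrize(
    "dose,x,z1,z2",
    [(0, -1.5, 0, 0), (1, -0.5, 0, 1), (2, 0.5, 1, 0), (3, 1.5, 0, 0)],
)
def test_endosperm_coding(dose, x, z1, z2):
    assert code_endosperm(dose) == (x, z1, z2)


def test_coding_rejects_invalid_doses():
    with pytest.raises(ValueError):
        code_embryo(3)
    with pytest.raises(ValueError):
        code_endosperm(4)


def _seeds(dose_days, locus="L"):
    return [
        SeedRecord(seed_id=str(i), locus_doses={locus: d}, germination_day=t)
        for i, (d, t) in enumerate(dose_days)
    ]


def test_embryo_model_exact_additive_construction():
    """Heterozygote at the homozygote midpoint: pure additive, d not kept."""
    # embryo doses 0,1,2 correspond to endosperm doses 0, 1 (or 2), 3
    seeds = _seeds([(0, 3.0), (0, 3.0), (1, 4.0), (2, 4.0), (3, 5.0), (3, 5.0)])
    res = fit_effect_model(seeds, "L", model="embryo")
    assert res.selected_terms == ("a",)
    assert res.effect("a").estimate == pytest.approx(1.0, abs=1e-10)
    assert res.mu == pytest.approx(4.0, abs=1e-10)


def test_endosperm_model_exact_additive_construction():
    seeds = _seeds(
        [(0, 2.0), (0, 2.0), (1, 3.0), (1, 3.0), (2, 4.0), (2, 4.0), (3, 5.0), (3, 5.0)]
    )
    res = fit_effect_model(seeds, "L", model="endosperm")
    assert res.selected_terms == ("a",)
    assert res.effect("a").estimate == pytest.approx(1.0, abs=1e-10)


def test_stepwise_keeps_nothing_when_classes_share_their_mean():
    seeds = _seeds([(d, t) for d in (0, 1, 2, 3) for t in (3.0, 4.0, 5.0)])
    res = fit_effect_model(seeds, "L", model="endosperm")
    assert res.selected_terms == ()
    assert res.mu == pytest.approx(4.0)


def test_singular_design_rejected():
    seeds = _seeds([(2, 3.0), (2, 4.0), (2, 5.0)])
    with pytest.raises(SingularDesignError):
        fit_effect_model(seeds, "L", model="endosperm")


def test_ols_matches_normal_equations(rng):
    """Full-model estimates agree with a closed-form least-squares oracle."""
    for _ in range(25):
        n = int(rng.integers(12, 40))
        doses = rng.integers(0, 4, n)
        y = rng.normal(4.0, 1.0, n)
        seeds = _seeds(list(zip(doses.tolist(), y.tolist())))
        res = fit_effect_model(seeds, "L", model="endosperm", stepwise=False)
        X = np.column_stack(
            [np.ones(n)]
            + [np.array([code_endosperm(d)[k] for d in doses]) for k in range(3)]
        )
        keep = [0] + [
            1 + k
            for k, t in enumerate(("a", "d1", "d2"))
            if t in res.selected_terms
        ]
        Xk = X[:, keep]
        beta = np.linalg.solve(Xk.T @ Xk, Xk.T @ y)
        assert res.mu == pytest.approx(beta[0], abs=1e-8)
        for j, term in enumerate(res.selected_terms):
            assert res.effect(term).estimate == pytest.approx(beta[1 + j], abs=1e-8)


def test_nesting_consistency_on_noiseless_data():
    """For noiseless embryo-additive data the endosperm model needs its
    dominance terms; for noiseless endosperm-additive data the embryo model's
    slope is 1.5x the endosperm slope (embryo span 2 doses vs endosperm 3)."""
    a = 0.8
    seeds = _seeds([(d, 4.0 + a * (d - 1.5)) for d in (0, 1, 2, 3) for _ in range(3)])
    endo = fit_effect_model(seeds, "L", model="endosperm")
    assert endo.selected_terms == ("a",)
    assert endo.effect("a").estimate == pytest.approx(a, abs=1e-10)
    embryo = fit_effect_model(seeds, "L", model="embryo", stepwise=False)
    assert embryo.effect("a").estimate == pytest.approx(1.5 * a, abs=1e-8)


def _two_locus_seeds(cells, reps=2):
    # cells: {(embryo_a, embryo_b): y}; embryo dose e encoded via endosperm
    # dose (0->0, 1->1, 2->3) so the embryo conversion lands on e
    endo = {0: 0, 1: 1, 2: 3}
    seeds = []
    i = 0
    for (ea, eb), y in cells.items():
        for _ in range(reps):
            seeds.append(
                SeedRecord(
                    seed_id=str(i),
                    locus_doses={"A": endo[ea], "B": endo[eb]},
                    germination_day=y,
                )
            )
            i += 1
    return seeds


def test_anova_pure_main_effect():
    cells = {(0, 0): 3.0, (0, 1): 3.0, (1, 0): 5.0, (1, 1): 5.0}
    seeds = _two_locus_seeds(cells, reps=3)
    table = two_locus_anova(seeds, "A", "B")
    assert table.table.loc["A", "sum_sq"] > 0
    assert table.table.loc["B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
    assert table.table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)


def test_anova_additive_by_additive_has_zero_interaction():
    cells = {
        (ea, eb): 4.0 + 0.5 * (ea - 1) + 0.3 * (eb - 1)
        for ea in (0, 1, 2)
        for eb in (0, 1, 2)
    }
    seeds = _two_locus_seeds(cells, reps=2)
    table = two_locus_anova(seeds, "A", "B")
    assert table.table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-8)
    # decomposition is exhaustive: sum of all SS equals total SS
    y = np.array([r.germination_day for r in seeds])
    assert table.table["sum_sq"].sum() == pytest.approx(
        ((y - y.mean()) ** 2).sum(), abs=1e-8
    )


def test_anova_digenic_simulation_isolates_the_effective_locus():
    """With one maternal and one embryo-additive locus, the embryo locus
    dominates the two-way decomposition (its F dwarfs the other sources)."""
    cfg = scenario_presets()["digenic_like"]
    pop = simulate_population(cfg, rng=np.random.default_rng(42))
    germ, _ = partition_subpopulations(pop)
    table = two_locus_anova(germ, "SD7-1", "SD12")
    f_b = table.table.loc["SD12", "F"]
    assert table.table.loc["SD12", "PR(>F)"] < 0.05
    assert f_b > 5 * table.table.loc["SD7-1", "F"]
    assert f_b > 5 * table.table.loc["SD7-1:SD12", "F"]
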