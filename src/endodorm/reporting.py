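"""Pipeline orchestration and report rendering.

``run_pipeline`` runs the analysis in the published order -- frequencies and
tests per subpopulation, germination curves and allele trajectories, effect
models, tissue inference -- and collects everything in a :class:`ReportBundle`
whose tables mirror the layout of the published summary tables (genotype
frequencies with chi-square, starred allelic/gametic frequencies; effect
estimates with SE, t, P and model label).  All randomness (the permutation
test) is seeded, so a bundle regenerated from the run log's inputs is
identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import allele_trajectory, genotype_curves, population_curve
from .effects import SingularDesignError, fit_effect_model, two_locus_anova
from .frequencies import (
    GenotypeCounts,
    pool_counts,
    significance_stars,
    tally,
)
from .genotypes import SeedPopulation, partition_subpopulations
from .inference import TissueInference, classify_population, evaluate_counts

__all__ = ["ReportBundle", "run_pipeline", "render_report"]


@dataclass
class ReportBundle:
    frequency_table: pd.DataFrame
    effects_table: pd.DataFrame
    anova_tables: dict[str, pd.DataFrame]
    curve_table: pd.DataFrame
    trajectory_table: pd.DataFrame
    inference: dict[str, TissueInference]
    run_log: dict

    def inference_json(self) -> str:
        payload = {
            locus: {
                "tissue_call": inf.tissue_call,
                "offspring_rule": inf.offspring_rule,
                "maternal_rule": inf.maternal_rule,
                "sdl_flag": inf.sdl_flag,
                "sdl_side": inf.sdl_side,
                "dosage_flag": inf.dosage_flag,
                "preferential_fertilization_flag": inf.preferential_fertilization_flag,
                "evidence": inf.evidence,
                "not_evaluable": inf.not_evaluable,
            }
            for locus, inf in self.inference.items()
        }
        return json.dumps(payload, indent=2)


def _freq_row(label: str, locus: str, counts: GenotypeCounts) -> dict:
    ev = evaluate_counts(counts, label=label)
    est = ev.est
    return {
        "locus": locus,
        "subpopulation": label,
        "N": est.N,
        "n_missing": counts.n_missing,
        "F_ddd": round(est.F_ddd, 3),
        "F_Ddd": round(est.F_Ddd, 3),
        "F_DDd": round(est.F_DDd, 3),
        "F_DDD": round(est.F_DDD, 3),
        "chi2": round(ev.chi2.statistic, 2),
        "chi2_p": ev.chi2.p_value,
        "F_d": f"{est.F_d:.3f}{significance_stars(ev.fd_test.p_value)}",
        "F_d_male": f"{est.F_d_male:.3f}{significance_stars(ev.fd_male_test.p_value)}",
        "F_d_female": f"{est.F_d_female:.3f}{significance_stars(ev.fd_female_test.p_value)}",
        "gamete_eq_p": ev.gamete_eq.p_value,
    }


def run_pipeline(
    pop: SeedPopulation,
    loci: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    literal_denominator: bool = False,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> ReportBundle:
    """Frequencies -> tests -> curves -> effects -> inference, per locus."""
    loci = list(loci) if loci is not None else list(pop.loci)
    germ, nong = partition_subpopulations(pop)

    freq_rows, effect_rows, curve_rows, traj_rows = [], [], [], []
    inference: dict[str, TissueInference] = {}
    anova_tables: dict[str, pd.DataFrame] = {}
    stage = "frequencies"
    try:
        for locus in loci:
            g_counts = tally(germ, locus)
            ng_counts = tally(nong, locus)
            if g_counts.N >= 1:
                freq_rows.append(_freq_row("G", locus, g_counts))
            if ng_counts.N >= 1:
                freq_rows.append(_freq_row("NG", locus, ng_counts))
            if g_counts.N >= 1 and ng_counts.N >= 1:
                freq_rows.append(
                    _freq_row("G+NG", locus, pool_counts(g_counts, ng_counts))
                )

        stage = "curves"
        pc = population_curve(pop)
        for day, pct in zip(pc.days, pc.cumulative_pct):
            curve_rows.append(
                {"locus": "", "label": "population", "day": day, "cumulative_pct": pct}
            )
        for locus in loci:
            if tally(nong, locus).N >= 1:
                for dose, curve in genotype_curves(
                    pop, locus, literal_denominator=literal_denominator
                ).items():
                    for day, pct in zip(curve.days, curve.cumulative_pct):
                        curve_rows.append(
                            {
                                "locus": locus,
                                "label": curve.label,
                                "day": day,
                                "cumulative_pct": pct,
                            }
                        )
            genotyped_g = [r for r in germ if r.dose(locus) is not None]
            if genotyped_g:
                traj = allele_trajectory(germ, locus, grid=pop.counting_grid())
                for i, day in enumerate(traj.days):
                    traj_rows.append(
                        {
                            "locus": locus,
                            "day": day,
                            "F_d": traj.F_d_at_day[i],
                            "F_d_male": traj.F_d_male_at_day[i],
                            "F_d_female": traj.F_d_female_at_day[i],
                            "n": int(traj.n_at_day[i]),
                        }
                    )

        stage = "effects"
        for locus in loci:
            for model in ("embryo", "endosperm"):
                try:
                    res = fit_effect_model(germ, locus, model=model)
                except SingularDesignError:
                    continue
                for eff in res.effects:
                    effect_rows.append(
                        {
                            "locus": locus,
                            "effect": eff.term,
                            "estimate_days": eff.estimate,
                            "se_days": eff.se,
                            "t": eff.t,
                            "p": eff.p,
                            "model": eff.model_label,
                            "n": res.n,
                        }
                    )
        if len(loci) == 2:
            try:
                an = two_locus_anova(germ, loci[0], loci[1])
                anova_tables[f"{loci[0]}x{loci[1]}"] = an.table
            except SingularDesignError:
                pass

        stage = "inference"
        rng = np.random.default_rng(rng_seed)
        for locus in loci:
            if tally(germ, locus).N >= 1:
                inference[locus] = classify_population(
                    pop,
                    locus,
                    alpha=alpha,
                    n_permutations=n_permutations,
                    rng=rng,
                )
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    run_log = {
        "experiment_id": pop.experiment_id,
        "n_total_tested": pop.n_total_tested,
        "n_scored": len(pop.records),
        "n_contaminated": pop.n_contaminated,
        "loci": loci,
        "alpha": alpha,
        "literal_denominator": literal_denominator,
        "n_permutations": n_permutations,
        "rng_seed": rng_seed,
    }
    return ReportBundle(
        frequency_table=pd.DataFrame(freq_rows),
        effects_table=pd.DataFrame(effect_rows),
        anova_tables=anova_tables,
        curve_table=pd.DataFrame(curve_rows),
        trajectory_table=pd.DataFrame(traj_rows),
        inference=inference,
        run_log=run_log,
    )


def render_report(bundle: ReportBundle) -> str:
    """Human-readable text report (tables + inference summary)."""
    parts = [
        "# endodorm report",
        f"run log: {json.dumps(bundle.run_log)}",
        "",
        "## Genotypic and allelic frequencies",
        bundle.frequency_table.to_string(index=False)
        if not bundle.frequency_table.empty
        else "(no genotyped seeds)",
        "",
        "## Genetic component effects on time to germination",
        bundle.effects_table.to_string(index=False)
        if not bundle.effects_table.empty
        else "(no term survived selection or no usable design)",
    ]
    for name, table in bundle.anova_tables.items():
        parts += ["", f"## Two-way ANOVA ({name}, Type I, order as listed)",
                  table.to_string()]
    parts += ["", "## Tissue inference"]
    for locus, inf in bundle.inference.items():
        parts.append(f"{locus}: {inf.tissue_call}"
                     f" (SDL: {inf.sdl_flag}, side {inf.sdl_side};"
                     f" dosage: {inf.dosage_flag};"
                     f" preferential fertilization: {inf.preferential_fertilization_flag})")
        for line in inf.evidence:
            parts.append(f"  - {line}")
        for line in inf.not_evaluable:
            parts.append(f"  - [not evaluable] {line}")
    return "\n".join(parts) + "\n"
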