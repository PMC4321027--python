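"""Additive-dominance models of germination time on seed genotypes.

The response is the incubation time (days) at which each germinated seed was
scored.  Two dummy-coded ordinary least squares models are fitted within a
germinated subpopulation:

* embryo model:     y = mu + a*x + d*z,
  x in {-1, 0, 1} for dd/Dd/DD, z = 0.5 for Dd else -0.5;
* endosperm model:  y = mu + a*x + d1*z1 + d2*z2,
  x in {-1.5, -0.5, 0.5, 1.5} for ddd/Ddd/DDd/DDD,
  z1 = 1 iff DDd (two D over one d), z2 = 1 iff Ddd (one D over two d).

Candidate genetic terms enter by stepwise selection (forward entry and
backward stay both at P < 0.05; the intercept is always kept), so a reported
term is one that survived at the 5 % level.  A two-locus factorial ANOVA on
embryo genotypes (main effects + interaction, sequential Type I sums of
squares in the order A, B, A x B) screens digenic systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols as _ols_formula
from statsmodels.stats.anova import anova_lm

from .genotypes import SeedRecord, endosperm_to_embryo

__all__ = [
    "EffectEstimate",
    "EffectModelResult",
    "code_embryo",
    "code_endosperm",
    "fit_effect_model",
    "two_locus_anova",
]

EMBRYO_TERMS = ("a", "d")
ENDOSPERM_TERMS = ("a", "d1", "d2")


class SingularDesignError(ValueError):
    """Raised when germinated seeds span fewer than two genotype classes."""


def code_embryo(dose: int) -> tuple[float, float]:
    """(additive, dominance) codes for an embryo D-dose."""
    if dose not in (0, 1, 2):
        raise ValueError(f"embryo dose must be in {{0,1,2}}, got {dose!r}")
    return float(dose - 1), 0.5 if dose == 1 else -0.5


def code_endosperm(dose: int) -> tuple[float, float, float]:
    """(additive, first-dominance, second-dominance) codes for an endosperm dose."""
    if dose not in (0, 1, 2, 3):
        raise ValueError(f"endosperm dose must be in {{0,1,2,3}}, got {dose!r}")
    return float(dose) - 1.5, 1.0 if dose == 2 else 0.0, 1.0 if dose == 1 else 0.0


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    estimate: float
    se: float
    t: float
    p: float
    model_label: str


@dataclass
class EffectModelResult:
    model_label: str
    locus: str
    mu: float
    effects: list[EffectEstimate]
    n: int
    selected_terms: tuple[str, ...]
    candidate_terms: tuple[str, ...]

    def effect(self, term: str) -> Optional[EffectEstimate]:
        for eff in self.effects:
            if eff.term == term:
                return eff
        return None


def _design(records: Sequence[SeedRecord], locus: str, model: str) -> pd.DataFrame:
    rows = []
    for rec in records:
        if not rec.germinated:
            continue
        dose = rec.dose(locus)
        if dose is None:
            continue
        if model == "embryo":
            x, z = code_embryo(endosperm_to_embryo(dose))
            rows.append({"y": rec.germination_day, "a": x, "d": z})
        elif model == "endosperm":
            x, z1, z2 = code_endosperm(dose)
            rows.append({"y": rec.germination_day, "a": x, "d1": z1, "d2": z2})
        else:
            raise ValueError(f"model must be 'embryo' or 'endosperm', got {model!r}")
    return pd.DataFrame(rows)


def _fit_terms(df: pd.DataFrame, terms: Sequence[str]):
    X = sm.add_constant(df[list(terms)], has_constant="add") if terms else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    return sm.OLS(df["y"].to_numpy(), X.to_numpy(float)), list(X.columns)


def _term_pvalues(df: pd.DataFrame, terms: Sequence[str]) -> dict[str, tuple[float, float, float, float]]:
    """Fit mu + terms; return {term: (estimate, se, t, p)}."""
    model, cols = _fit_terms(df, terms)
    res = model.fit()
    out = {}
    for j, name in enumerate(cols):
        if name == "const":
            continue
        out[name] = (
            float(res.params[j]),
            float(res.bse[j]),
            float(res.tvalues[j]),
            float(res.pvalues[j]),
        )
    return out, float(res.params[cols.index("const")])


def fit_effect_model(
    germinated: Iterable[SeedRecord],
    locus: str,
    model: str = "embryo",
    entry: float = 0.05,
    stay: float = 0.05,
    stepwise: bool = True,
) -> EffectModelResult:
    """Stepwise OLS of germination time on the coded genotype design.

    With ``stepwise=False`` all candidate terms are fitted and reported
    regardless of significance (useful for recovery studies); otherwise terms
    enter forward at ``entry`` and are re-checked backward at ``stay``.
    """
    df = _design(list(germinated), locus, model)
    candidates = EMBRYO_TERMS if model == "embryo" else ENDOSPERM_TERMS
    if df.empty or df[list(candidates)].drop_duplicates().shape[0] < 2:
        raise SingularDesignError(
            f"need >= 2 genotype classes among germinated seeds at {locus!r}"
        )
    usable = tuple(t for t in candidates if df[t].nunique() > 1)

    if stepwise:
        selected: list[str] = []
        for _ in range(20):  # guard against entry/stay cycling
            changed = False
            # forward step: best single addition below the entry threshold
            best_term, best_p = None, entry
            for term in usable:
                if term in selected:
                    continue
                stats_map, _ = _term_pvalues(df, selected + [term])
                p = stats_map[term][3]
                if p < best_p:
                    best_term, best_p = term, p
            if best_term is not None:
                selected.append(best_term)
                changed = True
            # backward step: drop anything no longer below the stay threshold
            while selected:
                stats_map, _ = _term_pvalues(df, selected)
                worst = max(selected, key=lambda t: stats_map[t][3])
                if stats_map[worst][3] > stay:
                    selected.remove(worst)
                    changed = True
                else:
                    break
            if not changed:
                break
        terms = tuple(selected)
    else:
        terms = usable

    stats_map, mu = _term_pvalues(df, list(terms)) if terms else ({}, float(df["y"].mean()))
    label = f"{model}({3 if model == 'embryo' else 4})"
    effects = [
        EffectEstimate(term, *stats_map[term], model_label=label) for term in terms
    ]
    return EffectModelResult(
        model_label=label,
        locus=locus,
        mu=mu,
        effects=effects,
        n=len(df),
        selected_terms=terms,
        candidate_terms=usable,
    )


@dataclass
class AnovaTable:
    """Two-way factorial ANOVA on embryo genotypes (Type I, order A, B, AxB)."""

    table: pd.DataFrame
    locus_a: str
    locus_b: str
    order: tuple[str, ...]
    note: str = ""

    def p_value(self, source: str) -> float:
        return float(self.table.loc[source, "PR(>F)"])


def two_locus_anova(
    germinated: Iterable[SeedRecord],
    locus_a: str,
    locus_b: str,
) -> AnovaTable:
    """Main and interaction effects of two loci on germination time.

    Seeds missing either locus call are excluded.  Unbalanced cells are
    handled with sequential (Type I) sums of squares in the documented order
    (A, then B, then A x B).
    """
    rows = []
    for rec in germinated:
        if not rec.germinated:
            continue
        da, db = rec.dose(locus_a), rec.dose(locus_b)
        if da is None or db is None:
            continue
        rows.append(
            {
                "y": rec.germination_day,
                "A": endosperm_to_embryo(da),
                "B": endosperm_to_embryo(db),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or (df["A"].nunique() < 2 and df["B"].nunique() < 2):
        raise SingularDesignError("ANOVA needs variation in at least one locus")
    note = ""
    if df.groupby(["A", "B"]).size().shape[0] < df["A"].nunique() * df["B"].nunique():
        note = "some factor-level combinations are empty; table is reduced"
    fit = _ols_formula("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    table = anova_lm(fit, typ=1)
    table = table.rename(
        index={
            "C(A)": locus_a,
            "C(B)": locus_b,
            "C(A):C(B)": f"{locus_a}:{locus_b}",
            "Residual": "error",
        }
    )
    return AnovaTable(
        table=table,
        locus_a=locus_a,
        locus_b=locus_b,
        order=(locus_a, locus_b, f"{locus_a}:{locus_b}"),
        note=note,
    )
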