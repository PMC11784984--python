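"""Two-condition mediator pre-screening.

A candidate is retained as a potential mediator when (1) it is associated
with the outcome after adjusting for the other factors (GLM Wald test) and
(2) it is distributed differently across the exposure groups (chi-square
test for categorical candidates, one-way ANOVA for continuous ones).  Both
raw p-values must fall below the screening level (default 0.1).  Candidates
declared *forced* bypass the tests.  These are pre-screening filters, not
formal tests of mediation, so no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data import MediationDataset, MediatorSpec

__all__ = ["ScreeningReport", "test_exposure_difference", "test_outcome_association", "screen"]


@dataclass
class ScreeningReport:
    """Per-candidate p-value pair and inclusion decision."""

    table: pd.DataFrame
    alpha: float

    @property
    def included(self) -> List[str]:
        return list(self.table.loc[self.table["included"], "name"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScreeningReport(alpha={self.alpha})\n" + self.table.to_string(index=False)


def test_exposure_difference(values, spec: MediatorSpec, exposure) -> Dict[str, object]:
    """Condition 2: is the candidate distributed differently across the
    exposure groups?

    Categorical (and binary) candidates use the uncorrected chi-square test
    on the contingency table with the binary exposure; continuous candidates
    use one-way ANOVA.  A constant candidate cannot separate the groups and
    is reported with p-value 1 and a degenerate flag.
    """
    values = pd.Series(values).reset_index(drop=True)
    x = np.asarray(exposure)
    if set(np.unique(x)) - {0, 1}:
        raise ValueError("exposure must be binary 0/1 for the screening tests")
    if values.nunique() <= 1:
        return {"p_value": 1.0, "test_used": "degenerate", "degenerate": True}
    if spec.kind == "continuous":
        groups = [values[x == g].to_numpy(dtype=float) for g in (0, 1)]
        stat, p = stats.f_oneway(*groups)
        return {"p_value": float(p), "test_used": "ANOVA", "degenerate": False}
    table = pd.crosstab(values, pd.Series(x, name="exposure"))
    if (table.to_numpy() == 0).any() or (stats.contingency.expected_freq(table) < 1).any():
        warnings.warn(
            f"{spec.name!r}: contingency table has near-empty cells; "
            "the chi-square approximation may be poor", stacklevel=2,
        )
    if (stats.contingency.expected_freq(table) < 5).any():
        warnings.warn(
            f"{spec.name!r}: some expected cell counts are below 5", stacklevel=2,
        )
    res = stats.chi2_contingency(table, correction=False)
    return {"p_value": float(res.pvalue), "test_used": "chi-square",
            "statistic": float(res.statistic), "degenerate": False}


def test_outcome_association(values, spec: MediatorSpec, outcome, adjusters: pd.DataFrame,
                             outcome_kind: str = "continuous") -> Dict[str, object]:
    """Condition 1: Wald test of the candidate's block in a GLM of the
    outcome on candidate + adjusters.

    Continuous outcomes use an identity-link Gaussian GLM, binary outcomes a
    logit GLM.  Categorical candidates enter as reference-coded dummies and
    are tested jointly.
    """
    values = pd.Series(values, name=spec.name).reset_index(drop=True)
    adjusters = adjusters.reset_index(drop=True)
    if spec.name in adjusters.columns:
        raise ValueError(f"candidate {spec.name!r} also appears among the adjusters")
    if spec.kind == "categorical":
        block = pd.get_dummies(values, prefix=spec.name, drop_first=True, dtype=float)
    else:
        block = values.astype(float).to_frame()
    X = pd.concat([pd.Series(1.0, name="Intercept", index=block.index),
                   block, adjusters.astype(float)], axis=1)
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # identify offending columns via pivoted QR
        from .sampler import _check_rank
        _check_rank(arr, list(X.columns))
    y = np.asarray(outcome, dtype=float)
    family = sm.families.Binomial() if outcome_kind == "binary" else sm.families.Gaussian()
    fit = sm.GLM(y, X, family=family).fit()
    contrast = np.zeros((block.shape[1], X.shape[1]))
    for i, col in enumerate(block.columns):
        contrast[i, list(X.columns).index(col)] = 1.0
    res = fit.wald_test(contrast, scalar=True)
    return {"p_value": float(res.pvalue), "test_used": "GLM-Wald",
            "statistic": float(res.statistic), "degenerate": False}


def screen(data: MediationDataset, alpha: float = 0.1,
           forced: Optional[Iterable[str]] = None,
           adjust_for_exposure: bool = True,
           adjust_for_others: bool = True) -> ScreeningReport:
    """Run both screening conditions for every declared mediator.

    ``included = forced or (p_value_1 < alpha and p_value_2 < alpha)``.
    Adjusters for condition 1 default to the exposure plus the other
    candidates' blocks.  The result is a pure function of
    ``(data, alpha, forced)`` and serializes to CSV.
    """
    forced = set(forced or ())
    forced |= {m.name for m in data.mediators.values() if m.forced}
    unknown = forced - set(data.mediators)
    if unknown:
        raise ValueError(f"forced labels not among declared mediators: {sorted(unknown)}")

    x = data.exposure.to_numpy(dtype=float)
    rows = []
    for name, spec in data.mediators.items():
        adj_parts = []
        if adjust_for_exposure:
            adj_parts.append(data.exposure.astype(float).to_frame())
        if adjust_for_others:
            adj_parts.extend(
                data.mediator_block(other) for other in data.mediators if other != name
            )
        adjusters = (pd.concat(adj_parts, axis=1) if adj_parts
                     else pd.DataFrame(index=data.frame.index))
        r1 = test_outcome_association(data.mediator_values(name), spec, data.outcome,
                                      adjusters, outcome_kind=data.outcome_kind)
        r2 = test_exposure_difference(data.mediator_values(name), spec, x)
        included = name in forced or (r1["p_value"] < alpha and r2["p_value"] < alpha)
        rows.append({
            "name": name,
            "p_value_1": r1["p_value"],
            "p_value_2": r2["p_value"],
            "test_1": r1["test_used"],
            "test_2": r2["test_used"],
            "forced": name in forced,
            "included": bool(included),
            "degenerate": bool(r1.get("degenerate") or r2.get("degenerate")),
        })
    return ScreeningReport(table=pd.DataFrame(rows), alpha=alpha)
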