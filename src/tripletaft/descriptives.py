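"""Cohort descriptives around the main model.

Relative dose intensity (RDI), adverse-event relative risks with Katz
log-normal confidence intervals, and nonlinear age-probability curves
for binary characteristics via logistic regression on a restricted
cubic spline basis of age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .splines import default_knots, rcs_basis

__all__ = [
    "DoseRecord",
    "TwoByTwo",
    "rdi",
    "relative_risk",
    "RelativeRisk",
    "relative_risk_table",
    "age_probability_curve",
]


@dataclass(frozen=True)
class DoseRecord:
    """Planned vs delivered dose intensity for one drug (mg/m2 per week)."""

    drug: str
    planned: float
    delivered: float

    def __post_init__(self) -> None:
        if not self.planned > 0:
            raise ValueError(f"planned dose intensity must be > 0, got {self.planned}")
        if self.delivered < 0:
            raise ValueError("delivered dose intensity cannot be negative")


def rdi(record: DoseRecord) -> float:
    """Relative dose intensity: delivered / planned, as a percentage.

    Both intensities must share the same time unit; the ratio is then
    unit-free.
    """
    return 100.0 * record.delivered / record.planned


@dataclass(frozen=True)
class TwoByTwo:
    """Event counts in two exposure groups (group 1 vs group 2)."""

    events1: int
    total1: int
    events2: int
    total2: int

    def __post_init__(self) -> None:
        for ev, tot, grp in ((self.events1, self.total1, 1), (self.events2, self.total2, 2)):
            if tot <= 0:
                raise ValueError(f"group {grp} total must be > 0")
            if not 0 <= ev <= tot:
                raise ValueError(f"group {grp} events must lie in [0, total]")


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci_lo: float
    ci_hi: float
    continuity_corrected: bool = False


def relative_risk(t: TwoByTwo, alpha: float = 0.05) -> RelativeRisk:
    """Risk ratio of group 1 vs group 2 with a Katz log-normal CI.

    A zero event count in either group triggers the conventional 0.5
    continuity correction on all four cells, flagged on the result.
    """
    a, n1, b, n2 = float(t.events1), float(t.total1), float(t.events2), float(t.total2)
    corrected = a == 0 or b == 0
    if a == n1 and b == n2:
        corrected = False  # both risks are 1, RR defined without correction
    if corrected:
        a, b = a + 0.5, b + 0.5
        n1, n2 = n1 + 1.0, n2 + 1.0
    risk1, risk2 = a / n1, b / n2
    if risk2 == 0:
        raise ValueError("comparator risk is zero even after continuity correction")
    rr = risk1 / risk2
    if risk1 == 0:
        raise ValueError("group-1 risk is zero even after continuity correction")
    se = np.sqrt(max(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2, 0.0))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return RelativeRisk(
        rr=float(rr),
        ci_lo=float(rr * np.exp(-zcrit * se)),
        ci_hi=float(rr * np.exp(zcrit * se)),
        continuity_corrected=corrected,
    )


def relative_risk_table(counts: pd.DataFrame, reference_arm: str = "PF") -> pd.DataFrame:
    """Forest-plot-ready relative risks from long-format adverse-event counts.

    ``counts`` needs columns ``term, arm, events, total`` (optionally
    ``grade_band``); risks are referenced to ``reference_arm`` (the
    doublet by default), so RR > 1 means the event is more frequent on
    the triplet.
    """
    required = {"term", "arm", "events", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns {sorted(missing)}")
    rows = []
    group_cols = ["term"] + (["grade_band"] if "grade_band" in counts.columns else [])
    for key, grp in counts.groupby(group_cols, sort=False):
        arms = grp.set_index("arm")
        exposed = [arm for arm in arms.index if arm != reference_arm]
        if reference_arm not in arms.index or len(exposed) != 1:
            raise ValueError(f"term {key!r} needs exactly one exposed arm plus {reference_arm!r}")
        t = TwoByTwo(
            events1=int(arms.loc[exposed[0], "events"]),
            total1=int(arms.loc[exposed[0], "total"]),
            events2=int(arms.loc[reference_arm, "events"]),
            total2=int(arms.loc[reference_arm, "total"]),
        )
        res = relative_risk(t)
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({"rr": res.rr, "ci_lo": res.ci_lo, "ci_hi": res.ci_hi,
                    "continuity_corrected": res.continuity_corrected})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("rr", ascending=False).reset_index(drop=True)


def age_probability_curve(outcome, age, grid=None, knots: int = 3):
    """P(binary characteristic | age) via spline logistic regression.

    Fits a logistic regression of the 0/1 outcome on a restricted cubic
    spline basis of age (IRLS to convergence) and evaluates the fitted
    probability on an age grid.

    Returns ``(grid, probabilities)``.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(age, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and age must align")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    knot_pos = default_knots(x, knots)
    X = sm.add_constant(rcs_basis(x, knot_pos))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=200)
    except Exception as err:  # pragma: no cover - statsmodels wraps separation variously
        raise ValueError(
            "logistic fit failed (possible complete separation); "
            "coarsen the outcome or reduce the knot count"
        ) from err
    if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
        raise ValueError(
            "fitted coefficients diverged, which indicates complete separation; "
            "coarsen the outcome or reduce the knot count"
        )
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, dtype=float)
    Xg = sm.add_constant(rcs_basis(grid, knot_pos), has_constant="add")
    return grid, np.asarray(fit.predict(Xg))
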