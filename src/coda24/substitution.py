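"""Compositional isotemporal substitution.

Given a fitted composition model (or published clr coefficients), this
module predicts the outcome difference associated with moving a fixed
number of minutes from one behaviour to another while holding the other
two constant.  Because the model is linear in log-minutes, the predicted
difference for a reallocation from composition ``x0`` to ``x1`` is

    delta = sum_j a_j * (ln x1_j - ln x0_j)

with ``a`` the clr coefficient vector; intercept, covariates and the
school intercept cancel.  Differences are also expressed as effect sizes
in units of the model residual standard deviation.

The log-linearity makes reallocations asymmetric: adding 20 min to a
small part (MVPA) moves its log far more than removing 20 min from a
large part (ST), so "to MVPA" and "from MVPA" curves are not mirror
images — the substantive signature of compositional substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import ActivityComposition, ClrCoefficients, PARTS
from .models import MixedModelFit


class InfeasibleReallocationError(ValueError):
    """Raised when a reallocation would drive a behaviour to zero or below."""


def reallocate(
    c: ActivityComposition, from_b: str, to_b: str, minutes: float
) -> ActivityComposition:
    """Move ``minutes`` from one behaviour to another, total preserved."""
    if from_b == to_b:
        raise ValueError("from and to behaviours must differ")
    x = c.as_array().copy()
    i, j = PARTS.index(from_b), PARTS.index(to_b)
    x[i] -= minutes
    x[j] += minutes
    if x[i] <= 0 or x[j] <= 0:
        raise InfeasibleReallocationError(
            f"moving {minutes} min {from_b}->{to_b} leaves a nonpositive duration"
        )
    return ActivityComposition.from_array(x)


def predict_difference(
    model: MixedModelFit | ClrCoefficients,
    x0: ActivityComposition,
    x1: ActivityComposition,
    covariate_values: Mapping[str, float] | None = None,
) -> float:
    """Model-predicted outcome difference at ``x1`` versus ``x0``.

    With a fitted model the difference comes from the fixed-effect
    predictions (covariates held fixed, so they cancel); with clr
    coefficients it is the closed-form log-contrast.  The two routes
    agree exactly for a model and its own clr projection.
    """
    a0, a1 = x0.as_array(), x1.as_array()
    if np.any(a0 <= 0) or np.any(a1 <= 0):
        raise ValueError("compositions must be strictly positive")
    if isinstance(model, ClrCoefficients):
        return float(model.as_array() @ (np.log(a1) - np.log(a0)))
    return model.predict(x1, covariate_values) - model.predict(x0, covariate_values)


def effect_size(delta: float, residual_sd: float) -> float:
    """Standardise a predicted difference by the model residual SD."""
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    return delta / residual_sd


@dataclass(frozen=True)
class SubstitutionEstimate:
    """One reallocation: minutes moved from a donor into a focus behaviour."""

    outcome_name: str | None
    from_behaviour: str
    to_behaviour: str
    minutes: float
    delta: float
    effect_size: float
    feasible: bool
    base_composition: ActivityComposition


DEFAULT_MINUTES_GRID: tuple[float, ...] = (-20, -15, -10, -5, 0, 5, 10, 15, 20)


def substitution_grid(
    model: MixedModelFit | ClrCoefficients,
    base: ActivityComposition,
    focus_behaviour: str,
    minutes_list: Sequence[float] = DEFAULT_MINUTES_GRID,
    residual_sd: float | None = None,
    outcome_name: str | None = None,
) -> list[SubstitutionEstimate]:
    """Reallocation curves between the focus behaviour and every other.

    Positive minutes move time from the donor into the focus behaviour,
    negative minutes the reverse.  Grid points that would drive a part
    nonpositive are flagged infeasible (delta = NaN) rather than clamped
    or dropped, so plotted curves cannot silently distort.
    """
    if np.any(base.as_array() <= 0):
        raise ValueError("base composition must be strictly positive")
    if focus_behaviour not in PARTS:
        raise KeyError(f"unknown behaviour {focus_behaviour!r}")
    if isinstance(model, MixedModelFit):
        if residual_sd is None:
            residual_sd = model.residual_sd
        if outcome_name is None:
            outcome_name = model.outcome_name
    out: list[SubstitutionEstimate] = []
    for donor in (p for p in PARTS if p != focus_behaviour):
        for m in minutes_list:
            try:
                x1 = base if m == 0 else reallocate(base, donor, focus_behaviour, m)
                delta = predict_difference(model, base, x1)
                feasible = True
            except InfeasibleReallocationError:
                delta, feasible = float("nan"), False
            es = (
                effect_size(delta, residual_sd)
                if (residual_sd is not None and feasible)
                else float("nan")
            )
            out.append(
                SubstitutionEstimate(
                    outcome_name=outcome_name,
                    from_behaviour=donor,
                    to_behaviour=focus_behaviour,
                    minutes=float(m),
                    delta=delta,
                    effect_size=es,
                    feasible=feasible,
                    base_composition=base,
                )
            )
    return out


def grid_to_frame(estimates: Sequence[SubstitutionEstimate]) -> pd.DataFrame:
    """Long-format table (outcome, from, to, minutes, delta, es, feasible)."""
    return pd.DataFrame(
        {
            "outcome": [e.outcome_name for e in estimates],
            "from": [e.from_behaviour for e in estimates],
            "to": [e.to_behaviour for e in estimates],
            "minutes": [e.minutes for e in estimates],
            "delta": [e.delta for e in estimates],
            "es": [e.effect_size for e in estimates],
            "feasible": [e.feasible for e in estimates],
        }
    )


def plot_substitution_curves(frame: pd.DataFrame, ax=None, outcome: str | None = None):
    """Reallocation curves, one line per donor behaviour.

    Expects a :func:`grid_to_frame` table for a single focus behaviour.
    """
    import matplotlib.pyplot as plt

    if outcome is not None:
        frame = frame[frame["outcome"] == outcome]
    if ax is None:
        _, ax = plt.subplots()
    focus = frame["to"].iloc[0]
    for donor, sub in frame[frame["feasible"]].groupby("from"):
        sub = sub.sort_values("minutes")
        ax.plot(sub["minutes"], sub["delta"], marker="o", label=f"from {donor}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(f"minutes reallocated to {focus}")
    ax.set_ylabel("predicted score difference")
    ax.legend()
    return ax
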