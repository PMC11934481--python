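"""Bundled published reference estimates for the worked example.

The package ships the compositional means and first-pivot regression
coefficients of a published school-cohort analysis (see
``data/reference_values.yaml``) so the isotemporal-substitution
arithmetic can be exercised end to end without any cohort download.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .composition import ActivityComposition, ClrCoefficients, clr_from_pivot_beta1, close


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("coda24.data").joinpath("reference_values.yaml").open() as fh:
        return yaml.safe_load(fh)


def strata() -> tuple[str, ...]:
    """Strata for which reference values are available."""
    return tuple(_raw()["geometric_means"])


def reference_composition(stratum: str = "all_schools") -> ActivityComposition:
    """Reference compositional mean (closed to 1440 min) for a stratum."""
    means = _raw()["geometric_means"]
    if stratum not in means:
        raise KeyError(f"unknown stratum {stratum!r}; expected one of {tuple(means)}")
    return close(np.asarray(means[stratum], dtype=float))


def reference_beta1(stratum: str = "all_schools", outcome: str = "overall") -> np.ndarray:
    """First-pivot coefficients (canonical behaviour order) for one model."""
    block = _raw()["beta1"].get(stratum)
    if block is None:
        raise KeyError(f"no reference coefficients for stratum {stratum!r}")
    if outcome not in block:
        raise KeyError(
            f"no reference coefficients for outcome {outcome!r} in stratum {stratum!r} "
            "(only outcomes with a significant omnibus test were reported)"
        )
    return np.asarray(block[outcome]["coef"], dtype=float)


def reference_beta1_se(stratum: str = "all_schools", outcome: str = "overall") -> np.ndarray:
    """Standard errors matching :func:`reference_beta1`."""
    return np.asarray(_raw()["beta1"][stratum][outcome]["se"], dtype=float)


def reference_clr(stratum: str = "all_schools", outcome: str = "overall") -> ClrCoefficients:
    """Reference coefficients converted from first-pivot to clr scale."""
    return clr_from_pivot_beta1(reference_beta1(stratum, outcome))


def reference_outcomes(stratum: str = "all_schools") -> tuple[str, ...]:
    """Outcomes with reported coefficients in a stratum."""
    return tuple(_raw()["beta1"].get(stratum, {}))
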