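"""Synthetic school cohorts with the structure the analysis model assumes.

No participant-level data are distributable, so the generator produces
complete cohorts that mimic the published descriptives: ~360 children in
12 schools (10 primary, 2 secondary), daily compositions whose geometric
means sit near (sleep 543.2, ST 635.8, LPA 210.1, MVPA 50.9) min, and
motor-competence scores generated from the very model the analysis fits,

    y = intercept + sum_j a_j ln x_j + covariate effects + u_school + e,

with ``a`` a zero-sum clr effect vector, ``u_school ~ N(0, tau^2)`` and
``e ~ N(0, sigma^2)``.  Compositions are logistic-normal: Gaussian draws
in pivot-ILR space centred at the ILR image of the target compositional
mean, mapped back to the simplex and closed to 1440 min — which makes
the target compositional mean the exact population centre.

Outcomes are left continuous and unbounded: truncating to the scoring
ranges would bias parameter-recovery experiments, which are the point of
the generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    PARTS,
    TOTAL_MINUTES,
    close,
    pivot_basis,
    pivot_ilr,
)
from .models import COMPOSITION_COLUMNS, OUTCOME_COLUMNS, omnibus_ilr_test

_SQRT34 = np.sqrt(0.75)

#: published all-schools compositional means, canonical order (minutes)
TARGET_GEOMETRIC_MEANS: tuple[float, ...] = (543.2, 635.8, 210.1, 50.9)


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative parameters for one score.

    ``clr_effects`` (zero-sum, score units per log-minute) carry the
    composition signal; ``covariate_effects`` are ordinary linear terms;
    ``random_intercept_sd`` and ``residual_sd`` are the school-level and
    child-level noise SDs in score units.
    """

    clr_effects: tuple[float, float, float, float]
    covariate_effects: dict[str, float]
    intercept: float
    residual_sd: float
    random_intercept_sd: float

    def __post_init__(self):
        a = np.asarray(self.clr_effects, dtype=float)
        if a.shape != (4,):
            raise ValueError("clr_effects must have 4 entries")
        if abs(a.sum()) > 1e-6:
            raise ValueError(f"clr_effects must sum to 0, got {a.sum():.6f}")
        if self.residual_sd < 0 or self.random_intercept_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    def scaled(self, factor: float) -> "OutcomeSpec":
        """Same spec with the composition signal multiplied by ``factor``."""
        return dataclasses.replace(
            self, clr_effects=tuple(factor * np.asarray(self.clr_effects))
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one cohort reproducibly."""

    n_participants: int = 360
    n_schools: int = 12
    n_primary_schools: int = 10
    target_geometric_means: tuple[float, ...] = TARGET_GEOMETRIC_MEANS
    #: 3x3 positive-definite covariance of the pivot-ILR coordinates
    #: (pivot = sleep); diagonal defaults give realistic day-to-day spread
    #: with the widest variation on the LPA/MVPA contrast.
    ilr_covariance: tuple[tuple[float, ...], ...] = (
        (0.0225, 0.0, 0.0),
        (0.0, 0.0225, 0.0),
        (0.0, 0.0, 0.1225),
    )
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    boys_proportion: float = 0.493
    age_primary: tuple[float, float] = (10.4, 0.7)  # mean, SD years
    age_secondary: tuple[float, float] = (13.0, 0.3)
    bmi_z_mean: float = 0.39
    bmi_z_sd: float = 1.21
    imd_decile_mean: float = 7.3
    imd_decile_sd: float = 2.3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.boys_proportion <= 1):
            raise ValueError("boys_proportion must be in [0, 1]")
        cov = np.asarray(self.ilr_covariance, dtype=float)
        if cov.shape != (3, 3) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("ilr_covariance must be 3x3 positive definite")
        if len(self.target_geometric_means) != 4 or any(
            m <= 0 for m in self.target_geometric_means
        ):
            raise ValueError("target_geometric_means must be 4 positive minutes")


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """Cohort conditions matching the published study's descriptives.

    Composition effects for the overall, process and time scores are the
    published first-pivot coefficients converted to clr scale
    (``sqrt(3/4) * beta1``); the product score, whose omnibus test was
    not significant, gets a null composition effect.  Residual SDs are
    chosen so total score SDs land near the published descriptives, and
    intercepts centre each score at its published mean.  Covariate
    effects are generator choices of realistic size (boys modestly
    outscore girls; scores rise slowly with age).
    """
    gm = np.asarray(TARGET_GEOMETRIC_MEANS)
    beta1 = {
        "overall": (-2.45, -0.60, -1.76, 4.81),
        "process": (-1.00, -0.52, -0.86, 2.40),
        "product": (0.0, 0.0, 0.0, 0.0),
        "time": (-0.43, -0.03, -0.58, 1.04),
    }
    target_means = {"overall": 32.0, "process": 9.4, "product": 10.2, "time": 12.5}
    residual = {"overall": 6.5, "process": 2.9, "product": 3.3, "time": 1.9}
    school_sd = {"overall": 2.0, "process": 0.9, "product": 1.0, "time": 0.6}
    cov_effects = {
        "overall": {"age": 0.3, "sex": 2.5, "bmi_z": -0.3, "imd_decile": 0.15},
        "process": {"age": 0.3, "sex": 1.1, "bmi_z": -0.1, "imd_decile": 0.05},
        "product": {"age": 0.1, "sex": 0.8, "bmi_z": -0.1, "imd_decile": 0.05},
        "time": {"age": 0.2, "sex": 0.6, "bmi_z": -0.1, "imd_decile": 0.05},
    }
    cov_means = {"age": 11.5, "sex": 0.493, "bmi_z": 0.39, "imd_decile": 7.3}
    outcomes = {}
    for name in OUTCOME_COLUMNS:
        b = np.asarray(beta1[name], dtype=float)
        a = _SQRT34 * b
        a -= a.mean()  # exact zero sum despite 2-dp rounding of the inputs
        ce = cov_effects[name]
        intercept = (
            target_means[name]
            - float(a @ np.log(gm))
            - sum(ce[c] * cov_means[c] for c in ce)
        )
        outcomes[name] = OutcomeSpec(
            clr_effects=tuple(a.tolist()),
            covariate_effects=ce,
            intercept=intercept,
            residual_sd=residual[name],
            random_intercept_sd=school_sd[name],
        )
    return SimulationConfig(outcomes=outcomes, seed=seed)


def null_config(seed: int = 0) -> SimulationConfig:
    """Paper-like cohort with every composition effect set to zero."""
    cfg = paper_like_config(seed)
    outcomes = {name: spec.scaled(0.0) for name, spec in cfg.outcomes.items()}
    return dataclasses.replace(cfg, outcomes=outcomes)


def simulate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw one complete cohort as a participant-level table.

    Deterministic for a fixed config (same seed, byte-identical CSV).
    Column layout matches :data:`coda24.models.REQUIRED_COLUMNS`.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    school_ids = np.array([f"S{i + 1:02d}" for i in range(cfg.n_schools)])
    school_types = np.array(
        ["primary" if i < cfg.n_primary_schools else "secondary" for i in range(cfg.n_schools)]
    )
    school_idx = rng.integers(0, cfg.n_schools, size=n)  # multinomial-uniform sizes

    is_secondary = school_types[school_idx] == "secondary"
    mu_age = np.where(is_secondary, cfg.age_secondary[0], cfg.age_primary[0])
    sd_age = np.where(is_secondary, cfg.age_secondary[1], cfg.age_primary[1])
    age = rng.normal(mu_age, sd_age)
    boy = rng.random(n) < cfg.boys_proportion
    bmi_z = rng.normal(cfg.bmi_z_mean, cfg.bmi_z_sd, size=n)
    imd = np.clip(np.rint(rng.normal(cfg.imd_decile_mean, cfg.imd_decile_sd, size=n)), 1, 10)

    # logistic-normal compositions centred at the target compositional mean
    centre = pivot_ilr(close(np.asarray(cfg.target_geometric_means)), pivot=PARTS[0]).as_array()
    Z = rng.multivariate_normal(centre, np.asarray(cfg.ilr_covariance), size=n)
    logx = Z @ pivot_basis(PARTS[0]).T
    raw = np.exp(logx)
    comp = raw / raw.sum(axis=1, keepdims=True) * TOTAL_MINUTES
    log_comp = np.log(comp)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "school_id": school_ids[school_idx],
            "school_type": school_types[school_idx],
            "sex": np.where(boy, "boy", "girl"),
            "age": np.round(age, 3),
            "bmi_z": np.round(bmi_z, 3),
            "imd_decile": imd.astype(int),
        }
    )
    for j, part in enumerate(PARTS):
        df[COMPOSITION_COLUMNS[part]] = np.round(comp[:, j], 9)
    log_comp = np.log(df[[COMPOSITION_COLUMNS[p] for p in PARTS]].to_numpy())

    covariate_vals = {"age": df["age"].to_numpy(), "sex": boy.astype(float),
                      "bmi_z": df["bmi_z"].to_numpy(), "imd_decile": imd.astype(float)}
    for name, spec in cfg.outcomes.items():
        u = rng.normal(0.0, spec.random_intercept_sd, size=cfg.n_schools)
        y = (
            spec.intercept
            + log_comp @ np.asarray(spec.clr_effects)
            + sum(w * covariate_vals[c] for c, w in spec.covariate_effects.items())
            + u[school_idx]
            + rng.normal(0.0, spec.residual_sd, size=n)
        )
        df[name] = np.round(y, 6)
    for name in OUTCOME_COLUMNS:  # keep the documented header even if unspecified
        if name not in df.columns:
            df[name] = 0.0
    return df


def omnibus_rejection_rate(
    cfg: SimulationConfig,
    outcome_name: str,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts whose omnibus composition test rejects."""
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_replicates):
        rep_cfg = dataclasses.replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        cohort = simulate_cohort(rep_cfg)
        res = omnibus_ilr_test(cohort, outcome_name)
        rejections += res.p_value < alpha
    return rejections / n_replicates


def recovery_experiment(
    cfg: SimulationConfig,
    n_replicates: int = 200,
    seed: int = 0,
    outcome_name: str = "overall",
) -> pd.DataFrame:
    """Repeated-simulation check that the pipeline recovers its own truth.

    Each replicate simulates a cohort, runs the four-rotation fit, and
    converts the first-pivot coefficients to clr scale.  Returns one row
    per clr effect plus the residual and school-intercept SDs, with the
    truth, mean estimate, bias, empirical SD, mean model SE and the
    coverage of +/- 2 SE intervals (for the clr effects).
    """
    from .models import rotation_table

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    spec = cfg.outcomes[outcome_name]
    truth = np.asarray(spec.clr_effects)
    ss = np.random.SeedSequence(seed)
    est = np.empty((n_replicates, 4))
    ses = np.empty((n_replicates, 4))
    resid = np.empty(n_replicates)
    ri = np.empty(n_replicates)
    for r, child in enumerate(ss.spawn(n_replicates)):
        rep_cfg = dataclasses.replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        cohort = simulate_cohort(rep_cfg)
        rt = rotation_table(cohort, outcome_name)
        est[r] = _SQRT34 * rt.table["beta1"].to_numpy()
        ses[r] = _SQRT34 * rt.table["se"].to_numpy()
        fit = rt.fits[PARTS[0]]
        resid[r] = fit.residual_sd
        ri[r] = fit.random_intercept_sd
    covered = np.abs(est - truth) <= 2.0 * ses
    rows = []
    for j, part in enumerate(PARTS):
        rows.append(
            {
                "parameter": f"clr_{part}",
                "truth": truth[j],
                "mean_estimate": est[:, j].mean(),
                "bias": est[:, j].mean() - truth[j],
                "empirical_sd": est[:, j].std(ddof=1),
                "mean_se": ses[:, j].mean(),
                "coverage_2se": covered[:, j].mean(),
            }
        )
    for pname, truth_v, vals in (
        ("residual_sd", spec.residual_sd, resid),
        ("random_intercept_sd", spec.random_intercept_sd, ri),
    ):
        rows.append(
            {
                "parameter": pname,
                "truth": truth_v,
                "mean_estimate": vals.mean(),
                "bias": vals.mean() - truth_v,
                "empirical_sd": vals.std(ddof=1),
                "mean_se": float("nan"),
                "coverage_2se": float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
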