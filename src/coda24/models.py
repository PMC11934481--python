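"""Linear mixed models for outcome ~ pivot-ILR composition + covariates.

The analysis model regresses a motor-competence score on the three pivot
ILR coordinates of the daily time-use composition plus individual
covariates, with a school random intercept to absorb clustering.  The
three coordinates form one explanatory block: an omnibus likelihood-ratio
test (df = 3) decides whether the composition is associated with the
outcome at all, and the model is then refitted under each of the four
pivot rotations so every behaviour in turn receives an interpretable
"this behaviour relative to the rest" first coordinate.

Estimation is by REML for reported coefficients, standard errors and
variance components (statsmodels ``MixedLM``); the omnibus test compares
ML log-likelihoods of the models with and without the ILR block, since
fixed-effect blocks may not be compared across REML fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .composition import (
    PARTS,
    ActivityComposition,
    ClrCoefficients,
    clr_from_ilr,
    pivot_basis,
)

#: cohort CSV column for each behaviour, canonical order
COMPOSITION_COLUMNS: dict[str, str] = {p: f"{p}_min" for p in PARTS}

OUTCOME_COLUMNS: tuple[str, ...] = ("overall", "process", "product", "time")

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "bmi_z", "imd_decile")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "school_id",
    "school_type",
    "sex",
    "age",
    "bmi_z",
    "imd_decile",
    *COMPOSITION_COLUMNS.values(),
    *OUTCOME_COLUMNS,
)

ILR_NAMES = ("z1", "z2", "z3")


class RankDeficientDesignError(ValueError):
    """Raised when fixed-effect columns are collinear; names the culprits."""


def load_cohort_csv(path, drop_incomplete: bool = False) -> pd.DataFrame:
    """Read a cohort table, validating the documented header.

    Rows with missing values are rejected by default (imputation is out
    of scope here); pass ``drop_incomplete=True`` for complete-case
    filtering instead.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        if drop_incomplete:
            df = df.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
        else:
            raise ValueError(
                "cohort contains missing values; impute upstream or pass drop_incomplete=True"
            )
    return df


def cohort_compositions(records: pd.DataFrame) -> np.ndarray:
    """(n, 4) array of minutes in canonical behaviour order."""
    return records[[COMPOSITION_COLUMNS[p] for p in PARTS]].to_numpy(dtype=float)


def _encode_covariate(records: pd.DataFrame, name: str) -> np.ndarray:
    if name == "sex":
        sex = records["sex"]
        if sex.dtype == object:
            bad = set(sex.unique()) - {"girl", "boy"}
            if bad:
                raise ValueError(f"sex column must be 'girl'/'boy', found {sorted(bad)}")
            return (sex == "boy").to_numpy(dtype=float)  # girl = 0, boy = 1
        return sex.to_numpy(dtype=float)
    if name not in records.columns:
        raise ValueError(f"covariate column {name!r} not in cohort")
    return records[name].to_numpy(dtype=float)


def _check_rank(exog: pd.DataFrame) -> None:
    X = exog.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # walk columns left to right; flag each one inside the span of its predecessors
    culprits = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            culprits.append(exog.columns[j])
    raise RankDeficientDesignError(
        f"fixed-effect design is rank deficient; collinear columns: {culprits}"
    )


def build_design(
    records: pd.DataFrame,
    pivot_part: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    check_rank: bool = True,
) -> pd.DataFrame:
    """Fixed-effects design: intercept, pivot ILR coordinates, covariates."""
    comp = cohort_compositions(records)
    if np.any(comp <= 0) or np.any(~np.isfinite(comp)):
        raise ValueError("compositions must be strictly positive and finite")
    Z = np.log(comp) @ pivot_basis(pivot_part)
    exog = pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    for j, name in enumerate(ILR_NAMES):
        exog[name] = Z[:, j]
    for cov in covariates:
        exog[cov] = _encode_covariate(records, cov)
    if check_rank:
        _check_rank(exog)
    return exog


@dataclass
class MixedModelFit:
    """Fitted random-intercept model for one outcome under one pivot."""

    outcome_name: str
    pivot_part: str
    covariates: tuple[str, ...]
    fixed_effects: pd.DataFrame  # index: term; columns: coef, se, p
    random_intercept_sd: float
    residual_sd: float
    loglik: float
    loglik_ml: float | None
    estimation_method: str
    n_obs: int
    n_schools: int
    converged: bool
    singular: bool = False
    _covariate_means: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def beta1(self) -> float:
        return float(self.fixed_effects.loc["z1", "coef"])

    @property
    def beta1_se(self) -> float:
        return float(self.fixed_effects.loc["z1", "se"])

    @property
    def beta1_p(self) -> float:
        return float(self.fixed_effects.loc["z1", "p"])

    @property
    def ilr_coefficients(self) -> np.ndarray:
        return self.fixed_effects.loc[list(ILR_NAMES), "coef"].to_numpy(dtype=float)

    @property
    def clr_coefficients(self) -> ClrCoefficients:
        """Fitted composition effect projected onto the clr scale."""
        return clr_from_ilr(self.ilr_coefficients, self.pivot_part)

    def predict(
        self,
        composition: ActivityComposition | Sequence[float],
        covariate_values: Mapping[str, float] | None = None,
    ) -> float:
        """Population-level (fixed effects only) predicted outcome.

        Unspecified covariates are held at their estimation-sample means,
        so predictions describe an average participant; they cancel in
        any substitution difference.
        """
        x = (
            composition.as_array()
            if isinstance(composition, ActivityComposition)
            else np.asarray(composition, dtype=float)
        )
        z = np.log(x) @ pivot_basis(self.pivot_part)
        coefs = self.fixed_effects["coef"]
        y = float(coefs["const"]) + float(z @ coefs[list(ILR_NAMES)].to_numpy())
        covariate_values = covariate_values or {}
        for cov in self.covariates:
            val = covariate_values.get(cov, self._covariate_means.get(cov, 0.0))
            y += float(coefs[cov]) * float(val)
        return y


def _validate_records(records: pd.DataFrame, outcome_name: str, n_fixed: int) -> None:
    if outcome_name not in records.columns:
        raise ValueError(f"outcome column {outcome_name!r} not in cohort")
    cols = [c for c in REQUIRED_COLUMNS if c in records.columns] + [outcome_name]
    if records[cols].isna().any().any():
        raise ValueError("cohort contains missing values; this model requires complete rows")
    n_schools = records["school_id"].nunique()
    if n_schools < 2:
        raise ValueError(f"need >= 2 schools for a random intercept, got {n_schools}")
    if len(records) < n_fixed + 2:
        raise ValueError(f"need >= {n_fixed + 2} observations for {n_fixed} fixed effects")


# a between-school variance below this fraction of the residual variance is
# treated as a boundary (zero) estimate and reported as such
_SINGULAR_TOL = 1e-4


def _fit_mixedlm(endog, exog, groups, reml: bool):
    # boundary (zero variance) solutions can make the default optimizer's
    # Hessian singular; fall back to derivative-free searches, which recover
    # the boundary optimum
    model = MixedLM(endog, exog, groups=groups)
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm"):
            try:
                return model.fit(reml=reml, **({} if method is None else {"method": method}))
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
    raise RuntimeError(f"mixed-model fit failed under all optimizers: {last_err}")


def fit_mixed_model(
    records: pd.DataFrame,
    outcome_name: str,
    pivot_part: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    estimation: str = "REML",
    random_intercept: bool = True,
    compute_ml_loglik: bool = False,
) -> MixedModelFit:
    """Fit outcome ~ pivot ILRs + covariates with a school random intercept.

    ``random_intercept=False`` drops the school term entirely (ordinary
    least squares), which is also the reported fit when the variance
    component collapses to zero.  A boundary (zero between-school
    variance) fit is returned with ``singular=True`` rather than raised.
    """
    if estimation not in {"REML", "ML"}:
        raise ValueError("estimation must be 'REML' or 'ML'")
    covariates = tuple(covariates)
    _validate_records(records, outcome_name, 4 + len(covariates))
    exog = build_design(records, pivot_part, covariates)
    endog = records[outcome_name].to_numpy(dtype=float)

    if random_intercept:
        res = _fit_mixedlm(endog, exog, records["school_id"].to_numpy(), reml=(estimation == "REML"))
        params = pd.Series(res.fe_params, index=exog.columns)
        bse = pd.Series(res.bse_fe, index=exog.columns)
        var_re = float(np.squeeze(res.cov_re))
        scale = float(res.scale)
        ri_sd = float(np.sqrt(max(var_re, 0.0)))
        singular = var_re <= _SINGULAR_TOL * scale
        if singular:
            ri_sd = 0.0
            warnings.warn(
                f"between-school variance estimated at boundary (~0) for {outcome_name}; "
                "random intercept is not identifiable in these data",
                stacklevel=2,
            )
        loglik = float(res.llf)
        residual_sd = float(np.sqrt(scale))
        converged = bool(res.converged)
        loglik_ml = loglik if estimation == "ML" else None
        if compute_ml_loglik and loglik_ml is None:
            loglik_ml = float(_fit_mixedlm(endog, exog, records["school_id"].to_numpy(), reml=False).llf)
    else:
        import statsmodels.api as sm

        ols = sm.OLS(endog, exog).fit()
        params, bse = pd.Series(ols.params, index=exog.columns), pd.Series(ols.bse, index=exog.columns)
        ri_sd, singular = 0.0, False
        residual_sd = float(np.sqrt(ols.mse_resid))
        loglik = float(ols.llf)
        loglik_ml = loglik
        converged = True

    zvals = params / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))  # Wald z
    fixed = pd.DataFrame({"coef": params, "se": bse, "p": pvals})
    cov_means = {c: float(_encode_covariate(records, c).mean()) for c in covariates}
    return MixedModelFit(
        outcome_name=outcome_name,
        pivot_part=pivot_part,
        covariates=covariates,
        fixed_effects=fixed,
        random_intercept_sd=ri_sd,
        residual_sd=residual_sd,
        loglik=loglik,
        loglik_ml=loglik_ml,
        estimation_method=estimation if random_intercept else "OLS",
        n_obs=len(records),
        n_schools=int(records["school_id"].nunique()),
        converged=converged,
        singular=singular,
        _covariate_means=cov_means,
    )


@dataclass(frozen=True)
class OmnibusResult:
    """Likelihood-ratio test of the 3-coordinate composition block."""

    outcome_name: str
    chi2: float
    df: int
    p_value: float


def omnibus_ilr_test(
    records: pd.DataFrame,
    outcome_name: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> OmnibusResult:
    """LRT (df = 3) of the ILR block, from ML fits with and without it.

    Constant ILR columns (a composition identical across participants)
    carry no information and are excluded from the full model, so a
    degenerate cohort yields chi2 = 0 rather than a singular fit.
    """
    covariates = tuple(covariates)
    _validate_records(records, outcome_name, 4 + len(covariates))
    exog_full = build_design(records, PARTS[0], covariates, check_rank=False)
    keep = [c for c in exog_full.columns if c not in ILR_NAMES or exog_full[c].std() > 1e-12]
    exog_full = exog_full[keep]
    _check_rank(exog_full)
    exog_red = exog_full[[c for c in keep if c not in ILR_NAMES]]
    endog = records[outcome_name].to_numpy(dtype=float)
    groups = records["school_id"].to_numpy()
    if not any(c in ILR_NAMES for c in keep):
        chi2 = 0.0
    else:
        llf_full = _fit_mixedlm(endog, exog_full, groups, reml=False).llf
        llf_red = _fit_mixedlm(endog, exog_red, groups, reml=False).llf
        chi2 = max(0.0, 2.0 * float(llf_full - llf_red))
    df = 3
    return OmnibusResult(outcome_name, chi2, df, float(stats.chi2.sf(chi2, df)))


@dataclass
class RotationTable:
    """First-coordinate coefficients from the four pivot rotations.

    One row per behaviour: beta1 is the effect of that behaviour relative
    to the geometric mean of the other three.  The four beta1 values from
    exact fits of the same data sum to zero (they are four projections of
    one clr vector).
    """

    outcome_name: str
    table: pd.DataFrame  # index: behaviour; columns: beta1, se, p
    fits: dict[str, MixedModelFit] = field(default_factory=dict, repr=False)

    @property
    def sum_beta1(self) -> float:
        return float(self.table["beta1"].sum())

    @property
    def clr_coefficients(self) -> ClrCoefficients:
        from .composition import _SQRT34

        return ClrCoefficients(*(_SQRT34 * self.table["beta1"].to_numpy()).tolist())


def rotation_table(
    records: pd.DataFrame,
    outcome_name: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    estimation: str = "REML",
) -> RotationTable:
    """Refit the model under each pivot; collect (beta1, SE, Wald p) rows."""
    rows, fits = [], {}
    for part in PARTS:
        fit = fit_mixed_model(records, outcome_name, part, covariates, estimation)
        fits[part] = fit
        rows.append({"behaviour": part, "beta1": fit.beta1, "se": fit.beta1_se, "p": fit.beta1_p})
    table = pd.DataFrame(rows).set_index("behaviour")
    return RotationTable(outcome_name, table, fits)


def dominant_behaviour(table: RotationTable, alpha: float = 0.05) -> str | None:
    """Behaviour with the smallest significant first-coordinate p-value.

    Ties on p are broken by larger \\|beta1\\|; returns ``None`` when no
    behaviour reaches significance.
    """
    sig = table.table[table.table["p"] < alpha]
    if sig.empty:
        return None
    best = sig.sort_values(["p", "beta1"], key=lambda s: s if s.name == "p" else -s.abs())
    return str(best.index[0])
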