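import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coda24.composition import PARTS, close
from coda24.models import (
    RankDeficientDesignError,
    RotationTable,
    build_design,
    dominant_behaviour,
    fit_mixed_model,
    load_cohort_csv,
    omnibus_ilr_test,
    rotation_table,
)
from coda24.simulate import paper_like_config, simulate_cohort

from _lmm_oracle import ml_loglik


def test_noise_free_outcome_recovered_exactly(small_cohort):
    """With zero noise the model interpolates: coefficients exact to 1e-8."""
    df = small_cohort.copy()
    X = build_design(df, "sleep")
    beta = 0.3 * np.arange(1, X.shape[1] + 1, dtype=float)
    df["overall"] = X.to_numpy() @ beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_mixed_model(df, "overall", "sleep")
    assert np.allclose(fit.fixed_effects["coef"].to_numpy(), beta, atol=1e-8)
    assert fit.residual_sd < 1e-6


def test_rotation_invariance_of_fit(small_cohort, rng):
    """The four pivots are one model in different bases: same likelihood,
    variance components and predictions."""
    fits = {p: fit_mixed_model(small_cohort, "overall", p) for p in PARTS}
    logliks = [f.loglik for f in fits.values()]
    assert np.ptp(logliks) < 1e-6
    assert np.ptp([f.residual_sd for f in fits.values()]) < 1e-6
    assert np.ptp([f.random_intercept_sd for f in fits.values()]) < 1e-6
    for _ in range(5):
        comp = close(rng.uniform(30, 700, size=4))
        preds = [f.predict(comp, {"age": 11, "sex": 1, "bmi_z": 0.2, "imd_decile": 6}) for f in fits.values()]
        assert np.ptp(preds) < 1e-8


def test_matches_ols_without_random_intercept(small_cohort):
    fit = fit_mixed_model(small_cohort, "overall", "mvpa", random_intercept=False)
    X = build_design(small_cohort, "mvpa")
    ols = sm.OLS(small_cohort["overall"].to_numpy(), X).fit()
    assert np.allclose(fit.fixed_effects["coef"].to_numpy(), ols.params, atol=1e-8)
    assert fit.random_intercept_sd == 0.0


def test_omnibus_matches_brute_force_likelihood(tiny_cohort):
    """The LRT chi2 equals a direct profiled-likelihood maximisation."""
    res = omnibus_ilr_test(tiny_cohort, "overall")
    X_full = build_design(tiny_cohort, "sleep").to_numpy()
    X_red = X_full[:, [0, 4, 5, 6, 7]]  # drop the three ILR columns
    y = tiny_cohort["overall"].to_numpy()
    g = tiny_cohort["school_id"].to_numpy()
    chi2_oracle = 2.0 * (ml_loglik(y, X_full, g) - ml_loglik(y, X_red, g))
    assert res.chi2 == pytest.approx(chi2_oracle, abs=1e-4)
    assert res.df == 3


def test_omnibus_zero_for_constant_composition(small_cohort):
    df = small_cohort.copy()
    for col, val in zip(("sleep_min", "st_min", "lpa_min", "mvpa_min"), (540, 640, 210, 50)):
        df[col] = float(val)
    res = omnibus_ilr_test(df, "overall")
    assert res.chi2 == 0.0
    assert res.p_value == 1.0


def test_rotation_table_beta1_sums_to_zero(small_cohort):
    rt = rotation_table(small_cohort, "overall")
    assert abs(rt.sum_beta1) < 1e-6
    assert list(rt.table.index) == list(PARTS)


def test_rotation_clr_matches_fitted_ilr_projection(small_cohort):
    """The four beta1 readings and any single fit's clr projection agree."""
    rt = rotation_table(small_cohort, "overall")
    fit = rt.fits["sleep"]
    assert np.allclose(
        rt.clr_coefficients.as_array(), fit.clr_coefficients.as_array(), atol=1e-6
    )


def test_boundary_between_school_variance_flagged(paper_cohort):
    """School-centred noise puts the variance component on the zero boundary."""
    df = paper_cohort.copy()
    noise = np.random.default_rng(1).normal(0, 6, len(df))
    school_mean = pd.Series(noise).groupby(df["school_id"].values).transform("mean")
    df["overall"] = 30 + (noise - school_mean.to_numpy())
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_mixed_model(df, "overall", "sleep")
    assert fit.singular
    assert fit.random_intercept_sd == 0.0


def test_rank_deficient_design_names_columns(small_cohort):
    df = small_cohort.copy()
    df["age_copy"] = df["age"]
    with pytest.raises(RankDeficientDesignError, match="age_copy"):
        fit_mixed_model(df, "overall", "sleep", covariates=("age", "sex", "age_copy"))


def test_missing_values_rejected(small_cohort):
    df = small_cohort.copy()
    df.loc[3, "bmi_z"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_mixed_model(df, "overall", "sleep")


def test_single_school_rejected(small_cohort):
    df = small_cohort[small_cohort["school_id"] == small_cohort["school_id"].iloc[0]]
    with pytest.raises(ValueError, match="schools"):
        fit_mixed_model(df, "overall", "sleep")


class TestDominantBehaviour:
    @staticmethod
    def _table(rows):
        df = pd.DataFrame(rows, columns=["behaviour", "beta1", "se", "p"]).set_index("behaviour")
        return RotationTable("overall", df)

    def test_smallest_significant_p_wins(self):
        t = self._table(
            [("sleep", -2.45, 2.25, 0.28), ("st", -0.60, 1.80, 0.74),
             ("lpa", -1.76, 2.64, 0.50), ("mvpa", 4.81, 1.37, 0.0005)]
        )
        assert dominant_behaviour(t) == "mvpa"

    def test_none_when_nothing_significant(self):
        t = self._table(
            [("sleep", 1.0, 1.0, 0.3), ("st", 1.0, 1.0, 0.4),
             ("lpa", 1.0, 1.0, 0.5), ("mvpa", 1.0, 1.0, 0.06)]
        )
        assert dominant_behaviour(t) is None

    def test_tie_broken_by_larger_effect(self):
        t = self._table(
            [("sleep", -3.0, 1.0, 0.01), ("st", 1.0, 1.0, 0.5),
             ("lpa", 2.0, 1.0, 0.01), ("mvpa", 1.0, 1.0, 0.5)]
        )
        assert dominant_behaviour(t) == "sleep"


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    small_cohort.to_csv(path, index=False)
    df = load_cohort_csv(path)
    assert len(df) == len(small_cohort)
    df.loc[0, "age"] = np.nan
    path2 = tmp_path / "incomplete.csv"
    df.to_csv(path2, index=False)
    with pytest.raises(ValueError, match="missing"):
        load_cohort_csv(path2)
    assert len(load_cohort_csv(path2, drop_incomplete=True)) == len(df) - 1


def test_true_effects_recovered_within_sampling_error(paper_cohort):
    """One paper-like cohort: fitted clr effects land within ~3 SE of truth."""
    cfg = paper_like_config()
    truth = np.asarray(cfg.outcomes["overall"].clr_effects)
    rt = rotation_table(paper_cohort, "overall")
    est = np.sqrt(0.75) * rt.table["beta1"].to_numpy()
    se = np.sqrt(0.75) * rt.table["se"].to_numpy()
    assert np.all(np.abs(est - truth) < 4 * se)
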