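"""Group-comparison and interoception-emotion linkage statistics.

Student's pooled-variance t (computable from raw data or printed summary
statistics), Pearson chi-square without continuity correction, partial
correlation with a covariate set, z-score normalization, classical
forward-stepwise regression with backward checks, and the HEP -> LPP
linkage analysis combining them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "TestResult",
    "RegressionModel",
    "two_sample_t",
    "chi_square",
    "partial_correlation",
    "zscore",
    "stepwise_regression",
    "linkage_analysis",
    "DEFAULT_COVARIATES",
]

#: Covariates controlled for in the HEP-LPP partial correlations:
#: age, BMI, gender, parents' education, illness duration, and the
#: depression / state / trait anxiety scores.
DEFAULT_COVARIATES = (
    "age",
    "bmi",
    "gender",
    "parent_education_years",
    "duration_months",
    "bdi_total",
    "sai",
    "tai",
)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    kind: str  # "t" | "chi2"
    summary: dict = field(default_factory=dict)


def _summarize(v) -> tuple[float, float, int]:
    """Accept raw values or a (mean, sd, n) summary triple."""
    if isinstance(v, tuple) and len(v) == 3 and np.isscalar(v[0]):
        mean, sd, n = float(v[0]), float(v[1]), int(v[2])
        if sd < 0 or n < 2:
            raise ValueError("summary requires sd >= 0 and n >= 2")
        return mean, sd, n
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 observations per group")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def two_sample_t(a, b, variant: str = "student") -> TestResult:
    """Independent two-sample t test, ``t = (mean_b - mean_a) / SE``.

    ``a`` and ``b`` are raw value arrays or ``(mean, sd, n)`` summaries —
    the two paths give identical results.  ``student`` (default) pools the
    variances; ``welch`` uses the Welch-Satterthwaite correction.
    With zero variance in both groups, equal means give t = 0 and unequal
    means give a signed infinity.
    """
    ma, sa, na = _summarize(a)
    mb, sb, nb = _summarize(b)
    diff = mb - ma
    if variant == "student":
        df = na + nb - 2
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variant == "welch":
        va, vb = sa**2 / na, sb**2 / nb
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1)) if se > 0 else na + nb - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0.0:
        t = 0.0 if diff == 0.0 else float(np.sign(diff)) * np.inf
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / se
        p = 2.0 * spstats.t.sf(abs(t), df)
    return TestResult(
        float(t), float(df), float(p), "t",
        {"mean_a": ma, "sd_a": sa, "n_a": na, "mean_b": mb, "sd_b": sb, "n_b": nb,
         "variant": variant},
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    stat, p, dof, _ = spstats.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(dof), float(p), "chi2")


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), controls])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Correlation of x and y after projecting out the controls (+intercept).

    Returns ``(r, p)`` with ``p`` from the t transform at
    ``df = n - n_controls - 2``.  With no controls this is exactly the
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if controls is None:
        c = np.empty((len(x), 0))
    else:
        c = np.atleast_2d(np.asarray(controls, dtype=float))
        if c.shape[0] != len(x):
            c = c.T
    k = c.shape[1]
    n = len(x)
    if len(y) != n or c.shape[0] != n:
        raise ValueError("x, y and controls must have the same length")
    if n <= k + 2:
        raise ValueError(f"need n > n_controls + 2 (n={n}, controls={k})")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = [
            j for j in range(k)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == np.linalg.matrix_rank(design)
        ]
        raise ValueError(f"rank-deficient control matrix; collinear columns (0-based): {bad}")
    rx, ry = _residualize(x, c), _residualize(y, c)
    # a variable fully explained by the controls has no residual variance:
    # its partial correlation with anything is zero
    for res, orig in ((rx, x), (ry, y)):
        if np.sum(res**2) <= 1e-16 * max(np.sum((orig - orig.mean()) ** 2), 1e-300):
            return 0.0, 1.0
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0.0:
        return 0.0, 1.0
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * spstats.t.sf(abs(t), df))
    return r, p


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, denominator n-1)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant (or degenerate) input")
    return (v - v.mean()) / sd


@dataclass
class RegressionModel:
    """Final stepwise-regression model report."""

    predictors: list[str]
    coef: dict  # unstandardized B per predictor
    se: dict
    p_values: dict
    beta: dict  # standardized coefficients
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    model_p: float
    p_enter: float
    p_remove: float
    empty: bool = False


def _ols_fit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionModel:
    """Forward-stepwise OLS with backward elimination checks.

    At each step the candidate with the smallest partial-F p value enters
    if that p is <= ``p_enter`` (ties broken by column order); any included
    predictor whose p rises to >= ``p_remove`` is then removed (largest p
    first).  Iterates to a fixed point.  If nothing enters, an
    intercept-only model is returned with ``empty=True``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not isinstance(candidates, pd.DataFrame):
        raise TypeError("candidates must be a named-column DataFrame")
    names = list(candidates.columns)
    if len(y) <= len(names) + 2:
        raise ValueError("need n > number of candidates + 2")

    included: list[str] = []
    while True:
        changed = False
        # forward step
        best_name, best_p = None, np.inf
        for name in names:
            if name in included:
                continue
            fit = _ols_fit(y, candidates[included + [name]])
            p = float(fit.pvalues[name])
            if p < best_p - 1e-15:
                best_name, best_p = name, p
        if best_name is not None and best_p <= p_enter:
            included.append(best_name)
            changed = True
        # backward step(s)
        while included:
            fit = _ols_fit(y, candidates[included])
            pv = fit.pvalues[included]
            worst = pv.idxmax()
            if float(pv[worst]) >= p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        return RegressionModel(
            [], {}, {}, {}, {}, float(np.mean(y)), 0.0, 0.0, float("nan"), float("nan"),
            p_enter, p_remove, empty=True,
        )
    fit = _ols_fit(y, candidates[included])
    sy = y.std(ddof=1)
    beta = {
        name: float(fit.params[name]) * candidates[name].std(ddof=1) / sy for name in included
    }
    return RegressionModel(
        predictors=list(included),
        coef={n: float(fit.params[n]) for n in included},
        se={n: float(fit.bse[n]) for n in included},
        p_values={n: float(fit.pvalues[n]) for n in included},
        beta=beta,
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        model_p=float(fit.f_pvalue),
        p_enter=p_enter,
        p_remove=p_remove,
    )


def _encode_gender(table: pd.DataFrame) -> pd.Series:
    """Gender coded 0/1 (F=0, M=1) for use as a regression predictor."""
    if "gender" in table.columns:
        return table["gender"].astype(float)
    if "sex" not in table.columns:
        raise ValueError("subject table needs a 'sex' (M/F) or numeric 'gender' column")
    return table["sex"].map({"F": 0.0, "M": 1.0}).astype(float)


def linkage_analysis(
    table: pd.DataFrame,
    hep_cols: list[str],
    lpp_cols: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group_col: str = "group",
    patient_group: str = "MDD",
    stepwise_targets: dict | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    alpha: float = 0.05,
) -> dict:
    """HEP -> LPP linkage: per-group partial correlations plus patient-group
    stepwise predictive models.

    For every (HEP cluster, LPP cluster) pair and each group, computes the
    partial correlation controlling for the covariate set.  Within the
    patient group, fits stepwise models predicting each target LPP cluster
    from the z-scored HEP clusters plus gender (and any extra candidates
    given in ``stepwise_targets``: a mapping of dependent LPP column ->
    list of extra candidate columns).
    """
    table = table.copy()
    table["gender"] = _encode_gender(table)
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    for col in hep_cols + lpp_cols:
        if col not in table.columns:
            raise ValueError(f"missing cluster-mean column: {col}")

    if stepwise_targets is None:
        stepwise_targets = {col: [] for col in lpp_cols}

    partial: dict = {}
    for group, sub in table.groupby(group_col):
        ctrl_cols = [c for c in covariates if sub[c].nunique() > 1]
        controls = sub[list(ctrl_cols)].to_numpy(float)
        cells = {}
        for h in hep_cols:
            for l in lpp_cols:
                r, p = partial_correlation(sub[h], sub[l], controls)
                cells[(h, l)] = {"r": r, "p": p, "significant": bool(p < alpha)}
        partial[group] = cells

    patients = table[table[group_col] == patient_group]
    models: dict = {}
    for target, extra in stepwise_targets.items():
        cand_cols = list(hep_cols) + ["gender"] + list(extra)
        X = pd.DataFrame(index=patients.index)
        for c in cand_cols:
            col = patients[c].astype(float)
            # normalize continuous candidates; keep the 0/1 gender coding
            X[c] = col if c == "gender" else zscore(col)
        y = zscore(patients[target].astype(float))
        models[target] = stepwise_regression(y, X, p_enter=p_enter, p_remove=p_remove)

    return {"partial_correlations": partial, "stepwise_models": models, "alpha": alpha}
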