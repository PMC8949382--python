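"""Baseline predictors of profile membership.

Binary logistic regression (maximum likelihood via iteratively reweighted
least squares, as provided by statsmodels), backward elimination of
candidate covariates against an information criterion with a forced core
model, and post-fit diagnostics: logit-linearity for continuous covariates,
variance inflation factors, and influence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

#: term name -> design columns; multi-column terms move as one unit
TERM_COLUMNS = {
    "gender": ["gender_male"],
    "age": ["age"],
    "randomisation": ["rand_single", "rand_control"],
    "bmi": ["bmi"],
    "hypertension": ["hypertension"],
    "copd": ["copd"],
    "other_disease": ["other_disease"],
    "guideline": ["guideline"],
}
FORCED_TERMS = ("gender", "age", "randomisation")
CONTINUOUS_COLUMNS = ("age", "bmi")
SEPARATION_COEF = 15.0


def build_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix with explicit reference levels.

    Gender reference is female; randomisation reference is the
    multi-component arm.  Raw covariate columns may be given either in
    design form (gender_male/rand_single/rand_control) or in the cohort CSV
    dialect (gender F/M, randomisation multi/single/control).
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for term in terms:
        if term not in TERM_COLUMNS:
            raise ValueError(f"unknown term: {term!r}")
        for col in TERM_COLUMNS[term]:
            if col in data.columns:
                X[col] = data[col].astype(float)
            elif col == "gender_male":
                X[col] = (data["gender"] == "M").astype(float)
            elif col == "rand_single":
                X[col] = (data["randomisation"] == "single").astype(float)
            elif col == "rand_control":
                X[col] = (data["randomisation"] == "control").astype(float)
            else:
                raise ValueError(f"column {col!r} not found for term {term!r}")
    return X


@dataclass
class PredictorFit:
    terms: list[str]
    table: pd.DataFrame      # column, term, coef, se, odds_ratio, ci_low, ci_high, p
    intercept: float
    loglik: float
    aic: float
    bic: float
    nobs: int
    converged: bool
    separation_flags: list[str] = field(default_factory=list)
    elimination_trace: list[dict] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _term_of(column: str) -> str:
    for term, cols in TERM_COLUMNS.items():
        if column in cols:
            return term
    return column


def fit_logistic(data: pd.DataFrame, outcome: str, terms: list[str]) -> PredictorFit:
    """Fit outcome ~ terms; report odds ratios with Wald 95% intervals.

    Rejects rank-deficient designs; flags (without raising) coefficient
    divergence symptomatic of separation.
    """
    y = data[outcome].astype(float)
    levels = set(np.unique(y))
    if not levels <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(levels) < 2:
        raise ValueError("outcome is constant; both levels required")
    X = build_design(data, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    result = model.fit(maxiter=200)
    coefs = result.params
    ses = result.bse
    flags = [c for c in X.columns if c != "const" and abs(coefs[c]) > SEPARATION_COEF]
    llf = float(result.llf)
    n_par = X.shape[1]
    aic = -2.0 * llf + 2.0 * n_par
    bic = -2.0 * llf + n_par * np.log(len(y))
    rows = []
    for col in X.columns:
        if col == "const":
            continue
        coef, se = float(coefs[col]), float(ses[col])
        rows.append(
            {
                "column": col,
                "term": _term_of(col),
                "coef": coef,
                "se": se,
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * se)),
                "ci_high": float(np.exp(coef + 1.96 * se)),
                "p": float(result.pvalues[col]),
            }
        )
    return PredictorFit(
        terms=list(terms),
        table=pd.DataFrame(rows),
        intercept=float(coefs["const"]),
        loglik=llf,
        aic=aic,
        bic=bic,
        nobs=int(result.nobs),
        converged=bool(getattr(result, "converged", True)),
        separation_flags=flags,
    )


def backward_eliminate(
    data: pd.DataFrame,
    outcome: str,
    forced_terms: list[str] | None = None,
    candidate_terms: list[str] | None = None,
    criterion: str = "aic",
) -> PredictorFit:
    """Drop the candidate whose removal most improves the criterion, repeat.

    Forced terms are never removed.  The elimination trace (step, dropped
    term, criterion before/after) is attached to the returned fit.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    forced = list(forced_terms if forced_terms is not None else FORCED_TERMS)
    candidates = list(candidate_terms or [])
    current = fit_logistic(data, outcome, forced + candidates)
    trace: list[dict] = []
    step = 0
    while candidates:
        current_ic = getattr(current, criterion)
        best_drop, best_fit, best_ic = None, None, current_ic
        for term in candidates:
            reduced_terms = forced + [t for t in candidates if t != term]
            reduced = fit_logistic(data, outcome, reduced_terms)
            ic = getattr(reduced, criterion)
            if ic < best_ic - 1e-12:
                best_drop, best_fit, best_ic = term, reduced, ic
        if best_drop is None:
            break
        step += 1
        trace.append(
            {
                "step": step,
                "dropped": best_drop,
                f"{criterion}_before": current_ic,
                f"{criterion}_after": best_ic,
            }
        )
        candidates.remove(best_drop)
        current = best_fit
    current.elimination_trace = trace
    return current


def diagnostics(fit: PredictorFit, data: pd.DataFrame, outcome: str) -> dict:
    """Logit-linearity, intercorrelation and influence checks.

    * linearity: a ``x * ln(x)`` augmentation per continuous covariate,
      flagged when its Wald p < 0.05 (requires x > 0);
    * intercorrelation: variance inflation factors, flagged above 5;
    * influence: Cook's distance from the equivalent binomial GLM, rows
      flagged above 4/n.
    """
    X = build_design(data, fit.terms)
    y = data[outcome].astype(float)
    report: dict = {"linearity": {}, "vif": {}, "influence": {}}

    for col in CONTINUOUS_COLUMNS:
        if col not in X.columns:
            continue
        x = X[col]
        if (x <= 0).any():
            report["linearity"][col] = {"tested": False, "reason": "non-positive values"}
            continue
        X_aug = X.copy()
        aug_col = f"{col}_xlogx"
        X_aug[aug_col] = x * np.log(x)
        aug = sm.GLM(y, X_aug, family=sm.families.Binomial()).fit(maxiter=200)
        p = float(aug.pvalues[aug_col])
        report["linearity"][col] = {"tested": True, "p": p, "flag": p < 0.05}

    X_np = X.to_numpy()
    cols = [c for c in X.columns if c != "const"]
    for col in cols:
        j = list(X.columns).index(col)
        vif = float(variance_inflation_factor(X_np, j))
        report["vif"][col] = {"vif": vif, "flag": vif > 5.0}

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    cooks = glm.get_influence(observed=True).cooks_distance[0]
    cutoff = 4.0 / len(y)
    flagged = np.flatnonzero(cooks > cutoff)
    report["influence"] = {
        "cutoff": cutoff,
        "max_cooks_distance": float(np.max(cooks)),
        "flagged_rows": [int(i) for i in flagged],
    }
    return report


def write_diagnostics(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
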