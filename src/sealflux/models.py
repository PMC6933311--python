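"""All-subsets AICc multimodel inference with conditional model averaging.

Fits every main-effect subset of a candidate predictor set (including the
intercept-only model) by maximum likelihood, ranks the models with the
small-sample Akaike criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

derives Akaike weights, forms the 95% confidence set (the minimal
weight-sorted prefix whose cumulative weight reaches 0.95), and averages
each coefficient conditionally — over the confidence-set models that
contain it, with renormalized weights.  Unconditional standard errors
follow Burnham & Anderson:

    SE = sqrt( sum_i w_i [ se_i^2 + (b_i - b_bar)^2 ] ),

and 95% CIs are normal-based (estimate ± 1.96 SE).

A random intercept per grouping unit is supported; models whose estimated
random-effect variance collapses to the boundary (effectively zero, as with
repeated measures that carry no detectable individual signal) are refit as
plain linear models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "CandidateModelSet",
    "fit_candidates",
    "effect_as_percent",
]

#: categorical codings: reference level first, dummies for the rest
CATEGORICAL_EFFECTS = {
    "season": {"reference": "summer", "levels": ("summer", "fall")},
    "fa_cluster": {"reference": 1, "levels": (1, 2, 3)},
}


@dataclass(frozen=True)
class ModelSpec:
    """Response, candidate fixed effects, and optional random intercept group."""

    response: str
    fixed_effects: tuple[str, ...]
    random_intercept: str | None = None


@dataclass
class CandidateModelSet:
    """All fitted subsets plus the averaged coefficients.

    ``models`` has one row per candidate (effects, k, logLik, AICc, dAICc,
    weight); ``averaged`` one row per coefficient (estimate, unconditional
    SE, 95% CI, sum of Akaike weights of models containing it).
    """

    spec: ModelSpec
    n: int
    models: pd.DataFrame
    averaged: pd.DataFrame
    confidence_level: float = 0.95
    confidence_set: list[int] = field(default_factory=list)


def _design(d: pd.DataFrame, effects: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame(index=d.index)
    X["Intercept"] = 1.0
    for e in effects:
        if e in CATEGORICAL_EFFECTS:
            spec = CATEGORICAL_EFFECTS[e]
            for lev in spec["levels"]:
                if lev == spec["reference"]:
                    continue
                X[f"{e}[{lev}]"] = (d[e] == lev).astype(float)
        else:
            X[e] = d[e].astype(float)
    return X


def _fit_one(y, X, groups, n):
    """ML fit; returns (logLik, params, bse, k) or None if inadmissible.

    With a grouping factor a random-intercept model is attempted first; a
    boundary variance estimate (or a singular fit) triggers the plain linear
    refit, dropping the pseudo-parameter from k.
    """
    p = X.shape[1]
    if groups is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sm.MixedLM(y, X, groups=groups).fit(reml=False, method="lbfgs")
            re_var = float(m.cov_re.values[0, 0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bse = m.bse_fe
            if np.isfinite(re_var) and re_var > 1e-6 and np.isfinite(bse).all():
                k = p + 2  # fixed effects + residual var + RE var
                return float(m.llf), m.fe_params, bse, k
        except (np.linalg.LinAlgError, ValueError):
            pass  # boundary/singular: fall through to OLS
    res = sm.OLS(y, X).fit()
    k = p + 1  # fixed effects + residual variance
    if n <= k + 1:
        return None
    return float(res.llf), res.params, res.bse, k


def fit_candidates(
    data,
    spec: ModelSpec,
    confidence_level: float = 0.95,
) -> CandidateModelSet:
    """Fit all 2^p main-effect subsets and model-average the coefficients.

    ``data`` may be a DataFrame or a StudyTable; rows with missing response
    or effect values are dropped (complete-case analysis).
    """
    df = data.records if hasattr(data, "records") else data
    cols = [spec.response, *spec.fixed_effects]
    if spec.random_intercept:
        cols.append(spec.random_intercept)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"effects absent from data: {missing}")
    d = df.dropna(subset=[spec.response, *spec.fixed_effects]).copy()
    n = len(d)
    y = d[spec.response].astype(float).values
    groups = d[spec.random_intercept].values if spec.random_intercept else None

    rows = []
    dropped = 0
    for r in range(len(spec.fixed_effects) + 1):
        for subset in itertools.combinations(spec.fixed_effects, r):
            X = _design(d, subset)
            fit = _fit_one(y, X, groups, n)
            if fit is None:
                dropped += 1
                continue
            ll, params, bse, k = fit
            aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            rows.append(
                {"effects": subset, "k": k, "logLik": ll, "AICc": aicc,
                 "params": params, "bse": bse}
            )
    if dropped:
        warnings.warn(
            f"{dropped} candidate model(s) dropped: too many parameters for n={n}",
            RuntimeWarning,
            stacklevel=2,
        )
    models = pd.DataFrame(rows)
    models["dAICc"] = models["AICc"] - models["AICc"].min()
    rel = np.exp(-models["dAICc"] / 2.0)
    models["weight"] = rel / rel.sum()
    models = models.sort_values("weight", ascending=False).reset_index(drop=True)

    cum = models["weight"].cumsum()
    n_conf = int((cum >= confidence_level).idxmax()) + 1
    conf = models.iloc[:n_conf]

    terms: list[str] = []
    for p in models["params"]:
        for t in p.index:
            if t not in terms:
                terms.append(t)
    avg_rows = []
    for term in terms:
        contains_all = models[[term in p.index for p in models["params"]]]
        sel = conf[[term in p.index for p in conf["params"]]]
        if len(sel) == 0:  # term only in models outside the confidence set
            sel = contains_all
        w = sel["weight"].values / sel["weight"].sum()
        est = np.array([p[term] for p in sel["params"]])
        se = np.array([b[term] for b in sel["bse"]])
        b_bar = float((w * est).sum())
        se_u = float(np.sqrt((w * (se**2 + (est - b_bar) ** 2)).sum()))
        avg_rows.append(
            {
                "term": term,
                "estimate": b_bar,
                "se": se_u,
                "ci_low": b_bar - 1.96 * se_u,
                "ci_high": b_bar + 1.96 * se_u,
                "sum_weight": float(contains_all["weight"].sum()),
            }
        )
    averaged = pd.DataFrame(avg_rows).set_index("term")

    out_models = models[["effects", "k", "logLik", "AICc", "dAICc", "weight"]].copy()
    return CandidateModelSet(
        spec=spec,
        n=n,
        models=out_models,
        averaged=averaged,
        confidence_level=confidence_level,
        confidence_set=list(range(n_conf)),
    )


def effect_as_percent(model_set: CandidateModelSet, term: str) -> float:
    """A coefficient expressed as percent of the averaged intercept.

    For a seasonal dummy this is the percent change from the reference
    season; for a slope, the percent change per unit of the predictor.
    """
    averaged = model_set.averaged
    intercept = float(averaged.loc["Intercept", "estimate"])
    if abs(intercept) < 1e-12:
        raise ZeroDivisionError("averaged intercept is (near) zero")
    return 100.0 * float(averaged.loc[term, "estimate"]) / intercept
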