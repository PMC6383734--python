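"""Negative-binomial models of reproductive success.

Offspring counts per spawner are modelled with a negative-binomial GLM
(log link), sexes fit separately (the male stratum includes jacks), with
return year, origin and either body length or age (never both — they are
strongly correlated) plus return day as predictors. Continuous covariates
are transformed within return year to mean-absolute-deviation units to
absorb between-year differences in run timing and growth. Candidate
models are compared by AIC, counting the dispersion parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

CONTINUOUS = {"body_length", "return_day"}
FACTORS = {"return_year", "origin", "age"}
ALLOWED = CONTINUOUS | FACTORS


def mad_transform(values, year_labels, scale: bool = True) -> np.ndarray:
    """Within-year centering and mean-absolute-deviation scaling.

    Each value becomes (value - year mean) / MAD(year), where MAD is the
    mean absolute deviation about the year mean. A year with zero MAD
    (constant values) maps to 0 with a warning. With ``scale=False`` only
    the centering is applied.
    """
    v = np.asarray(values, dtype=float)
    years = np.asarray(year_labels)
    out = np.empty_like(v)
    for y in np.unique(years):
        mask = years == y
        d = v[mask] - v[mask].mean()
        if not scale:
            out[mask] = d
            continue
        mad = np.abs(d).mean()
        if mad == 0:
            warnings.warn(f"zero MAD in year {y}; values set to 0",
                          stacklevel=2)
            out[mask] = 0.0
        else:
            out[mask] = d / mad
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: an ordered predictor subset for one sex stratum.

    Predictors come from {return_year, origin, body_length, age,
    return_day}; body_length and age never co-occur; 2-4 predictors; no
    interactions or quadratics.
    """

    predictors: tuple
    sex_stratum: str = "female"  # or "male_with_jacks"

    def __post_init__(self):
        preds = tuple(self.predictors)
        if not 2 <= len(preds) <= 4:
            raise ValueError("a candidate model has 2-4 predictors")
        unknown = set(preds) - ALLOWED
        if unknown:
            raise ValueError(f"unknown predictors: {unknown}")
        if "body_length" in preds and "age" in preds:
            raise ValueError("body_length and age never co-occur")
        object.__setattr__(self, "predictors", preds)

    @property
    def label(self) -> str:
        return " + ".join(self.predictors)

    def formula(self, ref_year, mad_scale: bool = True) -> str:
        terms = []
        for p in self.predictors:
            if p == "return_year":
                terms.append(f"C(return_year, Treatment({ref_year}))")
            elif p == "origin":
                terms.append("C(origin, Treatment('HOR'))")
            elif p == "age":
                terms.append("C(age)")
            else:
                terms.append(f"{p}_t")
        return "rs ~ " + " + ".join(terms)


def candidate_models(sex_stratum: str = "female") -> list[ModelSpec]:
    """The eight candidate models: every model contains return year; body
    length and age alternate; the two four-predictor models are the stated
    full models."""
    sets = [
        ("return_year", "origin"),
        ("return_year", "body_length"),
        ("return_year", "age"),
        ("return_year", "return_day"),
        ("return_year", "origin", "body_length"),
        ("return_year", "origin", "age"),
        ("return_year", "origin", "body_length", "return_day"),
        ("return_year", "origin", "age", "return_day"),
    ]
    return [ModelSpec(s, sex_stratum) for s in sets]


@dataclass
class GLMFit:
    """A fitted negative-binomial GLM."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    theta: float          # NB dispersion (1 / alpha)
    aic: float            # -2 loglik + 2 (k + 1), counting the dispersion
    llf: float
    n: int
    converged: bool
    result: object = field(repr=False, default=None)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "p": self.pvalues})


def prepare_covariates(data: pd.DataFrame, mad_scale: bool = True) -> pd.DataFrame:
    """Add the within-year MAD-transformed covariate columns."""
    out = data.copy()
    for col in ("body_length", "return_day"):
        if col in out:
            out[f"{col}_t"] = mad_transform(out[col], out["return_year"],
                                            scale=mad_scale)
    return out


def fit_nb_glm(spec: ModelSpec, data: pd.DataFrame,
               mad_scale: bool = True, maxiter: int = 100) -> GLMFit:
    """Fit one candidate model by maximum likelihood.

    The response ``rs`` must be a nonnegative integer column. The
    dispersion is estimated jointly with the coefficients; reference
    levels are the earliest return year and hatchery origin (so the origin
    coefficient reads as the natural-origin effect). Non-convergence is
    reported on the returned fit, never silently."""
    if (data["rs"] < 0).any() or (data["rs"] % 1 != 0).any():
        raise ValueError("rs must contain nonnegative integers")
    df = prepare_covariates(data, mad_scale)
    ref_year = int(df["return_year"].min())
    formula = spec.formula(ref_year, mad_scale)
    model = smf.negativebinomial(formula, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = None
        try:
            poisson = smf.poisson(formula, df).fit(disp=0, maxiter=maxiter)
            start = np.append(poisson.params.to_numpy(), 0.1)
        except Exception:
            pass
        res = model.fit(disp=0, maxiter=maxiter, start_params=start,
                        method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=5 * maxiter, method="nm",
                            start_params=res.params)
    alpha = float(res.params.get("alpha", np.nan))
    theta = 1.0 / alpha if alpha > 0 else np.inf
    converged = bool(res.mle_retvals.get("converged", False))
    return GLMFit(spec=spec,
                  params=res.params.drop(labels=["alpha"], errors="ignore"),
                  bse=res.bse.drop(labels=["alpha"], errors="ignore"),
                  pvalues=res.pvalues.drop(labels=["alpha"], errors="ignore"),
                  theta=theta, aic=float(res.aic), llf=float(res.llf),
                  n=int(res.nobs), converged=converged, result=res)


def select_model(candidates: Sequence[ModelSpec], data: pd.DataFrame,
                 mad_scale: bool = True):
    """Fit all candidates on the identical observation set and return the
    lowest-AIC fit plus a delta-AIC table.

    Rows with a missing value in any covariate used by any candidate are
    removed before every fit. Candidates that fail to converge are
    excluded from the minimum with a warning.
    """
    used = sorted({p for c in candidates for p in c.predictors})
    cols = ["rs"] + used
    df = data.dropna(subset=[c for c in cols if c in data.columns])
    fits = [fit_nb_glm(spec, df, mad_scale) for spec in candidates]
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise RuntimeError("no candidate model converged")
    bad = len(fits) - len(ok)
    if bad:
        warnings.warn(f"{bad} candidate model(s) failed to converge and "
                      "were excluded from selection", stacklevel=2)
    best = min(ok, key=lambda f: f.aic)
    table = pd.DataFrame({
        "model": [f.spec.label for f in fits],
        "k": [len(f.params) + 1 for f in fits],
        "aic": [f.aic for f in fits],
        "converged": [f.converged for f in fits],
    })
    table["delta_aic"] = table["aic"] - best.aic
    return best, table.sort_values("aic").reset_index(drop=True)


def glm_dataset(fitness: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Naturally spawning fish of one sex stratum, ready for fitting.

    ``sex='female'`` keeps 4- and 5-year-old females; ``sex='male'`` keeps
    males of ages 3-5 (jacks included). Broodstock and the rare excluded
    classes are dropped; columns are renamed to the model's names.
    """
    df = fitness[fitness["include_rrs"] & ~fitness["broodstock"].astype(bool)]
    if sex == "female":
        df = df[(df["sex"] == "F") & df["age"].isin([4, 5])]
    elif sex == "male":
        df = df[(df["sex"] == "M") & df["age"].isin([3, 4, 5])]
    else:
        raise ValueError("sex must be 'female' or 'male'")
    out = df[["rs", "return_year", "origin", "age"]].copy()
    out["body_length"] = df["body_length_mm"].to_numpy()
    out["return_day"] = df["return_day"].to_numpy()
    return out.reset_index(drop=True)
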