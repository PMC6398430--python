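"""All-subsets count models with Akaike-weighted full model averaging.

The environmental analysis fits every subset of a candidate term set
(2^5 = 32 models for the per-transect local flock size, 2^10 = 1024 for
subgroup size), each a log-link count regression with a date-level random
intercept, ranks them by AIC, and reports the *full* (zero-substitution)
weighted average of each coefficient: a model that omits a term
contributes an estimate of 0 with that model's Akaike weight

    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2),
    Delta_i = AIC_i - min AIC.

The unconditional standard error follows Burnham & Anderson,

    SE(b) = sqrt( sum_i w_i (SE_i^2 + (b_i - b_bar)^2) ),

with ``SE_i = 0`` and ``b_i = 0`` for models omitting the term, and a
two-sided normal p-value is derived from ``b_bar / SE``.

Responses: the per-transect flock size estimate rounded to the nearest
integer (Poisson), and the subgroup size minus one (so that singletons map
to zero counts; Poisson or negative binomial).  Categorical factors are
dummy-coded against fixed reference levels (Morning, nonbreeder season,
cold, rain, few visitors, in forest, on building, juvenile, grass).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import fit_count_glmm
from .seasons import assign_season

logger = logging.getLogger(__name__)

__all__ = [
    "FLOCK_TERMS",
    "SUBGROUP_TERMS",
    "REFERENCE_LEVELS",
    "ModelData",
    "ModelSpec",
    "FitResult",
    "prepare_model_data",
    "enumerate_models",
    "fit_model",
    "akaike_weights",
    "full_average",
    "all_subsets_average",
]

FLOCK_TERMS = ("weather", "temperature", "transect_time", "season", "visitors")
SUBGROUP_TERMS = (
    "weather",
    "temperature",
    "transect_time",
    "season",
    "visitors",
    "n_crows_present",
    "age_class",
    "forested_area",
    "food",
    "on_building",
)

# reference level first, remaining levels get dummy columns
FACTOR_LEVELS = {
    "weather": ("rain", "clouds", "sun"),
    "temperature": ("cold", "warm", "hot"),
    "transect_time": ("Morning", "Noon", "Afternoon"),
    "season": ("nonbreeder", "breeding", "parental_care"),
    "visitors": ("few", "some", "many"),
    "age_class": ("juvenile", "nonjuvenile"),
    "forested_area": ("in_forest", "out_of_forest"),
    "food": ("grass", "vegetarian", "mixed", "mainly_meat", "human_gastronomy"),
    "on_building": ("on", "off"),
}
REFERENCE_LEVELS = {k: v[0] for k, v in FACTOR_LEVELS.items()}
NUMERIC_TERMS = ("n_crows_present",)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which terms enter the linear predictor."""

    terms: tuple
    family: str = "poisson"
    random_intercept: bool = True


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict  # column -> estimate (log scale)
    ses: dict  # column -> SE
    llf: float
    aic: float
    converged: bool


@dataclass
class ModelData:
    """Encoded model table: response, dummy design columns, date codes."""

    response: np.ndarray
    design: pd.DataFrame  # dummy/numeric columns, no intercept
    term_columns: dict  # term -> list of design column names
    group_codes: np.ndarray
    candidate_terms: tuple


def _encode_factor(series: pd.Series, term: str) -> pd.DataFrame:
    levels = FACTOR_LEVELS[term]
    vals = series.astype(str)
    bad = set(vals.unique()) - set(levels)
    if bad:
        raise ValueError(f"unknown level(s) {sorted(bad)} for factor {term!r}; valid levels: {levels}")
    out = {}
    for lev in levels[1:]:
        out[f"{term}[{lev}]"] = (vals == lev).astype(float).to_numpy()
    return pd.DataFrame(out, index=series.index)


def prepare_model_data(
    table: pd.DataFrame,
    response: str,
    candidate_terms: tuple | None = None,
) -> ModelData:
    """Encode a merged observation/covariate table for all-subsets fitting.

    Parameters
    ----------
    table : rows are per-transect estimates (``response="flock"``) or
        subgroup observations (``response="subgroup"``).  Must carry
        ``date`` plus the factor columns for the candidate terms; flock
        tables need ``FS_e_t``, subgroup tables need ``subgroup_size``.
    response : ``"flock"`` (FS_e per transect, rounded to integer) or
        ``"subgroup"`` (size minus one).
    candidate_terms : defaults to the standard 5-term flock set or the
        10-term subgroup set.
    """
    table = table.copy()
    if "transect_time" not in table.columns and "session" in table.columns:
        table["transect_time"] = table["session"]
    if "season" not in table.columns:
        table["season"] = pd.to_datetime(table["date"]).map(assign_season)
    if "forested_area" not in table.columns and "forested" in table.columns:
        table["forested_area"] = np.where(table["forested"].astype(int) == 1, "in_forest", "out_of_forest")
    if "on_building" in table.columns and table["on_building"].dtype != object:
        table["on_building"] = np.where(table["on_building"].astype(int) == 1, "on", "off")

    if response == "flock":
        y = np.rint(table["FS_e_t"].to_numpy(dtype=float)).astype(int)
        terms = candidate_terms or FLOCK_TERMS
    elif response == "subgroup":
        y = table["subgroup_size"].to_numpy(dtype=int) - 1
        terms = candidate_terms or SUBGROUP_TERMS
    else:
        raise ValueError("response must be 'flock' or 'subgroup'")
    if (y < 0).any():
        raise ValueError("encoded response contains negative counts")

    cols = []
    term_columns = {}
    for term in terms:
        if term in NUMERIC_TERMS:
            x = table[term].to_numpy(dtype=float)
            col = pd.DataFrame({term: x - x.mean()}, index=table.index)  # centred for stability
        else:
            if term not in table.columns:
                raise ValueError(f"table lacks column for term {term!r}")
            if table[term].isna().any():
                raise ValueError(f"missing values in factor {term!r}")
            col = _encode_factor(table[term], term)
        term_columns[term] = list(col.columns)
        cols.append(col)
    design = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=table.index)
    dates = pd.to_datetime(table["date"])
    group_codes = dates.factorize(sort=True)[0]
    return ModelData(
        response=y,
        design=design,
        term_columns=term_columns,
        group_codes=np.asarray(group_codes),
        candidate_terms=tuple(terms),
    )


def enumerate_models(
    candidates: tuple,
    family: str = "poisson",
    random_intercept: bool = True,
) -> list[ModelSpec]:
    """All 2^k term subsets, intercept-only first, in deterministic
    bitmask order."""
    candidates = tuple(candidates)
    specs = []
    for mask in range(2 ** len(candidates)):
        terms = tuple(t for i, t in enumerate(candidates) if mask >> i & 1)
        specs.append(ModelSpec(terms=terms, family=family, random_intercept=random_intercept))
    return specs


def fit_model(
    spec: ModelSpec,
    data: ModelData,
    start: dict | None = None,
) -> FitResult:
    """Fit one candidate model.

    With ``random_intercept`` the Laplace GLMM engine is used; without it,
    statsmodels' Poisson GLM or ML negative binomial.  Singular or
    non-finite fits are flagged nonconverged rather than raising, so the
    all-subsets loop can drop them from the average.
    """
    columns = [c for t in spec.terms for c in data.term_columns[t]]
    X = np.column_stack([np.ones(len(data.response))] + [data.design[c].to_numpy() for c in columns])
    names = ["(Intercept)"] + columns
    y = data.response

    try:
        if spec.random_intercept:
            start_beta = None
            if start:
                start_beta = np.array([start.get(n, 0.0) for n in names])
                start_beta[0] = start.get("(Intercept)", np.log(y.mean() + 0.5))
            res = fit_count_glmm(X, y, data.group_codes, family=spec.family, start_beta=start_beta)
            params, bse, llf, aic, conv = res.params, res.bse, res.llf, res.aic, res.converged
        elif spec.family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            params, bse, llf, aic, conv = res.params, res.bse, float(res.llf), float(res.aic), True
        else:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            conv = bool(res.mle_retvals.get("converged", True))
            params, bse = res.params[:-1], res.bse[:-1]  # drop alpha row
            llf, aic = float(res.llf), float(res.aic)
    except Exception as exc:
        logger.warning("model %s failed (%s); flagged nonconverged", spec.terms, exc)
        return FitResult(spec=spec, estimates={}, ses={}, llf=-np.inf, aic=np.inf, converged=False)

    if not (np.isfinite(params).all() and np.isfinite(aic)):
        conv = False
    return FitResult(
        spec=spec,
        estimates=dict(zip(names, np.asarray(params, dtype=float))),
        ses=dict(zip(names, np.asarray(bse, dtype=float))),
        llf=llf,
        aic=aic,
        converged=conv,
    )


def akaike_weights(aics) -> np.ndarray:
    """Normalized relative likelihoods exp(-Delta_i/2); overflow-safe."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - np.min(aics)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def full_average(fits: list[FitResult], weights=None) -> pd.DataFrame:
    """Weighted full (zero-substitution) model average.

    Returns a table indexed by coefficient with columns
    ``estimate, se, z, p``.  Nonconverged fits must be excluded before
    calling (see :func:`all_subsets_average`).
    """
    if not fits:
        raise ValueError("no converged models to average")
    if weights is None:
        weights = akaike_weights([f.aic for f in fits])
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")

    names: list[str] = []
    for f in fits:
        for n in f.estimates:
            if n not in names:
                names.append(n)
    rows = []
    for name in names:
        b = np.array([f.estimates.get(name, 0.0) for f in fits])
        s = np.array([f.ses.get(name, 0.0) for f in fits])
        b_bar = float(np.sum(weights * b))
        se = float(np.sqrt(np.sum(weights * (s**2 + (b - b_bar) ** 2))))
        z = b_bar / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else np.nan
        rows.append({"coefficient": name, "estimate": b_bar, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows).set_index("coefficient")


def all_subsets_average(
    data: ModelData,
    family: str = "poisson",
    random_intercept: bool = True,
) -> dict:
    """Fit every term subset, weight by AIC, and form the full average.

    Returns ``{"average": DataFrame, "fits": [...], "weights": array,
    "aic_table": DataFrame}``.  Nonconverged models are dropped and the
    weights renormalized (logged).
    """
    specs = enumerate_models(data.candidate_terms, family=family, random_intercept=random_intercept)
    # the full model first: its coefficients warm-start the submodels
    full_spec = specs[-1]
    full_fit = fit_model(full_spec, data)
    start = full_fit.estimates if full_fit.converged else None
    fits = []
    for spec in specs:
        if spec is full_spec:
            fits.append(full_fit)
        else:
            fits.append(fit_model(spec, data, start=start))
    ok = [f for f in fits if f.converged]
    dropped = len(fits) - len(ok)
    if dropped:
        logger.warning("%d of %d models nonconverged; dropped before averaging", dropped, len(fits))
    if not ok:
        raise ValueError("all candidate models failed to converge")
    weights = akaike_weights([f.aic for f in ok])
    table = full_average(ok, weights)
    aic_table = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.terms) or "(intercept only)" for f in ok],
            "aic": [f.aic for f in ok],
            "weight": weights,
        }
    ).sort_values("aic", ignore_index=True)
    return {"average": table, "fits": ok, "weights": weights, "aic_table": aic_table}
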