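"""All-subsets AICc model selection and full model averaging.

Candidate models are every subset of the candidate terms that respects
marginality (an interaction enters only alongside both main effects),
including the intercept-only model. Gaussian models are fitted by maximum
likelihood (optionally with one random intercept), ranked by AICc, and a
top set (ΔAICc ≤ cutoff, default 4) is averaged with Akaike weights.

Averaging is FULL (zero method): a term absent from a model contributes a
coefficient of 0 with that model's weight, shrinking weakly supported
effects toward zero — more conservative than the conditional average.
Unconditional standard errors follow Buckland et al. (1997):

    SE(β̄) = Σ_i w_i · sqrt(se_i² + (β_i − β̄)²)

with se_i = β_i = 0 where the term is absent. Confidence intervals use the
normal quantile by default and a term is "strongly supported" when its
interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning


def z_scale(values) -> np.ndarray:
    """Center and scale to unit sample standard deviation (Z-score)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot Z-scale a constant (zero-variance) column")
    return (x - x.mean()) / sd


def _interaction_parents(term: str) -> list[str]:
    return term.split(":") if ":" in term else []


def enumerate_models(candidate_terms: list[str]) -> list[tuple[str, ...]]:
    """All term subsets respecting marginality, intercept-only first.

    Deterministic order: by model size, then by term positions in
    ``candidate_terms``. At most 12 terms (4096 subsets before the
    marginality cull).
    """
    terms = list(candidate_terms)
    if len(terms) > 12:
        raise ValueError("more than 12 candidate terms; all-subsets would explode")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate candidate terms")
    models: list[tuple[str, ...]] = []
    for k in range(len(terms) + 1):
        for combo in combinations(range(len(terms)), k):
            subset = tuple(terms[i] for i in combo)
            ok = all(
                all(p in subset for p in _interaction_parents(t)) for t in subset
            )
            if ok:
                models.append(subset)
    return models


@dataclass
class FitRecord:
    """One fitted candidate model."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    k: int
    n: int
    random_intercept_var: float | None = None


def fit_model(
    data: pd.DataFrame,
    response: str,
    terms: tuple[str, ...] | list[str],
    random_intercept: str | None = None,
) -> FitRecord:
    """Fit one Gaussian candidate model by maximum likelihood.

    ``terms`` name columns of ``data`` (``a:b`` for an interaction);
    categorical columns are expanded by the formula machinery. With
    ``random_intercept`` set to a grouping column, a single random
    intercept is estimated by ML alongside the fixed effects. ``k`` counts
    every estimated parameter: fixed effects, the residual variance, and
    the random-intercept variance when present.
    """
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    if random_intercept is None:
        model = smf.ols(formula, data=data)
        _check_rank(model, terms)
        fit = model.fit()
        coefs = dict(fit.params)
        ses = dict(fit.bse)
        # OLS llf is already the ML (biased-variance) Gaussian log-likelihood
        return FitRecord(
            terms=tuple(terms),
            coefficients=coefs,
            standard_errors=ses,
            loglik=float(fit.llf),
            k=len(fit.params) + 1,
            n=int(fit.nobs),
        )
    model = smf.mixedlm(formula, data=data, groups=data[random_intercept])
    _check_rank(model, terms)
    with warnings.catch_warnings():
        # a boundary MLE (intercept variance ~ 0) is a routine outcome in
        # all-subsets scans, not a defect worth one warning per candidate
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(reml=False)
    fe = fit.fe_params
    coefs = {name: float(fe[name]) for name in fe.index}
    ses = {name: float(fit.bse_fe[name]) for name in fe.index}
    return FitRecord(
        terms=tuple(terms),
        coefficients=coefs,
        standard_errors=ses,
        loglik=float(fit.llf),
        k=len(fe) + 2,
        n=int(fit.nobs),
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0] * fit.scale),
    )


def _check_rank(model, terms) -> None:
    exog = np.asarray(model.exog, dtype=float)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(
            f"singular design matrix for terms {tuple(terms)}; drop collinear terms"
        )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: −2·logL + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class AveragedCoefficientTable:
    """Full model-averaged coefficients plus the underlying model ranking."""

    coefficients: pd.DataFrame
    model_set: pd.DataFrame
    delta_cutoff: float


def model_average(
    fits: list[FitRecord],
    delta_cutoff: float = 4.0,
    ci_quantile: float | None = None,
) -> AveragedCoefficientTable:
    """Rank fits by AICc and average coefficients over the top model set.

    The top set contains every fit within ``delta_cutoff`` AICc of the
    best; Akaike weights are renormalized over that set. ``ci_quantile``
    defaults to the 1.96 normal quantile; pass e.g. a t quantile to
    override. See the module docstring for the averaging formulas.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    aiccs = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    order = np.argsort(aiccs, kind="stable")
    delta = aiccs - aiccs.min()
    in_top = delta <= delta_cutoff
    top = [fits[i] for i in np.flatnonzero(in_top)]
    d_top = delta[in_top]
    w = np.exp(-0.5 * d_top)
    w /= w.sum()
    w_full = np.zeros(len(fits))
    w_full[in_top] = w

    model_set = pd.DataFrame(
        {
            "terms": [" + ".join(fits[i].terms) or "(intercept only)" for i in order],
            "k": [fits[i].k for i in order],
            "loglik": [fits[i].loglik for i in order],
            "aicc": aiccs[order],
            "delta_aicc": delta[order],
            "weight": w_full[order],
        }
    )

    names: list[str] = []
    for f in top:
        for name in f.coefficients:
            if name not in names:
                names.append(name)

    q = 1.959963984540054 if ci_quantile is None else float(ci_quantile)
    rows = []
    for name in names:
        betas = np.array([f.coefficients.get(name, 0.0) for f in top])
        ses = np.array([f.standard_errors.get(name, 0.0) for f in top])
        beta_bar = float((w * betas).sum())
        se_u = float((w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)).sum())
        lo, hi = beta_bar - q * se_u, beta_bar + q * se_u
        if se_u > 0:
            p = float(2.0 * sps.norm.sf(abs(beta_bar) / se_u))
        else:
            p = float("nan")
        rows.append(
            {
                "term": name,
                "coefficient": beta_bar,
                "unconditional_se": se_u,
                "p_value": p,
                "ci_low": lo,
                "ci_high": hi,
                "strongly_supported": bool(lo > 0 or hi < 0),
            }
        )
    return AveragedCoefficientTable(
        coefficients=pd.DataFrame(rows),
        model_set=model_set,
        delta_cutoff=float(delta_cutoff),
    )
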