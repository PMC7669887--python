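"""Per-trait linear mixed models and inter-individual variability screens.

Each of the 15 behavioural/physiological traits is fit with a Gaussian
linear mixed model: temperature and pCO2 as interacting two-level nominal
fixed effects (ambient cell = intercept) and replicate holding group as a
random intercept.  Fixed-effect significance is judged by 95% confidence
intervals built from posterior simulation: coefficient vectors are drawn
from a multivariate normal centred at the (RE)ML estimates with the
estimated coefficient covariance, and the CI is the 2.5/97.5 percentile
band of the draws.  Variance components are held at their point estimates
during simulation — a stated limitation of this style of interval.

Secondary screens quantify inter-individual variability: within-cell
coefficients of variation, all-pairs Pearson correlations at a
Bonferroni-corrected alpha, and Kolmogorov-Smirnov / Bartlett comparisons
of the lateralisation distributions between treatment cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TRAIT_NAMES",
    "TERM_NAMES",
    "EffectEstimate",
    "TraitModelFit",
    "make_trait_table",
    "fit_trait_model",
    "effect_ci",
    "cv_screen",
    "correlation_screen",
    "lateralisation_tests",
    "fit_all_traits",
]

TRAIT_NAMES = [
    "lateralisation_relative",
    "lateralisation_absolute",
    "odba",
    "hypoxia_tolerance",
    "mo2_min",
    "mo2_max",
    "aas",
    "fas",
    "epoc",
    "recovery_time",
    "blood_ph",
    "lactate",
    "hct",
    "hb",
    "mchc",
]

TERM_NAMES = ["intercept", "temperature", "pco2", "interaction"]


@dataclass(frozen=True)
class EffectEstimate:
    trait: str
    term: str
    mean: float
    ci_low: float
    ci_high: float
    significant: bool  # CI excludes zero (never claimed for the intercept)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("point estimate must lie inside its CI")


@dataclass
class TraitModelFit:
    """Fixed-effect estimates plus what posterior simulation needs."""

    trait: str
    terms: list[str]
    params: np.ndarray  # fixed-effect estimates, ordered as `terms`
    cov: np.ndarray  # their estimated covariance
    group_var: float
    resid_var: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool  # random-intercept variance collapsed to ~0
    reml: bool


def make_trait_table(roster, trait_columns: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble the shark x traits table from a roster and trait arrays."""
    base = pd.DataFrame(
        {
            "shark_id": [s.id for s in roster],
            "mass": [s.mass for s in roster],
            "temperature": [s.temperature for s in roster],
            "pco2": [s.pco2 for s in roster],
            "group_id": [s.group_id for s in roster],
        }
    )
    for name, col in trait_columns.items():
        base[name] = col
    return base


def _design_matrix(
    table: pd.DataFrame, include_interaction: bool
) -> tuple[np.ndarray, list[str]]:
    hi_t = (table["temperature"] == table["temperature"].max()).to_numpy(float)
    hi_c = (table["pco2"] == table["pco2"].max()).to_numpy(float)
    if table["temperature"].nunique() == 1:
        hi_t = np.zeros(len(table))
    if table["pco2"].nunique() == 1:
        hi_c = np.zeros(len(table))
    cols = [np.ones(len(table)), hi_t, hi_c]
    names = ["intercept", "temperature", "pco2"]
    if include_interaction:
        cols.append(hi_t * hi_c)
        names.append("interaction")
    return np.column_stack(cols), names


def _fit_mixedlm(y, exog, groups, reml: bool):
    """MixedLM fit with an optimiser fallback chain; None if all fail."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                result = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged and np.isfinite(result.llf):
                return result
    return None


def fit_trait_model(
    table: pd.DataFrame,
    trait: str,
    include_interaction: bool = True,
    reml: bool = True,
) -> TraitModelFit:
    """Fit the mixed model for one trait (complete-case rows).

    REML estimates are the reporting default; refit with ``reml=False``
    for nested likelihood-ratio comparisons.  A random-intercept variance
    that collapses to (numerically) zero is flagged ``singular`` rather
    than treated as an error.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    data = table.dropna(subset=[trait])
    if data.empty:
        raise ValueError(f"trait {trait!r} has no non-missing values")
    y = data[trait].to_numpy(float)
    exog, names = _design_matrix(data, include_interaction)
    groups = data["group_id"].to_numpy()
    result = _fit_mixedlm(y, exog, groups, reml=reml)
    if result is None:
        raise ValueError(f"mixed model for trait {trait!r} failed to converge")
    k = len(names)
    cov = np.asarray(result.cov_params())[:k, :k]
    group_var = float(np.asarray(result.cov_re)[0, 0])
    resid_var = float(result.scale)
    # lme4-style singularity: random-intercept variance at (numerically)
    # the boundary relative to the residual variance
    singular = group_var < 1e-4 * max(resid_var, 1e-12)
    return TraitModelFit(
        trait=trait,
        terms=names,
        params=np.asarray(result.fe_params, dtype=float),
        cov=cov,
        group_var=group_var,
        resid_var=resid_var,
        llf=float(result.llf),
        n_obs=len(data),
        n_groups=int(data["group_id"].nunique()),
        converged=bool(result.converged),
        singular=singular,
        reml=reml,
    )


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() >= 0:
        return cov
    warnings.warn("coefficient covariance not PSD; clipping negative eigenvalues")
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(vals) @ vecs.T


def effect_ci(
    fit: TraitModelFit,
    n_sim: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> list[EffectEstimate]:
    """Posterior-simulation CIs for every fixed-effect term.

    Each draw first samples an overall scale from its marginal
    (scale^2 ~ df / chi2_df), then a coefficient vector from
    N(estimates, covariance * scale^2) — the classic
    informative-prior-free posterior simulation for linear models, which
    gives t-like rather than normal tails.  Random-effect variances stay
    at their point estimates.  The degrees of freedom follow the
    between-within convention: treatments are randomised to replicate
    groups, so treatment contrasts are between-group comparisons and
    df = n_groups - p (falling back to n - p when the random intercept is
    absent or collapsed).  CIs are 2.5/97.5 percentile bands; a term is
    significant when its band excludes zero (the intercept is reported
    but never flagged).
    """
    rng = np.random.default_rng(seed)
    cov = _nearest_psd(fit.cov)
    p = len(fit.terms)
    if fit.singular or fit.n_groups <= p:
        df = max(fit.n_obs - p, 1)
    else:
        df = fit.n_groups - p
    scale2 = df / rng.chisquare(df, size=n_sim)
    draws = rng.multivariate_normal(
        np.zeros_like(fit.params), cov, size=n_sim, method="svd"
    )
    draws = fit.params + draws * np.sqrt(scale2)[:, None]
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    # the point estimate can fall (just) outside the percentile band in
    # tiny samples of draws; widen to keep the triple ordered
    lo = np.minimum(lo, fit.params)
    hi = np.maximum(hi, fit.params)
    out = []
    for j, term in enumerate(fit.terms):
        sig = term != "intercept" and (lo[j] > 0.0 or hi[j] < 0.0)
        out.append(
            EffectEstimate(
                trait=fit.trait,
                term=term,
                mean=float(fit.params[j]),
                ci_low=float(lo[j]),
                ci_high=float(hi[j]),
                significant=bool(sig),
            )
        )
    return out


def fit_all_traits(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    n_sim: int = 1000,
    seed: int | None = None,
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Tidy effect-estimate table (trait, term, mean, ci_low, ci_high, significant)."""
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        fit = fit_trait_model(table, trait, include_interaction=include_interaction)
        for est in effect_ci(fit, n_sim=n_sim, seed=int(rng.integers(2**31))):
            rows.append(est.__dict__)
    return pd.DataFrame(rows)


def cv_screen(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Within-cell coefficients of variation (%), pooled as the mean of cell CVs."""
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    rows = []
    for trait in traits:
        cell_cvs = []
        for (_, _), cell in table.groupby(["temperature", "pco2"]):
            vals = cell[trait].dropna().to_numpy(float)
            if vals.size < 2:
                continue
            m = vals.mean()
            if m == 0:
                continue
            cell_cvs.append(abs(vals.std(ddof=1) / m) * 100.0)
        if not cell_cvs:
            raise ValueError(f"trait {trait!r}: no cell with >= 2 values")
        rows.append(
            {"trait": trait, "cv_percent": float(np.mean(cell_cvs)), "n_cells": len(cell_cvs)}
        )
    return pd.DataFrame(rows)


def correlation_screen(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = 0.0005,
    strong_r: float = 0.80,
    strong_p: float = 0.001,
) -> pd.DataFrame:
    """All-pairs Pearson screen: 15 traits -> 105 tests.

    ``significant`` applies the Bonferroni-corrected alpha (0.05 / 105
    rounds to the conventional 0.0005); ``strong`` additionally requires
    r > ``strong_r`` at p < ``strong_p``.
    """
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    rows = []
    for a, b in itertools.combinations(traits, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sub[a], sub[b])
        rows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "r": float(r),
                "p": float(p),
                "n": len(sub),
                "significant": bool(p < alpha) if np.isfinite(p) else False,
                "strong": bool(r > strong_r and p < strong_p)
                if np.isfinite(p)
                else False,
            }
        )
    return pd.DataFrame(rows)


def lateralisation_tests(
    table: pd.DataFrame,
    trait: str = "lateralisation_relative",
    mode: str = "all_pairs",
) -> dict:
    """Distribution and variance comparisons of lateralisation across cells.

    Two-sample Kolmogorov-Smirnov D (and p) for treatment-cell pairs —
    either every pair (``all_pairs``) or each cell against the ambient
    cell (``vs_ambient``) — plus Bartlett's variance-homogeneity test
    across all four cells for both the signed and absolute indices.
    """
    cells = {
        key: grp[trait].dropna().to_numpy(float)
        for key, grp in table.groupby(["temperature", "pco2"])
    }
    keys = sorted(cells)
    if mode == "all_pairs":
        pairs = list(itertools.combinations(keys, 2))
    elif mode == "vs_ambient":
        ambient = (table["temperature"].min(), table["pco2"].min())
        pairs = [(ambient, k) for k in keys if k != ambient]
    else:
        raise ValueError("mode must be 'all_pairs' or 'vs_ambient'")
    ks_rows = []
    for ka, kb in pairs:
        d, p = stats.ks_2samp(cells[ka], cells[kb], method="auto")
        ks_rows.append({"cell_a": ka, "cell_b": kb, "D": float(d), "p": float(p)})

    bartlett = {}
    for name in ("lateralisation_relative", "lateralisation_absolute"):
        if name not in table.columns:
            continue
        groups = [
            grp[name].dropna().to_numpy(float)
            for _, grp in table.groupby(["temperature", "pco2"])
        ]
        k2, p = stats.bartlett(*groups)
        bartlett[name] = {"K2": float(k2), "p": float(p)}
    return {"ks": pd.DataFrame(ks_rows), "bartlett": bartlett}
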