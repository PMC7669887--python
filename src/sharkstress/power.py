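"""Monte-Carlo power analysis for the factorial mixed design.

Power to detect a fixed effect is estimated by simulate-refit-test: data
are simulated from a fully specified mixed model (cell means, replicate
group intercept SD, residual SD), the model is refit and a test of the
term under test at alpha decides significance.  Power is the significant
fraction with a Wilson binomial CI.

Two test rules are available.  The default (``test_rule="t"``) is a
between-within t test on the REML fit: treatments are randomised to
replicate groups, so treatment contrasts carry df = n_groups - p; its
size is accurate at the handful-of-groups designs this package targets.
``test_rule="lrt"`` is the likelihood-ratio chi2 test of nested
full-likelihood refits — the convention of the simulation-power R
ecosystem — which is noticeably anticonservative when groups are few
(its chi2 reference undercounts the cost of estimating the group
variance).  Utilities grow the number of replicate groups until
power clears a target (with common random numbers across grid points so
the curve is monotone up to test noise), and translate treatment/control
effect *ratios* from the meta-analysis literature into the additive
shifts the linear model uses: effect = (ratio - 1) x control intercept.

In the degenerate no-random-effect case (group SD = 0) the refits are
ordinary least squares and the nested comparison is the exact F test,
which for a single coefficient coincides with the two-sided t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .inference import _fit_mixedlm
from .synthetic import StudyDesign, _stable_key, generate_design

__all__ = [
    "EffectRatioSet",
    "PowerSpec",
    "PowerResult",
    "RequiredGroupsResult",
    "simulate_power",
    "interaction_retention",
    "required_groups",
    "ratios_to_effects",
    "two_sample_t_power",
]

_TERMS = ("temperature", "pco2", "interaction")
_TERM_INDEX = {"temperature": 1, "pco2": 2, "interaction": 3}


@dataclass(frozen=True)
class EffectRatioSet:
    """Treatment/control ratios (meta-analysis scale) for the three terms."""

    temperature: float = 1.67
    pco2: float = 1.06
    interaction: float = 1.60

    def __post_init__(self) -> None:
        if min(self.temperature, self.pco2, self.interaction) <= 0:
            raise ValueError("effect ratios must be positive")


def ratios_to_effects(ratios: EffectRatioSet, intercept: float) -> dict[str, float]:
    """Additive model effects implied by ratios: (r - 1) x intercept per term."""
    if intercept <= 0:
        raise ValueError("intercept must be positive to interpret ratios")
    return {
        "temperature": (ratios.temperature - 1.0) * intercept,
        "pco2": (ratios.pco2 - 1.0) * intercept,
        "interaction": (ratios.interaction - 1.0) * intercept,
    }


@dataclass(frozen=True)
class PowerSpec:
    """Fully specified generative model + design + test rule."""

    intercept: float
    effects: dict = field(default_factory=dict)  # additive, keys in _TERMS
    group_sd: float = 0.0
    residual_sd: float = 1.0
    groups_per_cell: int = 3
    sharks_per_group: tuple[int, int] = (3, 4)
    effect: str = "interaction"  # term under test
    alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 0
    test_rule: str = "t"  # "t" (between-within) or "lrt"
    max_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.effect not in _TERMS:
            raise ValueError(f"effect must be one of {_TERMS}")
        if self.test_rule not in ("t", "lrt"):
            raise ValueError("test_rule must be 't' or 'lrt'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_sim < 100:
            raise ValueError("n_sim below 100 gives unusable power estimates")
        bad = set(self.effects) - set(_TERMS)
        if bad:
            raise ValueError(f"unknown effect terms {sorted(bad)}")


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_significant: int
    n_sim: int
    groups_per_cell: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.power <= self.ci_high:
            raise ValueError("power estimate must lie inside its CI")


@dataclass(frozen=True)
class RequiredGroupsResult:
    curve: pd.DataFrame  # groups, power, ci_low, ci_high
    required: int | None  # smallest count with power > target
    plateau_required: int | None  # additionally, successor gain < 2 points
    attained: bool
    target: float


def _design_for(spec: PowerSpec, groups_per_cell: int | None = None) -> StudyDesign:
    return StudyDesign(
        groups_per_cell=groups_per_cell or spec.groups_per_cell,
        sharks_per_group=spec.sharks_per_group,
        seed=0,  # roster randomness is re-seeded per replicate below
    )


def _simulate_dataset(spec: PowerSpec, groups_per_cell: int, rep: int) -> tuple:
    """One simulated dataset: (y, X_full, X_reduced, groups).

    Every random draw is keyed on (spec.seed, replicate index, structural
    identity of the group/shark), never on position in a stream, so
    enlarging the design reuses the identical draws for the groups it
    shares with a smaller design — the common-random-numbers scheme the
    group-count search relies on.
    """
    design_seed = int(
        np.random.SeedSequence((spec.seed, 7, rep)).generate_state(1)[0] % (2**31)
    )
    design = StudyDesign(
        groups_per_cell=groups_per_cell,
        sharks_per_group=spec.sharks_per_group,
        seed=design_seed,
    )
    roster = generate_design(design)
    hi_t = np.array([s.temperature == 31.0 for s in roster], dtype=float)
    hi_c = np.array([s.pco2 == 1050.0 for s in roster], dtype=float)
    x_full = np.column_stack([np.ones(len(roster)), hi_t, hi_c, hi_t * hi_c])
    names = ["intercept", "temperature", "pco2", "interaction"]
    beta = np.array(
        [spec.intercept] + [spec.effects.get(t, 0.0) for t in _TERMS]
    )
    groups = np.array([s.group_id for s in roster])
    g_map = {
        g: float(
            np.random.default_rng(
                np.random.SeedSequence((spec.seed, 11, rep, _stable_key(g)))
            ).normal(0.0, spec.group_sd)
        )
        for g in pd.unique(groups)
    }
    resid = np.array(
        [
            np.random.default_rng(
                np.random.SeedSequence((spec.seed, 13, rep, _stable_key(s.id)))
            ).normal(0.0, spec.residual_sd)
            for s in roster
        ]
    )
    y = x_full @ beta + np.array([g_map[g] for g in groups]) + resid
    drop = names.index(spec.effect)
    x_red = np.delete(x_full, drop, axis=1)
    return y, x_full, x_red, groups


def _lrt_mixed(y, x_full, x_red, groups, alpha: float) -> bool | None:
    """Likelihood-ratio test of the dropped term in the mixed model (ML fits).

    Returns None when either refit fails to converge.
    """
    full = _fit_mixedlm(y, x_full, groups, reml=False)
    red = _fit_mixedlm(y, x_red, groups, reml=False)
    if full is None or red is None:
        return None
    lr = 2.0 * (full.llf - red.llf)
    p = stats.chi2.sf(max(lr, 0.0), df=1)
    return bool(p < alpha)


def _t_mixed(y, x_full, effect_idx: int, groups, alpha: float) -> bool | None:
    """Between-within t test of one coefficient on the REML fit.

    Treatment contrasts compare whole replicate groups, so the group is
    the effective experimental unit and df = n_groups - p.  When the
    random-intercept variance collapses to the boundary the mixed model
    *is* ordinary least squares, and the exact OLS t test (df = n - p) is
    the correct reference; using the group-level df there would be
    needlessly conservative.
    """
    fit = _fit_mixedlm(y, x_full, groups, reml=True)
    if fit is None:
        return None
    p_params = x_full.shape[1]
    singular = float(np.asarray(fit.cov_re)[0, 0]) < 1e-4 * float(fit.scale)
    if singular:
        ols = sm.OLS(y, x_full).fit()
        tval = float(ols.tvalues[effect_idx])
        df = len(y) - p_params
    else:
        se = float(np.sqrt(np.asarray(fit.cov_params())[effect_idx, effect_idx]))
        if not np.isfinite(se) or se <= 0:
            return None
        tval = float(fit.fe_params[effect_idx]) / se
        df = len(np.unique(groups)) - p_params
    if df < 1:
        return None
    p = 2.0 * stats.t.sf(abs(tval), df)
    return bool(p < alpha)


def _ftest_ols(y, x_full, x_red, alpha: float) -> bool:
    """Exact nested F test (== two-sided t test for one coefficient)."""
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df_num = x_full.shape[1] - x_red.shape[1]
    df_den = len(y) - x_full.shape[1]
    f = (red.ssr - full.ssr) / df_num / (full.ssr / df_den)
    p = stats.f.sf(f, df_num, df_den)
    return bool(p < alpha)


def simulate_power(spec: PowerSpec, groups_per_cell: int | None = None) -> PowerResult:
    """Estimate power for ``spec.effect`` by simulate-refit-test Monte Carlo."""
    g = groups_per_cell or spec.groups_per_cell
    n_sig = 0
    n_ok = 0
    n_failed = 0
    for i in range(spec.n_sim):
        y, x_full, x_red, groups = _simulate_dataset(spec, g, i)
        if spec.group_sd == 0.0:
            sig = _ftest_ols(y, x_full, x_red, spec.alpha)
        elif spec.test_rule == "lrt":
            sig = _lrt_mixed(y, x_full, x_red, groups, spec.alpha)
        else:
            sig = _t_mixed(
                y, x_full, _TERM_INDEX[spec.effect], groups, spec.alpha
            )
        if sig is None:
            n_failed += 1
            continue
        n_ok += 1
        n_sig += int(sig)
    if n_failed > spec.max_failure_rate * spec.n_sim:
        raise RuntimeError(
            f"{n_failed}/{spec.n_sim} refits failed to converge "
            f"(groups_per_cell={g}); model too unstable for power estimation"
        )
    power = n_sig / n_ok
    lo, hi = proportion_confint(n_sig, n_ok, alpha=0.05, method="wilson")
    return PowerResult(
        power=float(power),
        ci_low=float(lo),
        ci_high=float(hi),
        n_significant=n_sig,
        n_sim=n_ok,
        groups_per_cell=g,
        n_failed=n_failed,
    )


def interaction_retention(spec: PowerSpec, threshold: float = 0.80) -> bool:
    """Keep the interaction term only when its power strictly exceeds 80%."""
    spec = replace(spec, effect="interaction")
    return simulate_power(spec).power > threshold


def required_groups(
    spec: PowerSpec,
    target: float = 0.80,
    max_groups: int = 12,
    grid: list[int] | None = None,
    plateau_gain: float = 0.02,
) -> RequiredGroupsResult:
    """Smallest replicate-group count whose power exceeds ``target``.

    Evaluates the power curve on an increasing grid with common random
    numbers across grid points.  Reports both the strict-threshold answer
    and a plateau answer (power > target AND the gain to the next grid
    point is below ``plateau_gain``).  ``attained`` is False when no grid
    point clears the target.
    """
    grid = grid or list(range(spec.groups_per_cell, max_groups + 1))
    rows = []
    for g in grid:
        res = simulate_power(spec, groups_per_cell=g)
        rows.append(
            {
                "groups": g,
                "power": res.power,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    curve = pd.DataFrame(rows)
    required = None
    for _, row in curve.iterrows():
        if row["power"] > target:
            required = int(row["groups"])
            break
    plateau = None
    for i in range(len(curve) - 1):
        if (
            curve.loc[i, "power"] > target
            and curve.loc[i + 1, "power"] - curve.loc[i, "power"] < plateau_gain
        ):
            plateau = int(curve.loc[i, "groups"])
            break
    return RequiredGroupsResult(
        curve=curve,
        required=required,
        plateau_required=plateau,
        attained=required is not None,
        target=target,
    )


def two_sample_t_power(
    effect: float,
    sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    df: int | None = None,
) -> float:
    """Closed-form two-sided two-sample t-test power (equal n, equal sd).

    Independent analytic oracle for the degenerate no-random-effect
    design.  ``df`` defaults to the classic 2n - 2; pass the residual
    degrees of freedom of a larger model (e.g. N - 4 in the 2x2 factorial,
    whose single-coefficient F test is a two-cell contrast with pooled
    variance) when comparing against that model's test.
    """
    if df is None:
        df = 2 * n_per_group - 2
    ncp = effect / (sd * np.sqrt(2.0 / n_per_group))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
    )
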