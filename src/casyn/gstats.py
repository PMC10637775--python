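"""Group statistics: ROUT outlier screening and mixed-model comparisons.

Per-movie metrics are nested within animals (several movies per animal), so
group comparisons use a linear mixed model with a random intercept per animal,
fitted by REML, with Dunnett-style adjustment of each treated-vs-control
contrast.  Before modelling, per-movie counts are screened for outliers with a
one-sample adaptation of the ROUT method (robust center + robust SD + FDR
step-down on t-ratios), the procedure behind the Q=1% outlier removal of
common graphing software.

Normative ROUT definition used here (and by the tests): center = median;
robust SD = 68.27th percentile of |residuals| corrected by n/(n-1); per-point
two-sided p from the t distribution with n-1 df; sort p ascending and flag the
leading block with p_(i) <= Q*i/n, stopping at the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = ["OutlierResult", "GroupComparison", "rout_outliers", "fit_group_lmm"]


@dataclass(frozen=True)
class OutlierResult:
    mask: np.ndarray  # True = flagged outlier
    q: float
    center: float
    robust_sd: float

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroupComparison:
    """Mixed-model group estimates and Dunnett-adjusted contrasts vs control.

    ``contrasts`` has one row per non-control group with columns estimate, se,
    df, t, p_unadj, p_dunnett, ci_lo, ci_hi (unadjusted 95% CI).
    """

    group_means: dict[str, float]
    group_ses: dict[str, float]
    contrasts: pd.DataFrame
    var_animal: float
    var_residual: float
    control: str
    singular: bool = False


def rout_outliers(values: np.ndarray, q: float = 0.01) -> OutlierResult:
    """Flag outliers in a one-sample batch by the ROUT rule at FDR level Q.

    Robust center is the median; the robust SD (RSDR) is the 68.27th
    percentile of absolute residuals with the small-sample correction
    n/(n-1).  Points are tested by two-sided t-ratios and the most extreme
    ones flagged by a step-down FDR rule: with p-values sorted ascending,
    flag while p_(i) <= Q*i/n.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not 0.0 < q < 0.5:
        raise ValueError("Q must be in (0, 0.5)")
    center = float(np.median(x))
    resid = np.abs(x - center)
    rsdr = float(np.percentile(resid, 68.27)) * n / (n - 1)
    mask = np.zeros(n, dtype=bool)
    if rsdr == 0.0:
        # more than ~68% of points identical: anything deviating is infinitely
        # extreme, flag it
        mask = resid > 0
        return OutlierResult(mask=mask, q=q, center=center, robust_sd=0.0)
    t = resid / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(p, kind="stable")
    for i, idx in enumerate(order, start=1):
        if p[idx] <= q * i / n:
            mask[idx] = True
        else:
            break
    return OutlierResult(mask=mask, q=q, center=center, robust_sd=rsdr)


def fit_group_lmm(
    data: pd.DataFrame,
    control: str,
    value_col: str = "value",
    group_col: str = "group",
    animal_col: str = "animal",
    n_mc: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """Random-intercept mixed model with Dunnett-adjusted contrasts vs control.

    Model: value ~ group (fixed) + animal (random intercept) + residual,
    REML.  Each non-control group is contrasted against the control; the
    familywise adjustment is computed by seeded Monte-Carlo on the joint
    max-|t| distribution implied by the fitted contrast covariance, with the
    residual-based df for the t reference.  Adjusted p-values are never below
    the unadjusted ones.
    """
    df = data[[value_col, group_col, animal_col]].dropna().copy()
    groups = df[group_col].unique().tolist()
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    df = df.rename(columns={value_col: "_y", group_col: "_g", animal_col: "_a"})

    model = smf.mixedlm(f"_y ~ C(_g, Treatment('{control}'))", df, groups=df["_a"])
    fit = model.fit(reml=True)
    var_animal = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    singular = (not fit.converged) or var_animal < 1e-10 * max(var_resid, 1e-12)

    fe = fit.fe_params
    cov = fit.cov_params().loc[fe.index, fe.index]
    others = [g for g in groups if g != control]
    names = {g: f"C(_g, Treatment('{control}'))[T.{g}]" for g in others}

    n_obs = len(df)
    n_animals = df["_a"].nunique()
    dof = max(1, n_obs - len(groups) - n_animals + 1)

    est = np.array([fe[names[g]] for g in others])
    se = np.array([np.sqrt(cov.loc[names[g], names[g]]) for g in others])
    tvals = est / se
    p_unadj = 2.0 * stats.t.sf(np.abs(tvals), df=dof)

    # Dunnett adjustment: Monte-Carlo max-|t| under the fitted contrast
    # correlation, t-scaled with the same df
    sub = cov.loc[[names[g] for g in others], [names[g] for g in others]].to_numpy()
    d = np.sqrt(np.diag(sub))
    corr = sub / np.outer(d, d)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(others)))
    z = rng.standard_normal((n_mc, len(others))) @ chol.T
    scale = np.sqrt(rng.chisquare(dof, size=n_mc) / dof)
    max_abs_t = np.max(np.abs(z), axis=1) / scale
    p_adj = np.array([np.mean(max_abs_t >= abs(t)) for t in tvals])
    p_adj = np.maximum(p_adj, p_unadj)

    tcrit = stats.t.ppf(0.975, df=dof)
    contrasts = pd.DataFrame(
        {
            "group": others,
            "estimate": est,
            "se": se,
            "df": dof,
            "t": tvals,
            "p_unadj": p_unadj,
            "p_dunnett": p_adj,
            "ci_lo": est - tcrit * se,
            "ci_hi": est + tcrit * se,
        }
    )

    intercept = float(fe["Intercept"])
    means = {control: intercept}
    ses_out = {control: float(np.sqrt(cov.loc["Intercept", "Intercept"]))}
    for g in others:
        means[g] = intercept + float(fe[names[g]])
        var = (
            cov.loc["Intercept", "Intercept"]
            + cov.loc[names[g], names[g]]
            + 2.0 * cov.loc["Intercept", names[g]]
        )
        ses_out[g] = float(np.sqrt(max(var, 0.0)))

    return GroupComparison(
        group_means=means,
        group_ses=ses_out,
        contrasts=contrasts,
        var_animal=var_animal,
        var_residual=var_resid,
        control=control,
        singular=singular,
    )
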