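"""Derived performance traits and enterotype-phenotype association models."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def derive_performance_traits(ph: pd.DataFrame, period_days: int = 100) -> pd.DataFrame:
    """Compute growth/efficiency traits from raw phenotype fields.

    Expects columns BW80, BW180 (kg); optional FI (total feed intake, kg),
    body_length (m), carcass_weight, live_weight, and fat component weights.
    FCR is left missing (and flagged) where ADG <= 0.
    """
    out = pd.DataFrame(index=ph.index)
    out["ADG"] = (ph["BW180"] - ph["BW80"]) / period_days
    out["MBW"] = (0.5 * (ph["BW80"] + ph["BW180"])) ** 0.75
    if "FI" in ph:
        out["ADFI"] = ph["FI"] / period_days
        bad = out["ADG"] <= 0
        if bad.any():
            logger.warning("FCR undefined for %d animal(s) with ADG <= 0", int(bad.sum()))
        out["FCR"] = np.where(bad, np.nan, out["ADFI"] / out["ADG"])
    if "body_length" in ph:
        out["BMI"] = ph["BW180"] / ph["body_length"] ** 2
    if {"carcass_weight", "live_weight"} <= set(ph.columns):
        out["dressing_pct"] = ph["carcass_weight"] / ph["live_weight"]
    for fat in ("tail_fat", "perirenal_fat", "omental_fat"):
        if fat in ph:
            if "carcass_weight" in ph:
                out[f"{fat}_rel_carcass"] = ph[fat] / ph["carcass_weight"]
            if "live_weight" in ph:
                out[f"{fat}_rel_live"] = ph[fat] / ph["live_weight"]
    fats = [f for f in ("tail_fat", "perirenal_fat", "omental_fat") if f in ph]
    if fats and "live_weight" in ph:
        out["total_fat_rel_live"] = ph[fats].sum(axis=1) / ph["live_weight"]
    if "ADFI" in out:
        fit_ok = out[["ADFI", "MBW", "ADG"]].notna().all(axis=1)
        if fit_ok.sum() >= 3:
            out["RFI"] = compute_rfi(out[fit_ok]).reindex(out.index)
    return out


def compute_rfi(derived: pd.DataFrame) -> pd.Series:
    """Residual feed intake: OLS residual of ADFI on MBW and ADG."""
    sub = derived[["ADFI", "MBW", "ADG"]].dropna()
    if len(sub) < 3:
        raise ValueError("need ADFI, MBW, ADG for at least 3 animals")
    x = sm.add_constant(sub[["MBW", "ADG"]])
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("MBW and ADG are collinear; RFI regression is rank deficient")
    res = sm.OLS(sub["ADFI"], x).fit()
    return pd.Series(res.resid, index=sub.index, name="RFI")


def enterotype_trait_assoc(
    traits: pd.DataFrame,
    enterotype: pd.Series,
    birthplace: pd.Series | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-trait OLS y = b0 + b1*Enterotype + b2*Birthplace, BH over traits.

    Enterotype enters as a binary indicator of the second level; the returned
    table reports the enterotype coefficient per trait with BH q-values.
    Constant traits are skipped with a log entry.
    """
    levels = pd.Categorical(enterotype)
    if len(levels.categories) < 2:
        raise ValueError("need at least two enterotype levels")
    design = pd.DataFrame(
        {"enterotype": (levels.codes > 0).astype(float)}, index=traits.index
    )
    if birthplace is not None:
        design = pd.concat(
            [design, pd.get_dummies(pd.Categorical(birthplace), drop_first=True,
                                    prefix="birthplace", dtype=float)
             .set_axis(traits.index)], axis=1)
    if extra_covariates is not None:
        design = pd.concat([design, extra_covariates.astype(float)], axis=1)
    rows = []
    for trait in traits.columns:
        y = traits[trait]
        ok = y.notna() & design.notna().all(axis=1)
        if y[ok].nunique() < 2:
            logger.warning("enterotype_trait_assoc: trait %r constant; skipped", trait)
            continue
        x = sm.add_constant(design[ok])
        fit = sm.OLS(y[ok], x).fit()
        rows.append({
            "trait": trait, "term": "enterotype",
            "estimate": fit.params["enterotype"], "se": fit.bse["enterotype"],
            "statistic": fit.tvalues["enterotype"], "p": fit.pvalues["enterotype"],
            "n": int(ok.sum()),
        })
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(res["p"])
    return res


@dataclasses.dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame  # level_a, level_b, chi2, p, q


def covariate_chi_square(
    table_or_enterotype,
    covariate: pd.Series | None = None,
    correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square of enterotype x covariate (default: no Yates).

    Accepts either a prebuilt contingency table (2D array / DataFrame) or two
    factors. Pairwise two-level comparisons are BH-adjusted.
    """
    if covariate is None:
        ct = pd.DataFrame(np.asarray(table_or_enterotype, dtype=float))
    else:
        ct = pd.crosstab(pd.Series(table_or_enterotype), pd.Series(covariate))
    ct = ct.loc[ct.sum(axis=1) > 0, ct.sum(axis=0) > 0]
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise ValueError("contingency table needs at least 2x2 nonempty margins")
    chi2, p, df, _ = scipy.stats.chi2_contingency(ct.to_numpy(), correction=correction)
    # pairwise comparisons over levels of the larger margin
    axis = 0 if ct.shape[0] >= ct.shape[1] else 1
    labels = list(ct.index if axis == 0 else ct.columns)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            sub = ct.iloc[[i, j], :] if axis == 0 else ct.iloc[:, [i, j]]
            c2, pp, _, _ = scipy.stats.chi2_contingency(sub.to_numpy(),
                                                        correction=correction)
            rows.append({"level_a": labels[i], "level_b": labels[j],
                         "chi2": c2, "p": pp})
    pw = pd.DataFrame(rows)
    if len(pw):
        pw["q"] = bh_adjust(pw["p"])
    return ChiSquareResult(float(chi2), int(df), float(p), pw)


def covariate_logistic(
    enterotype: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """One logistic model per covariate (paper-style Models 1..k).

    The binary outcome is the indicator of the second enterotype level.
    Perfect separation / non-convergence is flagged per model.
    """
    levels = pd.Categorical(enterotype)
    if len(levels.categories) != 2:
        raise ValueError("covariate_logistic requires a binary enterotype")
    y = pd.Series((levels.codes > 0).astype(float), index=covariates.index)
    rows = []
    for model_i, cov in enumerate(covariates.columns, start=1):
        x = pd.get_dummies(pd.Categorical(covariates[cov]), drop_first=True,
                           prefix=cov, dtype=float).set_axis(covariates.index)
        x = sm.add_constant(x)
        converged = True
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, bses, pvals = fit.params, fit.bse, fit.pvalues
        except Exception:  # separation / singular Hessian
            converged = False
            params = pd.Series(np.nan, index=x.columns)
            bses = pd.Series(np.nan, index=x.columns)
            pvals = pd.Series(np.nan, index=x.columns)
        if converged and np.any(np.asarray(bses) > 1e3):
            converged = False  # quasi-separation: SEs blown up
        for term in x.columns:
            rows.append({
                "model": f"Model {model_i}", "covariate": cov, "term": term,
                "estimate": params[term], "se": bses[term], "p": pvals[term],
                "converged": converged,
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CovariateReport:
    spearman: pd.DataFrame
    condition_index: pd.Series
    flags: pd.Series  # "ok" | "potential" (CI>10) | "severe" (CI>30)


def covariate_collinearity(covariates: pd.DataFrame) -> CovariateReport:
    """Spearman correlations between integer-coded covariates + condition index.

    Condition index per single-covariate dummy design = ratio of the largest
    to smallest singular value of the column-scaled design matrix (intercept
    included). Thresholds: >10 potential, >30 severe collinearity.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates")
    coded = covariates.apply(lambda c: pd.Series(pd.Categorical(c).codes, index=c.index))
    const = coded.nunique() <= 1
    if const.any():
        logger.warning("constant covariate(s): %s", list(coded.columns[const]))
    rho = coded.corr(method="spearman")
    rho.loc[const, :] = np.nan
    rho.loc[:, const] = np.nan
    np.fill_diagonal(rho.values, 1.0)
    ci = {}
    for cov in covariates.columns:
        x = pd.get_dummies(pd.Categorical(covariates[cov]), drop_first=True, dtype=float)
        x = sm.add_constant(x).to_numpy()
        x = x / np.linalg.norm(x, axis=0)
        s = np.linalg.svd(x, compute_uv=False)
        ci[cov] = float(s[0] / s[-1]) if s[-1] > 1e-300 else np.inf
    ci = pd.Series(ci)
    flags = pd.Series(np.where(ci > 30, "severe", np.where(ci > 10, "potential", "ok")),
                      index=ci.index)
    return CovariateReport(rho, ci, flags)
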