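"""Two-part genus screening: Beta regression and zero-inflated Beta regression.

Genera prevalent in >= 60% of samples are modelled with a Beta regression on
smoothed relative abundances (logit mean link, precision phi); rarer genera
use a zero-inflated Beta mixture whose zero probability has its own logit
model. The mixture likelihood factorizes over the zero indicator and the
positive part, so the two components are maximized separately and reported
jointly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special as sp
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from rumenet.phenotype import bh_adjust
from rumenet.tables import AbundanceTable

logger = logging.getLogger(__name__)


def smooth_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress [0,1] data strictly inside (0,1): y' = (y*(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("n must be >= 2")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


def build_design(
    enterotype: np.ndarray | pd.Series,
    birthplace: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Intercept + binary enterotype indicator + birthplace dummies."""
    ent = pd.Categorical(np.asarray(enterotype))
    if len(ent.categories) != 2:
        raise ValueError("enterotype must have exactly two levels")
    x = pd.DataFrame({"const": 1.0, "enterotype": (ent.codes > 0).astype(float)})
    if birthplace is not None:
        dums = pd.get_dummies(pd.Categorical(np.asarray(birthplace)),
                              drop_first=True, prefix="birthplace", dtype=float)
        x = pd.concat([x, dums.set_axis(x.index)], axis=1)
    return x


@dataclasses.dataclass
class BetaRegFit:
    params: pd.Series           # mean-model coefficients (logit link)
    se: pd.Series
    p: pd.Series                # Wald p per coefficient
    phi: float
    phi_se: float
    loglik: float
    converged: bool
    n: int


@dataclasses.dataclass
class ZibrFit:
    zero_params: pd.Series      # gamma coefficients (logit of P(y=0))
    zero_se: pd.Series
    zero_p: pd.Series
    mean_params: pd.Series      # beta coefficients (logit mean of positives)
    mean_se: pd.Series
    mean_p: pd.Series
    phi: float
    loglik: float
    converged: bool
    n: int
    n_zero: int


def _beta_negll_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    p = x.shape[1]
    beta, logphi = theta[:p], theta[p]
    phi = np.exp(logphi)
    eta = x @ beta
    mu = sp.expit(eta)
    a, b = mu * phi, (1 - mu) * phi
    ll = np.sum(sp.gammaln(phi) - sp.gammaln(a) - sp.gammaln(b)
                + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))
    dmu = phi * (-sp.digamma(a) + sp.digamma(b) + np.log(y) - np.log1p(-y))
    gbeta = x.T @ (dmu * mu * (1 - mu))
    dphi = np.sum(sp.digamma(phi) - mu * sp.digamma(a) - (1 - mu) * sp.digamma(b)
                  + mu * np.log(y) + (1 - mu) * np.log1p(-y))
    return -ll, -np.concatenate([gbeta, [dphi * phi]])


def fit_beta_regression(
    y: np.ndarray,
    enterotype=None,
    birthplace=None,
    design: pd.DataFrame | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> BetaRegFit:
    """ML Beta regression with logit mean link and scalar precision phi.

    Either pass ``enterotype``/``birthplace`` factors or a full ``design``
    (must include an intercept column). Wald SEs come from the numerically
    observed information; failed optimizations get random restarts before
    the fit is flagged unconverged.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly in (0,1); smooth first")
    x = build_design(enterotype, birthplace) if design is None else design
    xm = np.asarray(x, dtype=float)
    if np.linalg.matrix_rank(xm) < xm.shape[1]:
        raise ValueError("design matrix is rank deficient")
    p = xm.shape[1]
    # moment-based start: OLS on logit(y), phi from residual variance
    eta0 = sp.logit(np.clip(y, 1e-6, 1 - 1e-6))
    beta0, *_ = np.linalg.lstsq(xm, eta0, rcond=None)
    mu0 = sp.expit(xm @ beta0)
    v = max(np.var(y - mu0), 1e-8)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / v - 1, 1.0)
    starts = [np.concatenate([beta0, [np.log(phi0)]])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.normal(0, 0.5, size=p + 1))
    best = None
    for s in starts:
        res = scipy.optimize.minimize(_beta_negll_grad, s, args=(xm, y),
                                      jac=True, method="L-BFGS-B",
                                      options={"maxiter": 500, "gtol": 1e-8})
        if best is None or (res.success and res.fun < best.fun - 1e-9) \
                or (not best.success and res.success):
            best = res
        if best.success and s is starts[0]:
            break  # primary start converged; restarts unnecessary
    theta = best.x
    hess = approx_hess1(theta, lambda t: _beta_negll_grad(t, xm, y)[0])
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(p + 1, np.nan)
    names = list(x.columns)
    params = pd.Series(theta[:p], index=names)
    se = pd.Series(se_all[:p], index=names)
    z = params / se
    pvals = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=names)
    phi = float(np.exp(theta[p]))
    return BetaRegFit(params, se, pvals, phi, float(se_all[p] * phi),
                      -float(best.fun), bool(best.success), len(y))


def fit_zibr(
    y: np.ndarray,
    enterotype=None,
    birthplace=None,
    design: pd.DataFrame | None = None,
    seed: int = 0,
) -> ZibrFit | BetaRegFit:
    """ML zero-inflated Beta regression.

    Zeros contribute log(nu_i); positives contribute log(1-nu_i) plus the
    Beta log-density, so the logistic zero model and the Beta mean model are
    fit on their own likelihood factors and the joint log-likelihood is their
    sum. With no zeros the call falls back to plain Beta regression (logged);
    all-zero input is an error. Exact ones are smoothed.
    """
    y = np.asarray(y, dtype=float)
    x = build_design(enterotype, birthplace) if design is None else design
    zero = y == 0
    if zero.all():
        raise ValueError("all observations are zero; ZIBR undefined")
    if not zero.any():
        logger.info("fit_zibr: no zeros; falling back to Beta regression")
        ysm = np.where(y >= 1, smooth_unit_interval(y), y)
        return fit_beta_regression(ysm, design=x, seed=seed)
    names = list(x.columns)
    xm = np.asarray(x, dtype=float)
    # zero component: logistic regression on the zero indicator
    converged = True
    try:
        zfit = sm.Logit(zero.astype(float), xm).fit(disp=0, maxiter=200)
        zconv = bool(zfit.mle_retvals.get("converged", True))
        gpar = pd.Series(zfit.params, index=names)
        gse = pd.Series(zfit.bse, index=names)
        gp = pd.Series(zfit.pvalues, index=names)
        ll_zero = float(zfit.llf)
        converged &= zconv and not np.any(np.asarray(gse) > 1e3)
    except Exception:
        converged = False
        gpar = gse = gp = pd.Series(np.nan, index=names)
        ll_zero = np.nan
    # mean component on the positive part
    ypos = y[~zero]
    ypos = np.where(ypos >= 1, smooth_unit_interval(ypos, n=len(ypos)), ypos)
    bfit = fit_beta_regression(ypos, design=x.loc[~zero].reset_index(drop=True),
                               seed=seed)
    converged &= bfit.converged
    return ZibrFit(
        zero_params=gpar, zero_se=gse, zero_p=gp,
        mean_params=bfit.params, mean_se=bfit.se, mean_p=bfit.p,
        phi=bfit.phi, loglik=ll_zero + bfit.loglik,
        converged=converged, n=len(y), n_zero=int(zero.sum()),
    )


def zibr_loglik(
    y: np.ndarray, design: pd.DataFrame,
    zero_params: np.ndarray, mean_params: np.ndarray, phi: float,
) -> float:
    """Mixture log-likelihood of a ZIBR parameter set (for diagnostics)."""
    y = np.asarray(y, dtype=float)
    xm = np.asarray(design, dtype=float)
    nu = sp.expit(xm @ np.asarray(zero_params))
    mu = sp.expit(xm @ np.asarray(mean_params))
    zero = y == 0
    ll = np.sum(np.log(nu[zero]))
    yp, mup = y[~zero], mu[~zero]
    a, b = mup * phi, (1 - mup) * phi
    ll += np.sum(np.log1p(-nu[~zero]) + sp.gammaln(phi) - sp.gammaln(a)
                 - sp.gammaln(b) + (a - 1) * np.log(yp) + (b - 1) * np.log1p(-yp))
    return float(ll)


def screen_genera(
    tab: AbundanceTable,
    enterotype,
    birthplace=None,
    prevalence_cut: float = 0.60,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-genus enterotype association via the two-part routing rule.

    Prevalence >= ``prevalence_cut`` -> Beta branch on smoothed relative
    abundance; below the cut -> ZIBR. Returns one row per genus (ZIBR genera
    additionally carry the zero-model enterotype test) with BH q-values over
    all converged enterotype tests; ``significant`` marks q <= fdr.
    """
    rel = tab.rel_abundance
    prev = (tab.counts > 0).mean(axis=0)
    design = build_design(enterotype, birthplace)
    rows = []
    for j, genus in enumerate(tab.genus_ids):
        y = rel[:, j]
        if prev[j] == 0:
            logger.warning("screen_genera: %s absent everywhere; skipped", genus)
            continue
        if prev[j] >= prevalence_cut:
            ysm = smooth_unit_interval(y)
            fit = fit_beta_regression(ysm, design=design, seed=seed)
            rows.append({
                "genus": genus, "prevalence": prev[j], "branch": "beta",
                "term": "enterotype_mean", "estimate": fit.params["enterotype"],
                "se": fit.se["enterotype"], "p": fit.p["enterotype"],
                "converged": fit.converged,
            })
        else:
            fit = fit_zibr(y, design=design, seed=seed)
            if isinstance(fit, BetaRegFit):  # no-zeros fallback
                rows.append({
                    "genus": genus, "prevalence": prev[j], "branch": "zibr",
                    "term": "enterotype_mean", "estimate": fit.params["enterotype"],
                    "se": fit.se["enterotype"], "p": fit.p["enterotype"],
                    "converged": fit.converged,
                })
                continue
            rows.append({
                "genus": genus, "prevalence": prev[j], "branch": "zibr",
                "term": "enterotype_mean", "estimate": fit.mean_params["enterotype"],
                "se": fit.mean_se["enterotype"], "p": fit.mean_p["enterotype"],
                "converged": fit.converged,
            })
            rows.append({
                "genus": genus, "prevalence": prev[j], "branch": "zibr",
                "term": "enterotype_zero", "estimate": fit.zero_params["enterotype"],
                "se": fit.zero_se["enterotype"], "p": fit.zero_p["enterotype"],
                "converged": fit.converged,
            })
    res = pd.DataFrame(rows)
    if not len(res):
        return res
    res["q"] = np.nan
    fam = res["converged"] & res["p"].notna()
    res.loc[fam, "q"] = bh_adjust(res.loc[fam, "p"])
    res["significant"] = res["q"] <= fdr
    # per-genus combined call: minimum BH-q across that genus's tested terms
    genus_q = res[fam].groupby("genus")["q"].min()
    res["genus_significant"] = res["genus"].map(genus_q <= fdr).fillna(False)
    res["significant_p05"] = res["p"] < 0.05
    return res
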