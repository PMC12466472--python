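"""Host-genetics layer: SNP QC, LD pruning, GRM, heritability, rG, GWAS.

Heritability of the binary enterotype is estimated on the observed 0/1 scale
by single-component REML (eigenrotation of the GRM, profiled restricted
likelihood over the heritability ratio) and mapped to the liability scale by
the threshold-model transformation. Genetic correlations use Haseman-Elston
moment regression with a block jackknife. The binary GWAS is a per-SNP
logistic score test with covariates, which stays well defined under
separation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from rumenet.phenotype import bh_adjust
from rumenet.tables import AbundanceTable, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- QC / LD

def qc_filter_variants(
    g: GenotypeMatrix,
    min_maf: float = 0.05,
    max_missingness: float = 0.3,
    biallelic_only: bool = True,
    depth: np.ndarray | None = None,
    min_depth: float = 3.0,
) -> GenotypeMatrix:
    """Retain SNPs with MAF >= min_maf, missingness < max_missingness,
    biallelic sites only, and (when per-SNP depth is supplied) depth > min_depth."""
    keep = np.ones(g.n_snps, dtype=bool)
    if biallelic_only and g.n_alleles is not None:
        keep &= g.n_alleles == 2
    keep &= g.missingness() < max_missingness
    with np.errstate(invalid="ignore"):
        maf = g.maf()
    keep &= np.nan_to_num(maf, nan=0.0) >= min_maf
    if depth is not None:
        keep &= np.asarray(depth) > min_depth
    logger.info("qc_filter_variants: %d / %d SNPs retained", int(keep.sum()), g.n_snps)
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    return g.subset_snps(keep)


def ld_prune(
    g: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.1
) -> list[str]:
    """PLINK-style indep-pairwise pruning; returns retained SNP ids.

    A window of ``window`` SNPs slides by ``step``; within each window, while
    any kept pair has r^2 > ``r2_max``, the member with the higher mean r^2
    against the window is removed (ties -> later position).
    """
    x = g.mean_imputed()
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic SNPs present; run QC first")
    z = (x - x.mean(axis=0)) / sd
    m = g.n_snps
    keep = np.ones(m, dtype=bool)
    n = g.n_samples
    for start in range(0, max(m - 1, 1), step):
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size < 2:
            continue
        r2 = (z[:, idx].T @ z[:, idx] / n) ** 2
        np.fill_diagonal(r2, 0.0)
        while True:
            i, j = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[i, j] <= r2_max:
                break
            mean_r2 = r2.mean(axis=1)
            drop_local = i if mean_r2[i] > mean_r2[j] else j if mean_r2[j] > mean_r2[i] \
                else max(i, j)  # tie -> later position
            keep[idx[drop_local]] = False
            r2[drop_local, :] = 0.0
            r2[:, drop_local] = 0.0
    kept = [g.snp_ids[i] for i in np.flatnonzero(keep)]
    logger.info("ld_prune: %d / %d SNPs retained", len(kept), m)
    return kept


# ---------------------------------------------------------------- GRM

@dataclasses.dataclass
class GRM:
    sample_ids: list[str]
    values: np.ndarray
    n_snps: int

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")


def compute_grm(g: GenotypeMatrix) -> GRM:
    """Genomic relationship matrix from standardized dosages.

    g_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).
    Missing dosages are mean-imputed per SNP (logged).
    """
    n_missing = int(np.isnan(g.dosages).sum())
    if n_missing:
        logger.info("compute_grm: mean-imputing %d missing dosages", n_missing)
    x = g.mean_imputed()
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP reached compute_grm; QC should remove it")
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    grm = z @ z.T / g.n_snps
    return GRM(list(g.sample_ids), (grm + grm.T) / 2, g.n_snps)


def grm_pcs(grm: GRM, n_pcs: int = 5) -> np.ndarray:
    """Leading eigenvectors of the GRM (genotype principal components)."""
    evals, evecs = np.linalg.eigh(grm.values)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[:n_pcs]]


# ---------------------------------------------------------------- REML h2

@dataclasses.dataclass
class H2Estimate:
    h2_observed: float
    se_observed: float
    h2_liability: float
    se_liability: float
    prevalence: float
    lrt: float
    lrt_p: float
    loglik: float


def _reml_loglik(h2: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """Restricted log-likelihood (constants dropped) at heritability ratio h2."""
    w = h2 * lam + (1.0 - h2)
    n, p = xstar.shape
    xw = xstar / w[:, None]
    xtx = xstar.T @ xw
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    beta = np.linalg.solve(xtx, xw.T @ ystar)
    r = ystar - xstar @ beta
    rss = float(r @ (r / w))
    sigma2 = rss / (n - p)
    return -0.5 * (np.sum(np.log(w)) + logdet_xtx + (n - p) * np.log(sigma2) + (n - p))


def reml_h2_observed(
    y: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | pd.DataFrame | None = None,
    prevalence: float | None = None,
) -> H2Estimate:
    """Observed-scale REML heritability of a (binary) trait with one genetic
    variance component, plus the liability-scale transform.

    The GRM is eigendecomposed (negative eigenvalues clipped with a warning);
    the restricted likelihood is profiled over h2 in [0, 0.999] by a grid +
    bounded refinement. SE from the numerical observed information; LRT
    against h2 = 0 uses the 0.5*chi2(1) boundary mixture.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    evals, evecs = np.linalg.eigh(grm.values)
    if evals.min() < -1e-8 * max(abs(evals.max()), 1.0):
        logger.warning("GRM not PSD (min eigenvalue %.3g); clipping", evals.min())
    lam = np.clip(evals, 0.0, None)
    if covariates is None:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    ystar = evecs.T @ y
    xstar = evecs.T @ x

    grid = np.linspace(0.0, 0.999, 60)
    lls = np.array([_reml_loglik(h, lam, ystar, xstar) for h in grid])
    h_best = grid[int(np.argmax(lls))]
    lo, hi = max(0.0, h_best - 0.03), min(0.999, h_best + 0.03)
    res = scipy.optimize.minimize_scalar(
        lambda h: -_reml_loglik(h, lam, ystar, xstar), bounds=(lo, hi),
        method="bounded", options={"xatol": 1e-6})
    h2 = float(res.x)
    ll_opt = -float(res.fun)
    ll0 = _reml_loglik(0.0, lam, ystar, xstar)
    if ll0 > ll_opt:  # boundary optimum
        h2, ll_opt = 0.0, ll0
    eps = 1e-3
    hm = np.clip(h2, eps, 0.999 - eps)
    d2 = (_reml_loglik(hm + eps, lam, ystar, xstar)
          - 2 * _reml_loglik(hm, lam, ystar, xstar)
          + _reml_loglik(hm - eps, lam, ystar, xstar)) / eps**2
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan
    lrt = max(0.0, 2 * (ll_opt - ll0))
    lrt_p = 0.5 * scipy.stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0

    is_binary = set(np.unique(y)) <= {0.0, 1.0}
    if is_binary:
        k = prevalence if prevalence is not None else float(np.mean(y))
        mult = _liability_multiplier(k, float(np.mean(y)))
        h2_liab, se_liab = h2 * mult, se * mult
    else:  # liability transform only applies to 0/1 traits
        k, h2_liab, se_liab = np.nan, np.nan, np.nan
    return H2Estimate(h2, se, h2_liab, se_liab, k, lrt, float(lrt_p), ll_opt)


def _liability_multiplier(k: float, p: float) -> float:
    if not (0 < k < 1 and 0 < p < 1):
        raise ValueError("prevalence and case fraction must lie strictly in (0,1)")
    t = scipy.stats.norm.ppf(1 - k)
    z = scipy.stats.norm.pdf(t)
    return (k * (1 - k) / z**2) * (k * (1 - k) / (p * (1 - p)))


def observed_to_liability(h2_obs: float, K: float, P: float | None = None) -> float:
    """Threshold-model transform of observed-scale heritability to the
    liability scale: h2_l = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))]."""
    if P is None:
        P = K
    return h2_obs * _liability_multiplier(K, P)


# ---------------------------------------------------------------- rG (HE)

@dataclasses.dataclass
class RgEstimate:
    rg: float
    se: float
    var_gx: float
    var_gy: float
    cov_gxy: float
    clamped: bool


def genetic_correlation(
    y_x: np.ndarray, y_y: np.ndarray, grm: GRM, n_blocks: int = 20
) -> RgEstimate:
    """Haseman-Elston genetic correlation with block-jackknife SE.

    Cross-products of standardized traits over sample pairs are regressed on
    GRM off-diagonals for the two genetic variances and the genetic
    covariance; rG = cov / sqrt(vx * vy), clamped to [-1, 1] with a flag.
    """
    yx = np.asarray(y_x, dtype=float)
    yy = np.asarray(y_y, dtype=float)
    n = yx.size
    yx = (yx - yx.mean()) / yx.std()
    yy = (yy - yy.mean()) / yy.std()

    def he(keep: np.ndarray):
        a = grm.values[np.ix_(keep, keep)]
        iu, ju = np.triu_indices(keep.sum(), 1)
        g_od = a[iu, ju]
        denom = float(g_od @ g_od)
        sx, sy = yx[keep], yy[keep]
        vx = float(g_od @ (sx[iu] * sx[ju])) / denom
        vy = float(g_od @ (sy[iu] * sy[ju])) / denom
        cov = float(g_od @ (0.5 * (sx[iu] * sy[ju] + sy[iu] * sx[ju]))) / denom
        return vx, vy, cov

    all_idx = np.ones(n, dtype=bool)
    vx, vy, cov = he(all_idx)
    if vx <= 0 or vy <= 0:
        return RgEstimate(np.nan, np.nan, vx, vy, cov, False)
    rg = cov / np.sqrt(vx * vy)
    blocks = np.array_split(np.arange(n), n_blocks)
    reps = []
    for b in blocks:
        keep = all_idx.copy()
        keep[b] = False
        bvx, bvy, bcov = he(keep)
        if bvx > 0 and bvy > 0:
            reps.append(bcov / np.sqrt(bvx * bvy))
    reps = np.array(reps)
    nb = len(reps)
    se = float(np.sqrt((nb - 1) / nb * np.sum((reps - reps.mean()) ** 2))) if nb > 1 else np.nan
    clamped = abs(rg) > 1
    return RgEstimate(float(np.clip(rg, -1, 1)), se, vx, vy, cov, bool(clamped))


# ---------------------------------------------------------------- GWAS

@dataclasses.dataclass
class GwasResult:
    table: pd.DataFrame        # snp, chrom, pos, beta, se, statistic, p
    lambda_gc: float
    threshold_genome_wide: float
    threshold_suggestive: float


def significance_thresholds(n_independent_snps: int) -> dict:
    """Bonferroni genome-wide (0.05/N) and suggestive (1/N) thresholds,
    reported at full precision and rounded to two significant figures."""
    if n_independent_snps <= 0:
        raise ValueError("n_independent_snps must be positive")
    gw = 0.05 / n_independent_snps
    sug = 1.0 / n_independent_snps

    def round2sig(v: float) -> float:
        return float(f"{v:.1e}")

    return {
        "genome_wide": gw, "suggestive": sug,
        "genome_wide_2sig": round2sig(gw), "suggestive_2sig": round2sig(sug),
    }


def gwas_binary_trait(
    y: np.ndarray,
    g: GenotypeMatrix,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_independent_snps: int | None = None,
) -> GwasResult:
    """Per-SNP logistic score test for a binary trait with fixed covariates.

    The null logistic model (covariates only) is fit once; each SNP's score
    statistic uses the covariate-residualized dosage, which remains valid
    under separation. Reported beta/SE are the one-step score approximations
    U/V and 1/sqrt(V). lambda = median(chi2) / 0.4549.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    null = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    mu = null.fittedvalues
    w = mu * (1 - mu)
    resid = y - mu

    geno = g.mean_imputed()
    xw = x * w[:, None]
    xtwx_inv = np.linalg.inv(x.T @ xw)
    # W-orthogonal projection of each SNP against the covariate space
    proj = x @ (xtwx_inv @ (xw.T @ geno))
    gt = geno - proj
    u = gt.T @ resid
    v = np.einsum("ij,i->j", gt**2, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = u**2 / v
        beta = u / v
        se = 1.0 / np.sqrt(v)
    mono = v <= 1e-12
    if mono.any():
        logger.warning("gwas_binary_trait: %d monomorphic SNP(s) skipped", int(mono.sum()))
    stat = np.where(mono, np.nan, stat)
    p = scipy.stats.chi2.sf(stat, 1)
    lam = float(np.nanmedian(stat) / scipy.stats.chi2.ppf(0.5, 1))
    thr = significance_thresholds(
        n_independent_snps if n_independent_snps is not None else g.n_snps)
    table = pd.DataFrame({
        "snp": g.snp_ids, "chrom": g.chrom, "pos": g.pos,
        "beta": beta, "se": se, "statistic": stat, "p": p,
    })
    return GwasResult(table, lam, thr["genome_wide"], thr["suggestive"])


# ---------------------------------------------------------------- clr + SNP effects

def clr_transform(
    tab: AbundanceTable, zero_replacement: float | None = None
) -> pd.DataFrame:
    """Centered log-ratio transform of relative abundances.

    Zeros are replaced by ``zero_replacement`` (default: half the smallest
    nonzero relative abundance in the table) before taking logs.
    """
    rel = tab.rel_abundance
    if np.any(rel.sum(axis=1) == 0):
        raise ValueError("all-zero sample(s); clr undefined")
    if zero_replacement is None:
        zero_replacement = 0.5 * rel[rel > 0].min()
    x = np.where(rel > 0, rel, zero_replacement)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=tab.sample_ids, columns=tab.genus_ids)


def snp_microbiota_effects(
    g: GenotypeMatrix,
    snp_ids: list[str],
    tab: AbundanceTable,
    birthplace=None,
    prevalence_cut: float = 0.60,
    genus_prevalence_floor: float = 0.015,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Effects of candidate SNPs on genus abundances.

    Genera below ``genus_prevalence_floor`` prevalence are excluded. Prevalent
    genera (>= ``prevalence_cut``) are tested with a linear model on clr
    abundance ~ dosage + birthplace; rarer genera with a logistic model on
    presence/absence. BH-FDR across all genus x SNP tests.
    """
    prev = tab.prevalence()
    genera = [gn for gn in tab.genus_ids if prev[gn] >= genus_prevalence_floor]
    clr = clr_transform(tab)
    if birthplace is not None:
        bp = pd.get_dummies(pd.Categorical(np.asarray(birthplace)),
                            drop_first=True, dtype=float).to_numpy()
    else:
        bp = np.empty((tab.n_samples, 0))
    rows = []
    for sid in snp_ids:
        dose = g.mean_imputed()[:, g.snp_index(sid)]
        if np.std(dose) == 0:
            logger.warning("snp_microbiota_effects: %s monomorphic; skipped", sid)
            continue
        x = np.column_stack([np.ones(tab.n_samples), dose, bp])
        for gn in genera:
            if prev[gn] >= prevalence_cut:
                fit = sm.OLS(clr[gn].to_numpy(), x).fit()
                rows.append({"snp": sid, "genus": gn, "model": "linear_clr",
                             "estimate": fit.params[1], "se": fit.bse[1],
                             "p": fit.pvalues[1]})
            else:
                yb = (tab.counts[:, tab.genus_ids.index(gn)] > 0).astype(float)
                try:
                    fit = sm.Logit(yb, x).fit(disp=0, maxiter=100)
                    est, se_, pv = fit.params[1], fit.bse[1], fit.pvalues[1]
                    if se_ > 1e3:
                        est = se_ = pv = np.nan
                except Exception:
                    est = se_ = pv = np.nan
                rows.append({"snp": sid, "genus": gn, "model": "logistic_presence",
                             "estimate": est, "se": se_, "p": pv})
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(res["p"])
        res["significant"] = res["q"] <= fdr
    return res
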