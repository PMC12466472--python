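"""Colocalization of association signals: overlap, cross-signal LD, ABF coloc."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp

from rumenet.tables import GenotypeMatrix

logger = logging.getLogger(__name__)


def overlap_hypergeometric(
    set_a: set | list, set_b: set | list, universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric test for the overlap of two SNP sets.

    Returns (observed overlap, P(X >= overlap)); an observed overlap of 0
    yields p = 1 by convention.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    p = float(scipy.stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def cross_signal_ld(
    snps_a: list[str], snps_b: list[str], g: GenotypeMatrix
) -> tuple[pd.DataFrame, float]:
    """Pairwise r^2 between two SNP sets from dosages; returns (matrix, mean)."""
    dose = g.mean_imputed()
    idx_a = [g.snp_index(s) for s in snps_a]
    idx_b = [g.snp_index(s) for s in snps_b]
    vals = np.full((len(idx_a), len(idx_b)), np.nan)
    for i, ia in enumerate(idx_a):
        xa = dose[:, ia]
        if xa.std() == 0:
            logger.warning("cross_signal_ld: %s monomorphic; skipped", snps_a[i])
            continue
        for j, ib in enumerate(idx_b):
            xb = dose[:, ib]
            if xb.std() == 0:
                continue
            vals[i, j] = np.corrcoef(xa, xb)[0, 1] ** 2
    mat = pd.DataFrame(vals, index=snps_a, columns=snps_b)
    return mat, float(np.nanmean(vals))


@dataclasses.dataclass
class ColocResult:
    pp: dict[str, float]  # PP.H0 .. PP.H4
    priors: tuple[float, float, float]
    n_snps: int

    @property
    def shared_variant(self) -> bool:
        return self.pp["PP.H4"] > 0.50


def _log_abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per SNP."""
    v = se**2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w_a: float = 0.15**2,
    w_b: float = 0.15**2,
) -> ColocResult:
    """Bayesian colocalization via Wakefield ABFs (single causal variant).

    ``stats_a``/``stats_b`` need columns snp, beta, se over a shared SNP list.
    Prior effect variances: 0.15^2 suits log-odds scale binary traits, 0.2^2
    quantitative traits. PP.H4 > 0.5 is called a shared variant.
    """
    a = stats_a.set_index("snp")
    b = stats_b.set_index("snp")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("SNP lists are disjoint")
    la = _log_abf(a.loc[common, "beta"].to_numpy(), a.loc[common, "se"].to_numpy(), w_a)
    lb = _log_abf(b.loc[common, "beta"].to_numpy(), b.loc[common, "se"].to_numpy(), w_b)
    lh0 = 0.0
    lh1 = np.log(p1) + logsumexp(la)
    lh2 = np.log(p2) + logsumexp(lb)
    both = la[:, None] + lb[None, :]
    np.fill_diagonal(both, -np.inf)
    lh3 = np.log(p1) + np.log(p2) + logsumexp(both)
    lh4 = np.log(p12) + logsumexp(la + lb)
    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lall - logsumexp(lall))
    pp /= pp.sum()
    keys = ["PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4"]
    return ColocResult(dict(zip(keys, map(float, pp))), (p1, p2, p12), len(common))
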