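"""Synthetic cohort generator for end-to-end testing of every pipeline stage.

Produces (a) a two-or-more enterotype Dirichlet-multinomial genus table with
designated driver genera, (b) HWE genotypes with optional block LD and
designated causal SNPs, (c) a binary enterotype phenotype from a
liability-threshold model at a specified heritability, and (d) performance
phenotypes shifted by enterotype with covariate confounding. Fixed seed ->
byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from rumenet.tables import AbundanceTable, GenotypeMatrix


@dataclasses.dataclass
class SimConfig:
    n_samples: int = 200
    n_genera: int = 50
    n_snps: int = 500
    k_true: int = 2
    driver_ids: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5))
    driver_enrichment: float = 10.0
    dirichlet_concentration: float = 50.0
    library_size_range: tuple[int, int] = (5000, 20000)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_flip_prob: float = 0.05
    h2_liability: float = 0.4
    prevalence: float = 0.5
    n_causal_snps: int = 20
    trait_effects: dict = dataclasses.field(default_factory=dict)
    n_birthplaces: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genera < 2 or self.k_true < 1:
            raise ValueError("invalid sizes in SimConfig")
        if len(self.driver_ids) != self.k_true:
            raise ValueError("driver_ids must list one driver set per cluster")
        flat = [g for grp in self.driver_ids for g in grp]
        if len(flat) != len(set(flat)):
            raise ValueError("driver sets must be disjoint across clusters")
        if flat and max(flat) >= self.n_genera:
            raise ValueError("driver genus index out of range")
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError("h2_liability must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.library_size_range[0] > self.library_size_range[1] \
                or self.library_size_range[0] < 1:
            raise ValueError("invalid library_size_range")


@dataclasses.dataclass
class SimTruth:
    assignments: np.ndarray | None = None        # sample -> cluster (0-based)
    liabilities: np.ndarray | None = None
    causal_effects: dict[str, float] | None = None
    cluster_compositions: np.ndarray | None = None  # k x genera base means


def _genus_names(n: int) -> list[str]:
    return [f"g{i}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    return [f"s{i:04d}" for i in range(n)]


def gen_abundance_table(cfg: SimConfig) -> tuple[AbundanceTable, SimTruth]:
    """Dirichlet-multinomial genus table with cluster-specific compositions.

    A shared base composition (lognormal genus weights) is multiplied by
    ``driver_enrichment`` at each cluster's driver genera and renormalized;
    per-sample compositions are Dirichlet draws around the cluster base with
    the configured concentration, then multinomial counts at a log-uniform
    library size.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genera)
    base /= base.sum()
    comps = np.tile(base, (cfg.k_true, 1))
    for c, drivers in enumerate(cfg.driver_ids):
        comps[c, list(drivers)] *= cfg.driver_enrichment
    comps /= comps.sum(axis=1, keepdims=True)
    assign = rng.integers(cfg.k_true, size=cfg.n_samples)
    lo, hi = cfg.library_size_range
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_samples)).astype(int)
    counts = np.empty((cfg.n_samples, cfg.n_genera), dtype=np.int64)
    for i in range(cfg.n_samples):
        p = rng.dirichlet(cfg.dirichlet_concentration * comps[assign[i]])
        counts[i] = rng.multinomial(libs[i], p)
    tab = AbundanceTable(_sample_names(cfg.n_samples), _genus_names(cfg.n_genera), counts)
    return tab, SimTruth(assignments=assign, cluster_compositions=comps)


def gen_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """HWE dosages at per-SNP MAFs with optional block-copula LD.

    Within an LD block all SNPs copy a shared latent haplotype pair, each
    allele flipped independently with ``ld_flip_prob``; block size 1 gives
    independent SNPs, flip probability 0 gives perfect duplicates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = cfg.n_samples, cfg.n_snps
    block = max(1, cfg.ld_block_size)
    dosages = np.empty((n, m), dtype=float)
    mafs = rng.uniform(*cfg.maf_range, size=m)
    j = 0
    while j < m:
        width = min(block, m - j)
        p = mafs[j]
        latent = rng.random((n, 2)) < p  # two latent haplotypes per sample
        for t in range(width):
            flip = rng.random((n, 2)) < cfg.ld_flip_prob
            hap = latent ^ flip
            dosages[:, j + t] = hap.sum(axis=1)
        j += width
    snp_ids = [f"snp{i}" for i in range(m)]
    chrom = np.array(["1"] * m)
    pos = np.arange(1, m + 1) * 1000
    return GenotypeMatrix(_sample_names(n), snp_ids, chrom, pos, dosages)


def gen_enterotype_liability(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[np.ndarray, SimTruth]:
    """Binary enterotype phenotype from a liability-threshold model.

    The genetic score over ``n_causal_snps`` standardized causal dosages is
    rescaled to variance h2; an independent normal residual of variance 1-h2
    is added, and cases are samples whose liability exceeds the standard
    normal quantile at 1 - prevalence.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    n = g.n_samples
    n_causal = min(cfg.n_causal_snps, g.n_snps)
    causal_idx = rng.choice(g.n_snps, size=n_causal, replace=False)
    effects = rng.normal(size=n_causal)
    x = g.mean_imputed()[:, causal_idx]
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    score = z @ effects
    if cfg.h2_liability > 0 and score.std() > 0:
        score = score / score.std() * np.sqrt(cfg.h2_liability)
    else:
        score = np.zeros(n)
    resid_sd = np.sqrt(max(1.0 - cfg.h2_liability, 0.0))
    liability = score + rng.normal(scale=resid_sd, size=n) if resid_sd > 0 else score
    threshold = scipy.stats.norm.ppf(1 - cfg.prevalence)
    y = (liability > threshold).astype(int)
    truth = SimTruth(
        liabilities=liability,
        causal_effects={g.snp_ids[i]: float(e) for i, e in zip(causal_idx, effects)},
    )
    return y, truth


def gen_performance_phenotypes(
    assignments: np.ndarray, cfg: SimConfig, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Raw phenotype table (BW80, BW180, FI, body_length, ...) with per-trait
    enterotype shifts (in SD units) and a birthplace confounder.

    ``cfg.trait_effects`` maps trait name -> shift applied to cluster-2+
    samples; unlisted traits get shift 0.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3)
    n = len(assignments)
    if covariates is None:
        birthplace = rng.integers(1, cfg.n_birthplaces + 1, size=n)
    else:
        birthplace = covariates["Birthplace"].to_numpy()
    bp_effects = rng.normal(scale=0.5, size=cfg.n_birthplaces + 1)
    base = {
        "BW80": (22.0, 2.0), "BW180": (48.0, 4.0), "FI": (160.0, 12.0),
        "body_length": (0.8, 0.04), "live_weight": (48.0, 4.0),
        "carcass_weight": (24.0, 2.5), "tail_fat": (1.5, 0.3),
        "perirenal_fat": (0.5, 0.1), "omental_fat": (0.6, 0.12),
    }
    is_shifted = (np.asarray(assignments) > 0).astype(float)
    out = {"Birthplace": birthplace}
    for trait, (mu, sd) in base.items():
        shift = cfg.trait_effects.get(trait, 0.0)
        out[trait] = (mu + sd * (shift * is_shifted + bp_effects[birthplace]
                                 + rng.normal(size=n)))
    extra = {t: e for t, e in cfg.trait_effects.items() if t not in base}
    for trait, shift in extra.items():
        out[trait] = shift * is_shifted + bp_effects[birthplace] + rng.normal(size=n)
    df = pd.DataFrame(out, index=_sample_names(n))
    df.index.name = "sample_id"
    return df


def write_fixture_set(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write abundance TSV, phenotype TSV, genotype VCF, and a truth JSON
    sidecar; all files round-trip losslessly through the package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab, truth_ab = gen_abundance_table(cfg)
    geno = gen_genotypes(cfg)
    y, truth_li = gen_enterotype_liability(geno, cfg)
    pheno = gen_performance_phenotypes(truth_ab.assignments, cfg)
    pheno["enterotype_binary"] = y
    paths = {
        "abundance": out / "abundance.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "genotypes": out / "genotypes.vcf",
        "truth": out / "truth.json",
    }
    tab.to_tsv(paths["abundance"])
    pheno.to_csv(paths["phenotypes"], sep="\t")
    geno.to_vcf(paths["genotypes"])
    truth = {
        "assignments": truth_ab.assignments.tolist(),
        "liabilities": truth_li.liabilities.tolist(),
        "causal_effects": truth_li.causal_effects,
        "prevalence": cfg.prevalence,
        "h2_liability": cfg.h2_liability,
        "seed": cfg.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
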