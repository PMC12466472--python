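import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rumenet.genetics import (
    clr_transform,
    compute_grm,
    genetic_correlation,
    grm_pcs,
    gwas_binary_trait,
    ld_prune,
    observed_to_liability,
    qc_filter_variants,
    reml_h2_observed,
    significance_thresholds,
    snp_microbiota_effects,
)
from rumenet.synthetic import (
    SimConfig,
    gen_abundance_table,
    gen_enterotype_liability,
    gen_genotypes,
)
from rumenet.tables import AbundanceTable, GenotypeMatrix


def make_geno(dosages, n_alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix([f"i{i}" for i in range(n)],
                          [f"snp{j}" for j in range(m)],
                          np.array(["1"] * m), np.arange(1, m + 1), dosages,
                          None if n_alleles is None else np.asarray(n_alleles))


# ---------------------------------------------------------------- QC

def test_qc_maf_threshold():
    rng = np.random.default_rng(0)
    low = rng.binomial(2, 0.04, size=(500, 1)).astype(float)   # MAF ~ 0.04
    high = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
    g = make_geno(np.hstack([low, high]))
    assert qc_filter_variants(g).snp_ids == ["snp1"]


def test_qc_missingness_threshold():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
    d[:35, 0] = np.nan  # 35% missing
    g = make_geno(d)
    assert qc_filter_variants(g).snp_ids == ["snp1"]


def test_qc_multiallelic_removed():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
    g = make_geno(d, n_alleles=[3, 2])
    assert qc_filter_variants(g).snp_ids == ["snp1"]


def test_qc_all_filtered_errors():
    g = make_geno(np.zeros((50, 1)))
    with pytest.raises(ValueError):
        qc_filter_variants(g)


# ---------------------------------------------------------------- LD pruning

def test_prune_duplicate_column():
    rng = np.random.default_rng(3)
    a = rng.binomial(2, 0.4, size=(200, 1)).astype(float)
    b = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
    g = make_geno(np.hstack([a, a, b]))
    kept = ld_prune(g)
    assert len(kept) == 4
    assert ("snp0" in kept) != ("snp1" in kept)


def test_prune_independent_snps_low_rate():
    g = gen_genotypes(SimConfig(n_samples=2000, n_snps=100, ld_block_size=1,
                                seed=4))
    kept = ld_prune(g)
    # r^2 > 0.1 at n=2000 between independent SNPs is vanishingly rare
    assert len(kept) >= 98


def test_prune_sample_order_invariant(hwe_genotypes):
    g = hwe_genotypes
    kept1 = ld_prune(g)
    perm = np.random.default_rng(5).permutation(g.n_samples)
    g2 = GenotypeMatrix([g.sample_ids[i] for i in perm], g.snp_ids, g.chrom,
                        g.pos, g.dosages[perm])
    assert kept1 == ld_prune(g2)


# ---------------------------------------------------------------- GRM

def test_grm_single_snp_hand_value():
    # one SNP, p = 0.5, individual with x = 2: diagonal (2-1)^2/(2*0.5*0.5) = 2
    g = make_geno(np.array([[2.0], [0.0], [1.0], [1.0]]))
    grm = compute_grm(g)
    assert grm.values[0, 0] == pytest.approx(2.0)
    assert grm.values[1, 1] == pytest.approx(2.0)
    assert grm.values[2, 2] == pytest.approx(0.0)


def test_grm_matches_bruteforce_double_loop():
    g = gen_genotypes(SimConfig(n_samples=12, n_snps=25, seed=6))
    grm = compute_grm(g)
    x = g.dosages
    p = x.mean(axis=0) / 2
    m = g.n_snps
    brute = np.zeros((12, 12))
    for j in range(12):
        for k in range(12):
            brute[j, k] = np.sum((x[j] - 2 * p) * (x[k] - 2 * p)
                                 / (2 * p * (1 - p))) / m
    assert np.allclose(grm.values, brute, atol=1e-10)


def test_grm_hwe_mean_diagonal_and_offdiag():
    g = gen_genotypes(SimConfig(n_samples=400, n_snps=3000, seed=7))
    grm = compute_grm(g)
    assert abs(np.diag(grm.values).mean() - 1.0) < 0.05
    off = grm.values[np.triu_indices(400, 1)]
    assert abs(off.mean()) < 0.01


def test_grm_monomorphic_errors():
    g = make_geno(np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 1.0]]))
    with pytest.raises(ValueError):
        compute_grm(g)


# ---------------------------------------------------------------- REML h2

def test_reml_null_h2_small():
    cfg = SimConfig(n_samples=400, n_snps=800, h2_liability=0.0, seed=8)
    g = gen_genotypes(cfg)
    y, _ = gen_enterotype_liability(g, cfg)
    est = reml_h2_observed(y, compute_grm(g))
    assert est.h2_observed < 0.15
    assert est.lrt_p > 0.01


def test_reml_loglik_optimum_dominates_null():
    cfg = SimConfig(n_samples=300, n_snps=600, h2_liability=0.5, seed=9)
    g = gen_genotypes(cfg)
    y, _ = gen_enterotype_liability(g, cfg)
    grm = compute_grm(g)
    from rumenet.genetics import _reml_loglik

    evals, evecs = np.linalg.eigh(grm.values)
    lam = np.clip(evals, 0, None)
    x = np.ones((300, 1))
    est = reml_h2_observed(y, grm)
    ll0 = _reml_loglik(0.0, lam, evecs.T @ y, evecs.T @ x)
    assert est.loglik >= ll0 - 1e-9


def test_reml_invariant_to_phenotype_shift():
    cfg = SimConfig(n_samples=250, n_snps=500, h2_liability=0.4, seed=10)
    g = gen_genotypes(cfg)
    y, _ = gen_enterotype_liability(g, cfg)
    grm = compute_grm(g)
    e1 = reml_h2_observed(y.astype(float), grm)
    e2 = reml_h2_observed(y.astype(float) + 7.5, grm)
    assert e1.h2_observed == pytest.approx(e2.h2_observed, abs=1e-5)


# ---------------------------------------------------------------- liability transform

def test_liability_half_prevalence_closed_form():
    assert observed_to_liability(1.0, 0.5) == pytest.approx(np.pi / 2)
    assert observed_to_liability(0.2, 0.5) == pytest.approx(0.2 * np.pi / 2)


def test_liability_zero_maps_to_zero():
    assert observed_to_liability(0.0, 0.3) == 0.0


def test_liability_printed_cohort_value():
    # h2_obs = 0.27 at prevalence 553/1150 -> ~0.424 (prints as 0.43 from
    # unrounded inputs)
    val = observed_to_liability(0.27, 553 / 1150)
    assert val == pytest.approx(0.4245, abs=5e-4)


def test_liability_boundary_errors():
    with pytest.raises(ValueError):
        observed_to_liability(0.3, 0.0)
    with pytest.raises(ValueError):
        observed_to_liability(0.3, 1.0)


def test_liability_linear_and_matches_monte_carlo():
    # multiplier is linear in h2_obs and matches a liability-threshold
    # Monte-Carlo evaluation of the observed/liability variance ratio
    k = 0.3
    m = observed_to_liability(1.0, k)
    assert observed_to_liability(0.4, k) == pytest.approx(0.4 * m)
    rng = np.random.default_rng(11)
    n = 2_000_000
    liab = rng.normal(size=n)
    thresh = scipy.stats.norm.ppf(1 - k)
    y = liab > thresh
    # regression of 0/1 on liability: slope^2 = h2_obs for h2_liab = 1
    slope = np.cov(y, liab)[0, 1] / np.var(liab)
    h2_obs_mc = slope**2 * np.var(liab) / np.var(y)
    assert 1.0 == pytest.approx(h2_obs_mc * m, rel=0.01)


# ---------------------------------------------------------------- rG

def test_rg_same_trait_is_one():
    cfg = SimConfig(n_samples=300, n_snps=600, seed=12)
    g = gen_genotypes(cfg)
    grm = compute_grm(g)
    rng = np.random.default_rng(12)
    z = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0)
    y = z[:, :50] @ rng.normal(size=50) + rng.normal(size=300)
    est = genetic_correlation(y, y, grm)
    assert est.rg == pytest.approx(1.0, abs=1e-9)


def test_rg_negated_trait_is_minus_one():
    cfg = SimConfig(n_samples=300, n_snps=600, seed=13)
    g = gen_genotypes(cfg)
    grm = compute_grm(g)
    rng = np.random.default_rng(13)
    z = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0)
    y = z[:, :50] @ rng.normal(size=50) + rng.normal(size=300)
    est = genetic_correlation(y, -y, grm)
    assert est.rg == pytest.approx(-1.0, abs=1e-9)


def test_rg_independent_traits_near_zero():
    cfg = SimConfig(n_samples=500, n_snps=1000, seed=14)
    g = gen_genotypes(cfg)
    grm = compute_grm(g)
    rng = np.random.default_rng(14)
    z = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0)
    yx = z[:, :100] @ rng.normal(size=100) * 0.1 + rng.normal(size=500)
    yy = z[:, 500:600] @ rng.normal(size=100) * 0.1 + rng.normal(size=500)
    est = genetic_correlation(yx, yy, grm)
    assert np.isfinite(est.rg)
    assert abs(est.rg) < max(2 * est.se, 0.5)


def test_rg_nonpositive_variance_flagged():
    rng = np.random.default_rng(15)
    cfg = SimConfig(n_samples=150, n_snps=300, seed=15)
    g = gen_genotypes(cfg)
    grm = compute_grm(g)
    est = genetic_correlation(rng.normal(size=150), rng.normal(size=150), grm)
    # pure-noise traits: genetic variance may be <= 0 -> rG undefined, or tiny
    assert np.isnan(est.rg) or abs(est.rg) <= 1.0


# ---------------------------------------------------------------- GWAS

def test_gwas_null_lambda_near_one():
    g = gen_genotypes(SimConfig(n_samples=500, n_snps=5000, seed=16))
    y = np.random.default_rng(16).binomial(1, 0.5, 500)
    res = gwas_binary_trait(y, g)
    assert abs(res.lambda_gc - 1.0) < 0.05


def test_gwas_detects_planted_causal_snp():
    cfg = SimConfig(n_samples=800, n_snps=400, h2_liability=0.6,
                    n_causal_snps=2, seed=17)
    g = gen_genotypes(cfg)
    y, truth = gen_enterotype_liability(g, cfg)
    res = gwas_binary_trait(y, g, n_independent_snps=400)
    causal = list(truth.causal_effects)
    pmin = res.table.set_index("snp").loc[causal, "p"].min()
    assert pmin < res.threshold_suggestive


def test_gwas_permuted_phenotype_breaks_association():
    cfg = SimConfig(n_samples=400, n_snps=300, h2_liability=0.6,
                    n_causal_snps=2, seed=18)
    g = gen_genotypes(cfg)
    y, _ = gen_enterotype_liability(g, cfg)
    yperm = np.random.default_rng(18).permutation(y)
    res = gwas_binary_trait(yperm, g)
    assert res.table["p"].min() > 0.05 / 300 / 100  # consistent with null


def test_gwas_covariates_absorb_confounder():
    rng = np.random.default_rng(19)
    g = gen_genotypes(SimConfig(n_samples=400, n_snps=200, seed=19))
    conf = rng.normal(size=400)
    y = (conf + rng.normal(size=400) > 0).astype(int)
    res = gwas_binary_trait(y, g, covariates=conf[:, None])
    assert abs(res.lambda_gc - 1.0) < 0.25


# ---------------------------------------------------------------- thresholds

def test_thresholds_printed_cohort():
    thr = significance_thresholds(1_608_328)
    assert thr["genome_wide_2sig"] == 3.1e-8
    assert thr["suggestive_2sig"] == 6.2e-7


def test_thresholds_small_n():
    thr = significance_thresholds(20)
    assert thr["genome_wide"] == pytest.approx(2.5e-3)
    assert thr["suggestive"] == pytest.approx(5.0e-2)


def test_thresholds_identity_and_errors():
    thr = significance_thresholds(777)
    assert thr["genome_wide"] == pytest.approx(thr["suggestive"] * 0.05)
    with pytest.raises(ValueError):
        significance_thresholds(0)


# ---------------------------------------------------------------- clr

def test_clr_rows_sum_zero(two_cluster_sim):
    tab, _ = two_cluster_sim
    clr = clr_transform(tab)
    assert np.allclose(clr.sum(axis=1), 0.0, atol=1e-10)


def test_clr_uniform_composition_zero():
    tab = AbundanceTable(["a"], ["g0", "g1", "g2"], np.array([[5, 5, 5]]))
    assert np.allclose(clr_transform(tab), 0.0)


def test_clr_scale_invariance():
    tab1 = AbundanceTable(["a"], ["g0", "g1"], np.array([[10, 30]]))
    tab2 = AbundanceTable(["a"], ["g0", "g1"], np.array([[50, 150]]))
    assert np.allclose(clr_transform(tab1), clr_transform(tab2))


def test_clr_all_zero_sample_errors():
    tab = AbundanceTable(["a"], ["g0", "g1"], np.array([[0, 0]]))
    with pytest.raises(ValueError):
        clr_transform(tab)


# ---------------------------------------------------------------- SNP effects

def test_snp_effect_planted_on_clr_mean():
    rng = np.random.default_rng(20)
    n = 500
    g = gen_genotypes(SimConfig(n_samples=n, n_snps=5, seed=20))
    dose = g.dosages[:, 0]
    base = rng.integers(500, 1500, size=(n, 4)).astype(float)
    base[:, 0] *= np.exp(0.5 * dose)  # additive genotype effect on one genus
    tab = AbundanceTable(g.sample_ids, [f"g{i}" for i in range(4)], base)
    res = snp_microbiota_effects(g, ["snp0"], tab)
    hit = res.set_index("genus").loc["g0"]
    assert hit["q"] < 0.05 and hit["model"] == "linear_clr"


def test_snp_effect_rare_genus_excluded_and_logistic_routing():
    rng = np.random.default_rng(21)
    n = 300
    g = gen_genotypes(SimConfig(n_samples=n, n_snps=3, seed=21))
    counts = rng.integers(100, 1000, size=(n, 3)).astype(float)
    counts[rng.random(n) < 0.7, 1] = 0.0   # ~30% prevalence -> logistic branch
    counts[2:, 2] = 0.0  # 2/300 prevalence -> below the 1.5% floor
    tab = AbundanceTable(g.sample_ids, ["common", "sparse", "rare"], counts)
    res = snp_microbiota_effects(g, ["snp0"], tab)
    models = res.set_index("genus")["model"]
    assert models["common"] == "linear_clr"
    assert models["sparse"] == "logistic_presence"
    assert "rare" not in models.index


def test_grm_pcs_orthonormal(hwe_genotypes):
    grm = compute_grm(hwe_genotypes)
    pcs = grm_pcs(grm, 5)
    assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)
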