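"""Regional F/LRT/score tests: K reduction, equivalences, rank handling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import funlmm as fl
from funlmm.regional import effective_K, region_from_dosages
from funlmm.regional import TestConfig as Config


def make_regions(ped, scenario, rng, sizes):
    return [fl.simulate_genotypes(ped, scenario, rng, m=m, name=f"r{i}")
            for i, m in enumerate(sizes)]


# --- effective_K -----------------------------------------------------------

@pytest.mark.parametrize(
    "m,gvf,bsf,reqG,reqB,expect",
    [
        (50, "F", "F", 25, 25, (25, 25, False)),
        (10, None, "F", 25, 25, (None, 9, False)),
        (20, "F", "B", 25, 15, (19, 15, False)),
        (20, "B", "B", 15, 15, (15, 15, False)),
        (3, "B", "B", 15, 15, (None, None, True)),   # below cubic order
        (3, None, "F", 25, 25, (None, 3, False)),
        (6, "F", "F", 25, 25, (5, 5, False)),         # odd cap then K_beta cap
    ],
)
def test_effective_K_reduction_rules(m, gvf, bsf, reqG, reqB, expect):
    assert effective_K(m, gvf, bsf, reqG, reqB) == expect


# --- statistic identities --------------------------------------------------

def test_beta_F_is_ols_for_independent_sample():
    """With Omega = I (and no covariate projection) beta_F is the OLS
    coefficient vector of y - X alpha on GW."""
    rng = np.random.default_rng(4)
    n, m = 120, 9
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    region = region_from_dosages("r", G, np.sort(rng.choice(5000, m, False)))
    X = np.ones((n, 1))
    y = rng.standard_normal(n)
    fit = fl.fit_null(y, X, np.eye(n))
    cfg = Config(project_covariates=False)
    res = fl.test_region(y, X, region, fit, "0-F", cfg)
    W, *_ = fl.simulate.region_W(region, "0-F", cfg)
    GW = region.G @ W
    ols = np.linalg.lstsq(GW, y - X @ fit.alpha, rcond=None)[0]
    assert np.allclose(res.beta_F, ols, atol=1e-8)


def test_same_K_equivalences_bb_0b_and_ff_0f(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(20)
    cfg = Config(K_bspline=7, K_fourier=7)
    for region in make_regions(ped, sc, rng, rng.integers(8, 26, size=25)):
        bb = fl.test_region(y, X, region, fit, "B-B", cfg)
        ob = fl.test_region(y, X, region, fit, "0-B", cfg)
        ff = fl.test_region(y, X, region, fit, "F-F", cfg)
        of = fl.test_region(y, X, region, fit, "0-F", cfg)
        assert bb.F_stat == pytest.approx(ob.F_stat, abs=1e-8)
        assert ff.F_stat == pytest.approx(of.F_stat, abs=1e-8)


def saturated_lmm_F(y, X, region, fit):
    """Dense-matrix oracle: GLS F-test of all dosages jointly, with
    alpha/Omega at the null fit and the covariate projection applied."""
    R = fit.eigen.U @ np.diag(fit.eigen.d) @ fit.eigen.U.T
    Om = fit.sigma_h2 * R + fit.sigma_e2 * np.eye(fit.n)
    Oi = np.linalg.inv(Om)
    P = Oi - Oi @ X @ np.linalg.inv(X.T @ Oi @ X) @ X.T @ Oi
    r0 = y - X @ fit.alpha
    RSS0 = r0 @ Oi @ r0
    G = region.G
    u = G.T @ P @ r0
    expl = u @ np.linalg.pinv(G.T @ P @ G, rcond=1e-10) @ u
    r = np.linalg.matrix_rank(G)
    df2 = fit.n - r - 1
    return ((expl / r) / ((RSS0 - expl) / df2), r, df2)


def test_K_equal_m_reduces_to_saturated_lmm(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(21)
    cfg = Config(K_bspline=7, K_fourier=7)
    for region in make_regions(ped, sc, rng, [7, 7, 7]):
        F_oracle, r, df2 = saturated_lmm_F(y, X, region, fit)
        for label in fl.MODEL_LABELS:
            res = fl.test_region(y, X, region, fit, label, cfg)
            assert res.F_stat == pytest.approx(F_oracle, abs=1e-8)
            assert (res.df1, res.df2) == (r, df2)


def test_duplicated_variant_column_reduces_rank(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    rng = np.random.default_rng(5)
    n = fit.n
    g = rng.integers(0, 3, size=(n, 4)).astype(float)
    G = np.column_stack([g, g[:, 0]])  # exact duplicate column
    region = region_from_dosages("dup", G, [10, 20, 30, 40, 50])
    res = fl.test_region(y, X, region, fit, "0-F",
                         Config(K_fourier=5))
    assert res.m == 5 and res.rank == 4 and res.df1 == 4


def test_monomorphic_region_rejected(small_null):
    y, X, fit = small_null
    n = fit.n
    region = fl.Region(
        name="mono", variant_ids=["a", "b"],
        positions=fl.scale_positions([1, 2]),
        G=np.zeros((n, 2)), mafs=np.zeros(2),
    )
    with pytest.raises(ValueError, match="monomorphic"):
        fl.test_region(y, X, region, fit, "0-F")


def test_single_variant_wald_fallback(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    rng = np.random.default_rng(6)
    G = rng.integers(0, 3, size=(fit.n, 1)).astype(float)
    region = region_from_dosages("one", G, [100])
    res = fl.test_region(y, X, region, fit, "F-F")
    assert res.note == "m1-wald" and res.df1 == 1
    assert 0 <= res.p_F <= 1


def test_df_convention_flag(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(9)
    region = fl.simulate_genotypes(ped, sc, rng, m=10)
    a = fl.test_region(y, X, region, fit, "0-F", Config())
    b = fl.test_region(y, X, region, fit, "0-F",
                       Config(df_subtract_covariates=True))
    assert b.df2 == a.df2 - fit.c


def test_dominance_coding_changes_design(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(10)
    region = fl.simulate_genotypes(ped, sc, rng, m=12)
    add = fl.test_region(y, X, region, fit, "0-B")
    dom = fl.test_region(y, X, region, fit, "0-B", Config(dominance=True))
    assert dom.F_stat != pytest.approx(add.F_stat)


def test_f_and_score_pvalues_track_each_other(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(30)
    pf, psc = [], []
    for region in make_regions(ped, sc, rng, rng.integers(3, 30, size=60)):
        res = fl.test_region(y, X, region, fit, "0-F")
        pf.append(res.p_F)
        psc.append(res.p_score)
    rho = stats.spearmanr(pf, psc).statistic
    assert rho > 0.99


def test_run_genome_contract(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, R = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(31)
    regions = make_regions(ped, sc, rng, [5, 8, 12])
    mono = fl.Region(
        name="mono", variant_ids=["a", "b"],
        positions=fl.scale_positions([1, 2]),
        G=np.zeros((fit.n, 2)), mafs=np.zeros(2),
    )
    cfg = Config(models=("0-F",))
    out = fl.run_genome(regions + [mono], y, X, R, cfg, fit=fit)
    assert len(out) == 4
    assert out["p_F"].notna().sum() == 3
    assert out.loc[out.region == "mono", "note"].str.contains("monomorphic").all()
    out2 = fl.run_genome(regions + [mono], y, X, R, cfg, fit=fit)
    pd.testing.assert_frame_equal(out, out2)


def test_rss_invariants_and_pvalue_ranges(small_sample, small_null):
    _, _, eigen = small_sample
    y, X, fit = small_null
    sc = fl.SimScenario(n_families=2)
    ped, _ = fl.simulate_pedigrees(sc)
    rng = np.random.default_rng(32)
    for region in make_regions(ped, sc, rng, [2, 6, 17, 40]):
        for label in fl.MODEL_LABELS:
            res = fl.test_region(y, X, region, fit, label)
            assert res.RSS0 >= res.RSS1 >= 0
            assert res.df1 == res.rank >= 1 and res.df2 > 0
            for p in (res.p_F, res.p_LRT, res.p_score):
                assert 0.0 <= p <= 1.0
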