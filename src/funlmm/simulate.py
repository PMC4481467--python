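"""Synthetic pedigrees, genotypes and traits for calibration experiments.

The generator emulates a mini-exome family study: eight three-generation
pedigrees totalling ~700 individuals, gene-sized regions of 2-60
variants whose founder haplotypes come from a finite pool (creating
within-region linkage disequilibrium), a rare-shifted allele-frequency
spectrum (median MAF ~1%, range ~0.1%-35%), and a polygenic quantitative
trait with narrow-sense heritability 0.29.

Genotypes are produced by whole-haplotype Mendelian gene dropping: a
gene-sized region recombines essentially never within a generation, so
each transmitted haplotype is one of the parent's two, chosen at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .null_model import EigenR, fit_null
from .pedigree import Pedigree, RelationshipMatrix, kinship_from_pedigree
from .regional import (
    Region,
    TestConfig,
    full_rank_columns,
    region_from_dosages,
    region_W,
    test_region,
)

GENOME_WIDE_ALPHA = 2.5e-6  # exome-wide threshold used for power


@dataclass
class SimScenario:
    """Generator settings for one simulation condition."""

    n_families: int = 8
    n_children: int = 7          # married children per founder couple
    n_grandchildren: int = 10    # per child couple
    pool_haplotypes: int = 100   # founder haplotype pool size H (LD strength)
    m: int = 50                  # variants per region (power experiments)
    maf_beta: tuple[float, float] = (0.2, 20.0)
    maf_range: tuple[float, float] = (0.001, 0.35)
    h2: float = 0.29
    causal_fraction: float = 0.1
    unidirectional_fraction: float = 1.0
    c: float = 5.0
    rare_only: bool = False
    rare_maf: float = 0.03
    prune_noncausal: float = 0.0
    alpha_level: float = GENOME_WIDE_ALPHA
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.causal_fraction, self.unidirectional_fraction,
                  self.prune_noncausal):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0,1)")
        if self.c <= 1.0:
            raise ValueError("effect-size constant c must exceed 1")

    @property
    def family_size(self) -> int:
        return 2 + 2 * self.n_children + self.n_children * self.n_grandchildren


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_pedigrees(
    scenario: SimScenario, seed=None
) -> tuple[Pedigree, RelationshipMatrix]:
    """Regular three-generation pedigrees: a founder couple, their
    married children (spouses are founders) and grandchildren.

    The default template gives 8 x 86 = 688 individuals, emulating a
    ~700-individual, eight-family exome sample.  Deterministic: the seed
    only matters if the template is ever randomized.
    """
    ids: list[str] = []
    fam: list[str] = []
    father: list[int] = []
    mother: list[int] = []
    sex: list[int] = []

    for f in range(scenario.n_families):
        fname = f"FAM{f + 1}"

        def add(iid: str, fa: int, mo: int, sx: int) -> int:
            ids.append(f"{fname}_{iid}")
            fam.append(fname)
            father.append(fa)
            mother.append(mo)
            sex.append(sx)
            return len(ids) - 1

        gf = add("gf", -1, -1, 1)
        gm = add("gm", -1, -1, 2)
        for ch in range(scenario.n_children):
            child_sex = 1 + ch % 2
            child = add(f"c{ch + 1}", gf, gm, child_sex)
            spouse = add(f"s{ch + 1}", -1, -1, 3 - child_sex)
            pa, ma = (child, spouse) if child_sex == 1 else (spouse, child)
            for gc in range(scenario.n_grandchildren):
                add(f"g{ch + 1}_{gc + 1}", pa, ma, 1 + gc % 2)

    ped = Pedigree(
        ids=ids,
        father=np.asarray(father),
        mother=np.asarray(mother),
        family=fam,
        sex=np.asarray(sex, dtype=float),
    )
    return ped, kinship_from_pedigree(ped)


def _founder_slots(ped: Pedigree) -> dict[int, int]:
    slots = {}
    for i in range(len(ped)):
        if ped.father[i] < 0 and ped.mother[i] < 0:
            slots[i] = 2 * len(slots)
    return slots


def gene_drop(ped: Pedigree, rng) -> np.ndarray:
    """One whole-haplotype Mendelian drop through the pedigree.

    Returns an (n, 2) array mapping each individual's paternal/maternal
    haplotype to a founder haplotype slot (0 .. 2*n_founders-1).
    """
    rng = _rng(rng)
    slots = _founder_slots(ped)
    n = len(ped)
    desc = np.empty((n, 2), dtype=np.int64)
    picks = rng.integers(0, 2, size=(n, 2))
    for i in ped.topological_order():
        f, m = ped.father[i], ped.mother[i]
        if f < 0:
            base = slots[i]
            desc[i, 0] = base
            desc[i, 1] = base + 1
        else:
            desc[i, 0] = desc[f, picks[i, 0]]
            desc[i, 1] = desc[m, picks[i, 1]]
    return desc


def _draw_frequencies(rng, size: int, scenario: SimScenario) -> np.ndarray:
    a, b = scenario.maf_beta
    lo, hi = scenario.maf_range
    out = np.empty(size)
    have = 0
    while have < size:
        cand = rng.beta(a, b, size=2 * (size - have) + 8)
        cand = cand[(cand >= lo) & (cand <= hi)]
        take = min(cand.size, size - have)
        out[have : have + take] = cand[:take]
        have += take
    return out


def _draw_pool_columns(rng, p: np.ndarray, H: int, hi: float) -> np.ndarray:
    """Pool haplotype alleles for sites with target frequencies p.

    Allele counts are binomial around p but clipped to [1, hi*H]: every
    site keeps at least one carrier haplotype (otherwise the rare end of
    the spectrum would be lost to the polymorphism filter) and never
    exceeds the spectrum's upper bound.
    """
    m = p.size
    counts = np.clip(rng.binomial(H, p), 1, max(1, int(hi * H)))
    cols = np.zeros((H, m), dtype=np.int8)
    for j in range(m):
        cols[rng.choice(H, size=counts[j], replace=False), j] = 1
    return cols


def simulate_genotypes(
    ped: Pedigree, scenario: SimScenario, seed=None, m: int | None = None,
    name: str = "R1",
) -> Region:
    """LD-structured regional genotypes via a finite founder-haplotype pool.

    H pool haplotypes carry alleles drawn from the rare-shifted site
    frequency spectrum; each founder haplotype is sampled (with
    replacement) from the pool, and whole haplotypes are gene-dropped.
    Sites monomorphic in the realized sample are redrawn (bounded
    retries).
    """
    rng = _rng(seed)
    m = m or scenario.m
    H = scenario.pool_haplotypes
    n = len(ped)

    p = _draw_frequencies(rng, m, scenario)
    pool = _draw_pool_columns(rng, p, H, scenario.maf_range[1])

    n_slots = 2 * ped.n_founders
    pool_of_slot = rng.integers(0, H, size=n_slots)
    desc = gene_drop(ped, rng)
    hap_idx = pool_of_slot[desc]  # (n, 2) pool rows

    G = pool[hap_idx[:, 0]].astype(np.int16) + pool[hap_idx[:, 1]]

    for _ in range(200):
        mono = np.ptp(G, axis=0) == 0
        if not mono.any():
            break
        k = int(mono.sum())
        p_new = _draw_frequencies(rng, k, scenario)
        pool[:, mono] = _draw_pool_columns(rng, p_new, H, scenario.maf_range[1])
        G[:, mono] = pool[hap_idx[:, 0]][:, mono].astype(np.int16) + \
            pool[hap_idx[:, 1]][:, mono]
    else:
        raise RuntimeError(f"could not obtain {m} polymorphic sites")

    span = max(10 * m, 2000)
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=m, replace=False))
    return region_from_dosages(name, G.astype(float), positions,
                               variant_ids=[f"{name}_v{j}" for j in range(m)])


def simulate_region_set(
    ped: Pedigree, scenario: SimScenario, seed=None, n_regions: int = 1702,
    size_range: tuple[int, int] = (2, 60), mean_size: float = 7.4,
) -> list[Region]:
    """A mini-exome's worth of regions with a small-skewed size
    distribution (geometric, clipped to ``size_range``); the default mean
    matches ~12,600 variants over ~1,700 gene regions."""
    rng = _rng(seed)
    lo, hi = size_range
    sizes = lo + rng.geometric(1.0 / (mean_size - lo + 1), size=n_regions) - 1
    sizes = np.clip(sizes, lo, hi)
    return [
        simulate_genotypes(ped, scenario, rng, m=int(sz), name=f"G{i + 1:04d}")
        for i, sz in enumerate(sizes)
    ]


def causal_effects(
    region: Region, scenario: SimScenario, rng
) -> tuple[np.ndarray, dict[int, float]]:
    """Causal variant selection and effect sizes.

    ceil(causal_fraction * m) variants are drawn uniformly (from the
    rare subset when ``rare_only``); each gets |beta| =
    ln(c) * |log10(MAF)| / 2, positive with probability
    ``unidirectional_fraction``.
    """
    m = region.m
    n_causal = int(np.ceil(scenario.causal_fraction * m))
    beta = np.zeros(m)
    if n_causal == 0:
        return beta, {}
    eligible = np.arange(m)
    if scenario.rare_only:
        eligible = eligible[region.mafs <= scenario.rare_maf]
    if eligible.size < n_causal:
        raise ValueError("fewer rare variants than requested causal count")
    idx = rng.choice(eligible, size=n_causal, replace=False)
    mag = np.log(scenario.c) * np.abs(np.log10(region.mafs[idx])) / 2.0
    sign = np.where(rng.random(n_causal) < scenario.unidirectional_fraction,
                    1.0, -1.0)
    beta[idx] = sign * mag
    return beta, {int(i): float(b) for i, b in zip(idx, beta[idx])}


def polygenic_background(eigen: EigenR, scenario: SimScenario, rng,
                         size: int | None = None) -> np.ndarray:
    """h + e with var(h)/(var(h)+var(e)) = h2 and unit total variance,
    h drawn with covariance sigma_h^2 R via the eigenfactorization."""
    n = eigen.d.size
    reps = size or 1
    z = rng.standard_normal((reps, n))
    h = (z * np.sqrt(scenario.h2 * eigen.d)) @ eigen.U.T
    e = np.sqrt(1.0 - scenario.h2) * rng.standard_normal((reps, n))
    out = h + e
    return out[0] if size is None else out


def simulate_trait(
    ped: Pedigree,
    R: RelationshipMatrix | EigenR,
    region: Region | None,
    scenario: SimScenario,
    seed=None,
) -> tuple[np.ndarray, dict[int, float]]:
    """Quantitative trait y = G beta + h + e (pure null when no region
    or no causal variants)."""
    rng = _rng(seed)
    eigen = R if isinstance(R, EigenR) else EigenR.from_matrix(R.R)
    if region is None:
        return polygenic_background(eigen, scenario, rng), {}
    beta, causal = causal_effects(region, scenario, rng)
    y = region.G @ beta + polygenic_background(eigen, scenario, rng)
    return y, causal


# ---------------------------------------------------------------------------
# experiment drivers


def _prepare_rotated_designs(regions, eigen: EigenR, models, cfg: TestConfig):
    """Per region/model: rotated full-rank design A = U'(G W_kept) and df.

    The retained column set does not depend on the fitted variances
    (whitening weights are strictly positive), so it is computed once
    and shared by all trait replicates.
    """
    designs = {}
    for region in regions:
        for label in models:
            W, _, _, _ = region_W(region, label, cfg)
            GW = region.G @ W
            kept = full_rank_columns(GW)
            A = eigen.U.T @ GW[:, kept]
            designs[(region.name, label)] = (A, kept.size)
    return designs


def _batched_f_pvalues(designs, models, region_names, W2mat, R0rot, n, Xrot):
    """Vectorized F p-values for all replicates of each region/model.

    W2mat holds per-replicate Omega^-1 eigenweights (reps x n), R0rot the
    rotated null residuals y - X alpha (reps x n) and Xrot the rotated
    covariates; the tested design is projected off the covariates
    exactly as in :func:`funlmm.regional.test_region`.
    """
    RSS0 = np.einsum("rn,rn->r", W2mat, R0rot**2)
    WR = W2mat * R0rot
    WX = W2mat[:, :, None] * Xrot[None, :, :]          # reps x n x c
    S = np.einsum("rnc,nd->rcd", WX, Xrot)             # X' Omega^-1 X
    out = {label: [] for label in models}
    for name in region_names:
        for label in models:
            A, r = designs[(name, label)]
            M = np.einsum("rn,nk,nj->rkj", W2mat, A, A, optimize=True)
            C = np.einsum("rnc,nk->rck", WX, A)        # X' Omega^-1 A
            M = M - np.einsum(
                "rck,rcd,rdj->rkj", C, np.linalg.inv(S), C
            )
            u = WR @ A
            sol = np.linalg.solve(M, u[..., None])[..., 0]
            expl = np.einsum("rk,rk->r", u, sol)
            df2 = n - r - 1
            F = (expl / r) / ((RSS0 - expl) / df2)
            out[label].append(stats.f.sf(F, r, df2))
    return {label: np.concatenate(v) if v else np.empty(0)
            for label, v in out.items()}


def run_type1_experiment(
    scenario: SimScenario,
    n_replicates: int | None = None,
    n_regions: int = 1702,
    models=("B-B", "0-B", "F-B", "B-F", "0-F", "F-F"),
    alphas=(0.05, 0.01, 1e-3),
    cfg: TestConfig | None = None,
    seed=None,
    force_identity_R: bool = False,
    return_pvalues: bool = False,
):
    """Empirical type I error of the regional F-test under the null.

    Simulates a fixed family sample and region set, then repeatedly
    draws pure-null polygenic traits, refits the null model per
    replicate and tests every region under every model, pooling the
    P values.  ``force_identity_R`` deliberately mis-specifies the null
    model (independence assumed on family data) as a diagnostic.

    Returns a table of empirical rates with binomial standard errors
    (plus the pooled P values when ``return_pvalues``).
    """
    cfg = cfg or TestConfig()
    reps = scenario.n_replicates if n_replicates is None else n_replicates
    columns = ["model", "alpha", "n_tests", "rate", "se"]
    if reps == 0:
        empty = pd.DataFrame(columns=columns)
        return (empty, {}) if return_pvalues else empty

    ss = np.random.SeedSequence(scenario.seed if seed is None else seed)
    rng_struct, rng_trait = [np.random.default_rng(s) for s in ss.spawn(2)]

    ped, R = simulate_pedigrees(scenario, rng_struct)
    eigen = EigenR.from_matrix(R.R)
    fit_eigen = EigenR.from_matrix(np.eye(len(ped))) if force_identity_R else eigen
    regions = simulate_region_set(ped, scenario, rng_struct, n_regions=n_regions)
    n = len(ped)
    X = np.ones((n, 1))

    designs = _prepare_rotated_designs(regions, fit_eigen, models, cfg)

    Y = polygenic_background(eigen, scenario, rng_trait, size=reps)
    W2mat = np.empty((reps, n))
    R0rot = np.empty((reps, n))
    h2_hats = np.empty(reps)
    Xt = fit_eigen.U.T @ X
    for r_i in range(reps):
        fit = fit_null(Y[r_i], X, fit_eigen)
        h2_hats[r_i] = fit.heritability
        W2mat[r_i] = 1.0 / fit.omega_eigenvalues
        R0rot[r_i] = fit_eigen.U.T @ Y[r_i] - (Xt @ fit.alpha)

    pvals = _batched_f_pvalues(designs, models, [rg.name for rg in regions],
                               W2mat, R0rot, n, Xt)
    rows = []
    for label in models:
        p = pvals[label]
        for a in alphas:
            rate = float(np.mean(p < a))
            se = float(np.sqrt(a * (1 - a) / p.size))
            rows.append({"model": label, "alpha": a, "n_tests": p.size,
                         "rate": rate, "se": se})
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["h2_hats"] = h2_hats
    return (table, pvals) if return_pvalues else table


def run_power_experiment(
    scenarios: list[SimScenario],
    n_replicates: int = 1000,
    models=("B-B", "0-B", "F-B", "B-F", "0-F", "F-F"),
    cfg: TestConfig | None = None,
    seed=0,
    paired: bool = True,
    return_hits: bool = False,
):
    """Power of the regional F-test over a grid of effect scenarios.

    All scenarios share one family sample and one fixed multi-variant
    region (the first scenario's size settings).  With ``paired=True``
    the causal sets, effect signs and the polygenic-plus-residual noise
    are common random numbers across scenarios, so power comparisons
    along c or along the unidirectional fraction are paired.

    Power is the fraction of replicates with P below
    ``scenario.alpha_level`` (2.5e-6 by default, the exome-wide level).
    """
    cfg = cfg or TestConfig()
    base = scenarios[0]
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_common = [np.random.default_rng(s) for s in ss.spawn(2)]

    ped, R = simulate_pedigrees(base, rng_struct)
    eigen = EigenR.from_matrix(R.R)
    region_full = simulate_genotypes(ped, base, rng_struct, m=base.m)
    n = len(ped)
    X = np.ones((n, 1))

    # common random primitives, shared across scenarios when paired
    noise = polygenic_background(eigen, base, rng_common, size=n_replicates)
    perms = [rng_common.permutation(base.m) for _ in range(n_replicates)]
    sign_u = rng_common.random((n_replicates, base.m))
    prune_u = rng_common.random((n_replicates, base.m))

    rows = []
    all_hits: dict[tuple[int, str], np.ndarray] = {}
    for s_i, sc in enumerate(scenarios):
        rng_sc = np.random.default_rng(ss.spawn(1)[0]) if not paired else None
        hits = {label: np.zeros(n_replicates, dtype=bool) for label in models}
        n_done = 0
        for rep in range(n_replicates):
            eligible = np.arange(base.m)
            if sc.rare_only:
                eligible = eligible[region_full.mafs <= sc.rare_maf]
            n_causal = int(np.ceil(sc.causal_fraction * base.m))
            if eligible.size < n_causal:
                raise ValueError("fewer rare variants than causal count")
            if paired:
                elig = set(eligible.tolist())
                causal = np.array([j for j in perms[rep] if j in elig])[:n_causal]
                su = sign_u[rep]
                pu = prune_u[rep]
                eps = noise[rep]
            else:
                causal = rng_sc.choice(eligible, n_causal, replace=False)
                su = rng_sc.random(base.m)
                pu = rng_sc.random(base.m)
                eps = polygenic_background(eigen, sc, rng_sc)
            beta = np.zeros(base.m)
            mag = np.log(sc.c) * np.abs(np.log10(region_full.mafs[causal])) / 2
            beta[causal] = np.where(su[causal] < sc.unidirectional_fraction,
                                    1.0, -1.0) * mag
            y = region_full.G @ beta + eps

            keep = np.ones(base.m, dtype=bool)
            if sc.rare_only:
                keep &= region_full.mafs <= sc.rare_maf
            if sc.prune_noncausal > 0:
                noncausal = keep.copy()
                noncausal[causal] = False
                drop = noncausal & (pu < sc.prune_noncausal)
                keep &= ~drop
            region = _subset_region(region_full, np.flatnonzero(keep))

            fit = fit_null(y, X, eigen)
            for label in models:
                res = test_region(y, X, region, fit, label, cfg)
                hits[label][rep] = res.p_F < sc.alpha_level
            n_done += 1
        for label in models:
            all_hits[(s_i, label)] = hits[label]
            pw = float(hits[label].sum()) / n_done
            rows.append({
                "scenario": s_i, "c": sc.c,
                "causal_fraction": sc.causal_fraction,
                "unidirectional_fraction": sc.unidirectional_fraction,
                "rare_only": sc.rare_only,
                "prune_noncausal": sc.prune_noncausal,
                "model": label, "n_replicates": n_done, "power": pw,
                "se": float(np.sqrt(pw * (1 - pw) / n_done)),
            })
    table = pd.DataFrame(rows)
    return (table, all_hits) if return_hits else table


def _subset_region(region: Region, idx: np.ndarray) -> Region:
    from .bases import scale_positions

    return Region(
        name=region.name,
        variant_ids=[region.variant_ids[i] for i in idx],
        positions=scale_positions(region.positions.raw[idx]),
        G=region.G[:, idx],
        mafs=region.mafs[idx],
    )
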