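"""Functional regional association tests in the polygenic mixed model.

For a region with genotype matrix G (n x m minor-allele dosages) and
scaled variant positions, the genotype rows are smoothed onto K_G basis
functions (the GVF) and the per-variant effect curve onto K_beta basis
functions (the BSF), giving the working model

    y = X alpha + G W beta_F + h + e,

with W = Phi (Phi'Phi)^-1 [int phi psi' dt] (or W = Psi for BSF-only
models).  The null hypothesis beta_F = 0 is tested with an F statistic,
a likelihood-ratio statistic and a score statistic, all computed with
alpha and Omega held at their null ML estimates.

Model labels name the GVF/BSF basis pair: B-B, 0-B, F-B, B-F, 0-F, F-F,
where "0" means no genotype smoothing and B/F are B-spline/Fourier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as qr_pivoted

from .bases import (
    SPLINE_ORDER,
    BasisSystem,
    ScaledPositions,
    build_basis_matrices,
    scale_positions,
)
from .null_model import NullModelFit, fit_null, whiten
from .pedigree import RelationshipMatrix

MODEL_LABELS = ("B-B", "0-B", "F-B", "B-F", "0-F", "F-F")

_RANK_TOL = 1e-8


@dataclass
class Region:
    """Ordered polymorphic variants of one genomic region."""

    name: str
    variant_ids: list[str]
    positions: ScaledPositions
    G: np.ndarray  # n x m dosages, missing already imputed
    mafs: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape[1] != len(self.positions):
            raise ValueError("genotype columns do not match positions")

    @property
    def m(self) -> int:
        return self.G.shape[1]


@dataclass
class TestConfig:
    """Settings shared by all regional tests of a run."""

    models: tuple[str, ...] = MODEL_LABELS
    K_bspline: int = 15
    K_fourier: int = 25
    dominance: bool = False
    # the printed F denominator df is n - K_beta - 1; covariates are not
    # subtracted by default (set True for the conservative variant)
    df_subtract_covariates: bool = False
    # project the tested design onto the orthocomplement of the (whitened)
    # covariates, i.e. account for alpha estimation in the numerator as
    # the score test does; False fits beta_F against raw null residuals,
    # which is mildly conservative whenever GW overlaps X
    project_covariates: bool = True
    lrt_refit: bool = False

    def __post_init__(self) -> None:
        for lab in self.models:
            if lab not in MODEL_LABELS:
                raise ValueError(f"unknown model label {lab!r}")

    def requested_K(self, code: str) -> int:
        return self.K_bspline if code == "B" else self.K_fourier


@dataclass
class RegionalTestResult:
    region: str
    model: str
    m: int
    K_G: int | None
    K_beta: int | None
    rank: int
    beta_F: np.ndarray
    RSS0: float
    RSS1: float
    F_stat: float
    df1: int
    df2: int
    p_F: float
    LRT_stat: float
    p_LRT: float
    score_stat: float
    p_score: float
    note: str = ""


def _largest_odd(k: int) -> int:
    return k if k % 2 == 1 else k - 1


def effective_K(
    m: int, gvf: str | None, bsf: str, K_G_req: int, K_B_req: int
) -> tuple[int | None, int | None, bool]:
    """Reduce the requested basis counts to the region size.

    Returns ``(K_G, K_beta, saturated)``.  Rules: each K is capped at m;
    Fourier K drops to the largest odd value <= min(requested, m);
    B-spline K is max(4, min(requested, m)) and a region with m < 4
    falls back to the saturated design (multiple-regression LMM on the
    raw dosages); finally K_beta is capped at K_G when a GVF basis is
    present.  Unsatisfiable combinations (e.g. a B-spline BSF capped
    below 4 by a small Fourier GVF) also fall back to saturation, which
    is the m = K limit of every model.
    """
    if m < 1:
        raise ValueError("empty region")

    def reduce(code: str, req: int) -> int | None:
        if code == "F":
            k = _largest_odd(min(req, m))
            return k if k >= 1 else None
        k = min(req, m)
        return k if k >= 4 else None  # B-spline impossible below cubic order

    K_B = reduce(bsf, K_B_req)
    if K_B is None:
        return None, None, True
    if gvf is None:
        return None, K_B, False
    K_G = reduce(gvf, K_G_req)
    if K_G is None:
        return None, None, True
    if K_B > K_G:
        K_B = _largest_odd(K_G) if bsf == "F" else K_G
        if bsf == "B" and K_B < 4:
            return None, None, True
        if K_B < 1:
            return None, None, True
    return K_G, K_B, False


def _model_systems(
    label: str, m: int, cfg: TestConfig
) -> tuple[BasisSystem | None, BasisSystem | None, int | None, int | None, bool]:
    gcode, bcode = label.split("-")
    gvf = None if gcode == "0" else gcode
    K_G, K_B, saturated = effective_K(
        m, gvf, bcode, cfg.requested_K(gcode if gvf else "B"), cfg.requested_K(bcode)
    )
    if saturated:
        return None, None, None, None, True
    sysG = None if gvf is None else BasisSystem(
        "bspline" if gvf == "B" else "fourier", K_G
    )
    sysB = BasisSystem("bspline" if bcode == "B" else "fourier", K_B)
    return sysG, sysB, K_G, K_B, False


def region_W(region: Region, label: str, cfg: TestConfig) -> tuple[np.ndarray, int | None, int | None, bool]:
    """Transition matrix W (m x K_beta) for one region and model label.

    Saturated fallbacks (and single-variant regions) use W = I_m.  A GVF
    basis that is rank-deficient at the region's positions (clustered
    variants can violate the spline interleaving condition) is reduced
    stepwise in K_G until it has full column rank, saturating if no
    valid count remains.
    """
    m = region.m
    if m == 1:
        return np.eye(1), None, None, True
    sysG, sysB, K_G, K_B, saturated = _model_systems(label, m, cfg)
    if saturated:
        return np.eye(m), None, None, True
    if K_B == m and (K_G is None or K_G == m):
        # K = m: the functional model reduces analytically to the
        # saturated multiple-regression LMM, so test the dosages directly
        return np.eye(m), K_G, K_B, True
    while True:
        try:
            bm = build_basis_matrices(sysG, sysB, region.positions)
            return bm.W, K_G, K_B, False
        except ValueError:
            if sysG is None:
                raise
        step = 2 if sysG.family == "fourier" else 1
        K_G = sysG.K - step
        if (sysG.family == "fourier" and K_G < 1) or (
            sysG.family == "bspline" and K_G < SPLINE_ORDER
        ):
            return np.eye(m), None, None, True
        sysG = BasisSystem(sysG.family, K_G)
        if K_B > K_G:
            K_B = K_G if sysB.family == "bspline" else _largest_odd(K_G)
            if (sysB.family == "bspline" and K_B < SPLINE_ORDER) or K_B < 1:
                return np.eye(m), None, None, True
            sysB = BasisSystem(sysB.family, K_B)


def _effective_G(region: Region, cfg: TestConfig) -> np.ndarray:
    if cfg.dominance:
        return (region.G == 1).astype(float)
    return region.G


def build_design(
    region: Region, fit: NullModelFit, label: str, cfg: TestConfig | None = None
):
    """Whitened tested design for one region/model.

    Returns ``(Z, kept, W, K_G, K_beta, saturated)`` where Z is the
    whitened G W restricted to a full-rank column subset chosen by
    pivoted QR (tolerance 1e-8 x leading singular value) and ``kept``
    are the retained column indices of G W.
    """
    cfg = cfg or TestConfig()
    G = _effective_G(region, cfg)
    if np.all(np.ptp(G, axis=0) == 0):
        raise ValueError("monomorphic region")
    W, K_G, K_B, saturated = region_W(region, label, cfg)
    GW = G @ W
    Z = whiten(fit, GW)
    kept = full_rank_columns(Z)
    return Z[:, kept], kept, W, K_G, K_B, saturated


def full_rank_columns(Z: np.ndarray) -> np.ndarray:
    """Column subset of Z spanning its column space (pivoted QR order)."""
    s = np.linalg.svd(Z, compute_uv=False)
    r = int(np.sum(s > _RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
    if r == 0:
        raise ValueError("monomorphic region")
    _, _, piv = qr_pivoted(Z, mode="economic", pivoting=True)
    return np.sort(piv[:r])


def test_region(
    y,
    X,
    region: Region,
    fit: NullModelFit,
    label: str = "0-F",
    cfg: TestConfig | None = None,
) -> RegionalTestResult:
    """F, LRT and score tests of beta_F = 0 for one region.

    alpha and Omega are held at the null fit; beta_F is the GLS estimate
    (W'G'Omega^-1 G W)^-1 W'G'Omega^-1 (y - X alpha), computed on the
    whitened design.  Single-variant regions get the saturated (Wald)
    test of the lone dosage.
    """
    cfg = cfg or TestConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = fit.n
    Zr, kept, W, K_G, K_B, saturated = build_design(region, fit, label, cfg)
    r = Zr.shape[1]

    z0 = whiten(fit, y - X @ fit.alpha)
    Xw = whiten(fit, X)
    RSS0 = float(z0 @ z0)

    Zfit = Zr
    if cfg.project_covariates:
        Zfit = Zr - Xw @ np.linalg.solve(Xw.T @ Xw, Xw.T @ Zr)
    A = Zfit.T @ Zfit
    b = Zfit.T @ z0
    beta = np.linalg.solve(A, b)
    resid = z0 - Zfit @ beta
    RSS1 = float(resid @ resid)

    df1 = r
    df2 = n - r - 1 - (fit.c if cfg.df_subtract_covariates else 0)
    if df2 <= 0:
        raise ValueError("region too large for sample")
    F = ((RSS0 - RSS1) / df1) / (RSS1 / df2)
    p_F = float(stats.f.sf(F, df1, df2))

    if cfg.lrt_refit:
        alt = fit_null(y, np.column_stack([X, region.G @ W]), fit.eigen,
                       reml=fit.reml)
        LRT = 2.0 * (alt.loglik - fit.loglik)
    else:
        LRT = n * np.log(RSS0 / RSS1)
    p_LRT = float(stats.chi2.sf(LRT, df1))

    # score statistic with the alpha-estimation projection (when the F
    # design is already projected, A is exactly the projected variance)
    if cfg.project_covariates:
        V = A
    else:
        C = Zr.T @ Xw
        V = A - C @ np.linalg.solve(Xw.T @ Xw, C.T)
    score = float(b @ np.linalg.solve(V, b))
    p_score = float(stats.chi2.sf(score, df1))

    note = ""
    if region.m == 1:
        note = "m1-wald"
    elif saturated:
        note = "saturated"

    return RegionalTestResult(
        region=region.name,
        model=label,
        m=region.m,
        K_G=K_G,
        K_beta=K_B,
        rank=r,
        beta_F=beta,
        RSS0=RSS0,
        RSS1=RSS1,
        F_stat=float(F),
        df1=df1,
        df2=df2,
        p_F=p_F,
        LRT_stat=float(LRT),
        p_LRT=p_LRT,
        score_stat=score,
        p_score=p_score,
        note=note,
    )


RESULT_COLUMNS = [
    "region", "m", "model", "K_G", "K_beta", "rank",
    "F", "df1", "df2", "p_F", "LRT", "p_LRT", "score", "p_score", "note",
]


def run_genome(
    regions: list[Region],
    y,
    X,
    R: RelationshipMatrix | np.ndarray,
    cfg: TestConfig | None = None,
    fit: NullModelFit | None = None,
    log=None,
) -> pd.DataFrame:
    """Test every region under every configured model.

    The null model is fitted once and shared.  Per-region failures are
    recorded as NA rows (with the reason in ``note``) and the run
    continues.
    """
    cfg = cfg or TestConfig()
    if fit is None:
        fit = fit_null(y, X, R)
    rows = []
    for region in regions:
        for label in cfg.models:
            try:
                res = test_region(y, X, region, fit, label, cfg)
                rows.append({
                    "region": res.region, "m": res.m, "model": label,
                    "K_G": res.K_G, "K_beta": res.K_beta, "rank": res.rank,
                    "F": res.F_stat, "df1": res.df1, "df2": res.df2,
                    "p_F": res.p_F, "LRT": res.LRT_stat, "p_LRT": res.p_LRT,
                    "score": res.score_stat, "p_score": res.p_score,
                    "note": res.note,
                })
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append({
                    "region": region.name, "m": region.m, "model": label,
                    "note": f"error: {exc}",
                })
                if log is not None:
                    log.warning("region %s (%s) failed: %s", region.name, label, exc)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def region_from_dosages(name, dosages, positions, variant_ids=None, impute=True) -> Region:
    """Build a Region from an n x m dosage array and raw coordinates.

    Missing entries (NaN) are imputed to the variant mean dosage; columns
    are reordered by position; dosages are flipped where needed so the
    counted allele is the minor one.
    """
    G = np.array(dosages, dtype=float)
    positions = np.asarray(positions, dtype=float)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    G = G[:, order]
    if variant_ids is None:
        variant_ids = [f"{name}_v{i}" for i in range(G.shape[1])]
    else:
        variant_ids = [variant_ids[i] for i in order]
    if impute and np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = mu[idx[1]]
    freq = G.mean(axis=0) / 2.0
    flip = freq > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    mafs = np.minimum(freq, 1.0 - freq)
    return Region(
        name=name,
        variant_ids=list(variant_ids),
        positions=scale_positions(positions),
        G=G,
        mafs=mafs,
    )
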