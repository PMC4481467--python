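"""Basis systems on [0,1] for functional smoothing of genotypes and effects.

Two families are supported: cubic B-splines with equally spaced interior
knots, and the orthonormal Fourier system {1, sqrt(2) sin(2*pi*k*t),
sqrt(2) cos(2*pi*k*t)}.  A basis system plays either of two roles in the
regional model: smoothing the genotype rows into genetic variant functions
(GVF) or smoothing the per-variant effect curve (BSF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

SPLINE_ORDER = 4  # cubic


@dataclass(frozen=True)
class BasisSystem:
    """A family of K basis functions on [0,1].

    Parameters
    ----------
    family : {"bspline", "fourier"}
    K : int
        Number of basis functions.  Fourier requires K odd (constant plus
        (K-1)/2 sine/cosine pairs); B-spline requires K >= 4 (cubic order).
    """

    family: str
    K: int
    order: int = SPLINE_ORDER

    def __post_init__(self) -> None:
        if self.family not in ("bspline", "fourier"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.family == "fourier":
            if self.K < 1 or self.K % 2 == 0:
                raise ValueError("Fourier basis requires odd K >= 1")
        else:
            if self.K < self.order:
                raise ValueError(f"B-spline basis requires K >= {self.order}")

    @property
    def knots(self) -> np.ndarray:
        """Full knot vector (B-spline only): repeated boundary knots plus
        K - order equally spaced interior knots."""
        if self.family != "bspline":
            raise AttributeError("knots only defined for B-spline systems")
        interior = np.linspace(0.0, 1.0, self.K - self.order + 2)[1:-1]
        return np.concatenate(
            [np.zeros(self.order), interior, np.ones(self.order)]
        )

    @property
    def breakpoints(self) -> np.ndarray:
        """Partition of [0,1] on which the basis is piecewise smooth."""
        if self.family == "bspline":
            return np.linspace(0.0, 1.0, self.K - self.order + 2)
        return np.array([0.0, 1.0])


@dataclass(frozen=True)
class ScaledPositions:
    """Physical variant coordinates mapped affinely onto [0,1].

    ``scaled`` is strictly increasing; exact duplicates in ``raw`` are
    separated after mapping (see :func:`scale_positions`).
    """

    raw: np.ndarray
    scaled: np.ndarray

    def __len__(self) -> int:
        return len(self.scaled)


@dataclass
class BasisMatrices:
    """Evaluation and transition matrices for one region.

    W maps the BSF coefficients beta_F onto per-variant effects:
    beta = W beta_F.  With a GVF basis, W = Phi (Phi' Phi)^-1 W2 where
    W2 = int_0^1 phi(t) psi(t)' dt; without one (BSF-only models) W = Psi.
    """

    Phi: np.ndarray | None
    Psi: np.ndarray
    W2: np.ndarray | None
    W1: np.ndarray | None
    W: np.ndarray = field(default=None)  # type: ignore[assignment]


def scale_positions(raw) -> ScaledPositions:
    """Map base-pair coordinates affinely onto [0,1].

    The map is t -> (t - t_1) / (t_m - t_1).  A single variant maps to 0.5.
    Runs of exactly duplicated coordinates are spread evenly between the
    neighbouring distinct scaled values so the result is strictly
    increasing (the first and last scaled values stay at 0 and 1).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("empty region")
    if np.any(np.diff(raw) < 0):
        raise ValueError("positions must be sorted non-decreasing")
    m = raw.size
    if m == 1:
        return ScaledPositions(raw=raw, scaled=np.array([0.5]))
    span = raw[-1] - raw[0]
    if span == 0:
        # all variants share one coordinate: no affine map exists
        return ScaledPositions(raw=raw, scaled=np.linspace(0.0, 1.0, m))
    scaled = (raw - raw[0]) / span
    scaled = _resolve_ties(scaled)
    return ScaledPositions(raw=raw, scaled=scaled)


def _resolve_ties(scaled: np.ndarray) -> np.ndarray:
    """Spread runs of equal scaled values evenly between their neighbours."""
    out = scaled.copy()
    m = out.size
    i = 0
    while i < m:
        j = i
        while j + 1 < m and scaled[j + 1] == scaled[i]:
            j += 1
        k = j - i + 1
        if k > 1:
            v = scaled[i]
            left = out[i - 1] if i > 0 else v
            right = scaled[j + 1] if j + 1 < m else v
            if i == 0:
                # run starts the region: keep 0, step toward the next value
                out[i : j + 1] = left + (right - left) * np.arange(k) / k
            elif j + 1 == m:
                # run ends the region: keep 1, step back from it
                out[i : j + 1] = v - (v - left) * np.arange(k - 1, -1, -1) / k
            else:
                out[i : j + 1] = left + (right - left) * np.arange(1, k + 1) / (
                    k + 1
                )
        i = j + 1
    if np.any(np.diff(out) <= 0):  # pragma: no cover - defensive
        raise ValueError("could not resolve duplicate positions")
    return out


def eval_basis(sys: BasisSystem, t) -> np.ndarray:
    """Evaluate all K basis functions at points t in [0,1].

    Returns a |t| x K matrix.  Fourier columns are ordered
    [1, sqrt(2) sin(2 pi t), sqrt(2) cos(2 pi t), sqrt(2) sin(4 pi t), ...].
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t < 0) | (t > 1)):
        raise ValueError("evaluation points must lie in [0,1]")
    if sys.family == "fourier":
        out = np.empty((t.size, sys.K))
        out[:, 0] = 1.0
        for k in range(1, (sys.K - 1) // 2 + 1):
            out[:, 2 * k - 1] = np.sqrt(2.0) * np.sin(2 * np.pi * k * t)
            out[:, 2 * k] = np.sqrt(2.0) * np.cos(2 * np.pi * k * t)
        return out
    M = BSpline.design_matrix(t, sys.knots, sys.order - 1).toarray()
    return M


def cross_integral(sysG: BasisSystem, sysB: BasisSystem) -> np.ndarray:
    """Gram-type matrix int_0^1 phi(t) psi(t)' dt between two systems.

    Computed by composite Gauss-Legendre quadrature on the union of the
    two systems' breakpoint partitions with 20 nodes per piece: exact for
    the polynomial pieces and far below double precision for the
    trigonometric factors at the K values used here.
    """
    pieces = [sysG.breakpoints, sysB.breakpoints]
    # keep at most ~one oscillation of the product per piece so 20-node
    # Gauss-Legendre resolves the trigonometric factors to machine precision
    cycles = sum((s.K - 1) // 2 for s in (sysG, sysB) if s.family == "fourier")
    if cycles:
        pieces.append(np.linspace(0.0, 1.0, cycles + 2))
    breaks = np.unique(np.concatenate(pieces))
    nodes, weights = leggauss(20)
    xs = []
    ws = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        xs.append(0.5 * (a + b) + half * nodes)
        ws.append(half * weights)
    x = np.concatenate(xs)
    w = np.concatenate(ws)
    PhiX = eval_basis(sysG, x)
    PsiX = eval_basis(sysB, x)
    return PhiX.T @ (w[:, None] * PsiX)


def build_basis_matrices(
    sysG: BasisSystem | None, sysB: BasisSystem, pos: ScaledPositions
) -> BasisMatrices:
    """Assemble Phi, Psi and the transition matrix W for one region.

    With a GVF system, W = Phi (Phi' Phi)^-1 W2 (an m x K_beta matrix);
    for BSF-only models (no genotype smoothing) W = Psi.  Effective basis
    counts must already satisfy m >= K_G >= K_beta.
    """
    t = pos.scaled
    Psi = eval_basis(sysB, t)
    if sysG is None:
        return BasisMatrices(Phi=None, Psi=Psi, W2=None, W1=None, W=Psi)
    Phi = eval_basis(sysG, t)
    PtP = Phi.T @ Phi
    # Phi must have full column rank at these positions
    if np.linalg.cond(PtP) > 1e12:
        raise ValueError("GVF basis rank-deficient at these positions")
    W1 = np.linalg.solve(PtP, Phi.T).T
    W2 = cross_integral(sysG, sysB)
    return BasisMatrices(Phi=Phi, Psi=Psi, W2=W2, W1=W1, W=W1 @ W2)
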