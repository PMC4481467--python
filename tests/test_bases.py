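"""Basis construction: position scaling, evaluation, cross-integrals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import comb

from funlmm import (
    BasisSystem,
    build_basis_matrices,
    cross_integral,
    eval_basis,
    scale_positions,
)


# --- independent oracles ---------------------------------------------------

def deboor_basis(t, knots, order):
    """Cox-de Boor recursion, written independently of scipy."""
    nb = len(knots) - order
    vals = np.zeros(nb)
    # degree 0
    B = np.zeros(len(knots) - 1)
    for i in range(len(knots) - 1):
        if knots[i] <= t < knots[i + 1]:
            B[i] = 1.0
    if t == knots[-1]:  # right-closed convention at the last interval
        for i in range(len(knots) - 2, -1, -1):
            if knots[i] < knots[i + 1]:
                B[i] = 1.0
                break
    for k in range(1, order):
        Bn = np.zeros(len(knots) - k - 1)
        for i in range(len(Bn)):
            left = 0.0
            if knots[i + k] > knots[i]:
                left = (t - knots[i]) / (knots[i + k] - knots[i]) * B[i]
            right = 0.0
            if knots[i + k + 1] > knots[i + 1]:
                right = (knots[i + k + 1] - t) / (
                    knots[i + k + 1] - knots[i + 1]
                ) * B[i + 1]
            Bn[i] = left + right
        B = Bn
    vals[:] = B[:nb]
    return vals


# --- scale_positions -------------------------------------------------------

def test_scale_positions_affine():
    assert np.allclose(scale_positions([100, 150, 200]).scaled, [0, 0.5, 1])


def test_scale_positions_single_variant_midpoint():
    assert scale_positions([7]).scaled.tolist() == [0.5]


def test_scale_positions_duplicates_resolved():
    s = scale_positions([0, 0, 10]).scaled
    assert s[0] == 0 and s[-1] == 1
    assert 0 < s[1] < 1
    assert np.all(np.diff(s) > 0)


def test_scale_positions_duplicate_run_at_end():
    s = scale_positions([0, 5, 10, 10]).scaled
    assert s[-1] == 1 and np.all(np.diff(s) > 0)


def test_scale_positions_all_equal_spread_evenly():
    assert np.allclose(scale_positions([5, 5, 5]).scaled, [0, 0.5, 1])


def test_scale_positions_errors():
    with pytest.raises(ValueError, match="empty"):
        scale_positions([])
    with pytest.raises(ValueError, match="sorted"):
        scale_positions([10, 5])


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.lists(st.integers(0, 10**6), min_size=2, max_size=40))
def test_scale_positions_strictly_increasing_unit_interval(raw):
    raw = sorted(raw)
    if raw[0] == raw[-1]:
        raw[-1] = raw[0] + 1
    s = scale_positions(raw).scaled
    assert s[0] == 0.0 and s[-1] == 1.0
    assert np.all(np.diff(s) > 0)
    assert np.all((s >= 0) & (s <= 1))


# --- eval_basis ------------------------------------------------------------

def test_fourier_constant_basis():
    assert np.allclose(eval_basis(BasisSystem("fourier", 1), [0.3]), [[1.0]])


def test_fourier_k3_at_zero():
    row = eval_basis(BasisSystem("fourier", 3), [0.0])[0]
    assert np.allclose(row, [1.0, 0.0, math.sqrt(2)])


def test_fourier_even_K_rejected():
    with pytest.raises(ValueError):
        BasisSystem("fourier", 4)


def test_bspline_below_order_rejected():
    with pytest.raises(ValueError):
        BasisSystem("bspline", 3)


def test_eval_outside_domain_rejected():
    with pytest.raises(ValueError):
        eval_basis(BasisSystem("fourier", 3), [1.2])


def test_bspline_partition_of_unity():
    sys = BasisSystem("bspline", 15)
    t = np.random.default_rng(0).random(1000)
    M = eval_basis(sys, t)
    assert np.max(np.abs(M.sum(axis=1) - 1.0)) < 1e-12


@pytest.mark.parametrize("K", [4, 7, 15])
def test_bspline_matches_deboor_recursion(K):
    sys = BasisSystem("bspline", K)
    ts = np.linspace(0, 1, 23)
    M = eval_basis(sys, ts)
    for i, t in enumerate(ts):
        assert np.allclose(M[i], deboor_basis(t, sys.knots, 4), atol=1e-12)


# --- cross_integral --------------------------------------------------------

@pytest.mark.parametrize("K", [1, 3, 9, 15, 25])
def test_fourier_orthonormal(K):
    sys = BasisSystem("fourier", K)
    assert np.max(np.abs(cross_integral(sys, sys) - np.eye(K))) < 1e-10


def test_bernstein_gram_closed_form():
    # K=4, no interior knots: cubic Bernstein polynomials;
    # int B_i B_j = C(3,i) C(3,j) / (7 C(6, i+j))
    sys = BasisSystem("bspline", 4)
    G = cross_integral(sys, sys)
    expect = np.array(
        [[comb(3, i) * comb(3, j) / (7 * comb(6, i + j)) for j in range(4)]
         for i in range(4)]
    )
    assert np.allclose(G, expect, atol=1e-12)


@pytest.mark.parametrize(
    "famG,KG,famB,KB",
    [("bspline", 6, "bspline", 5), ("bspline", 15, "fourier", 9),
     ("fourier", 11, "bspline", 7), ("fourier", 15, "fourier", 13)],
)
def test_cross_integral_against_adaptive_quadrature(famG, KG, famB, KB):
    sysG, sysB = BasisSystem(famG, KG), BasisSystem(famB, KB)
    W2 = cross_integral(sysG, sysB)
    rng = np.random.default_rng(1)
    for _ in range(6):  # spot-check random entries with an adaptive oracle
        i, j = rng.integers(KG), rng.integers(KB)
        val, _ = quad(
            lambda t: eval_basis(sysG, [t])[0, i] * eval_basis(sysB, [t])[0, j],
            0, 1, limit=400, epsabs=1e-12, epsrel=1e-12,
        )
        assert abs(W2[i, j] - val) < 1e-10


# --- build_basis_matrices --------------------------------------------------

def test_bsf_only_uses_psi():
    pos = scale_positions([10, 20, 30, 40, 50])
    bm = build_basis_matrices(None, BasisSystem("fourier", 3), pos)
    assert np.allclose(bm.W, eval_basis(BasisSystem("fourier", 3), pos.scaled))


def test_w_shape_contract():
    pos = scale_positions(np.arange(10) * 7 + 3)
    bm = build_basis_matrices(
        BasisSystem("fourier", 9), BasisSystem("bspline", 4), pos
    )
    assert bm.W.shape == (10, 4)
    assert bm.W1.shape == (10, 9) and bm.W2.shape == (9, 4)


def test_w_invariant_to_raw_position_scale():
    # Fourier is periodic so K_G is kept below m (rows at t=0 and t=1 coincide)
    raw = np.array([100, 180, 300, 420, 700, 950, 1000])
    sysB = BasisSystem("bspline", 5)
    sysG = BasisSystem("fourier", 5)
    W1 = build_basis_matrices(sysG, sysB, scale_positions(raw)).W
    W2 = build_basis_matrices(sysG, sysB, scale_positions(13 * raw + 10**6)).W
    assert np.allclose(W1, W2, atol=1e-12)


def test_gvf_rank_deficient_positions_error():
    # all points in the left quarter: right-end spline functions vanish
    from funlmm.bases import ScaledPositions

    pos = ScaledPositions(raw=np.arange(8.0), scaled=np.linspace(0, 0.2, 8))
    with pytest.raises(ValueError, match="rank-deficient"):
        build_basis_matrices(BasisSystem("bspline", 8), BasisSystem("bspline", 4), pos)
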