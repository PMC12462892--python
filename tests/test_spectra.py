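"""Eigen-spectra, Betti numbers, T/C/N split and spectral curves."""

import numpy as np
import pytest
import scipy.sparse as sp

from phl import (GridComplex, ball, build_bundle, betti_numbers,
                 betti_numbers_ff, component_count, four_ball_model, gf2_rank,
                 kernel_dimension, lambda1_tcn, smallest_spectrum, solid_torus,
                 spectral_curves, tnc_split, union)
from phl.spectra import lambda_max_estimate, zero_threshold
from tests.conftest import grid_about


def test_smallest_spectrum_matches_dense_oracle():
    g = GridComplex((3, 3, 3), 1.0)
    b = build_bundle(g, ball(radius=9.0), 0.0, variant="big")  # full support
    for k in range(4):
        s = smallest_spectrum(b.L[k], 10, k, "normal", "big")
        dense = np.sort(np.linalg.eigvalsh(b.L[k].toarray()))[:10]
        assert np.allclose(s.eigenvalues, dense, atol=1e-10)


def test_duplicated_disjoint_shape_doubles_multiplicity():
    f2 = union(ball(center=(-2, 0, 0), radius=0.8), ball(center=(2, 0, 0), radius=0.8))
    g = grid_about(3.1, 0.3)
    b = build_bundle(g, f2, 0.0, variant="big")
    vals = np.sort(np.linalg.eigvalsh(b.L[3].toarray()))
    # block-diagonal over two congruent components: even multiplicities
    assert len(vals) % 2 == 0
    assert np.allclose(vals[0::2], vals[1::2], atol=1e-8)
    assert tuple(betti_numbers(b)) == (2, 0, 0)


def test_empty_operator_yields_empty_summary():
    s = smallest_spectrum(sp.csr_matrix((0, 0)), 5)
    assert s.eigenvalues.size == 0 and s.zero_multiplicity == 0
    assert np.isnan(s.lambda1)


@pytest.mark.parametrize("fixture,expected", [
    ("ball_grid", (1, 0, 0)),
    ("torus_grid", (1, 1, 0)),
])
def test_betti_numbers_known_topologies(request, fixture, expected):
    g, f = request.getfixturevalue(fixture)
    b = build_bundle(g, f, 0.0, variant="big")
    assert tuple(betti_numbers(b, method="eigen")) == expected
    assert betti_numbers_ff(b) == expected
    assert component_count(b) == expected[0]


def test_four_ball_before_merge(four_ball_grid):
    g, f = four_ball_grid
    b = build_bundle(g, f, 0.15, variant="big")
    assert tuple(betti_numbers(b)) == (4, 0, 0)
    assert component_count(b) == 4


def test_betti_eigen_and_rank_paths_agree_on_hodge(ball_grid):
    g, f = ball_grid
    b = build_bundle(g, f, 0.1, variant="hodge")
    assert tuple(betti_numbers(b, method="eigen")) == betti_numbers_ff(b) == (1, 0, 0)


def test_gf2_rank_matches_dense_rank():
    rng = np.random.default_rng(11)
    for _ in range(5):
        nr, nc = rng.integers(4, 30, 2)
        M = sp.random(nr, nc, density=0.25, random_state=int(rng.integers(1e6)),
                      data_rvs=lambda n: np.ones(n))
        dense = M.toarray() % 2
        # dense GF(2) elimination oracle
        A = dense.astype(np.uint8).copy()
        rank = 0
        for c in range(nc):
            piv = next((r for r in range(rank, nr) if A[r, c]), None)
            if piv is None:
                continue
            A[[rank, piv]] = A[[piv, rank]]
            for r in range(nr):
                if r != rank and A[r, c]:
                    A[r] ^= A[rank]
            rank += 1
        assert gf2_rank(M) == rank


def test_l1_spectrum_decomposes_into_n_union_c(ball_grid):
    """spectrum(Lbar_1) \\ {0} equals N u C as multisets (small dense case)."""
    g = grid_about(1.3, 0.35)
    b = build_bundle(g, ball(radius=1.0), 0.0, variant="big")
    split = tnc_split(b.Dbar[0], b.Dbar[1], b.Dbar[2])
    vals = np.sort(np.linalg.eigvalsh(b.L[1].toarray()))
    tol = zero_threshold(vals[-1])
    nonzero = vals[vals >= tol]
    merged = np.sort(np.concatenate([split.N, split.C]))
    assert len(nonzero) == len(merged)
    assert np.abs(nonzero - merged).max() < 1e-8


def test_l2_spectrum_decomposes_into_t_union_c(ball_grid):
    g = grid_about(1.3, 0.35)
    b = build_bundle(g, ball(radius=1.0), 0.0, variant="big")
    split = tnc_split(b.Dbar[0], b.Dbar[1], b.Dbar[2])
    vals = np.sort(np.linalg.eigvalsh(b.L[2].toarray()))
    tol = zero_threshold(vals[-1])
    nonzero = vals[vals >= tol]
    merged = np.sort(np.concatenate([split.T, split.C]))
    assert len(nonzero) == len(merged)
    assert np.abs(nonzero - merged).max() < 1e-8


def test_lambda1_tcn_consistent_with_dense_split():
    g = grid_about(1.3, 0.3)
    b = build_bundle(g, ball(radius=1.0), 0.0, variant="big")
    split = tnc_split(b.Dbar[0], b.Dbar[1], b.Dbar[2])
    l1T, l1C, l1N = lambda1_tcn(b)
    assert l1T == pytest.approx(split.lambda1T, rel=1e-6)
    assert l1C == pytest.approx(split.lambda1C, rel=1e-6)
    assert l1N == pytest.approx(split.lambda1N, rel=1e-6)


def test_ball_lambda1N_converges_to_dirichlet_eigenvalue():
    """lambda1N / l^2 of the unit ball approaches pi^2 (first Dirichlet
    eigenvalue), with the error decreasing under refinement."""
    errs = []
    for l in (1 / 8, 1 / 16):
        g = grid_about(1.0 + 4 * l, l)
        b = build_bundle(g, ball(radius=1.0), 0.0, variant="big")
        s = smallest_spectrum(b.L[0], 4, 0, "normal", "big")
        lam = s.eigenvalues[0] / l ** 2   # kernel is empty at degree 0
        assert s.zero_multiplicity == 0
        errs.append(abs(lam - np.pi ** 2) / np.pi ** 2)
    assert errs[1] < 0.10
    assert errs[1] < errs[0]


def test_eigenvalue_nonnegativity(torus_grid):
    g, f = torus_grid
    b = build_bundle(g, f, 0.1, variant="big")
    for k in range(4):
        s = smallest_spectrum(b.L[k], 6, k, "normal", "big")
        lmax = lambda_max_estimate(b.L[k])
        assert s.eigenvalues.min() >= -1e-9 * max(lmax, 1.0)


def test_spectral_curves_ball_constant(ball_grid):
    g, f = ball_grid
    df = spectral_curves(f, g, [-0.1, 0.0, 0.1, 0.2], variant="big",
                         compute_lambdas=False)
    assert list(df.beta0) == [1, 1, 1, 1]
    assert list(df.beta1) == [0, 0, 0, 0]
    assert list(df.beta2) == [0, 0, 0, 0]
    with pytest.raises(ValueError):
        spectral_curves(f, g, [0.2, 0.1], variant="big")


def test_torus_filtration_beta1_and_lambda1C_drop():
    """beta1 drops 1 -> 0 at tunnel closure with a simultaneous drop in
    lambda1C (the freed curl eigenvalue is small)."""
    f = solid_torus(major_radius=1.2, minor_radius=0.6)   # hole closes at c=0.6
    g = grid_about(2.75, 0.22)
    df = spectral_curves(f, g, [0.05, 0.2, 0.5], variant="big", n_eigs=30)
    assert list(df.beta1) == [1, 1, 0]
    # after closure the dying harmonic 1-form becomes a small curl eigenvalue
    assert df.lambda1C.iloc[2] < 0.5 * df.lambda1C.iloc[1]
    assert list(df.beta0) == [1, 1, 1]
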