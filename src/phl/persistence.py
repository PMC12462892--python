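"""Filtrations, discrete harmonic extension and persistent Laplacians.

A filtration is the nested family of normal-support sub-complexes
K_0 c K_1 c ... c K_s obtained by sweeping the isovalue of a level-set
function.  A k-form on K_l is carried to K_{l+p} by the harmonic extension
I_{l,p}: values on cells of K_l pass through unchanged, while values on
the new cells of the difference region are d(zeta) for a (k-1)-form zeta
solving the Laplace system on the new (k-1)-cells, driven by the boundary
codifferential of the level-l form:

    Ltilde_{k-1} zeta = - S_{k-1} delta_{dK_l} omega,

solved as a minimum-norm least-squares problem (the interior operator may
be rank-deficient when the difference region carries topology).  At k = 0
no lower-degree potential exists and the extension is the plain harmonic
(Dirichlet) extension of vertex values.

The p-persistent Laplacian on k-forms of K_l combines the persistent
down-term (codifferential through the extension, with its adjoint) and the
ordinary level-l up-term; in symmetrized form

    L^k_{l,p} = B B^T + Dbar_l^k^T Dbar_l^k,
    B = S_{k,l}^{-1/2} I^T S_{k,l+p} D^{k-1}_{l+p} S_{k-1,l+p}^{-1/2},

which is symmetric positive semidefinite by construction and reduces
exactly to the ordinary level-l operator at p = 0.  Its kernel dimension
counts the cohomology classes of K_l that survive to K_{l+p}.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .grid import GridComplex
from .fields import ScalarField
from .laplacians import LaplacianBundle, build_bundle
from .spectra import kernel_dimension

__all__ = ["Filtration", "ExtensionOperator", "PersistentLaplacian",
           "build_filtration", "extension_operator", "persistent_laplacian",
           "persistent_betti", "persistent_component_count"]

_DENSE_SOLVE_CAP = 6000     # max difference-region unknowns for the dense solve
_LSTSQ_RCOND = 1e-10


@dataclass
class Filtration:
    """Nested normal-support complexes over strictly increasing isovalues."""

    complex: GridComplex
    field: ScalarField
    isovalues: np.ndarray
    _bundles: dict = dc_field(default_factory=dict)
    _extensions: dict = dc_field(default_factory=dict)

    def __len__(self):
        return len(self.isovalues)

    def bundle(self, l: int, variant: str = "big") -> LaplacianBundle:
        key = (int(l), variant)
        if key not in self._bundles:
            self._bundles[key] = build_bundle(
                self.complex, self.field, float(self.isovalues[l]),
                bc="normal", variant=variant)
        return self._bundles[key]

    def kept(self, l: int, k: int) -> np.ndarray:
        return self.bundle(l).mask.kept[k]

    def new_cells(self, l: int, lp: int, k: int) -> np.ndarray:
        """Grid ids of k-cells in K_{lp} but not K_l (the difference region)."""
        lo = self.bundle(l).mask.masks[k]
        hi = self.bundle(lp).mask.masks[k]
        return np.flatnonzero(hi & ~lo)


def build_filtration(complex: GridComplex, field: ScalarField, isovalues) -> Filtration:
    """Build and verify a nested filtration of normal supports."""
    iso = np.asarray(list(isovalues), float)
    if len(iso) == 0:
        raise ValueError("at least one isovalue required")
    if len(iso) > 1 and not (np.diff(iso) > 0).all():
        raise ValueError("isovalues must be strictly increasing")
    filt = Filtration(complex, field, iso)
    for l in range(len(iso) - 1):
        for k in range(4):
            lo = filt.bundle(l).mask.masks[k]
            hi = filt.bundle(l + 1).mask.masks[k]
            if (lo & ~hi).any():
                raise AssertionError(
                    f"support nesting violated at level {l}->{l + 1}, degree {k}")
    return filt


@dataclass
class ExtensionOperator:
    """Harmonic extension I_{l,p} of discrete k-forms from K_l to K_{l+p}.

    ``matrix`` maps compact level-l k-forms to compact level-(l+p) k-forms;
    rows of cells already in K_l are the identity, rows of new cells carry
    the dense harmonic fill-in.  ``solve_residual`` is the relative residual
    of the interior least-squares solve.
    """

    l: int
    p: int
    degree: int
    variant: str
    matrix: sp.csr_matrix
    solve_residual: float
    n_new: int


def _restrict(M: sp.spmatrix, rows: np.ndarray, cols: np.ndarray) -> sp.csr_matrix:
    return M[rows][:, cols].tocsr()


def _min_norm_solve(A: sp.spmatrix, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares solve A Z = B for symmetric PSD A (possibly singular).

    The extension only consumes d(zeta), which is identical for every
    least-squares solution (solutions differ by ker A = ker of the
    difference-region differential), so a rank-revealing QR solve suffices;
    the pseudo-inverse (minimum-norm) path is the fallback.
    """
    from scipy.linalg import lstsq as dense_lstsq

    n = A.shape[0]
    if n == 0:
        return np.zeros((0, B.shape[1])), 0.0
    if n > _DENSE_SOLVE_CAP:
        raise ValueError(
            f"difference region has {n} unknowns (> {_DENSE_SOLVE_CAP}); refine the "
            "isovalue sequence so the difference complexes stay small")
    Ad = A.toarray() if sp.issparse(A) else np.asarray(A)
    try:
        Z = dense_lstsq(Ad, B, cond=_LSTSQ_RCOND, lapack_driver="gelsy")[0]
    except Exception:  # pragma: no cover - LAPACK driver fallback
        Z = np.linalg.lstsq(Ad, B, rcond=_LSTSQ_RCOND)[0]
    res = float(np.linalg.norm(Ad @ Z - B) / max(np.linalg.norm(B), 1e-300))
    return Z, res


def extension_operator(filt: Filtration, l: int, p: int, k: int,
                       variant: str = "big",
                       construction: str = "direct") -> ExtensionOperator:
    """Build the discrete harmonic extension I_{l,p} at degree k.

    ``construction="direct"`` (canonical) solves one Laplace system on the
    difference complex K_{l,l+p}; ``"composed"`` chains the one-step
    extensions I_{l+p-1,1} o ... o I_{l,1}, which keeps each interior solve
    small when the levels are finely spaced.  The two need not agree
    exactly; their difference is a reportable diagnostic, not an assertion.
    """
    if construction not in ("direct", "composed"):
        raise ValueError(f"unknown construction {construction!r}")
    key = (int(l), int(p), int(k), variant, construction)
    cached = filt._extensions.get(key)
    if cached is not None:
        return cached
    ext = _build_extension(filt, l, p, k, variant, construction)
    filt._extensions[key] = ext
    return ext


def _build_extension(filt: Filtration, l: int, p: int, k: int,
                     variant: str, construction: str) -> ExtensionOperator:
    if construction == "composed" and p > 1:
        step = extension_operator(filt, l, 1, k, variant)
        I, res = step.matrix, step.solve_residual
        n_new = step.n_new
        for q in range(1, p):
            step = extension_operator(filt, l + q, 1, k, variant)
            I = (step.matrix @ I).tocsr()
            res = max(res, step.solve_residual)
            n_new += step.n_new
        return ExtensionOperator(l, p, k, variant, I, res, n_new)
    s = len(filt) - 1
    if not (0 <= l and l + p <= s and p >= 0):
        raise ValueError(f"levels out of range: l={l}, p={p}, s={s}")
    if not 0 <= k <= 3:
        raise ValueError(f"degree must be 0..3, got {k}")
    bl, bh = filt.bundle(l, variant), filt.bundle(l + p, variant)
    gc = filt.complex
    kept_l, kept_h = bl.mask.kept[k], bh.mask.kept[k]
    nl, nh = len(kept_l), len(kept_h)
    ch = bh.mask.compact_index(k)
    rows_id = ch[kept_l]                       # positions of K_l cells in K_{l+p}
    I_id = sp.csr_matrix((np.ones(nl), (rows_id, np.arange(nl))), shape=(nh, nl))
    new_k = filt.new_cells(l, l + p, k)
    if p == 0 or len(new_k) == 0:
        return ExtensionOperator(l, p, k, variant, I_id, 0.0, 0)

    if k == 0:
        # Dirichlet harmonic extension of vertex values onto new vertices
        W = ch[new_k]
        L = bh.L[0]
        A = L[W][:, W]
        Bm = -(L[W][:, rows_id]).toarray()
        Z, res = _min_norm_solve(A, Bm)
        add = sp.coo_matrix(Z)
        I = (I_id + sp.csr_matrix((add.data, (W[add.row], add.col)), shape=(nh, nl))).tocsr()
        return ExtensionOperator(l, p, k, variant, I, res, len(new_k))

    # potential zeta lives on the new (k-1)-cells bounding new k-cells
    # (the difference complex Cl(K_{l+p} \ K_l) minus the dK_l interface)
    new_km1 = filt.new_cells(l, l + p, k - 1)
    cm1 = bh.mask.compact_index(k - 1)
    B_rows = ch[new_k]
    D = bh.D[k - 1]                            # level-(l+p) restricted differential
    Dnew = D[B_rows]                           # faces of the new k-cells
    is_new_km1 = np.zeros(D.shape[1], bool)
    is_new_km1[cm1[new_km1]] = True
    touched = np.zeros(D.shape[1], bool)
    touched[np.unique(Dnew.indices)] = True
    W = np.flatnonzero(is_new_km1 & touched)
    if len(W) == 0:
        return ExtensionOperator(l, p, k, variant, I_id, 0.0, len(new_k))
    if variant == "big":
        s_diag = np.ones(nh)
    else:
        s_diag = bh.S[k].entries
    # coclosedness of the extension at the new (k-1)-cells:
    #   G_B^T S_B (G_B zeta) = -G_A^T S_A omega,  new values = G_B zeta
    GB = Dnew[:, W]
    GA = D[rows_id][:, W]
    SB = sp.diags(s_diag[B_rows])
    SA = sp.diags(s_diag[rows_id])
    A = (GB.T @ SB @ GB).tocsr()
    rhs = -(GA.T @ SA).toarray()
    Z, res = _min_norm_solve(A, rhs)
    fill = GB @ Z                              # d(zeta) on the new k-cells
    add = sp.coo_matrix(fill)
    I = (I_id + sp.csr_matrix((add.data, (B_rows[add.row], add.col)),
                              shape=(nh, nl))).tocsr()
    return ExtensionOperator(l, p, k, variant, I, res, len(new_k))


def restriction_operator(filt: Filtration, ext: ExtensionOperator,
                         normalized: bool = True) -> np.ndarray:
    """Restriction R_{l,p} from level-(l+p) k-forms back to level l.

    ``normalized=True`` (default) returns the S-orthogonal projection onto
    the space of harmonic extensions followed by restriction,
    R = (I^T S I)^{-1} I^T S, which satisfies R I = Id exactly.  The raw
    adjoint-consistent operator S_l^{-1} I^T S_{l+p} (used inside the
    persistent Laplacian) is returned otherwise.
    """
    bh = filt.bundle(ext.l + ext.p, ext.variant)
    bl = filt.bundle(ext.l, ext.variant)
    k = ext.degree
    I = ext.matrix
    if ext.variant == "big":
        Sh = sp.identity(I.shape[0], format="csr")
        Sl_inv = sp.identity(I.shape[1], format="csr")
    else:
        Sh = bh.S[k].matrix().tocsr()
        Sl_inv = bl.S[k].power(-1.0).tocsr()
    raw = (Sl_inv @ I.T @ Sh)
    if not normalized:
        return np.asarray(raw.todense())
    G = (I.T @ Sh @ I).toarray()
    return np.linalg.solve(G, np.asarray((I.T @ Sh).todense()))


@dataclass
class PersistentLaplacian:
    """The symmetrized p-persistent Laplacian on k-forms of level l."""

    l: int
    p: int
    degree: int
    variant: str
    operator: sp.csr_matrix          # symmetric PSD, level-l compact k-forms
    extension: ExtensionOperator
    down_factor: sp.csr_matrix       # B with down-term B @ B.T
    up_factor: sp.csr_matrix         # Dbar_l^k with up-term D^T @ D


def persistent_laplacian(filt: Filtration, l: int, p: int, k: int,
                         variant: str = "big",
                         construction: str = "direct") -> PersistentLaplacian:
    """Assemble the p-persistent Hodge or BIG Laplacian L^k_{l,p}.

    The down-term factors through the harmonic extension
    (B = S_{k,l}^{-1/2} I^T S_{k,l+p} Dbar-weighted differential); at p = 0
    it reduces exactly to the ordinary level-l operator.
    """
    ext = extension_operator(filt, l, p, k, variant, construction)
    bl, bh = filt.bundle(l, variant), filt.bundle(l + p, variant)
    I = ext.matrix
    if k >= 1:
        if p == 0:
            # identity extension: the down-factor is the ordinary level-l
            # normalized differential (exact, no star round-trip)
            B = bl.Dbar[k - 1].tocsr()
        elif variant == "big":
            B = (I.T @ bh.D[k - 1]).tocsr()
        else:
            B = (bl.S[k].power(-0.5) @ I.T @ bh.S[k].matrix()
                 @ bh.D[k - 1] @ bh.S[k - 1].power(-0.5)).tocsr()
    else:
        B = sp.csr_matrix((bl.mask.num_kept(0), 0))
    up = bl.Dbar[k] if k <= 2 else sp.csr_matrix((0, bl.mask.num_kept(3)))
    L = (B @ B.T + up.T @ up).tocsr()
    return PersistentLaplacian(l, p, k, variant, L, ext, B, up)


def persistent_betti(filt: Filtration, l: int, p: int, k: int,
                     variant: str = "big", construction: str = "direct") -> int:
    """Kernel dimension of the p-persistent Laplacian (persistent Betti
    number beta_{3-k} from level l to level l+p under the normal bc)."""
    PL = persistent_laplacian(filt, l, p, k, variant, construction)
    if PL.operator.shape[0] == 0:
        return 0
    dim, _ = kernel_dimension(PL.operator)
    return dim


def persistent_component_count(filt: Filtration, l: int, p: int) -> int:
    """Union-find oracle for persistent beta0: the number of connected
    components of the kept 3-cells of K_{l+p} that contain at least one
    3-cell of K_l."""
    bh = filt.bundle(l + p)
    n3 = bh.num_dof(3)
    if n3 == 0:
        return 0
    D2 = bh.D[2]
    A = abs(D2) @ abs(D2).T
    A.setdiag(0)
    A.eliminate_zeros()
    _, labels = connected_components(A, directed=False)
    ch = bh.mask.compact_index(3)
    low = ch[filt.bundle(l).mask.kept[3]]
    return int(len(np.unique(labels[low])))
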