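"""Restricted differentials and degree-wise Hodge / BIG Laplacians.

Given a support mask, the restricted differential is
D_{k,bc} = P_{k+1} D_k P_k^T; nilpotency D_{k+1,bc} D_{k,bc} = 0 survives
the restriction.  Two operator families are assembled per boundary
condition:

* ``hodge`` — the star-weighted operator
  L_k = D_k^T S_{k+1} D_k + S_k D_{k-1} S_{k-1}^{-1} D_{k-1}^T S_k,
  held in its symmetrized form
  Lbar_k = Dbar_k^T Dbar_k + Dbar_{k-1} Dbar_{k-1}^T with
  Dbar_k = S_{k+1}^{1/2} D_k S_k^{-1/2}; eigenvalues equal the generalized
  eigenvalues of (L_k, S_k).
* ``big`` — the boundary-induced graph Laplacian: all stars replaced by
  the identity.  Its spectra converge to Hodge spectra up to the l^-2
  scaling under grid refinement.

Operators act on compact (kept-cell) indices; empty degrees yield empty
operators and propagate as "no spectrum" rather than errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grid import GridComplex
from .fields import ScalarField
from .supports import (SupportMask, StarDiagonal, classify_support, hodge_star,
                       perturb_values, DEFAULT_DEPTH)

__all__ = ["LaplacianBundle", "restricted_differentials", "assemble_laplacian",
           "symmetrize", "build_bundle", "save_operator"]


def restricted_differentials(complex: GridComplex, mask: SupportMask) -> dict[int, sp.csr_matrix]:
    """D_{k,bc} = P_{k+1} D_k P_k^T for k = 0, 1, 2, on compact indices."""
    out = {}
    for k in range(3):
        D = complex.incidence_matrix(k)
        out[k] = D[mask.kept[k + 1]][:, mask.kept[k]].tocsr()
    return out


def assemble_laplacian(Dbar: dict[int, sp.spmatrix], k: int) -> sp.csr_matrix:
    """Lbar_k = Dbar_k^T Dbar_k + Dbar_{k-1} Dbar_{k-1}^T, null terms dropped."""
    if not 0 <= k <= 3:
        raise ValueError(f"degree must be 0..3, got {k}")
    terms = []
    up = Dbar.get(k)
    if up is not None and up.shape[0] * up.shape[1] >= 0 and k <= 2:
        terms.append((up.T @ up).tocsr())
    down = Dbar.get(k - 1)
    if down is not None and k >= 1:
        terms.append((down @ down.T).tocsr())
    if not terms:
        raise ValueError(f"no differential available at degree {k}")
    L = terms[0]
    for t in terms[1:]:
        L = L + t
    return L.tocsr()


def symmetrize(L: sp.spmatrix, S: StarDiagonal):
    """Lbar = S^{-1/2} L S^{-1/2}; returns (Lbar, transform) with transform =
    S^{-1/2} so eigenvectors map back as W = transform @ Wbar.

    Eigenvalues of Lbar equal the generalized eigenvalues of (L, S).
    """
    if len(S.entries) and not (S.entries > 0).all():
        raise ValueError("star diagonal must be strictly positive")
    T = S.power(-0.5)
    return (T @ L @ T).tocsr(), T


@dataclass
class LaplacianBundle:
    """Differentials, stars and assembled Laplacians of one support.

    ``D[k]`` are the restricted raw differentials, ``S[k]`` the boundary-
    adjusted stars (None for the big variant), ``Dbar[k]`` the normalized
    differentials and ``L[k]`` the symmetric PSD Laplacians, all over
    compact kept-cell indices.
    """

    complex: GridComplex
    bc: str
    variant: str
    isovalue: float
    mask: SupportMask
    D: dict
    S: dict
    Dbar: dict
    L: dict

    @property
    def spacing(self) -> float:
        return self.complex.spacing

    def num_dof(self, k: int) -> int:
        return self.mask.num_kept(k)

    def raw_laplacian(self, k: int) -> sp.spmatrix:
        """The unsymmetrized star-weighted operator S^{1/2} Lbar S^{1/2}
        (equals Lbar itself for the big variant)."""
        if self.variant == "big":
            return self.L[k]
        H = self.S[k].power(0.5)
        return (H @ self.L[k] @ H).tocsr()


def build_bundle(complex: GridComplex, field: ScalarField, isovalue: float,
                 bc: str = "normal", variant: str = "big",
                 depth: int = DEFAULT_DEPTH) -> LaplacianBundle:
    """Sample, perturb, classify supports and assemble all four Laplacians."""
    if variant not in ("big", "hodge"):
        raise ValueError(f"variant must be 'big' or 'hodge', got {variant!r}")
    primal = perturb_values(field.sample(complex, "primal"), isovalue, complex.spacing)
    dual = perturb_values(field.sample(complex, "dual"), isovalue, complex.spacing)
    mask = classify_support(complex, primal, dual, isovalue, bc)
    D = restricted_differentials(complex, mask)
    if variant == "big":
        S = {}
        Dbar = D
    else:
        S = {k: hodge_star(complex, k, bc, mask, primal, dual, isovalue, depth)
             for k in range(4)}
        Dbar = {k: (sp.diags(S[k + 1].entries ** 0.5) @ D[k]
                    @ sp.diags(S[k].entries ** -0.5)).tocsr()
                for k in range(3)}
    L = {k: assemble_laplacian(Dbar, k) for k in range(4)}
    return LaplacianBundle(complex, bc, variant, float(isovalue), mask, D, S, Dbar, L)


def save_operator(path, M: sp.spmatrix) -> None:
    """Export an operator as a Matrix Market (.mtx) file."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(M))
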