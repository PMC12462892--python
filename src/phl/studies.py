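"""Canonical demonstration studies: the four-ball, genus-3 and solid-torus
offset filtrations.

These fix the grids and isovalue schedules at which the discrete sublevel
topology of each model is resolution-clean.  Near a critical value of the
level-set function the isosurface runs sub-cell-tangent to large patches of
the grid, and the vertex-inclusion rule then bridges or perforates the
support erratically (spurious handles and pockets); the schedules below
keep every sampled isovalue at least about one grid spacing in level-set
value away from the critical values, following the usual requirement that
filtration parameters avoid critical isovalues.  Exact critical values for
the four-ball model (edge 3, unit balls): components merge at c = 0.5,
the three face tunnels fill at c = sqrt(3) - 1 ~ 0.732, and the central
cavity disappears at c = 3 sqrt(3/8) - 1 ~ 0.837.

Each study returns the per-isovalue table from :func:`phl.spectra
.spectral_curves`; Betti numbers use the package's kernel-dimension policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import GridComplex
from .fields import four_ball_model, genus3_solid, solid_torus
from .spectra import spectral_curves

__all__ = ["FourBallStudy", "Genus3Study", "TorusStudy"]


def _centered_grid(half_extents, spacing) -> GridComplex:
    half = np.atleast_1d(np.asarray(half_extents, float)) * np.ones(3)
    counts = tuple(int(np.ceil(2 * h / spacing)) + 1 for h in half)
    origin = tuple(-(c - 1) * spacing / 2.0 for c in counts)
    return GridComplex(counts, spacing, origin)


@dataclass
class FourBallStudy:
    """Offset filtration of four unit balls at regular-tetrahedron vertices
    (edge 3): beta0 4 -> 1 at the merge, beta1 0 -> 3 -> 0 as the face
    tunnels open and fill, beta2 0 -> 1 -> 0 around the transient cavity,
    with a simultaneous drop of lambda1T at the merge."""

    edge: float = 3.0
    radius: float = 1.0
    spacing: float = 0.16
    # ~20 isovalues spanning merge, tunnel fill and cavity, placed on the
    # clean plateaus between the critical bands (see module docstring)
    isovalues: tuple = (0.30, 0.32, 0.33, 0.34, 0.36, 0.38,
                        0.57, 0.58, 0.59, 0.595,
                        0.805, 0.81, 0.815, 0.82,
                        0.845, 0.855, 0.86, 0.92, 0.945, 0.97)

    def grid(self) -> GridComplex:
        half = self.edge * np.sqrt(3.0 / 8.0) / np.sqrt(3.0) \
            + self.radius + max(self.isovalues) + 3 * self.spacing
        return _centered_grid(half, self.spacing)

    def field(self):
        return four_ball_model(self.edge, self.radius)

    def run(self, compute_lambdas: bool = True, isovalues=None) -> pd.DataFrame:
        iso = self.isovalues if isovalues is None else isovalues
        return spectral_curves(self.field(), self.grid(), iso,
                               variant="big", compute_lambdas=compute_lambdas)


@dataclass
class Genus3Study:
    """Offset filtration of a box pierced by three parallel tunnels:
    beta1 starts at 3 and drops to 0 when the tunnels (radius 0.5) fill at
    c = 0.5."""

    spacing: float = 0.15
    isovalues: tuple = (0.03, 0.1, 0.2, 0.3, 0.6, 0.7)

    def grid(self) -> GridComplex:
        f = genus3_solid()
        hx = f.params["half_extents"][0] + max(self.isovalues) + 3 * self.spacing
        hy = f.params["half_extents"][1] + max(self.isovalues) + 3 * self.spacing
        return _centered_grid((hx, hy, hy), self.spacing)

    def field(self):
        return genus3_solid()

    def run(self, compute_lambdas: bool = False, isovalues=None) -> pd.DataFrame:
        iso = self.isovalues if isovalues is None else isovalues
        return spectral_curves(self.field(), self.grid(), iso,
                               variant="big", compute_lambdas=compute_lambdas)


@dataclass
class TorusStudy:
    """Offset filtration of a solid torus (major 2, minor 0.6): beta1 drops
    1 -> 0 when the hole (radius 1.4 - c) closes, with a simultaneous
    discontinuous drop of lambda1C."""

    major_radius: float = 2.0
    minor_radius: float = 0.6
    spacing: float = 0.2
    isovalues: tuple = (0.05, 0.3, 0.55, 0.8, 0.95, 1.65)

    def grid(self) -> GridComplex:
        h = self.major_radius + self.minor_radius + max(self.isovalues) \
            + 3 * self.spacing
        hz = self.minor_radius + max(self.isovalues) + 3 * self.spacing
        return _centered_grid((h, h, hz), self.spacing)

    def field(self):
        return solid_torus(major_radius=self.major_radius,
                           minor_radius=self.minor_radius)

    def run(self, compute_lambdas: bool = True, isovalues=None) -> pd.DataFrame:
        iso = self.isovalues if isovalues is None else isovalues
        return spectral_curves(self.field(), self.grid(), iso,
                               variant="big", compute_lambdas=compute_lambdas)
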