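"""Level-set fields: analytic implicit solids and molecular FRI densities.

A :class:`ScalarField` wraps a deterministic evaluator f: R^3 -> R; the
sublevel set {x | f(x) <= c} is the manifold analysed downstream.  The
built-in primitives cover the demonstration shapes used throughout the
test-suite:

* ``ball`` — exact signed distance to a sphere;
* ``union`` — pointwise min of member fields (a valid level-set whose
  sublevel sets are the unions, though not an exact distance function);
* ``solid_torus`` — exact signed distance to a solid torus;
* ``genus3_solid`` — a box pierced by three parallel cylindrical tunnels,
  combined with min/max (offsetting the isovalue fills the tunnels);
* ``four_ball_model`` — four balls centered at the vertices of a regular
  tetrahedron, whose offset filtration merges components, opens three
  tunnels, and encloses a transient cavity.

The FRI (flexibility-rigidity index) density of an atom set is

    rho(x, tau) = - sum_i exp(-(|x - x_i| / (tau * r_i))^2),

a strictly negative field approaching 0 away from all atoms; its sublevel
sets at negative isovalues are the molecular manifolds.

Grids of sampled values travel as NRRD files (raw or ascii encoding),
written and parsed here so externally produced density maps can enter the
pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .grid import GridComplex

__all__ = [
    "ScalarField", "AtomRecord", "sdf_primitive", "ball", "union",
    "solid_torus", "genus3_solid", "four_ball_model", "fri_density",
    "sample_field", "write_nrrd", "read_nrrd", "field_from_grid",
]


@dataclass
class AtomRecord:
    """One atom: element symbol, position (angstrom), van der Waals radius."""

    element: str
    coords: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"van der Waals radius must be positive, got {self.radius}")


class ScalarField:
    """A level-set function with cached samples on grid complexes.

    ``field(points)`` evaluates at an (..., 3) array of coordinates;
    ``field.sample(gc, site)`` returns one value per primal vertex
    (``site="primal"``) or per 3-cell center (``site="dual"``), in cell
    enumeration order, caching per (grid, site).
    """

    def __init__(self, evaluator, kind: str = "custom", params: dict | None = None):
        self._fn = evaluator
        self.kind = kind
        self.params = dict(params or {})
        self._cache: dict = {}

    def __call__(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        if squeeze:
            pts = pts[None, :]
        vals = np.asarray(self._fn(pts), dtype=float)
        return vals[0] if squeeze else vals

    def sample(self, gc: GridComplex, site: str = "primal") -> np.ndarray:
        if site not in ("primal", "dual"):
            raise ValueError(f"site must be 'primal' or 'dual', got {site!r}")
        key = (gc, site)
        if key not in self._cache:
            pts = gc.vertex_coords() if site == "primal" else gc.cube_centers()
            self._cache[key] = self(pts)
        return self._cache[key]

    def __repr__(self):
        return f"ScalarField(kind={self.kind!r}, params={self.params!r})"


def sample_field(field: ScalarField, complex: GridComplex, site: str = "primal") -> np.ndarray:
    """Sample a field at primal vertices or dual points (3-cell centers)."""
    return field.sample(complex, site)


# --------------------------------------------------------------- primitives

def ball(center=(0.0, 0.0, 0.0), radius: float = 1.0) -> ScalarField:
    """Exact signed distance to a sphere of given center and radius."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, float)

    def fn(p):
        return np.linalg.norm(p - c, axis=-1) - radius

    return ScalarField(fn, "ball", {"center": tuple(c), "radius": radius})


def union(*fields: ScalarField) -> ScalarField:
    """Pointwise min of member fields: sublevel sets are set unions."""
    if not fields:
        raise ValueError("union of zero fields")

    def fn(p):
        return np.min([f(p) for f in fields], axis=0)

    return ScalarField(fn, "union", {"members": [f.kind for f in fields]})


def solid_torus(center=(0.0, 0.0, 0.0), major_radius: float = 2.0,
                minor_radius: float = 0.6) -> ScalarField:
    """Exact signed distance to a solid torus around the z-axis through center."""
    if not (major_radius > 0 and minor_radius > 0):
        raise ValueError("torus radii must be positive")
    c = np.asarray(center, float)

    def fn(p):
        q = p - c
        ring = np.hypot(q[..., 0], q[..., 1]) - major_radius
        return np.hypot(ring, q[..., 2]) - minor_radius

    return ScalarField(fn, "solid_torus",
                       {"center": tuple(c), "major_radius": major_radius,
                        "minor_radius": minor_radius})


def _box_sdf(p, half):
    q = np.abs(p) - half
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def genus3_solid(half_extents=(2.4, 1.2, 1.2), tunnel_radius: float = 0.5,
                 tunnel_offsets=(-1.5, 0.0, 1.5)) -> ScalarField:
    """Box minus three parallel cylindrical tunnels along the y-axis.

    The tunnels sit at x = tunnel_offsets, z = 0.  At isovalue c the solid
    is the offset box minus tunnels of radius ``tunnel_radius - c``: each
    tunnel fills exactly at c = tunnel_radius, dropping beta1 from 3 to 0.
    """
    half = np.asarray(half_extents, float)
    offs = np.asarray(tunnel_offsets, float)
    if not tunnel_radius > 0 or not (half > 0).all():
        raise ValueError("box half-extents and tunnel radius must be positive")

    def fn(p):
        b = _box_sdf(p, half)
        # distance to nearest tunnel axis (lines parallel to y)
        d = np.min(np.hypot(p[..., 0, None] - offs[None, :], p[..., 2, None]), axis=-1)
        return np.maximum(b, tunnel_radius - d)

    return ScalarField(fn, "genus3_solid",
                       {"half_extents": tuple(half), "tunnel_radius": tunnel_radius,
                        "tunnel_offsets": tuple(offs)})


def tetrahedron_vertices(edge: float) -> np.ndarray:
    """Vertices of a regular tetrahedron with the given edge length,
    centered at the origin."""
    v = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                  [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    return v * (edge / (2.0 * np.sqrt(2.0)))


def four_ball_model(edge: float = 3.0, radius: float = 1.0) -> ScalarField:
    """Signed distance to four balls centered at regular-tetrahedron vertices."""
    if not (edge > 0 and radius > 0):
        raise ValueError("tetrahedron edge and ball radius must be positive")
    centers = tetrahedron_vertices(edge)

    def fn(p):
        d = np.linalg.norm(p[..., None, :] - centers[None, :, :], axis=-1)
        return d.min(axis=-1) - radius

    f = ScalarField(fn, "four_ball_model", {"edge": edge, "radius": radius})
    return f


_PRIMITIVES = {
    "ball": ball,
    "union": union,
    "solid_torus": solid_torus,
    "genus3_solid": genus3_solid,
    "four_ball_model": four_ball_model,
}


def sdf_primitive(kind: str, **params) -> ScalarField:
    """Dispatch to a named implicit-solid generator."""
    try:
        maker = _PRIMITIVES[kind]
    except KeyError:
        raise ValueError(f"unknown primitive {kind!r}; choose from {sorted(_PRIMITIVES)}")
    return maker(**params)


# ------------------------------------------------------------- FRI density

def fri_density(atoms, tau: float = 1.0) -> ScalarField:
    """FRI density rho(x, tau) = -sum_i exp(-(|x - x_i| / (tau r_i))^2).

    Strictly negative everywhere, approaching 0 at infinity; adding an atom
    makes the field strictly more negative.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("fri_density of an empty atom list")
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    centers = np.array([a.coords for a in atoms], float)
    widths = tau * np.array([a.radius for a in atoms], float)

    def fn(p):
        out = np.zeros(p.shape[:-1])
        for i in range(0, len(centers), 256):  # chunk atoms to bound memory
            d = np.linalg.norm(p[..., None, :] - centers[None, i:i + 256, :], axis=-1)
            out -= np.exp(-((d / widths[None, i:i + 256]) ** 2)).sum(axis=-1)
        return out

    return ScalarField(fn, "fri_density", {"n_atoms": len(atoms), "tau": tau})


# ----------------------------------------------------------------- NRRD IO

def write_nrrd(path, values: np.ndarray, spacing: float, origin, encoding: str = "raw") -> None:
    """Write a 3-D scalar grid as NRRD (x-fastest raveling, double precision)."""
    values = np.asarray(values, float)
    if values.ndim != 3:
        raise ValueError("values must be a 3-D array indexed [i, j, k]")
    if encoding not in ("raw", "ascii"):
        raise ValueError("encoding must be 'raw' or 'ascii'")
    ox, oy, oz = (float(v) for v in origin)
    header = (
        "NRRD0004\n"
        "type: double\n"
        "dimension: 3\n"
        f"sizes: {values.shape[0]} {values.shape[1]} {values.shape[2]}\n"
        f"spacings: {spacing!r} {spacing!r} {spacing!r}\n"
        f"axis mins: {ox!r} {oy!r} {oz!r}\n"
        f"encoding: {encoding}\n"
        "endian: little\n"
        "\n"
    )
    flat = values.ravel(order="F")
    with open(path, "wb") as fh:
        fh.write(header.encode())
        if encoding == "raw":
            fh.write(flat.astype("<f8").tobytes())
        else:
            fh.write("\n".join(repr(float(v)) for v in flat).encode())


def read_nrrd(path):
    """Read a 3-D NRRD written by :func:`write_nrrd` (raw/ascii, double).

    Returns ``(values, spacing, origin)`` with values indexed [i, j, k].
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    head, _, body = blob.partition(b"\n\n")
    fields = {}
    lines = head.decode().splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path} is not an NRRD file")
    for line in lines[1:]:
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.strip()
    sizes = tuple(int(s) for s in fields["sizes"].split())
    spacings = [float(s) for s in re.split(r"\s+", fields.get("spacings", "1 1 1"))]
    if len(set(spacings)) != 1:
        raise ValueError("only isotropic spacings are supported")
    origin = tuple(float(s) for s in fields.get("axis mins", "0 0 0").split())
    enc = fields.get("encoding", "raw")
    n = int(np.prod(sizes))
    if enc == "raw":
        flat = np.frombuffer(body, dtype="<f8", count=n)
    elif enc in ("ascii", "txt", "text"):
        flat = np.array(body.decode().split(), dtype=float)[:n]
    else:
        raise ValueError(f"unsupported NRRD encoding {enc!r}")
    values = flat.reshape(sizes, order="F")
    return values, spacings[0], origin


def field_from_grid(values: np.ndarray, spacing: float, origin) -> ScalarField:
    """Trilinear interpolant of a sampled grid, clamped at the box edges.

    The lower-fidelity entry path for externally produced (e.g. NRRD)
    density maps: dual points are then interpolated rather than evaluated.
    """
    from scipy.interpolate import RegularGridInterpolator

    values = np.asarray(values, float)
    axes = [np.asarray(origin)[a] + spacing * np.arange(values.shape[a]) for a in range(3)]
    interp = RegularGridInterpolator(axes, values, bounds_error=False, fill_value=None)

    def fn(p):
        lo = np.array([ax[0] for ax in axes])
        hi = np.array([ax[-1] for ax in axes])
        return interp(np.clip(p, lo, hi))

    return ScalarField(fn, "sampled_grid", {"shape": values.shape, "spacing": spacing})
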