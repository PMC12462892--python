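# Methods

This note records the model, the numerical policies and the design
choices behind `phl`, in the order the pipeline runs.

## Eulerian representation and supports

A solid M = {f ≤ c} is represented on a regular Cartesian grid purely by
the sampled values of the level-set function f at primal vertices and at
3-cell centers (the dual vertices).  All topology downstream is decided
by these samples and two inclusion rules: a k-cell joins the *normal*
support when at least one of its 2^k vertices lies inside or on the
boundary of M, and the *tangential* support when at least one corner of
its dual (3−k)-cell (a center of an incident cube) does.  Ties are
resolved by perturbing every sampled value at least ε = 10⁻⁵ℓ away from
the isovalue, pushing exact ties inward; this both fixes the inclusion
rule and bounds the fractional cell volumes away from zero.  Neither
support contains the other in general, and neither is a closed
subcomplex — cells at the fringe may lack faces.  That is intentional:
the missing rows act as Dirichlet conditions, and it is exactly what
makes dim ker L_{k,n} = β_{3−k}(M).

Users must size grids so M keeps at least one spacing of clearance from
the grid boundary (`check_boundary_clearance` warns otherwise).  With
clearance violated, outer-layer cells acquire spurious Dirichlet rows
and kernels can vanish — the failure is silent in the eigenvalues, which
is why the validator exists.

## Cut-cell volumes and Hodge stars

The star of degree k carries ℓ^(3−2k) on uncut cells.  For cells crossed
by the isosurface, the measure inside M is estimated from the corner
values of the multilinear interpolant:

* edges — exact fraction of the linear interpolant;
* faces, cubes, and all dual cells — the fraction of sub-cell centers of
  a dyadic subdivision (depth 4, i.e. 16 per axis; 256 samples per face,
  4096 per cube) at which the interpolant is non-positive.  The
  estimator is deterministic, convergent in depth, and is validated
  against a 10⁶-point quadrature in the tests.

Fractions are floored at 10⁻⁵ (the role the ε-perturbation plays in
keeping volumes well-behaved), so star entries stay within
[ℓ^(3−2k)·10⁻⁵-ish, ℓ^(3−2k)/10⁻⁵].  Under the normal condition the
primal volume of a cut cell is adjusted and dual volumes are kept;
tangentially it is the reverse.  Outside primal cells are never
volume-adjusted.  Dual cells clipped by the grid boundary count their
missing corners as outside; such cells only matter when the clearance
rule is already violated.

## Laplacians and spectra

Operators live on compact (kept-cell) indices.  The Hodge variant is
stored symmetrized, L̄ = S^(−1/2) L S^(−1/2), whose eigenvalues equal the
generalized eigenvalues of (L, S); the raw operator is reconstructable
from the stored star.  The BIG variant replaces stars by the identity;
its eigenvalues divided by ℓ² approach Hodge eigenvalues under
refinement, which the tests check on the unit ball against the continuum
limit λ1N/ℓ² → π² (first Dirichlet eigenvalue).

Eigenvalues are computed densely below 2000 unknowns (also for small
nearly-dense operators, e.g. persistent ones), and by shift-inverted
Lanczos above, with σ = −10⁻³·λ̂_max and a fixed all-ones start vector
(no randomness anywhere).  An eigenvalue counts as zero iff
λ < 10⁻⁸ + 10⁻⁶·λ̂_max, with λ̂_max a 30-step power-iteration estimate.
Any eigenvalue within a decade of the threshold raises an ambiguity flag
and triggers an exact cross-check.

Because the restricted differentials are integer matrices of a complex
embedded in R³ (torsion-free), kernel dimensions are also computable
exactly as n_k − rank D_k − rank D_{k−1} over GF(2).  `betti_numbers`
uses the eigensolver below 25 000 unknowns and the exact rank path above
it, where sparse factorization costs minutes per operator; the two paths
are asserted equal on every test shape.  The GF(2) rank is a bit-packed
low-pivot reduction (numba-accelerated, with a pure-numpy fallback) that
exploits the bandedness of lexicographically ordered incidence
operators.

The T/C/N split labels the squared nonzero singular values of D̄_2, D̄_1,
D̄_0 under the normal condition as T, C and N respectively.  The labels
follow from the primal-normal / dual-tangential equivalence: the grid
shifted by ℓ/2 in every axis swaps the two boundary conditions, so
tangential scalar fields live on the dual grid and their gradient
spectrum is the singular spectrum of D̄_2.  λ1T and λ1N are read off the
degree-3 and degree-0 operators (whose kernels are small); λ1C comes
from the smallest eigenpairs of L̄_2, classifying each eigenvector by
which Gram term carries it (‖D̄_1ᵀv‖ > ‖D̄_2v‖ ⇒ curl type), growing the
request until a curl-type vector appears.

## Persistence

A filtration stores the nested normal supports of strictly increasing
isovalues (nesting is verified).  The degree-k harmonic extension from
level l to l+p solves for a (k−1)-form potential ζ on W, the new
(k−1)-cells bounding new k-cells, from

    (G_Bᵀ S_B G_B) ζ = − G_Aᵀ S_A ω,

where G_B, G_A are the incidence blocks of new and old k-cells against W
and ω is the level-l form; the new values are G_B ζ.  This system is the
coclosedness condition of the extended form at the new cells, i.e. the
interior Laplace solve with Dirichlet data at the old-complex interface,
restricted to the up-term that actually determines dζ (a down-term would
only move ζ within ker d, which the extension discards).  Three
consequences hold to machine precision and are tested: constants extend
to constants, co-exact forms extend by zero, and the persistent
differential satisfies D^k_l D̃^{k−1}_{l,p} = 0.  At k = 0 no potential
exists and the extension is the plain Dirichlet harmonic extension of
vertex values.  The interior solve is a dense rank-revealing QR
least-squares (rcond 10⁻¹⁰) — every least-squares solution yields the
same dζ since solutions differ by ker G_B — and is capped at 6000
unknowns: refine the isovalue sequence rather than solve huge difference
regions.  A composed construction (chaining one-step extensions) is
available and cheaper for long spans; it need not equal the direct solve
and the tests only compare their kernel counts on clean steps.

The symmetrized p-persistent operator is assembled as B Bᵀ + D̄ᵀD̄ with
B = S_{k,l}^(−1/2) Iᵀ S_{k,l+p} D_{l+p} S_{k−1,l+p}^(−1/2), hence
symmetric PSD by construction, and reduces exactly to the ordinary
operator at p = 0.  Its kernel dimension is the persistent Betti number;
for degree 3 it is checked against union-find persistent component
counting.  Two restriction operators are exposed: the adjoint-consistent
R = S⁻¹IᵀS used inside the Laplacian, and the projection-normalized
R = (IᵀSI)⁻¹IᵀS which satisfies R∘I = Id exactly.

## Synthetic shapes and the resolution caveat

The generator ships exact signed distances (ball, solid torus), min
unions, a four-ball model (unit balls at the vertices of a regular
tetrahedron, edge 3 by default) and a genus-3 solid (box of half-extents
(2.4, 1.2, 1.2) pierced by three parallel tunnels of radius 0.5 —
parameters chosen so every feature spans at least ~2.5 cells at the
documented grids).  Offsetting the isovalue is the filtration mechanism;
no re-distancing is performed, since sublevel topology only needs the
sign structure.

The vertex-inclusion rule dilates the solid by up to one cell diagonal.
Wherever the isosurface passes within about one cell of itself — which
happens over large patches near *critical values* of f, where necks
pinch and gaps close tangentially — the discrete support becomes a
lattice sponge with spurious handles and pockets (β1 values in the
twenties were measured on the four-ball model near its merge).  The
bands are O(spacing) wide in the isovalue.  The canonical studies in
`phl.studies` therefore sample their isovalue schedules on the plateaus
between the critical bands (for the four-ball model: merges at 0.5,
tunnels fill at √3−1 ≈ 0.732, cavity dies at 3√(3/8)−1 ≈ 0.837), which
is the discrete form of the usual requirement that filtration parameters
avoid critical isovalues.  The study grids are ~45³ at spacing 0.16
(four-ball), 49×33×33 at 0.15 (genus-3) and 50×50×30 at 0.2 (torus) —
sizes at which a full 20-isovalue sweep runs in minutes on one CPU.
Consequently, passing tests demonstrate correctness of the operators on
resolution-clean inputs; they do not show that an arbitrary shape at an
arbitrary isovalue is free of discretization topology.  Real density
maps should be screened with the same clearance and resolution checks.

## Molecular featurization

Proteins keep heavy atoms in {C, N, O, S} (hydrogen is dropped); ligands
keep the 10-element set.  Van der Waals radii default to the Bondi
values and are overridable.  The FRI scale τ defaults to 1.0 — a
configuration choice, as no canonical value is fixed by the feature
definition.  The 12 Å cutoff is read as "protein atoms of the pair's
element within 12 Å of *any* ligand atom, plus all ligand atoms of the
pair's element".  Each selection is gridded at 0.549 Å (default) in a
frame snapped to the selection's bounding box — so rigid translations
change nothing, bitwise — padded so the density tail at the boundary
stays above the shallowest isovalue.  Components resolved by fewer than
8 cubes trigger one automatic spacing halving, then a logged warning.
β₀ is the zero-eigenvalue count of the degree-3 BIG Laplacian; blocks
with fewer than k nonzero eigenvalues are zero-padded and flagged; empty
selections contribute zero blocks.  Downstream regression on the feature
matrix is out of scope.

## Known limitations

* Cut volumes are center-counting estimates, not exact trilinear
  clipping; accuracy is ~2⁻⁴ per axis at the default depth.
* The fringe non-closedness means chain-level identities (e.g. exact
  co-exactness cancellation) hold on the supports the way the operators
  define them, not for arbitrary sub-complex manipulations.
* Difference regions above 6000 interior unknowns are refused rather
  than solved iteratively.
* 2-D grids are not a product surface; everything is 3-D.
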