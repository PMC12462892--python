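"""Protein-ligand parsing, element-specific atom pairs and topological
featurization.

Proteins (PDB) keep heavy atoms of elements {C, N, O, S}; ligands
(MOL2/SDF) keep {H, C, N, O, S, P, F, Cl, Br, I}.  The 40 ordered
(protein element, ligand element) pairs each select the protein atoms of
that element within a cutoff (12 A) of any ligand atom, together with the
ligand atoms of the pair's element.  Each selection is mapped to a
continuum by the FRI density and filtered over 9 evenly spaced isovalues
in [-0.5, -0.001]; per manifold the BIG Laplacian L_{3,n} under the normal
condition supplies beta0 (its zero-eigenvalue count) and the first k
nonzero eigenvalues.  The feature vector is pair-major, then isovalue,
then [beta0, lambda_1..lambda_k], of total length (k+1) * 9 * 40.

Van der Waals radii default to the Bondi set and can be overridden in the
config.  The parameter tau of the FRI kernel is configurable (default 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .grid import GridComplex
from .fields import AtomRecord, fri_density
from .laplacians import build_bundle
from .spectra import smallest_spectrum, component_count

__all__ = [
    "AtomSet", "FeatureConfig", "FeatureVector", "VDW_RADII",
    "PROTEIN_ELEMENTS", "LIGAND_ELEMENTS", "read_structures", "element_pairs",
    "pair_atom_selection", "featurize_complex",
]

log = logging.getLogger("phl.molecular")

# Bondi van der Waals radii (angstrom)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98}

PROTEIN_ELEMENTS = ("C", "N", "O", "S")
LIGAND_ELEMENTS = ("H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I")


class EmptySelectionError(ValueError):
    """Raised when a density is requested for an empty atom selection."""


@dataclass
class AtomSet:
    """A filtered set of atoms with element labels and vdW radii."""

    elements: np.ndarray        # dtype '<U2'
    coords: np.ndarray          # (n, 3) angstrom
    radii: np.ndarray           # (n,) angstrom
    source: str = "unknown"     # "protein" | "ligand" | "selection"
    provenance: dict = dc_field(default_factory=dict)

    def __len__(self):
        return len(self.elements)

    def subset(self, mask) -> "AtomSet":
        return AtomSet(self.elements[mask], self.coords[mask], self.radii[mask],
                       self.source, dict(self.provenance))

    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(e, tuple(c), r)
                for e, c, r in zip(self.elements, self.coords, self.radii)]

    @classmethod
    def from_lists(cls, elements, coords, source, provenance=None,
                   radii_table=None) -> "AtomSet":
        table = dict(VDW_RADII if radii_table is None else radii_table)
        elements = np.asarray(elements, dtype="<U2")
        radii = np.array([table[e] for e in elements], float)
        return cls(elements, np.asarray(coords, float).reshape(-1, 3), radii,
                   source, dict(provenance or {}))


_NAME_ELEMENT_HINTS = {"CL": "Cl", "BR": "Br"}


def _element_from_name(name: str) -> str:
    """Heuristic fallback: derive the element from a PDB atom name."""
    stripped = name.strip().upper()
    if stripped[:2] in _NAME_ELEMENT_HINTS:
        return _NAME_ELEMENT_HINTS[stripped[:2]]
    for ch in stripped:
        if ch.isalpha():
            return ch.capitalize()
    return ""


def _read_protein_pdb(path, radii_table=None) -> AtomSet:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    elements, coords = [], []
    skipped = 0
    fallback = 0
    for atom in structure.get_atoms():
        elem = (atom.element or "").strip().capitalize()
        if not elem:
            elem = _element_from_name(atom.get_name())
            fallback += 1
        if elem == "H" or elem not in PROTEIN_ELEMENTS:
            skipped += 1
            continue
        elements.append(elem)
        coords.append(atom.get_coord())
    if fallback:
        log.warning("%d protein atoms lacked an element column; used the "
                    "atom-name heuristic", fallback)
    if skipped:
        log.info("dropped %d protein atoms outside %s", skipped, PROTEIN_ELEMENTS)
    return AtomSet.from_lists(
        elements, np.array(coords, float) if coords else np.zeros((0, 3)),
        "protein", {"path": str(path), "n_raw": skipped + len(elements),
                    "n_kept": len(elements), "name_fallback": fallback},
        radii_table)


def _read_ligand(path, radii_table=None) -> AtomSet:
    from rdkit import Chem

    path = str(path)
    if path.lower().endswith(".mol2"):
        mol = Chem.MolFromMol2File(path, removeHs=False, sanitize=False)
    elif path.lower().endswith((".sdf", ".sd", ".mol")):
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
        mol = next((m for m in supplier if m is not None), None)
    else:
        raise ValueError(f"unsupported ligand format: {path}")
    if mol is None:
        raise ValueError(f"could not parse ligand file {path}")
    conf = mol.GetConformer()
    elements, coords = [], []
    skipped = 0
    for atom in mol.GetAtoms():
        elem = atom.GetSymbol().capitalize()
        if elem not in LIGAND_ELEMENTS:
            skipped += 1
            continue
        elements.append(elem)
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append((p.x, p.y, p.z))
    if skipped:
        log.info("dropped %d ligand atoms outside the 10-element set", skipped)
    return AtomSet.from_lists(
        elements, np.array(coords, float) if coords else np.zeros((0, 3)),
        "ligand", {"path": path, "n_kept": len(elements), "n_dropped": skipped},
        radii_table)


def read_structures(protein_path, ligand_path, radii_table=None) -> tuple[AtomSet, AtomSet]:
    """Parse a protein (PDB) and a ligand (MOL2/SDF) into filtered atom sets."""
    return (_read_protein_pdb(protein_path, radii_table),
            _read_ligand(ligand_path, radii_table))


def element_pairs() -> list[tuple[str, str]]:
    """The 40 ordered (protein element, ligand element) pairs:
    {C,N,O,S} x {H,C,N,O,S,P,F,Cl,Br,I}, protein-element major."""
    return [(pe, le) for pe in PROTEIN_ELEMENTS for le in LIGAND_ELEMENTS]


def pair_atom_selection(protein: AtomSet, ligand: AtomSet, pair: tuple[str, str],
                        cutoff: float = 12.0) -> AtomSet:
    """Atoms of one element pair: protein atoms of element ``pair[0]`` within
    ``cutoff`` of any ligand atom, plus all ligand atoms of element
    ``pair[1]``.  May be empty."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    pe, le = pair
    lig_sel = ligand.subset(ligand.elements == le)
    prot_elem = protein.subset(protein.elements == pe)
    if len(prot_elem) and len(ligand):
        tree = cKDTree(ligand.coords)
        dmin = tree.query(prot_elem.coords, k=1)[0]
        prot_sel = prot_elem.subset(dmin <= cutoff)
    else:
        prot_sel = prot_elem.subset(np.zeros(len(prot_elem), bool))
    return AtomSet(
        np.concatenate([prot_sel.elements, lig_sel.elements]),
        np.concatenate([prot_sel.coords.reshape(-1, 3), lig_sel.coords.reshape(-1, 3)]),
        np.concatenate([prot_sel.radii, lig_sel.radii]),
        "selection", {"pair": pair, "n_protein": len(prot_sel), "n_ligand": len(lig_sel)})


@dataclass
class FeatureConfig:
    """Featurization parameters.

    spacing : grid spacing (0.549 A); isovalues : nine evenly spaced values
    in [-0.5, -0.001]; k : number of nonzero eigenvalues kept per manifold;
    tau : FRI kernel scale; cutoff : pair selection distance (12 A).
    """

    spacing: float = 0.549
    isovalues: tuple = tuple(np.linspace(-0.5, -0.001, 9))
    k: int = 5
    tau: float = 1.0
    cutoff: float = 12.0
    variant: str = "big"
    min_component_cells: int = 8
    max_grid_cells: int = 3_000_000
    radii_table: dict = dc_field(default_factory=lambda: dict(VDW_RADII))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["isovalues"] = [float(v) for v in self.isovalues]
        return d


@dataclass
class FeatureVector:
    """Flat feature vector, pair-major then isovalue then [beta0, lambdas]."""

    values: np.ndarray
    config: FeatureConfig
    warnings: list = dc_field(default_factory=list)

    def __len__(self):
        return len(self.values)

    def labels(self) -> list[str]:
        out = []
        for pe, le in element_pairs():
            for i in range(len(self.config.isovalues)):
                out.append(f"{pe}{le}_iv{i}_beta0")
                out.extend(f"{pe}{le}_iv{i}_lam{j + 1}" for j in range(self.config.k))
        return out

    def block(self, pair_index: int, iso_index: int) -> np.ndarray:
        w = self.config.k + 1
        start = (pair_index * len(self.config.isovalues) + iso_index) * w
        return self.values[start:start + w]


def _local_frame(atoms: AtomSet, spacing: float, tau: float,
                 max_cells: int) -> tuple[GridComplex, AtomSet]:
    """Grid plus atoms translated to a molecule-snapped frame.

    The grid covers the selection's bounding box padded so the density
    exceeds every isovalue at the boundary (single-atom tail below 1e-3
    times the shallowest isovalue magnitude, plus one cell clearance); the
    origin sits at the padded minimal corner and coordinates are taken
    relative to it, so rigid translations of the input leave the features
    bitwise unchanged.
    """
    pad = tau * atoms.radii.max() * np.sqrt(np.log(max(len(atoms), 2) / 1e-3)) + 2 * spacing
    lo = atoms.coords.min(axis=0)
    hi = atoms.coords.max(axis=0)
    local = AtomSet(atoms.elements, atoms.coords - lo + pad, atoms.radii,
                    atoms.source, dict(atoms.provenance))
    counts = tuple(int(np.ceil((hi[a] - lo[a] + 2 * pad) / spacing)) + 1
                   for a in range(3))
    n_cells = int(np.prod(counts))
    if n_cells > max_cells:
        suggested = spacing * (n_cells / max_cells) ** (1 / 3)
        raise MemoryError(
            f"grid of {counts} = {n_cells} vertices exceeds the cap of {max_cells}; "
            f"increase spacing to about {suggested:.3f} A")
    return GridComplex(counts, spacing, (0.0, 0.0, 0.0)), local


def _pair_block(atoms: AtomSet, config: FeatureConfig, isovalue: float,
                spacing: float, warnings_out: list, tag: str) -> np.ndarray:
    """[beta0, first k nonzero eigenvalues] for one selection and isovalue,
    with one automatic spacing halving if a connected component is resolved
    by fewer than ``min_component_cells`` 3-cells."""
    for attempt in range(2):
        gc, local = _local_frame(atoms, spacing, config.tau, config.max_grid_cells)
        field = fri_density(local.atoms(), config.tau)
        bundle = build_bundle(gc, field, isovalue, bc="normal", variant=config.variant)
        n3 = bundle.num_dof(3)
        if n3 == 0:
            warnings_out.append(f"{tag}: empty support at isovalue {isovalue:.4g}")
            return np.zeros(config.k + 1)
        ncomp = component_count(bundle)
        if n3 >= config.min_component_cells * ncomp or attempt == 1:
            if n3 < config.min_component_cells * ncomp:
                warnings_out.append(
                    f"{tag}: components under-resolved ({n3} cells for {ncomp} "
                    f"components) even after refinement")
            break
        spacing = spacing / 2.0
    summary = smallest_spectrum(bundle.L[3], config.k + 8, 3, "normal", config.variant)
    beta0 = summary.zero_multiplicity
    lams = summary.nonzero[:config.k]
    if len(lams) < config.k:
        warnings_out.append(
            f"{tag}: only {len(lams)} nonzero eigenvalues available; zero-padded")
        lams = np.pad(lams, (0, config.k - len(lams)))
    return np.concatenate([[beta0], lams])


def featurize_complex(protein: AtomSet, ligand: AtomSet,
                      config: FeatureConfig | None = None) -> FeatureVector:
    """Persistent-spectral feature vector of one protein-ligand complex.

    Length (k+1) * n_isovalues * 40; empty pair selections contribute
    all-zero blocks.  Deterministic: repeated featurization of the same
    inputs is bitwise identical.
    """
    config = config or FeatureConfig()
    pairs = element_pairs()
    blocks, warns = [], []
    any_nonempty = False
    for pe, le in pairs:
        sel = pair_atom_selection(protein, ligand, (pe, le), config.cutoff)
        if len(sel) == 0:
            blocks.append(np.zeros((len(config.isovalues)) * (config.k + 1)))
            continue
        any_nonempty = True
        rows = [
            _pair_block(sel, config, c, config.spacing, warns, f"{pe}-{le}/iv={c:.4g}")
            for c in config.isovalues]
        blocks.append(np.concatenate(rows))
    if not any_nonempty:
        raise EmptySelectionError("every element-pair selection is empty")
    values = np.concatenate(blocks)
    expected = (config.k + 1) * len(config.isovalues) * len(pairs)
    assert len(values) == expected
    for w in warns:
        log.warning("%s", w)
    return FeatureVector(values, config, warns)


def write_features_csv(path, feature: FeatureVector, complex_id: str = "complex") -> None:
    """One-row CSV (labelled columns) plus a JSON sidecar with the resolved
    config and warnings."""
    import pandas as pd

    df = pd.DataFrame([feature.values], index=[complex_id], columns=feature.labels())
    df.to_csv(path)
    sidecar = Path(str(path)).with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"config": feature.config.to_dict(), "warnings": feature.warnings,
         "n_features": len(feature)}, indent=2))
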