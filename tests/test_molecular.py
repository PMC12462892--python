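"""Structure parsing, element pairs, selections and featurization."""

import numpy as np
import pytest

from phl.molecular import (AtomSet, EmptySelectionError, FeatureConfig,
                           VDW_RADII, element_pairs, featurize_complex,
                           pair_atom_selection, read_structures,
                           write_features_csv)

TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  O   ALA A   1       1.200   0.000   0.000  1.00  0.00           O
ATOM      3  H   ALA A   1       2.000   0.000   0.000  1.00  0.00           H
END
"""

# same atoms without the element column: exercises the atom-name fallback
TOY_PDB_NO_ELEMENT = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  O   ALA A   1       1.200   0.000   0.000  1.00  0.00
END
"""

TOY_SDF = """\
toy
  phl

  2  1  0  0  0  0  0  0  0  0999 V2000
    3.0000    0.0000    0.0000 O   0  0
    4.1000    0.0000    0.0000 Cl  0  0
  1  2  1  0
M  END
$$$$
"""

TOY_MOL2 = """\
@<TRIPOS>MOLECULE
toy
2 1
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 O1 3.0 0.0 0.0 O.2
2 CL1 4.1 0.0 0.0 Cl
@<TRIPOS>BOND
1 1 2 1
"""


@pytest.fixture
def toy_files(tmp_path):
    p = tmp_path / "prot.pdb"
    s = tmp_path / "lig.sdf"
    m = tmp_path / "lig.mol2"
    p.write_text(TOY_PDB)
    s.write_text(TOY_SDF)
    m.write_text(TOY_MOL2)
    return p, s, m


def test_read_structures_filters_and_radii(toy_files):
    p, s, _ = toy_files
    prot, lig = read_structures(p, s)
    assert list(prot.elements) == ["C", "O"]          # H dropped
    assert list(lig.elements) == ["O", "Cl"]          # Cl recognized
    assert lig.radii[1] == VDW_RADII["Cl"]
    assert prot.provenance["n_kept"] == 2


def test_read_mol2_ligand(toy_files):
    p, _, m = toy_files
    _, lig = read_structures(p, m)
    assert list(lig.elements) == ["O", "Cl"]


def test_element_fallback_from_atom_name(tmp_path):
    # files without an element column still parse (the parser derives the
    # element from the atom name) ...
    path = tmp_path / "noelem.pdb"
    path.write_text(TOY_PDB_NO_ELEMENT)
    prot, _ = read_structures(path, _write_sdf(tmp_path))
    assert list(prot.elements) == ["C", "O"]
    # ... and the in-house name heuristic handles two-letter elements
    from phl.molecular import _element_from_name
    assert _element_from_name(" CL1") == "Cl"
    assert _element_from_name("BR2") == "Br"
    assert _element_from_name("1HG") == "H"
    assert _element_from_name(" CA ") == "C"


def _write_sdf(tmp_path):
    s = tmp_path / "l.sdf"
    s.write_text(TOY_SDF)
    return s


def test_element_pairs_fixed_and_stable():
    pairs = element_pairs()
    assert len(pairs) == 40
    assert pairs == [(pe, le) for pe in "CNOS"
                     for le in ["H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]]
    assert ("S", "I") in pairs
    assert all(pe != "H" for pe, _ in pairs)
    assert element_pairs() == pairs      # stable across calls


def test_pair_selection_cutoff_rule():
    lig = AtomSet.from_lists(["O"], [[0.0, 0.0, 0.0]], "ligand")
    prot = AtomSet.from_lists(["C", "C", "S"],
                              [[11.9, 0, 0], [12.1, 0, 0], [1.0, 0, 0]], "protein")
    sel = pair_atom_selection(prot, lig, ("C", "O"), cutoff=12.0)
    # kept: one C within 12 A plus the ligand O; the 12.1 A C is dropped
    assert sorted(sel.elements) == ["C", "O"]
    empty = pair_atom_selection(prot, lig, ("S", "I"), cutoff=12.0)
    assert len(empty) == 1  # protein S kept, no ligand I
    none = pair_atom_selection(
        AtomSet.from_lists([], np.zeros((0, 3)), "protein"), lig, ("N", "I"))
    assert len(none) == 0


def test_pair_selection_matches_quadratic_oracle():
    rng = np.random.default_rng(21)
    prot = AtomSet.from_lists(["C"] * 40, rng.uniform(-20, 20, (40, 3)), "protein")
    lig = AtomSet.from_lists(["O"] * 5, rng.uniform(-3, 3, (5, 3)), "ligand")
    sel = pair_atom_selection(prot, lig, ("C", "O"), cutoff=12.0)
    d = np.linalg.norm(prot.coords[:, None] - lig.coords[None], axis=-1)
    expected = (d.min(axis=1) <= 12.0).sum() + 5
    assert len(sel) == expected


@pytest.mark.parametrize("k,expected", [(5, 2160), (10, 3960)])
def test_feature_vector_length(k, expected):
    prot = AtomSet.from_lists(["C"], [[0, 0, 0]], "protein")
    lig = AtomSet.from_lists(["O"], [[3, 0, 0]], "ligand")
    config = FeatureConfig(k=k, spacing=0.9)   # coarse grid keeps the toy fast
    fv = featurize_complex(prot, lig, config)
    assert len(fv) == expected == (k + 1) * 9 * 40
    assert len(fv.labels()) == expected


def test_toy_complex_features_sane_and_deterministic(tmp_path):
    prot = AtomSet.from_lists(["C"], [[0, 0, 0]], "protein")
    lig = AtomSet.from_lists(["O"], [[3, 0, 0]], "ligand")
    config = FeatureConfig(k=3, spacing=0.9)
    fv1 = featurize_complex(prot, lig, config)
    fv2 = featurize_complex(prot, lig, config)
    assert np.array_equal(fv1.values, fv2.values)   # bitwise deterministic
    pairs = element_pairs()
    co = pairs.index(("C", "O"))
    for iv in range(9):
        blk = fv1.block(co, iv)
        assert blk[0] in (1.0, 2.0)                  # beta0 of 1-2 blobs
        assert (blk[1:] >= 0).all()
    # pairs with no atoms at all give zero blocks
    si = pairs.index(("S", "I"))
    assert not fv1.block(si, 0).any()
    # CSV + sidecar round trip
    out = tmp_path / "feats.csv"
    write_features_csv(out, fv1, "toy")
    import pandas as pd, json
    df = pd.read_csv(out, index_col=0)
    assert df.shape == (1, len(fv1))
    sidecar = json.loads((tmp_path / "feats.json").read_text())
    assert sidecar["n_features"] == len(fv1)


def test_translation_invariance_with_snapped_origin():
    prot = AtomSet.from_lists(["C"], [[0, 0, 0]], "protein")
    lig = AtomSet.from_lists(["O"], [[3, 0, 0]], "ligand")
    shift = np.array([13.0, -7.0, 5.0])
    prot2 = AtomSet(prot.elements, prot.coords + shift, prot.radii, "protein")
    lig2 = AtomSet(lig.elements, lig.coords + shift, lig.radii, "ligand")
    config = FeatureConfig(k=3, spacing=0.9)
    a = featurize_complex(prot, lig, config)
    b = featurize_complex(prot2, lig2, config)
    # grid origin is snapped to the molecule frame: bitwise identical
    assert np.array_equal(a.values, b.values)


def test_empty_complex_raises():
    empty = AtomSet.from_lists([], np.zeros((0, 3)), "protein")
    lig = AtomSet.from_lists([], np.zeros((0, 3)), "ligand")
    with pytest.raises(EmptySelectionError):
        featurize_complex(empty, lig, FeatureConfig(k=2))
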