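"""Structure parsing, moiety labels and core geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pdnakit.structure import (
    PDBParseError,
    PHOSPHATE_ATOMS,
    SUGAR_ATOMS,
    assign_moiety,
    center_of_mass,
    radius_of_gyration,
    read_structure,
    residue_exposure_percent,
    sasa,
    shrake_rupley_sasa,
    write_pdb,
)
from pdnakit.synthetic import build_bdna

from conftest import make_atom, make_residue, make_structure, SEQUENCE_38BP


class TestReadStructure:
    def test_single_glycine(self, gly_pdb_text):
        s = read_structure(gly_pdb_text)
        assert len(s.chains) == 1
        residues = list(s.residues())
        assert len(residues) == 1
        assert residues[0].polymer_class == "protein"
        assert residues[0].name == "GLY"

    def test_synthetic_duplex_roundtrip(self):
        built = build_bdna(SEQUENCE_38BP)
        parsed = read_structure(write_pdb(built))
        dna_chains = [
            cid for cid, res in parsed.chains.items()
            if all(r.polymer_class == "dna" for r in res)
        ]
        assert len(dna_chains) == 2
        assert sum(len(c) for c in parsed.chains.values()) == 76
        assert len(parsed.atoms()) == len(built.atoms())

    def test_unknown_residue_is_other(self, gly_pdb_text):
        text = gly_pdb_text.replace("GLY", "XYZ")
        s = read_structure(text)
        assert next(s.residues()).polymer_class == "other"

    def test_malformed_coordinate_names_line(self, gly_pdb_text):
        bad = gly_pdb_text.replace("   1.458", "  abcdef", 1)
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(bad)

    def test_empty_input(self):
        with pytest.raises(PDBParseError):
            read_structure("")
        with pytest.raises(PDBParseError):
            read_structure("HEADER    NOTHING\nEND\n")


class TestMoiety:
    @pytest.mark.parametrize(
        "atom_name,resname,expected",
        [
            ("P", "DG", "phosphate"),
            ("OP1", "DG", "phosphate"),
            ("O1P", "DG", "phosphate"),
            ("N7", "DG", "base"),
            ("C1'", "DA", "sugar"),
            ("O3'", "DT", "sugar"),
            ("O5'", "DC", "sugar"),
            ("O6", "DG", "base"),
        ],
    )
    def test_dictionary(self, atom_name, resname, expected):
        res = make_residue(resname, [make_atom("C1'", 0, 0, 0, "C")])
        assert assign_moiety(atom_name, res) == expected

    def test_non_dna_rejected(self):
        res = make_residue("ARG", [make_atom("CA", 0, 0, 0)])
        with pytest.raises(ValueError):
            assign_moiety("CA", res)

    def test_partition_disjoint_and_exhaustive(self, duplex):
        """Every DNA heavy atom maps to exactly one moiety."""
        assert not (PHOSPHATE_ATOMS & SUGAR_ATOMS)
        for res in duplex.residues("dna"):
            for atom in res.atoms:
                labels = [assign_moiety(atom.name, res)]
                assert labels[0] in ("phosphate", "sugar", "base")


class TestComRgyr:
    def test_com_unit_masses(self):
        atoms = [make_atom("C", 0, 0, 0, mass=1.0), make_atom("C", 2, 0, 0, mass=1.0)]
        assert np.allclose(center_of_mass(atoms), [1, 0, 0])

    def test_com_weighted(self):
        atoms = [make_atom("C", 0, 0, 0, mass=1.0), make_atom("C", 4, 0, 0, mass=3.0)]
        assert np.allclose(center_of_mass(atoms), [3, 0, 0])

    def test_com_single_atom_identity(self):
        a = make_atom("C", 1.5, -2.0, 7.0)
        assert np.allclose(center_of_mass([a]), a.coords)

    def test_zero_mass_error(self):
        a = make_atom("C", 0, 0, 0)
        a.mass = 0.0  # degenerate input bypassing construction validation
        with pytest.raises(ValueError):
            center_of_mass([a])
        with pytest.raises(ValueError):
            center_of_mass([])

    def test_rgyr_two_points(self):
        atoms = [make_atom("C", -1, 0, 0, mass=1.0), make_atom("C", 1, 0, 0, mass=1.0)]
        assert radius_of_gyration(atoms) == pytest.approx(1.0)

    def test_rgyr_single_atom_zero(self):
        assert radius_of_gyration([make_atom("C", 3, 2, 1)]) == pytest.approx(0.0, abs=1e-12)

    def test_rgyr_uniform_ball(self):
        """Uniform density ball of radius R has Rgyr = R·sqrt(3/5)."""
        rng = np.random.default_rng(11)
        R = 5.0
        n = 20000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= R * rng.random(n)[:, None] ** (1 / 3)
        atoms = [make_atom("C", *p, mass=1.0) for p in pts]
        assert radius_of_gyration(atoms) == pytest.approx(R * math.sqrt(3 / 5), rel=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rgyr_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(12, 3)) * 4
        masses = rng.random(12) + 0.5
        atoms = [make_atom("C", *c, mass=m) for c, m in zip(coords, masses)]
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.normal(size=3) * 10
        moved = [make_atom("C", *(rot @ c + shift), mass=m) for c, m in zip(coords, masses)]
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(atoms), rel=1e-9)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        a = make_atom("C", 0, 0, 0, radius=1.5)
        total = shrake_rupley_sasa([a], probe_radius=1.4).sum()
        assert total == pytest.approx(4 * math.pi * 2.9**2, rel=1e-3)

    def test_coincident_atoms_count_once(self):
        atoms = [make_atom("C", 0, 0, 0), make_atom("C", 0, 0, 0)]
        single = shrake_rupley_sasa([atoms[0]]).sum()
        assert shrake_rupley_sasa(atoms).sum() == pytest.approx(single, rel=1e-6)

    def test_distant_atoms_additive(self):
        atoms = [make_atom("C", 0, 0, 0), make_atom("C", 50, 0, 0)]
        single = shrake_rupley_sasa([atoms[0]]).sum()
        assert shrake_rupley_sasa(atoms).sum() == pytest.approx(2 * single, rel=1e-9)

    def test_occluder_never_increases_area(self):
        base = [make_atom("C", 0, 0, 0), make_atom("N", 2.5, 0.4, 0)]
        before = shrake_rupley_sasa(base)
        after = shrake_rupley_sasa(base + [make_atom("O", 1.2, 1.8, 0.5)])
        assert np.all(after[:2] <= before + 1e-9)

    def test_min_points(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([make_atom("C", 0, 0, 0)], n_sphere_points=8)

    def test_matches_grid_oracle(self):
        """Shrake–Rupley within 2% of a brute-force point-count oracle."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = rng.integers(3, 10)
            coords = rng.normal(size=(n, 3)) * 2.0
            radii = rng.uniform(1.2, 1.9, size=n)
            atoms = [make_atom("C", *c, radius=r) for c, r in zip(coords, radii)]
            mine = shrake_rupley_sasa(atoms, n_sphere_points=960).sum()
            oracle = _grid_sasa_oracle(atoms)
            assert mine == pytest.approx(oracle, rel=0.02)

    def test_matches_biotite_on_duplex(self, duplex):
        """Independent SASA implementation agrees on a whole duplex."""
        bst = pytest.importorskip("biotite.structure")
        atoms = duplex.atoms()
        arr = bst.AtomArray(len(atoms))
        flat = [(r, a) for r in duplex.residues() for a in r.atoms]
        arr.coord = np.array([a.coords for _, a in flat])
        arr.element = np.array([a.element for _, a in flat])
        arr.res_name = np.array([r.name for r, _ in flat])
        arr.atom_name = np.array([a.name for _, a in flat])
        ref = float(np.nansum(bst.sasa(arr, vdw_radii="Single", point_number=500)))
        mine = sum(sasa(duplex).values())
        assert mine == pytest.approx(ref, rel=0.01)


def _grid_sasa_oracle(atoms, probe=1.4, n_points=8000):
    """Independent SASA: dense lattice point counting per expanded sphere."""
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5**0.5) * k
    unit = np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    total = 0.0
    for i, a in enumerate(atoms):
        R = a.vdw_radius + probe
        pts = a.coords + R * unit
        ok = np.ones(n_points, bool)
        for j, b in enumerate(atoms):
            if i == j:
                continue
            ok &= ((pts - b.coords) ** 2).sum(axis=1) > (b.vdw_radius + probe) ** 2
        total += 4 * math.pi * R * R * ok.mean()
    return total


class TestExposure:
    def test_isolated_residue_is_100_percent(self):
        atoms = [make_atom("CA", 0, 0, 0), make_atom("N", 1.5, 0, 0, "N")]
        res = make_residue("GLY", atoms)
        s = make_structure([res])
        iso = sum(shrake_rupley_sasa(atoms))
        pct = residue_exposure_percent(s, reference_max_sasa={"GLY": iso})
        assert pct[res.key] == pytest.approx(100.0, rel=1e-6)

    def test_buried_residue_is_zero(self):
        core = make_residue("LYS", [make_atom("NZ", 0, 0, 0, "N")], seq_number=1)
        # cage of carbons fully enclosing the central atom
        k = np.arange(80) + 0.5
        phi = np.arccos(1 - 2 * k / 80)
        theta = np.pi * (1 + 5**0.5) * k
        shell_pts = 3.0 * np.c_[
            np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
        ]
        cage = make_residue(
            "GLY", [make_atom("CA", *p, serial=i + 2) for i, p in enumerate(shell_pts)],
            seq_number=2,
        )
        s = make_structure([core, cage])
        pct = residue_exposure_percent(s)
        assert pct[core.key] == pytest.approx(0.0, abs=1e-6)

    def test_missing_reference_names_residue(self):
        res = make_residue("GLY", [make_atom("CA", 0, 0, 0)])
        with pytest.raises(KeyError, match="GLY"):
            residue_exposure_percent(make_structure([res]), reference_max_sasa={"ALA": 129.0})

    def test_half_occluded_dimer_matches_oracle(self):
        """Exposure of a partially occluded residue agrees with the grid oracle."""
        res_a = make_residue("GLY", [make_atom("CA", 0, 0, 0)], seq_number=1)
        res_b = make_residue("GLY", [make_atom("CA", 2.8, 0, 0, serial=2)], seq_number=2)
        s = make_structure([res_a, res_b])
        iso = sum(shrake_rupley_sasa(res_a.atoms))
        pct = residue_exposure_percent(s, reference_max_sasa={"GLY": iso})
        both = [res_a.atoms[0], res_b.atoms[0]]
        oracle_total = _grid_sasa_oracle(both)
        # symmetric dimer: each atom holds half the oracle total
        assert pct[res_a.key] == pytest.approx(100.0 * (oracle_total / 2) / iso, rel=0.02)
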