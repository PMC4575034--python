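"""Trajectory observables: COM distance, Rgyr, RDF, contacts, shortening."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdnakit.structure import write_pdb
from pdnakit.synthetic import build_bdna, generate_approach_trajectory, place_probe_residue
from pdnakit.trajectory import (
    Trajectory,
    atom_indices,
    com_distance_series,
    contact_pct_by_base,
    contact_pct_by_moiety,
    end_to_end_shortening,
    rdf_from_com,
    read_multi_model_pdb,
    read_xyz_frames,
    rgyr_series,
)

from conftest import make_atom, make_residue, make_structure


def _two_body_traj(n_frames=5, d=10.0):
    return generate_approach_trajectory(n_frames, d, d, 0.0, seed=0)


SEL_A = np.arange(8)
SEL_B = np.arange(8, 16)


class TestComDistance:
    def test_static_distance(self):
        series = com_distance_series(_two_body_traj(d=10.0), SEL_A, SEL_B)
        assert np.allclose(series.values, 10.0)

    def test_linear_approach_endpoints(self):
        traj = generate_approach_trajectory(100, 50, 10, 0.0, seed=1)
        series = com_distance_series(traj, SEL_A, SEL_B)
        assert series.values[0] == pytest.approx(50.0)
        assert series.values[-1] == pytest.approx(10.0)
        assert np.all(np.diff(series.values) <= 1e-9)

    def test_identical_selections_zero(self):
        series = com_distance_series(_two_body_traj(), SEL_A, SEL_A)
        assert np.allclose(series.values, 0.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            com_distance_series(_two_body_traj(), np.array([], dtype=int), SEL_B)


class TestRgyrSeries:
    def test_rigid_rotation_constant(self):
        traj = _two_body_traj(n_frames=10)
        rng = np.random.default_rng(2)
        frames = np.array([
            traj.frames[0] @ Rotation.random(random_state=int(s)).as_matrix().T
            + rng.normal(size=3) * 5
            for s in rng.integers(0, 1000, size=10)
        ])
        moved = Trajectory(traj.topology, frames, traj.dt)
        series = rgyr_series(moved, np.arange(16))
        assert np.allclose(series.values, series.values[0], rtol=1e-9)

    def test_isotropic_scaling_doubles(self):
        traj = _two_body_traj(n_frames=3)
        doubled = Trajectory(traj.topology, traj.frames * 2.0, traj.dt)
        a = rgyr_series(traj, SEL_A).values
        b = rgyr_series(doubled, SEL_A).values
        assert np.allclose(b, 2 * a)

    def test_breathing_sphere_tracks_radius(self):
        """A uniformly scaled blob's Rgyr scales with the planted factor."""
        traj = _two_body_traj(n_frames=2)
        factors = np.linspace(1.0, 3.0, 7)
        frames = np.array([traj.frames[0] * f for f in factors])
        series = rgyr_series(Trajectory(traj.topology, frames, 1.0), np.arange(16))
        assert np.allclose(series.values / series.values[0], factors)


class TestRdf:
    def _uniform_sphere_traj(self, n=4000, R=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= R * rng.random(n)[:, None] ** (1 / 3)
        ref = make_residue("LIG", [make_atom("C1", 0, 0, 0)], chain_id="X")
        tgt = make_residue(
            "LIG", [make_atom(f"C{i+2}", *p, serial=i + 2) for i, p in enumerate(pts)],
            chain_id="Y",
        )
        topo = make_structure([ref, tgt])
        frames = np.array([[a.coords for a in topo.atoms()]])
        return Trajectory(topo, frames, 1.0), n, R

    def test_uniform_gas_is_flat(self):
        traj, n, R = self._uniform_sphere_traj()
        centres, g = rdf_from_com(traj, np.array([0]), np.arange(1, n + 1), 1.0, R)
        assert np.allclose(g[2:-1], 1.0, atol=0.25)

    def test_integrates_to_count(self):
        traj, n, R = self._uniform_sphere_traj()
        centres, g = rdf_from_com(traj, np.array([0]), np.arange(1, n + 1), 0.5, R)
        shell_vol = 4 / 3 * np.pi * ((centres + 0.25) ** 3 - (centres - 0.25) ** 3)
        rho = n / (4 / 3 * np.pi * R**3)
        recovered = (g * shell_vol * rho).sum()
        assert recovered == pytest.approx(n, rel=0.02)

    def test_thin_shell_peak(self):
        r0 = 6.0
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(500, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * r0
        ref = make_residue("LIG", [make_atom("C1", 0, 0, 0)], chain_id="X")
        tgt = make_residue(
            "LIG", [make_atom(f"C{i+2}", *p, serial=i + 2) for i, p in enumerate(pts)],
            chain_id="Y",
        )
        topo = make_structure([ref, tgt])
        traj = Trajectory(topo, np.array([[a.coords for a in topo.atoms()]]), 1.0)
        centres, g = rdf_from_com(traj, np.array([0]), np.arange(1, 501), 1.0, 10.0)
        assert centres[np.argmax(g)] == pytest.approx(r0, abs=0.5)

    def test_empty_target_all_zero(self):
        traj, n, R = self._uniform_sphere_traj(n=50)
        _, g = rdf_from_com(traj, np.array([0]), np.array([], dtype=int), 1.0, R)
        assert np.all(g == 0)

    def test_rmax_beyond_half_box(self):
        traj, n, R = self._uniform_sphere_traj(n=50)
        boxed = Trajectory(traj.topology, traj.frames, 1.0, box=np.array([15.0] * 3))
        with pytest.raises(ValueError):
            rdf_from_com(boxed, np.array([0]), np.arange(1, 51), 1.0, 10.0)


def _planted_contact_complex(targets):
    """Duplex plus ARG probes planted 3.0 Å from the requested target atoms."""
    s = build_bdna("GCATGCAT")
    for chain, seq, atom in targets:
        place_probe_residue(s, (chain, seq, atom), "NH1", 3.0, resname="ARG")
    return s


class TestContactPercentages:
    def test_phosphate_only_snapshot(self):
        s = _planted_contact_complex([("A", 3, "OP1")])
        sel = atom_indices(s, polymer_class="protein")
        traj = Trajectory(s, np.array([[a.coords for a in s.atoms()]] * 3), 1.0)
        pct = contact_pct_by_moiety(traj, [0.0], sel)
        assert pct[0.0]["phosphate"] == pytest.approx(100.0)
        assert pct[0.0]["base"] == 0.0

    def test_percentages_sum_to_100(self):
        s = _planted_contact_complex([("A", 3, "OP1"), ("A", 5, "O3'"), ("A", 1, "O6")])
        sel = atom_indices(s, polymer_class="protein")
        traj = Trajectory(s, np.array([[a.coords for a in s.atoms()]]), 1.0)
        pct = contact_pct_by_moiety(traj, [0.0], sel)
        assert sum(pct[0.0].values()) == pytest.approx(100.0)

    def test_no_contacts_warns_zero(self):
        s = build_bdna("GCAT")
        place_probe_residue(s, ("A", 3, "N7"), "NH1", 30.0, resname="ARG",
                            clearance=3.91)
        sel = atom_indices(s, polymer_class="protein")
        traj = Trajectory(s, np.array([[a.coords for a in s.atoms()]]), 1.0)
        with pytest.warns(UserWarning):
            pct = contact_pct_by_moiety(traj, [0.0], sel)
        assert sum(pct[0.0].values()) == 0.0

    def test_base_contacts_guanine_only(self):
        s = build_bdna("GCATGCAT")
        dg = next(r for r in s.residues("dna") if r.name == "DG")
        place_probe_residue(s, (dg.chain_id, dg.seq_number, "O6"), "NH1", 3.0)
        sel = atom_indices(s, polymer_class="protein")
        traj = Trajectory(s, np.array([[a.coords for a in s.atoms()]] * 4), 1.0)
        pct = contact_pct_by_base(traj, window_ns=10.0, sel_terminal=sel)
        assert pct["G"] == pytest.approx(100.0)
        assert pct["A"] == pct["C"] == pct["T"] == 0.0


class TestShortening:
    def _dna_traj(self, scale_per_frame):
        s = build_bdna("GCATGCATGC")
        base = np.array([a.coords for a in s.atoms()])
        com = base.mean(axis=0)
        frames = np.array([com + (base - com) * f for f in scale_per_frame])
        return s, Trajectory(s, frames, 1.0)

    def test_reference_length_zero_pct(self):
        s, traj = self._dna_traj([1.0, 1.0])
        ref = com_distance_series(traj, *_terminal_sel(s)).values[0]
        series = end_to_end_shortening(traj, ref)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_quarter_shortening(self):
        s, traj = self._dna_traj([1.0, 0.75])
        ref = com_distance_series(traj, *_terminal_sel(s)).values[0]
        series = end_to_end_shortening(traj, ref)
        assert series.values[1] == pytest.approx(25.0, abs=1e-6)

    def test_planted_bending_curve(self):
        factors = np.linspace(1.0, 0.6, 9)
        s, traj = self._dna_traj(factors)
        ref = com_distance_series(traj, *_terminal_sel(s)).values[0]
        series = end_to_end_shortening(traj, ref)
        assert np.allclose(series.values, 100 * (1 - factors), atol=1e-6)

    def test_bad_reference(self):
        s, traj = self._dna_traj([1.0, 1.0])
        with pytest.raises(ValueError):
            end_to_end_shortening(traj, 0.0)


def _terminal_sel(structure):
    from pdnakit.trajectory import _terminal_basepair_indices

    return _terminal_basepair_indices(structure)


class TestReaders:
    def test_multi_model_pdb(self):
        s = build_bdna("GCAT")
        block = write_pdb(s)
        body = "".join(
            f"MODEL {i}\n" + block.replace("END\n", "ENDMDL\n") for i in (1, 2, 3)
        )
        traj = read_multi_model_pdb(body, dt_ns=0.5)
        assert traj.n_frames == 3
        assert traj.frames.shape[1] == len(s.atoms())
        assert np.allclose(traj.frames[0], traj.frames[2])

    def test_xyz_frames_with_sidecar(self):
        topo = make_structure([
            make_residue("LIG", [make_atom("C1", 0, 0, 0), make_atom("C2", 1, 0, 0)]),
        ])
        text = "0 0 0\n1 0 0\n\n0 0 1\n1 0 1\n"
        sidecar = json.loads('{"dt_ns": 2.0}')
        traj = read_xyz_frames(text, topo, sidecar)
        assert traj.n_frames == 2 and traj.dt == 2.0
        assert np.allclose(traj.frames[1][:, 2], 1.0)

    def test_frame_time_mapping(self):
        traj = generate_approach_trajectory(11, 20, 10, 0.0, seed=0, dt_ns=2.0)
        assert traj.frame_at(0.0) == 0
        assert traj.frame_at(20.0) == 10
        assert traj.frame_at(9.1) == 5  # nearest frame
        with pytest.raises(ValueError):
            traj.frame_at(100.0)
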