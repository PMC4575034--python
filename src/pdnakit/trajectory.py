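"""Multi-frame trajectory observables for DNA–nanoparticle complexation.

Computes the standard post-processing series of an approach/binding
simulation: centre-of-mass separation, radius of gyration, a radial
distribution function about a reference centre of mass, contact
percentages split by DNA moiety or base, and dsDNA end-to-end shortening.

Trajectories are plain coordinate stacks over a static topology; readers
accept multi-MODEL PDB or whitespace XYZ-per-frame text with a sidecar
dict carrying the frame spacing (ns) and optional periodic box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure, assign_moiety, read_structure

__all__ = [
    "Trajectory",
    "SeriesResult",
    "read_multi_model_pdb",
    "read_xyz_frames",
    "atom_indices",
    "com_distance_series",
    "rgyr_series",
    "rdf_from_com",
    "contact_pct_by_moiety",
    "contact_pct_by_base",
    "end_to_end_shortening",
]


@dataclass
class Trajectory:
    """Frames of coordinates (Å) over a fixed topology; dt in ns per frame."""

    topology: ComplexStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float
    box: np.ndarray | None = None  # orthorhombic box lengths, Å

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        n_atoms = len(self.topology.atoms())
        if self.frames.ndim != 3 or self.frames.shape[1] != n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with "
                f"{n_atoms} topology atoms"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def frame_at(self, t_ns: float) -> int:
        """Index of the frame nearest to the requested time."""
        if t_ns < 0 or t_ns > self.times[-1] + 0.5 * self.dt:
            raise ValueError(f"time {t_ns} ns outside trajectory span")
        return int(round(t_ns / self.dt))

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology.atoms()])


@dataclass
class SeriesResult:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack((self.times, self.values)),
                   delimiter=",", header=f"time_ns,{self.label or 'value'}", comments="")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_multi_model_pdb(pdb_text: str, dt_ns: float, box=None) -> Trajectory:
    """Read a MODEL/ENDMDL multi-frame PDB; model 1 defines the topology."""
    blocks = _split_models(pdb_text)
    topology = read_structure(blocks[0])
    frames = []
    for block in blocks:
        frames.append(_coords_from_pdb_block(block))
    return Trajectory(topology, np.array(frames), dt_ns,
                      None if box is None else np.asarray(box, float))


def _split_models(pdb_text: str) -> list[str]:
    models: list[list[str]] = []
    current: list[str] = []
    saw_model = False
    for line in pdb_text.splitlines():
        if line.startswith("MODEL"):
            saw_model = True
            current = []
        elif line.startswith("ENDMDL"):
            models.append(current)
            current = []
        elif line.startswith(("ATOM  ", "HETATM", "TER")):
            current.append(line)
    if not saw_model:
        models = [current]
    return ["\n".join(m) + "\nEND\n" for m in models if m]


def _coords_from_pdb_block(block: str) -> np.ndarray:
    coords = []
    for line in block.splitlines():
        if line.startswith(("ATOM  ", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return np.array(coords)


def read_xyz_frames(xyz_text: str, topology: ComplexStructure, sidecar: dict) -> Trajectory:
    """Read whitespace-separated XYZ-per-frame text (one 'x y z' triple per
    atom line, frames separated by blank lines) with sidecar
    ``{"dt_ns": ..., "box": ...}``."""
    frames = []
    current: list[list[float]] = []
    for line in xyz_text.splitlines():
        stripped = line.strip()
        if not stripped:
            if current:
                frames.append(current)
                current = []
            continue
        parts = stripped.split()
        current.append([float(parts[-3]), float(parts[-2]), float(parts[-1])])
    if current:
        frames.append(current)
    return Trajectory(topology, np.array(frames, dtype=float),
                      float(sidecar["dt_ns"]), sidecar.get("box"))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def atom_indices(
    structure: ComplexStructure,
    chain_id: str | None = None,
    polymer_class: str | None = None,
    resnames: set[str] | None = None,
    moiety: str | None = None,
) -> np.ndarray:
    """Flat atom indices (topology order) matching the given filters."""
    idx = []
    i = 0
    for residues in structure.chains.values():
        for res in residues:
            for atom in res.atoms:
                keep = True
                if chain_id is not None and res.chain_id != chain_id:
                    keep = False
                if polymer_class is not None and res.polymer_class != polymer_class:
                    keep = False
                if resnames is not None and res.name not in resnames:
                    keep = False
                if moiety is not None:
                    keep = keep and res.polymer_class == "dna" and \
                        assign_moiety(atom.name, res) == moiety
                if keep:
                    idx.append(i)
                i += 1
    return np.array(idx, dtype=int)


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def com_distance_series(traj: Trajectory, sel_a, sel_b) -> SeriesResult:
    """|COM(a) − COM(b)| per frame (Å), minimum-image when a box is set."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    masses = traj.masses
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        delta = _com(frame[sel_a], masses[sel_a]) - _com(frame[sel_b], masses[sel_b])
        values[t] = np.linalg.norm(_minimum_image(delta, traj.box))
    return SeriesResult(traj.times, values, "com_distance_A")


def rgyr_series(traj: Trajectory, sel) -> SeriesResult:
    """Radius of gyration of a selection per frame (Å)."""
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    masses = traj.masses[sel]
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        coords = frame[sel]
        com = _com(coords, masses)
        values[t] = np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum())
    return SeriesResult(traj.times, values, "rgyr_A")


def rdf_from_com(
    traj: Trajectory, sel_ref, sel_target, bin_width: float, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """g(r) of target atoms about the reference selection's centre of mass.

    Shell counts averaged over frames, normalized by shell volume and by
    the target's mean number density inside the analysis sphere, so a
    uniform (ideal-gas) target gives g(r) ≈ 1. Returns (bin_centres, g).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if traj.box is not None and r_max > 0.5 * float(np.min(traj.box)):
        raise ValueError("r_max exceeds half the smallest box length")
    sel_ref = np.asarray(sel_ref, dtype=int)
    sel_target = np.asarray(sel_target, dtype=int)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centres))
    masses = traj.masses
    n_inside = 0.0
    for frame in traj.frames:
        com = _com(frame[sel_ref], masses[sel_ref]) if sel_ref.size else np.zeros(3)
        if sel_target.size == 0:
            continue
        delta = _minimum_image(frame[sel_target] - com, traj.box)
        r = np.linalg.norm(delta, axis=1)
        hist += np.histogram(r, bins=edges)[0]
        n_inside += np.count_nonzero(r < r_max)
    if n_inside == 0:
        return centres, np.zeros_like(centres)
    hist /= traj.n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_mean = (n_inside / traj.n_frames) / (4.0 / 3.0 * np.pi * r_max ** 3)
    return centres, hist / (shell_vol * rho_mean)


def _moiety_indices(structure: ComplexStructure) -> dict[str, np.ndarray]:
    return {m: atom_indices(structure, moiety=m) for m in ("phosphate", "sugar", "base")}


def _count_pairs(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> int:
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree = cKDTree(coords_b)
    return int(sum(len(hits) for hits in cKDTree(coords_a).query_ball_tree(tree, cutoff)))


def contact_pct_by_moiety(
    traj: Trajectory, frames_at_ns, sel_terminal, cutoff: float = 3.5
) -> dict[float, dict[str, float]]:
    """Contact percentages to phosphate/sugar/base at the requested snapshots.

    Contacts are atom pairs between the terminal-group selection and DNA
    atoms within the cutoff; percentages are per snapshot over all DNA
    contacts. A snapshot without contacts reports zeros with a warning.
    """
    sel_terminal = np.asarray(sel_terminal, dtype=int)
    groups = _moiety_indices(traj.topology)
    result = {}
    for t_ns in frames_at_ns:
        frame = traj.frames[traj.frame_at(t_ns)]
        counts = {
            m: _count_pairs(frame[sel_terminal], frame[idx], cutoff)
            for m, idx in groups.items()
        }
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"no contacts at snapshot {t_ns} ns; percentages reported as 0")
            result[t_ns] = {m: 0.0 for m in counts}
        else:
            result[t_ns] = {m: 100.0 * n / total for m, n in counts.items()}
    return result


def contact_pct_by_base(
    traj: Trajectory, window_ns: float, sel_terminal, cutoff: float = 3.5
) -> dict[str, float]:
    """Contact percentages per base (A/C/G/T) pooled over the last window.

    Only base-moiety atoms count; 100% corresponds to the total number of
    base contacts in the window.
    """
    sel_terminal = np.asarray(sel_terminal, dtype=int)
    base_idx: dict[str, list[int]] = {b: [] for b in "ACGT"}
    i = 0
    for residues in traj.topology.chains.values():
        for res in residues:
            for atom in res.atoms:
                if res.polymer_class == "dna" and \
                        assign_moiety(atom.name, res) == "base" and res.base_type:
                    base_idx[res.base_type].append(i)
                i += 1
    t_start = max(0.0, traj.times[-1] - window_ns)
    frame_ids = [t for t, time in enumerate(traj.times) if time >= t_start]
    counts = {b: 0 for b in "ACGT"}
    for t in frame_ids:
        frame = traj.frames[t]
        for b, idx in base_idx.items():
            counts[b] += _count_pairs(frame[sel_terminal], frame[np.array(idx, int)], cutoff)
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no base contacts in window; percentages reported as 0")
        return {b: 0.0 for b in "ACGT"}
    return {b: 100.0 * n / total for b, n in counts.items()}


def end_to_end_shortening(
    traj: Trajectory,
    reference_length: float,
    sel_end1=None,
    sel_end2=None,
) -> SeriesResult:
    """dsDNA shortening (%) per frame: 100 × (1 − L(t)/L_ref).

    L(t) is the distance between the centres of mass of the two terminal
    base pairs; the reference length comes from a free-DNA run. Terminal
    base-pair selections are resolved automatically from the two DNA
    chains when not given.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if sel_end1 is None or sel_end2 is None:
        sel_end1, sel_end2 = _terminal_basepair_indices(traj.topology)
    length = com_distance_series(traj, sel_end1, sel_end2)
    return SeriesResult(traj.times, 100.0 * (1.0 - length.values / reference_length),
                        "shortening_pct")


def _terminal_basepair_indices(structure: ComplexStructure):
    dna_chains = [
        (cid, residues) for cid, residues in structure.chains.items()
        if residues and residues[0].polymer_class == "dna"
    ]
    if len(dna_chains) != 2:
        raise ValueError("automatic terminal base-pair selection needs exactly 2 DNA chains")
    (c1, r1), (c2, r2) = dna_chains
    offsets = {}
    i = 0
    for residues in structure.chains.values():
        for res in residues:
            offsets[id(res)] = (i, i + len(res.atoms))
            i += len(res.atoms)

    def _span(res):
        lo, hi = offsets[id(res)]
        return list(range(lo, hi))

    # pair 1: chain1 5' residue + chain2 3' residue; pair 2: the opposite ends
    end1 = np.array(_span(r1[0]) + _span(r2[-1]), dtype=int)
    end2 = np.array(_span(r1[-1]) + _span(r2[0]), dtype=int)
    return end1, end2
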