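"""Synthetic fixtures: idealized B-DNA, planted-contact complexes,
redundancy-structured collections, approach trajectories and Gaussian
coordinate ensembles.

The duplex builder places template nucleotides on an ideal helix (3.38 Å
rise, 36° twist by default). Base rings are generated from idealized
planar polygon geometry and paired so that the Watson–Crick anchor
distance (purine N1 to pyrimidine N3) is identical for every pair; the
sugar–phosphate backbone uses plausible fixed offsets. The fidelity target
is correct atom naming, moiety membership and controllable inter-atomic
distances — not crystallographic realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._elements import element_mass, element_vdw_radius, guess_element
from .nonredundancy import DomainAssignment
from .structure import AtomRecord, ComplexStructure, ResidueRecord
from .trajectory import Trajectory

__all__ = [
    "BDnaSpec",
    "CollectionSpec",
    "SyntheticCollection",
    "build_bdna",
    "place_probe_residue",
    "generate_collection",
    "generate_approach_trajectory",
    "gaussian_ensemble",
    "COMPLEMENT",
    "CANONICAL_DONOR_ATOM",
    "BASE_ACCEPTOR_ATOM",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Side-chain donor atom used when planting a hydrogen-bond contact.
CANONICAL_DONOR_ATOM = {
    "ARG": "NH1", "LYS": "NZ", "SER": "OG", "THR": "OG1",
    "ASN": "ND2", "GLN": "NE2", "TYR": "OH", "HIS": "NE2", "TRP": "NE1",
}

#: Representative groove acceptor atom per base for planted base contacts.
BASE_ACCEPTOR_ATOM = {"A": "N7", "C": "O2", "G": "O6", "T": "O4"}

_WC_ANCHOR_DISTANCE = 2.9  # Å, purine N1 ↔ pyrimidine N3
_RING_BOND = 1.39
_GLYCOSIDIC = 1.47


@dataclass
class BDnaSpec:
    """Recipe for an idealized B-DNA duplex."""

    sequence: str
    rise: float = 3.38
    twist: float = 36.0
    phosphorylated_5prime: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace(" ", "").replace("-", "")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Nucleotide templates (pair frame, base plane z = 0)
# ---------------------------------------------------------------------------

def _rot2(p: np.ndarray, angle: float, about: np.ndarray) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    d = p - about
    return about + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _hexagon(order: list[str], anchor: str) -> dict[str, np.ndarray]:
    """Regular hexagon (side = ring bond), anchor atom translated to origin.

    ``order`` walks the ring from the anchor; successive vertices step
    −60° so the ring extends toward −x with its Watson–Crick edge at +x.
    """
    pos = {}
    for k, name in enumerate(order):
        ang = math.radians(-60.0 * k)
        pos[name] = _RING_BOND * np.array([math.cos(ang), math.sin(ang)])
    shift = pos[anchor].copy()
    return {n: p - shift for n, p in pos.items()}


def _purine_template(base: str) -> dict[str, np.ndarray]:
    # hexagon N1→C2→N3→C4→C5→C6, stepping clockwise puts C6/O6/N6 on +y
    # (major-groove side) and C2/N2 on −y (minor-groove side)
    ring = _hexagon(["N1", "C2", "N3", "C4", "C5", "C6"], "N1")
    centre = np.array([-_RING_BOND, 0.0])

    # imidazole fused on the C4–C5 edge, regular pentagon on the outer side
    c4, c5 = ring["C4"], ring["C5"]
    mid = 0.5 * (c4 + c5)
    out = (mid - centre) / np.linalg.norm(mid - centre)
    apothem = _RING_BOND / (2.0 * math.tan(math.pi / 5.0))
    p_centre = mid + apothem * out
    step = math.radians(72.0)
    # walk C5 → N7 → C8 → N9 (→ C4); choose the rotation sense that ends on C4
    sense = 1.0
    probe = _rot2(c5, 4 * step * sense, p_centre)
    if np.linalg.norm(probe - c4) > 0.1:
        sense = -1.0
    ring["N7"] = _rot2(c5, step * sense, p_centre)
    ring["C8"] = _rot2(c5, 2 * step * sense, p_centre)
    ring["N9"] = _rot2(c5, 3 * step * sense, p_centre)

    def _exo(attached: str, dist: float, about=centre) -> np.ndarray:
        d = ring[attached] - about
        return ring[attached] + dist * d / np.linalg.norm(d)

    if base == "A":
        ring["N6"] = _exo("C6", 1.34)
    else:  # G
        ring["O6"] = _exo("C6", 1.23)
        ring["N2"] = _exo("C2", 1.34)
    ring["C1'"] = _exo("N9", _GLYCOSIDIC, about=p_centre)
    ring["_glyco"] = ring["N9"]
    return ring


def _pyrimidine_template(base: str) -> dict[str, np.ndarray]:
    # hexagon N3→C4→C5→C6→N1→C2 stepping counter-clockwise: C4 (N4/O4)
    # lands on +y (major groove), C2 (O2) on −y (minor groove)
    pos = {}
    for k, name in enumerate(["N3", "C4", "C5", "C6", "N1", "C2"]):
        ang = math.radians(60.0 * k)
        pos[name] = _RING_BOND * np.array([math.cos(ang), math.sin(ang)])
    shift = pos["N3"].copy()
    ring = {n: p - shift for n, p in pos.items()}
    centre = np.array([-_RING_BOND, 0.0])

    def _exo(attached: str, dist: float) -> np.ndarray:
        d = ring[attached] - centre
        return ring[attached] + dist * d / np.linalg.norm(d)

    ring["O2"] = _exo("C2", 1.23)
    if base == "C":
        ring["N4"] = _exo("C4", 1.34)
    else:  # T
        ring["O4"] = _exo("C4", 1.23)
        ring["C7"] = _exo("C5", 1.50)
    ring["C1'"] = _exo("N1", _GLYCOSIDIC)
    ring["_glyco"] = ring["N1"]
    return ring


#: Backbone offsets (u, v, w) from C1': u = in-plane glycosidic direction,
#: v = in-plane normal, w = chain direction (+z for strand I).
_BACKBONE_OFFSETS = {
    "O4'": (0.6, 1.1, 0.5),
    "C2'": (1.3, -0.7, 0.6),
    "C3'": (2.3, 0.1, 0.9),
    "O3'": (2.9, -0.6, 1.9),
    "C4'": (2.0, 1.3, 0.4),
    "C5'": (2.7, 2.2, -0.6),
    "O5'": (2.6, 2.0, -2.0),
    "P": (3.0, 1.4, -3.0),
    "OP1": (4.0, 2.4, -3.5),
    "OP2": (2.6, 0.2, -3.9),
}


def _nucleotide_template(base: str) -> dict[str, np.ndarray]:
    """Full nucleotide (base + backbone) in the strand-I pair frame, 3-D."""
    flat = _purine_template(base) if base in "AG" else _pyrimidine_template(base)
    glyco = flat.pop("_glyco")
    c1 = flat["C1'"]
    u2 = (c1 - glyco) / np.linalg.norm(c1 - glyco)
    u = np.array([u2[0], u2[1], 0.0])
    w = np.array([0.0, 0.0, 1.0])
    v = np.cross(w, u)
    template = {name: np.array([p[0], p[1], 0.0]) for name, p in flat.items()}
    c1_3d = template["C1'"]
    for name, (a, b, c) in _BACKBONE_OFFSETS.items():
        template[name] = c1_3d + a * u + b * v + c * w
    return template


_TEMPLATES = {b: _nucleotide_template(b) for b in "ACGT"}

#: Partner placement: 180° rotation about the pair y-axis, then the WC shift.
def _partner(p: np.ndarray) -> np.ndarray:
    return np.array([_WC_ANCHOR_DISTANCE - p[0], p[1], -p[2]])


def _make_atom(serial: int, name: str, coords: np.ndarray, charge: float = 0.0) -> AtomRecord:
    element = guess_element(name)
    return AtomRecord(
        serial=serial, name=name, element=element, coords=coords,
        mass=element_mass(element), vdw_radius=element_vdw_radius(element),
        partial_charge=charge,
    )


def build_bdna(spec: BDnaSpec | str) -> ComplexStructure:
    """Build an idealized antiparallel duplex from a sequence.

    Each phosphate carries formal charge −1; with free 5'-OH ends an n-bp
    duplex has 2(n−1) phosphates and net charge −2(n−1).
    """
    if isinstance(spec, str):
        spec = BDnaSpec(spec)
    seq = spec.sequence
    n = len(seq)
    twist = math.radians(spec.twist)

    structure = ComplexStructure(id="bdna", chains={"A": [], "B": []})
    serial = 0

    def _helix(p: np.ndarray, i: int) -> np.ndarray:
        c, s = math.cos(i * twist), math.sin(i * twist)
        return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1], p[2] + i * spec.rise])

    strand_b: list[ResidueRecord] = []
    for i, base in enumerate(seq):
        comp = COMPLEMENT[base]
        res_a = ResidueRecord(name=f"D{base}", chain_id="A", seq_number=i + 1,
                              polymer_class="dna")
        res_b = ResidueRecord(name=f"D{comp}", chain_id="B", seq_number=n - i,
                              polymer_class="dna")
        skip_a = () if (spec.phosphorylated_5prime or i > 0) else ("P", "OP1", "OP2")
        skip_b = () if (spec.phosphorylated_5prime or i < n - 1) else ("P", "OP1", "OP2")
        for name, p in _TEMPLATES[base].items():
            if name in skip_a:
                continue
            serial += 1
            charge = -1.0 if name == "P" else 0.0
            res_a.atoms.append(_make_atom(serial, name, _helix(p, i), charge))
        for name, p in _TEMPLATES[comp].items():
            if name in skip_b:
                continue
            serial += 1
            charge = -1.0 if name == "P" else 0.0
            res_b.atoms.append(_make_atom(serial, name, _helix(_partner(p), i), charge))
        structure.chains["A"].append(res_a)
        strand_b.append(res_b)

    # chain B runs antiparallel: store residues 5'→3' (reverse of pair order)
    structure.chains["B"] = strand_b[::-1]
    return structure


# ---------------------------------------------------------------------------
# Planted probe residues
# ---------------------------------------------------------------------------

def place_probe_residue(
    structure: ComplexStructure,
    target: tuple[str, int, str],
    donor_atom_name: str,
    distance: float,
    resname: str = "ARG",
    chain_id: str = "P",
    clearance: float = 3.91,
    n_directions: int = 96,
) -> ComplexStructure:
    """Add a minimal amino-acid probe with its named atom exactly ``distance``
    from the target atom, along an unoccluded direction.

    The probe carries the contact atom plus a short CA/C scaffold pointing
    away from the target. Directions are scanned on a quasi-uniform sphere;
    the one maximizing clearance from all other atoms is used. Raises if no
    direction keeps the probe at least ``clearance`` Å from everything but
    the target. Mutates and returns ``structure``.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    t_chain, t_seq, t_atom = target
    target_res = next(
        (r for r in structure.chains.get(t_chain, []) if r.seq_number == t_seq), None
    )
    if target_res is None:
        raise KeyError(f"no residue {t_chain}{t_seq} in structure")
    t_coords = target_res.atom(t_atom).coords

    others = np.array([
        a.coords for res in structure.residues() for a in res.atoms
        if not (res.chain_id == t_chain and res.seq_number == t_seq and a.name == t_atom)
    ])
    from .structure import _sphere_points

    best_dir, best_clear = None, -np.inf
    if len(others):
        tree = cKDTree(others)
        for direction in _sphere_points(n_directions):
            probe_pts = t_coords + direction * np.array([[distance], [distance + 1.5],
                                                         [distance + 2.9]])
            d, _ = tree.query(probe_pts)
            clear = float(d.min())
            if clear > best_clear:
                best_clear, best_dir = clear, direction
        if best_clear < clearance:
            raise ValueError(
                f"no clash-free direction for probe at {distance} Å from "
                f"{t_chain}{t_seq}:{t_atom} (best clearance {best_clear:.2f} Å)"
            )
    else:
        best_dir = np.array([1.0, 0.0, 0.0])

    existing = structure.chains.get(chain_id, [])
    seq_number = max((r.seq_number for r in existing), default=0) + 1
    serial = max((a.serial for a in structure.atoms()), default=0)
    res = ResidueRecord(name=resname, chain_id=chain_id, seq_number=seq_number,
                        polymer_class="protein")
    for name, offset in ((donor_atom_name, distance),
                         ("CA", distance + 1.5), ("C", distance + 2.9)):
        serial += 1
        res.atoms.append(_make_atom(serial, name, t_coords + best_dir * offset))
    structure.add_residue(res)
    return structure


# ---------------------------------------------------------------------------
# Collections with planted contact profiles
# ---------------------------------------------------------------------------

@dataclass
class CollectionSpec:
    """Recipe for a synthetic complex collection with a planted profile.

    ``profile`` maps an amino acid (or an (amino acid, target) pair, with
    target in {phosphate, sugar, A, C, G, T}) to the expected number of
    planted hydrogen-bond contacts per complex (Poisson-sampled).
    ``superfamily_labels`` lists labels with multiplicity (repeats allowed)
    assigned round-robin after shuffling, creating redundancy structure.
    """

    n_complexes: int
    superfamily_labels: list[str]
    profile: Mapping
    seed: int
    duplex_length: int = 8


@dataclass
class SyntheticCollection:
    complexes: list[ComplexStructure]
    assignments: list[DomainAssignment]
    truth: pd.DataFrame
    complex_superfamilies: dict[str, set[str]] = field(default_factory=dict)


_TARGET_ATOM = {"phosphate": "OP1", "sugar": "O3'"}  # O4' is groove-buried


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # guarantee every base occurs so base-targeted contacts always have a site
    letters = list("ACGT") + list(rng.choice(list("ACGT"), size=max(0, length - 4)))
    rng.shuffle(letters)
    return "".join(letters)


def generate_collection(spec: CollectionSpec) -> SyntheticCollection:
    """Generate complexes with contacts planted from the profile.

    Every planted contact is a canonical side-chain donor placed 3.0 Å from
    a target acceptor atom, so hydrogen-bond detection recovers the truth
    table exactly. Placements that cannot find a clash-free direction are
    skipped; the truth table records only what was actually placed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.superfamily_labels)
    rng.shuffle(labels)

    complexes, assignments = [], []
    complex_sfs: dict[str, set[str]] = {}
    truth_rows: dict[tuple[str, str], int] = {}

    for c in range(spec.n_complexes):
        cid = f"CPLX{c:04d}"
        seq = _random_sequence(rng, spec.duplex_length)
        structure = build_bdna(BDnaSpec(seq))
        structure.id = cid

        for key, rate in spec.profile.items():
            aa, target = key if isinstance(key, tuple) else (key, None)
            n_contacts = rng.poisson(rate)
            for _ in range(n_contacts):
                tgt = target or str(rng.choice(["phosphate", "sugar", "A", "C", "G", "T"]))
                placed = _plant_contact(structure, aa, tgt, rng)
                if placed:
                    truth_rows[(aa, tgt)] = truth_rows.get((aa, tgt), 0) + 1

        sf = labels[c % len(labels)]
        protein_residues = [r for r in structure.residues("protein")]
        if protein_residues:
            lo = min(r.seq_number for r in protein_residues)
            hi = max(r.seq_number for r in protein_residues)
            assignments.append(DomainAssignment(cid, "P", lo, hi, sf))
        complex_sfs[cid] = {sf}
        complexes.append(structure)

    from .propensity import FINE_TARGETS

    aas = sorted({aa for aa, _ in truth_rows} | {k[0] if isinstance(k, tuple) else k
                                                 for k in spec.profile})
    truth = pd.DataFrame(0, index=aas, columns=FINE_TARGETS, dtype=int)
    for (aa, tgt), count in truth_rows.items():
        truth.loc[aa, tgt] = count

    return SyntheticCollection(complexes, assignments, truth, complex_sfs)


def _plant_contact(structure, aa: str, target: str, rng: np.random.Generator) -> bool:
    donor = CANONICAL_DONOR_ATOM[aa]
    if target in _TARGET_ATOM:
        atom_name = _TARGET_ATOM[target]
        candidates = [
            (res.chain_id, res.seq_number)
            for res in structure.residues("dna") if res.has_atom(atom_name)
        ]
    else:
        atom_name = BASE_ACCEPTOR_ATOM[target]
        candidates = [
            (res.chain_id, res.seq_number)
            for res in structure.residues("dna") if res.base_type == target
        ]
    if not candidates:
        return False
    order = rng.permutation(len(candidates))
    for k in order[:4]:  # a few attempts, different sites
        chain, seqnum = candidates[k]
        try:
            place_probe_residue(structure, (chain, seqnum, atom_name), donor,
                                3.0, resname=aa)
            return True
        except ValueError:
            continue
    return False


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------

def generate_approach_trajectory(
    n_frames: int,
    d_start: float,
    d_end: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_atoms_per_body: int = 8,
    dt_ns: float = 1.0,
) -> Trajectory:
    """Two rigid bodies whose COM separation ramps d_start → d_end.

    Gaussian noise of the given SD perturbs the separation (endpoints are
    exact when the noise is zero). Bodies are random rigid blobs of carbon
    atoms; body A sits at the origin, body B on the +x axis.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)

    def _blob() -> np.ndarray:
        pts = rng.normal(scale=1.5, size=(n_atoms_per_body, 3))
        return pts - pts.mean(axis=0)  # equal masses: COM at origin

    body_a, body_b = _blob(), _blob()
    separations = np.linspace(d_start, d_end, n_frames)
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=n_frames)
        separations = separations + noise

    frames = np.empty((n_frames, 2 * n_atoms_per_body, 3))
    for t, d in enumerate(separations):
        frames[t, :n_atoms_per_body] = body_a
        frames[t, n_atoms_per_body:] = body_b + np.array([d, 0.0, 0.0])

    chains: dict[str, list[ResidueRecord]] = {}
    serial = 0
    for chain_id, body in (("X", body_a), ("Y", body_b)):
        res = ResidueRecord(name="LIG", chain_id=chain_id, seq_number=1,
                            polymer_class="other")
        for k in range(n_atoms_per_body):
            serial += 1
            res.atoms.append(_make_atom(serial, f"C{k + 1}", frames[0, serial - 1]))
        chains[chain_id] = [res]
    topology = ComplexStructure(id="approach", chains=chains)
    return Trajectory(topology, frames, dt_ns)


def gaussian_ensemble(
    n_atoms: int,
    covariance,
    masses,
    n_snapshots: int,
    seed: int = 0,
    mean=None,
) -> np.ndarray:
    """Snapshots drawn from a multivariate normal over 3N coordinates (Å).

    ``covariance`` may be a scalar (isotropic per-axis variance), a length
    3N diagonal, or a full (3N, 3N) positive semi-definite matrix. Returns
    an array of shape (n_snapshots, n_atoms, 3). Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    dim = 3 * n_atoms
    mu = np.zeros(dim) if mean is None else np.asarray(mean, float).reshape(dim)

    cov = np.asarray(covariance, dtype=float)
    if cov.ndim == 0:
        if cov < 0:
            raise ValueError("variance must be non-negative")
        draws = mu + rng.normal(scale=math.sqrt(float(cov)), size=(n_snapshots, dim))
    elif cov.ndim == 1:
        if np.any(cov < 0):
            raise ValueError("diagonal covariance must be non-negative")
        draws = mu + rng.normal(size=(n_snapshots, dim)) * np.sqrt(cov)
    else:
        if cov.shape != (dim, dim):
            raise ValueError(f"covariance must be ({dim}, {dim})")
        w, v = np.linalg.eigh(0.5 * (cov + cov.T))
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("covariance is not positive semi-definite")
        scale = v * np.sqrt(np.clip(w, 0.0, None))
        draws = mu + rng.normal(size=(n_snapshots, dim)) @ scale.T
    return draws.reshape(n_snapshots, n_atoms, 3)
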