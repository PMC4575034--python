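"""Structural model for protein–dsDNA complexes.

Parses PDB coordinate files into a light-weight residue/chain hierarchy,
classifies polymers (protein / DNA / other) and DNA atom moieties
(phosphate / sugar / base), and provides the core geometric primitives the
rest of the package builds on: centre of mass, radius of gyration,
Shrake–Rupley solvent-accessible surface area and per-residue relative
exposure.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._elements import element_mass, element_vdw_radius, guess_element

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ComplexStructure",
    "PDBParseError",
    "AMINO_ACIDS",
    "DNA_RESIDUES",
    "PHOSPHATE_ATOMS",
    "SUGAR_ATOMS",
    "MAX_SASA_EXTENDED",
    "read_structure",
    "write_pdb",
    "assign_moiety",
    "center_of_mass",
    "radius_of_gyration",
    "shrake_rupley_sasa",
    "sasa",
    "residue_exposure_percent",
    "net_formal_charge",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Modern and legacy deoxynucleotide residue names, mapped to the one-letter base.
DNA_RESIDUES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
}

#: Phosphate-group atoms (both modern OP1 and legacy O1P spellings).
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"})

#: Deoxyribose atoms. The bridging esters O3'/O5' belong to the sugar here
#: (they are ester oxygens of the deoxyribose); override via ``assign_moiety``
#: keyword arguments to move them to the phosphate.
SUGAR_ATOMS = frozenset({
    "C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'", "O5'", "O2'",
    "C1*", "C2*", "C3*", "C4*", "C5*", "O4*", "O3*", "O5*", "O2*",
})

#: Theoretical maximum SASA (Å²) of residue X in an extended Gly-X-Gly
#: tripeptide (Tien et al. 2013, "theoretical" column). Reference for
#: percent relative exposure.
MAX_SASA_EXTENDED = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class AtomRecord:
    """One atom: coordinates plus the per-element constants geometry needs."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    mass: float
    vdw_radius: float
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdW radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class ResidueRecord:
    name: str
    chain_id: str
    seq_number: int
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    polymer_class: str = "other"

    def __post_init__(self) -> None:
        if self.polymer_class == "auto":
            self.polymer_class = classify_residue(self.name)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.chain_id}{self.seq_number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def base_type(self) -> str | None:
        return DNA_RESIDUES.get(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.icode)


@dataclass
class ComplexStructure:
    """One protein–dsDNA complex: ordered residues grouped per chain."""

    id: str
    chains: dict[str, list[ResidueRecord]]
    resolution: float | None = None

    def residues(self, polymer_class: str | None = None):
        for residues in self.chains.values():
            for res in residues:
                if polymer_class is None or res.polymer_class == polymer_class:
                    yield res

    def atoms(self, polymer_class: str | None = None) -> list[AtomRecord]:
        return [a for res in self.residues(polymer_class) for a in res.atoms]

    @property
    def has_interface(self) -> bool:
        classes = {res.polymer_class for res in self.residues()}
        return "protein" in classes and "dna" in classes

    def add_residue(self, residue: ResidueRecord) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)


def classify_residue(name: str) -> str:
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    return "other"


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, structure_id: str = "complex") -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Only the first model of a multi-model file is read (use the trajectory
    reader for multi-frame files). Raises :class:`PDBParseError` on empty
    input or a malformed coordinate field, naming the offending line.
    """
    _validate_coordinate_lines(pdb_text)

    from Bio.PDB import PDBParser  # deferred: Bio import is slow

    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    resolution = _parse_resolution(pdb_text)

    model = next(iter(bio_structure), None)
    if model is None:
        raise PDBParseError("no coordinate records found")

    chains: dict[str, list[ResidueRecord]] = {}
    serial = 0
    for bio_chain in model:
        chain_id = bio_chain.id.strip() or "A"
        for bio_res in bio_chain:
            resname = bio_res.get_resname().strip()
            hetflag, seq_number, icode = bio_res.get_id()
            atoms = []
            for bio_atom in bio_res:
                serial += 1
                element = (bio_atom.element or "").strip() or guess_element(bio_atom.get_name())
                atoms.append(AtomRecord(
                    serial=bio_atom.get_serial_number() or serial,
                    name=bio_atom.get_name(),
                    element=element,
                    coords=np.asarray(bio_atom.get_coord(), dtype=float),
                    mass=element_mass(element),
                    vdw_radius=element_vdw_radius(element),
                ))
            if not atoms:
                continue
            residue = ResidueRecord(
                name=resname, chain_id=chain_id, seq_number=seq_number,
                icode=icode.strip(), atoms=atoms, polymer_class=classify_residue(resname),
            )
            chains.setdefault(chain_id, []).append(residue)

    if not chains:
        raise PDBParseError("no coordinate records found")
    return ComplexStructure(id=structure_id, chains=chains, resolution=resolution)


def read_structure_file(path: str | Path) -> ComplexStructure:
    path = Path(path)
    return read_structure(path.read_text(), structure_id=path.stem)


def _validate_coordinate_lines(pdb_text: str) -> None:
    if not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    n_coord = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_coord += 1
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise PDBParseError(
                    f"malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                ) from None
    if n_coord == 0:
        raise PDBParseError("no ATOM/HETATM records in input")


def _parse_resolution(pdb_text: str) -> float | None:
    for line in pdb_text.splitlines():
        if line.startswith("REMARK   2 RESOLUTION") and "ANGSTROM" in line.upper():
            for token in line.split():
                try:
                    return float(token)
                except ValueError:
                    continue
    return None


def _format_atom_line(serial: int, atom: AtomRecord, res: ResidueRecord) -> str:
    name = atom.name
    # PDB column convention: 1-letter elements start in column 14
    padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:>5d} {padded:>4s} {res.name:>3s} {res.chain_id:1s}"
        f"{res.seq_number:>4d}{res.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.rjust(2)}"
    )


def write_pdb(structure: ComplexStructure) -> str:
    """Serialize a structure as minimal PDB text (ATOM/TER/END records)."""
    lines = []
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(serial, atom, res))
        lines.append(f"TER   {serial + 1:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Moiety classification
# ---------------------------------------------------------------------------

def assign_moiety(
    atom_name: str,
    residue: ResidueRecord,
    phosphate_atoms: frozenset[str] = PHOSPHATE_ATOMS,
    sugar_atoms: frozenset[str] = SUGAR_ATOMS,
) -> str:
    """Classify a DNA atom as ``phosphate``, ``sugar`` or ``base``.

    Hydrogens follow the heavy atom they are bonded to, recognized by name
    (primed hydrogens belong to the sugar, HOPx to the phosphate).
    """
    if residue.polymer_class != "dna":
        raise ValueError(
            f"moiety labels apply to DNA residues only, got {residue.name!r} "
            f"({residue.polymer_class})"
        )
    name = atom_name.strip()
    if name in phosphate_atoms or name.startswith("HOP"):
        return "phosphate"
    if name in sugar_atoms or ("'" in name) or ("*" in name):
        return "sugar"
    return "base"


def net_formal_charge(structure: ComplexStructure) -> float:
    """Sum of per-atom formal/partial charges (e)."""
    return float(sum(a.partial_charge for a in structure.atoms()))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _coords_and_masses(atoms) -> tuple[np.ndarray, np.ndarray]:
    atoms = list(atoms)
    if not atoms:
        raise ValueError("empty atom list")
    coords = np.array([a.coords for a in atoms], dtype=float)
    masses = np.array([a.mass for a in atoms], dtype=float)
    return coords, masses


def center_of_mass(atoms) -> np.ndarray:
    """Mass-weighted mean position (Å)."""
    coords, masses = _coords_and_masses(atoms)
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (coords * masses[:, None]).sum(axis=0) / total


def radius_of_gyration(atoms) -> float:
    """Mass-weighted RMS distance from the centre of mass (Å)."""
    coords, masses = _coords_and_masses(atoms)
    com = center_of_mass(atoms)
    sq = ((coords - com) ** 2).sum(axis=1)
    return math.sqrt(float((masses * sq).sum() / masses.sum()))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    atoms,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å², Shrake–Rupley).

    Each atom is covered with ``n_sphere_points`` quasi-uniform test points
    at radius ``r_vdw + probe_radius``; the accessible area is the fraction
    of points not buried inside any neighbour's probe-expanded sphere.
    Hydrogens get zero area and do not occlude (united-atom convention for
    structures with explicit hydrogens is deliberately avoided: crystal
    inputs here are heavy-atom only).
    """
    if n_sphere_points < 12:
        raise ValueError("n_sphere_points must be >= 12")
    atoms = list(atoms)
    coords, _ = _coords_and_masses(atoms)
    radii = np.array(
        [0.0 if a.is_hydrogen else a.vdw_radius + probe_radius for a in atoms]
    )
    heavy = radii > 0
    unit = _sphere_points(n_sphere_points)

    areas = np.zeros(len(atoms))
    h_coords, h_radii = coords[heavy], radii[heavy]
    if len(h_coords) == 0:
        return areas
    tree = cKDTree(h_coords)
    max_r = h_radii.max()
    heavy_idx = np.flatnonzero(heavy)
    for local_i, i in enumerate(heavy_idx):
        pts = coords[i] + radii[i] * unit
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_sphere_points, dtype=bool)
        duplicate = False
        for local_j in neighbours:
            if local_j == local_i:
                continue
            centre_dist = np.linalg.norm(h_coords[local_j] - coords[i])
            if centre_dist < 1e-9 and h_radii[local_j] == radii[i]:
                # exactly coincident duplicate (e.g. altloc): surface owned
                # by the lowest-index copy, later copies fully buried
                if local_j < local_i:
                    duplicate = True
                    break
                continue
            d2 = ((pts - h_coords[local_j]) ** 2).sum(axis=1)
            accessible &= d2 > h_radii[local_j] ** 2 - 1e-9
        if not duplicate:
            areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def sasa(
    structure: ComplexStructure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA (Å²) of the whole assembly; total is the dict sum."""
    residues = list(structure.residues())
    atoms = [a for res in residues for a in res.atoms]
    per_atom = shrake_rupley_sasa(atoms, probe_radius, n_sphere_points)
    result: dict[tuple[str, int, str], float] = {}
    pos = 0
    for res in residues:
        n = len(res.atoms)
        result[res.key] = float(per_atom[pos:pos + n].sum())
        pos += n
    return result


def residue_exposure_percent(
    structure: ComplexStructure,
    reference_max_sasa: dict[str, float] | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[tuple[str, int, str], float]:
    """Percent relative exposure per protein residue.

    100 × (residue SASA in the assembly) / (reference maximum SASA of that
    residue type in an extended peptide). Values can exceed 100 for chain
    termini. Residue types absent from the reference table raise KeyError.
    """
    reference = MAX_SASA_EXTENDED if reference_max_sasa is None else reference_max_sasa
    per_res = sasa(structure, probe_radius, n_sphere_points)
    result = {}
    for res in structure.residues("protein"):
        if res.name not in reference:
            raise KeyError(f"no reference max-SASA entry for residue {res.name!r}")
        result[res.key] = 100.0 * per_res[res.key] / reference[res.name]
    return result


def sasa_report(structure: ComplexStructure, **kwargs):
    """Per-residue SASA/exposure table (pandas DataFrame, CSV-ready)."""
    import pandas as pd

    per_res = sasa(structure, **kwargs)
    exposure = {}
    try:
        exposure = residue_exposure_percent(structure, **kwargs)
    except KeyError:
        warnings.warn("nonstandard protein residue present; exposure column limited")
    rows = []
    for res in structure.residues():
        rows.append({
            "complex_id": structure.id,
            "chain": res.chain_id,
            "resnum": res.seq_number,
            "resname": res.name,
            "sasa_A2": per_res[res.key],
            "exposure_pct": exposure.get(res.key, float("nan")),
        })
    return pd.DataFrame(rows)
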