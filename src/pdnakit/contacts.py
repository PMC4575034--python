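"""Hydrogen-bond and van der Waals contact detection across protein–DNA interfaces.

Geometric criteria follow the HBPLUS convention: a donor–acceptor pair
counts as a hydrogen bond when the heavy-atom D···A distance is at most
3.35 Å, and — when an explicit hydrogen is present on the donor — the
H···A distance is additionally at most 2.7 Å. Crystal structures typically
lack hydrogens, so the heavy-atom criterion alone is the default path; no
hydrogen placement is attempted. Heavy-atom pairs within the vdW cutoff
that do not qualify as hydrogen bonds are reported as vdW contacts, so the
two interaction classes never double-count a pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    AtomRecord,
    ComplexStructure,
    ResidueRecord,
    assign_moiety,
)

__all__ = [
    "HBondParams",
    "InteractionRecord",
    "SiteInventory",
    "find_hbonds",
    "find_vdw_contacts",
    "count_contacts",
    "base_site_inventory",
    "load_default_site_table",
    "records_to_tsv",
    "PROTEIN_DONORS",
    "PROTEIN_ACCEPTORS",
    "DNA_DONORS",
    "DNA_ACCEPTORS",
]

# --- Donor / acceptor dictionaries -----------------------------------------
# Backbone amide N is a donor (except proline) and carbonyl O an acceptor for
# every amino acid; side-chain sites below. His ND1/NE2 count both ways;
# Cys SG is excluded by default as a weak donor.

_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

PROTEIN_DONORS = {
    aa: _BACKBONE_DONOR | _SIDECHAIN_DONORS.get(aa, set())
    for aa in (
        "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
        "THR TRP TYR VAL".split()
    )
}
PROTEIN_DONORS["PRO"] = set()  # no amide H

PROTEIN_ACCEPTORS = {
    aa: _BACKBONE_ACCEPTOR | _SIDECHAIN_ACCEPTORS.get(aa, set())
    for aa in PROTEIN_DONORS
}

# DNA: backbone oxygens are acceptors; base sites per base type.
_DNA_BACKBONE_ACCEPTORS = {
    "OP1", "OP2", "OP3", "O1P", "O2P", "O3'", "O5'", "O4'",
    "O3*", "O5*", "O4*",
}

_BASE_DONORS = {
    "A": {"N6"},
    "G": {"N1", "N2"},
    "C": {"N4"},
    "T": {"N3"},
}
_BASE_ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"N3", "N7", "O6"},
    "C": {"N3", "O2"},
    "T": {"O2", "O4"},
}

DNA_DONORS = dict(_BASE_DONORS)
DNA_ACCEPTORS = {
    base: _DNA_BACKBONE_ACCEPTORS | atoms for base, atoms in _BASE_ACCEPTORS.items()
}


@dataclass
class HBondParams:
    """Distance (and optional angle) criteria for hydrogen-bond detection."""

    max_h_acceptor: float = 2.7
    max_donor_acceptor: float = 3.35
    require_angle: bool = False
    min_dha_angle: float = 90.0

    def __post_init__(self) -> None:
        if not (0 < self.max_h_acceptor < self.max_donor_acceptor):
            raise ValueError("require 0 < max_h_acceptor < max_donor_acceptor")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interface contact (hydrogen bond or vdW)."""

    complex_id: str
    aa_resname: str
    aa_chain: str
    aa_seq: int
    aa_atom: str
    nt_resname: str
    nt_chain: str
    nt_seq: int
    nt_atom: str
    base_type: str
    moiety: str
    kind: str
    distance: float

    @property
    def target(self) -> str:
        """Counting axis: 'phosphate', 'sugar', or the base letter."""
        return self.base_type if self.moiety == "base" else self.moiety


@dataclass
class SiteInventory:
    """Hydrogen-bond donor/acceptor site counts per paired base."""

    donors: dict[str, int] = field(default_factory=dict)
    acceptors: dict[str, int] = field(default_factory=dict)

    def total(self, base: str) -> int:
        return self.donors.get(base, 0) + self.acceptors.get(base, 0)

    def ordering(self) -> list[str]:
        """Bases sorted by total site count (descending, ties alphabetical)."""
        bases = sorted(set(self.donors) | set(self.acceptors))
        return sorted(bases, key=lambda b: (-self.total(b), b))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _interface_atoms(structure: ComplexStructure):
    """(atom, residue) lists for the protein and DNA sides, heavy atoms only."""
    prot, dna = [], []
    for res in structure.residues():
        if res.polymer_class == "protein":
            prot.extend((a, res) for a in res.atoms if not a.is_hydrogen)
        elif res.polymer_class == "dna":
            dna.extend((a, res) for a in res.atoms if not a.is_hydrogen)
    return prot, dna


def _attached_hydrogens(residue: ResidueRecord, heavy: AtomRecord, bond_max: float = 1.25):
    return [
        h for h in residue.atoms
        if h.is_hydrogen and np.linalg.norm(h.coords - heavy.coords) <= bond_max
    ]


def _is_donor(atom: AtomRecord, res: ResidueRecord) -> bool:
    if res.polymer_class == "protein":
        return atom.name in PROTEIN_DONORS.get(res.name, set())
    base = res.base_type
    return base is not None and atom.name in DNA_DONORS[base]


def _is_acceptor(atom: AtomRecord, res: ResidueRecord) -> bool:
    if res.polymer_class == "protein":
        return atom.name in PROTEIN_ACCEPTORS.get(res.name, set())
    base = res.base_type
    return base is not None and atom.name in DNA_ACCEPTORS[base]


def _hbond_geometry_ok(
    donor: AtomRecord, donor_res: ResidueRecord, acceptor: AtomRecord,
    dist: float, params: HBondParams,
) -> bool:
    if dist > params.max_donor_acceptor:
        return False
    hydrogens = _attached_hydrogens(donor_res, donor)
    if not hydrogens:
        return True  # heavy-atom criterion alone (crystal structures)
    for h in hydrogens:
        ha = float(np.linalg.norm(h.coords - acceptor.coords))
        if ha > params.max_h_acceptor:
            continue
        if params.require_angle:
            v1 = donor.coords - h.coords
            v2 = acceptor.coords - h.coords
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle < params.min_dha_angle:
                continue
        return True
    return False


def _make_record(
    structure: ComplexStructure,
    prot_atom: AtomRecord, prot_res: ResidueRecord,
    dna_atom: AtomRecord, dna_res: ResidueRecord,
    kind: str, dist: float,
) -> InteractionRecord:
    return InteractionRecord(
        complex_id=structure.id,
        aa_resname=prot_res.name, aa_chain=prot_res.chain_id,
        aa_seq=prot_res.seq_number, aa_atom=prot_atom.name,
        nt_resname=dna_res.name, nt_chain=dna_res.chain_id,
        nt_seq=dna_res.seq_number, nt_atom=dna_atom.name,
        base_type=dna_res.base_type or "?",
        moiety=assign_moiety(dna_atom.name, dna_res),
        kind=kind, distance=round(dist, 4),
    )


def _candidate_pairs(prot, dna, cutoff: float):
    """Cross-interface heavy-atom pairs within cutoff, via KD-trees."""
    if not prot or not dna:
        return
    p_coords = np.array([a.coords for a, _ in prot])
    d_coords = np.array([a.coords for a, _ in dna])
    tree_p, tree_d = cKDTree(p_coords), cKDTree(d_coords)
    for i, js in enumerate(tree_p.query_ball_tree(tree_d, cutoff)):
        for j in js:
            dist = float(np.linalg.norm(p_coords[i] - d_coords[j]))
            if dist <= cutoff:
                yield i, j, dist


def find_hbonds(
    structure: ComplexStructure, params: HBondParams | None = None
) -> list[InteractionRecord]:
    """Detect interface hydrogen bonds (one record per donor–acceptor atom pair).

    Both polarities are considered (protein donor → DNA acceptor and DNA
    donor → protein acceptor); an atom pair qualifying in either polarity
    yields a single record carrying the heavy-atom distance.
    """
    if not structure.has_interface:
        raise ValueError(
            f"structure {structure.id!r} needs at least one protein and one DNA chain"
        )
    params = params or HBondParams()
    prot, dna = _interface_atoms(structure)
    records = []
    for i, j, dist in _candidate_pairs(prot, dna, params.max_donor_acceptor):
        p_atom, p_res = prot[i]
        d_atom, d_res = dna[j]
        ok = (
            _is_donor(p_atom, p_res) and _is_acceptor(d_atom, d_res)
            and _hbond_geometry_ok(p_atom, p_res, d_atom, dist, params)
        ) or (
            _is_donor(d_atom, d_res) and _is_acceptor(p_atom, p_res)
            and _hbond_geometry_ok(d_atom, d_res, p_atom, dist, params)
        )
        if ok:
            records.append(_make_record(structure, p_atom, p_res, d_atom, d_res, "hbond", dist))
    records.sort(key=lambda r: (r.aa_chain, r.aa_seq, r.aa_atom, r.nt_chain, r.nt_seq, r.nt_atom))
    return records


def find_vdw_contacts(
    structure: ComplexStructure,
    cutoff: float = 3.9,
    hbond_params: HBondParams | None = None,
    rule: str = "fixed",
    radii_margin: float = 0.5,
) -> list[InteractionRecord]:
    """Detect interface vdW contacts not already counted as hydrogen bonds.

    ``rule='fixed'`` uses a single heavy-atom distance cutoff (default
    3.9 Å, the HBPLUS non-bonded default); ``rule='radii'`` accepts a pair
    when the distance is below the sum of vdW radii plus ``radii_margin``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if rule not in ("fixed", "radii"):
        raise ValueError("rule must be 'fixed' or 'radii'")
    hb = {
        (r.aa_chain, r.aa_seq, r.aa_atom, r.nt_chain, r.nt_seq, r.nt_atom)
        for r in find_hbonds(structure, hbond_params)
    }
    prot, dna = _interface_atoms(structure)
    search_r = cutoff if rule == "fixed" else max(
        (a.vdw_radius for a, _ in prot + dna), default=2.0
    ) * 2 + radii_margin
    records = []
    for i, j, dist in _candidate_pairs(prot, dna, search_r):
        p_atom, p_res = prot[i]
        d_atom, d_res = dna[j]
        limit = cutoff if rule == "fixed" else p_atom.vdw_radius + d_atom.vdw_radius + radii_margin
        if dist > limit:
            continue
        key = (p_res.chain_id, p_res.seq_number, p_atom.name,
               d_res.chain_id, d_res.seq_number, d_atom.name)
        if key in hb:
            continue
        records.append(_make_record(structure, p_atom, p_res, d_atom, d_res, "vdw", dist))
    records.sort(key=lambda r: (r.aa_chain, r.aa_seq, r.aa_atom, r.nt_chain, r.nt_seq, r.nt_atom))
    return records


def count_contacts(atoms_a, atoms_b, cutoff: float = 3.5) -> int:
    """Number of cross pairs with distance strictly below ``cutoff``.

    Accepts AtomRecord sequences or plain (n, 3) coordinate arrays; empty
    inputs give zero.
    """
    coords_a = _as_coords(atoms_a)
    coords_b = _as_coords(atoms_b)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree_a, tree_b = cKDTree(coords_a), cKDTree(coords_b)
    count = 0
    for i, js in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for j in js:
            if np.linalg.norm(coords_a[i] - coords_b[j]) < cutoff:
                count += 1
    return count


def _as_coords(atoms) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return atoms.reshape(-1, 3)
    atoms = list(atoms)
    if not atoms:
        return np.empty((0, 3))
    if isinstance(atoms[0], AtomRecord):
        return np.array([a.coords for a in atoms])
    return np.asarray(atoms, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Donor/acceptor site inventory of paired dsDNA
# ---------------------------------------------------------------------------

def load_default_site_table() -> dict:
    """Default per-base hydrogen-bonding site table for Watson–Crick-paired dsDNA.

    Counts the free hydrogen-bonding valences each base retains after WC
    pairing: donor hydrogens and acceptor lone pairs accessible from the
    grooves. On these counts guanine is richest, thymine and adenine tie,
    and cytosine is poorest (G > T = A > C).
    """
    with resources.files("pdnakit.data").joinpath("base_hbond_sites.json").open() as fh:
        return json.load(fh)


def base_site_inventory(site_table: dict | None = None) -> SiteInventory:
    """Aggregate a per-base site table into donor/acceptor counts.

    ``site_table`` maps base → {"donors": {atom: count}, "acceptors": {atom: count}}.
    """
    table = load_default_site_table() if site_table is None else site_table
    inv = SiteInventory()
    for base, sites in table.items():
        if base not in ("A", "C", "G", "T"):
            raise KeyError(f"unknown base key {base!r}")
        inv.donors[base] = int(sum(sites.get("donors", {}).values()))
        inv.acceptors[base] = int(sum(sites.get("acceptors", {}).values()))
    return inv


def records_to_tsv(records) -> str:
    """Serialize interaction records as an HBPLUS-style TSV listing."""
    header = (
        "complex_id\taa_chain\taa_resnum\taa_resname\taa_atom\t"
        "nt_chain\tnt_resnum\tnt_resname\tnt_atom\tkind\tmoiety\tdistance_A"
    )
    lines = [header]
    for r in records:
        lines.append(
            f"{r.complex_id}\t{r.aa_chain}\t{r.aa_seq}\t{r.aa_resname}\t{r.aa_atom}\t"
            f"{r.nt_chain}\t{r.nt_seq}\t{r.nt_resname}\t{r.nt_atom}\t"
            f"{r.kind}\t{r.moiety}\t{r.distance:.2f}"
        )
    return "\n".join(lines) + "\n"
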