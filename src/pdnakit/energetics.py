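"""MM-GBSA free-energy assembly with quasi-harmonic entropy.

The end-point estimate splits each species' free energy into a
molecular-mechanics enthalpy averaged over the final stretch of a
trajectory, a Generalized-Born polar solvation term, a SASA-linear
nonpolar term, and a configurational entropy from the Schlitter
quasi-harmonic formula:

    G_total = H_MM + G_solv-polar + G_solv-nonpolar − TΔS_conf
    ΔG_bind = G_total(complex) − G_total(receptor) − G_total(ligand)

under the three-trajectory scheme (each species from its own run).

All energies in kcal/mol, lengths in Å, temperature in K. The GB term is
the pairwise Still formula with fixed intrinsic Born radii — adequate for
the toy systems this package assembles, whose contract is the Born-limit
and separability behaviour, not parity with a production GB solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyComponents",
    "NonpolarParams",
    "GTotalComponents",
    "BindingFreeEnergy",
    "mm_energy",
    "gb_polar",
    "nonpolar_solvation",
    "schlitter_entropy",
    "schlitter_entropy_single_atom",
    "g_total",
    "binding_free_energy",
    "h_mm_average",
]

#: Electrostatic conversion factor, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636

# SI constants for the entropy term
_KB_J = 1.380649e-23          # J/K
_HBAR = 1.054571817e-34       # J·s
_AMU = 1.66053906660e-27      # kg
_NA = 6.02214076e23
_J_PER_KCAL = 4184.0
_E_SQ = math.e ** 2           # Euler's number squared, from the Schlitter bound


@dataclass
class EnergyComponents:
    """Molecular-mechanics energy terms of one frame (kcal/mol)."""

    e_bond: float = 0.0
    e_angle: float = 0.0
    e_torsion: float = 0.0
    e_vdw: float = 0.0
    e_elec: float = 0.0

    @property
    def total(self) -> float:
        return self.e_bond + self.e_angle + self.e_torsion + self.e_vdw + self.e_elec


@dataclass
class NonpolarParams:
    """γ·SASA + β parameters (kcal/mol/Å² and kcal/mol)."""

    gamma: float = 0.00542
    beta: float = 0.92
    probe: float = 1.4

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class GTotalComponents:
    """Per-species free-energy components (kcal/mol)."""

    h_mm: float
    g_solv_polar: float
    g_solv_nonpolar: float
    minus_t_delta_s: float
    temperature: float = 310.0
    h_mm_sd: float = 0.0

    @property
    def g_total(self) -> float:
        return self.h_mm + self.g_solv_polar + self.g_solv_nonpolar + self.minus_t_delta_s


@dataclass
class BindingFreeEnergy:
    """ΔH / −TΔS / ΔG of complexation (kcal/mol)."""

    delta_h: float
    minus_t_delta_s: float
    delta_h_sd: float = 0.0

    @property
    def delta_g(self) -> float:
        return self.delta_h + self.minus_t_delta_s

    def to_dict(self) -> dict:
        return {
            "delta_h": self.delta_h,
            "delta_h_sd": self.delta_h_sd,
            "minus_t_delta_s": self.minus_t_delta_s,
            "delta_g": self.delta_g,
        }


# ---------------------------------------------------------------------------
# Molecular-mechanics energy of a frame (toy force field)
# ---------------------------------------------------------------------------

def mm_energy(coords: np.ndarray, params: dict) -> EnergyComponents:
    """Evaluate bonded + nonbonded MM terms for one frame.

    ``params`` holds:

    - ``bonds``: (i, j, k, r0) with E = k (r − r0)²  [CHARMM convention]
    - ``angles``: (i, j, k, k_theta, theta0_deg) with E = k (θ − θ0)², θ in rad
    - ``torsions``: (i, j, k, l, k_phi, n, delta_deg) with E = k (1 + cos(nφ − δ))
    - ``lj``: per-atom (epsilon, rmin_half) dict, Lorentz–Berthelot combined
    - ``charges``: per-atom charge (e)
    - ``pairs``: explicit nonbonded pair list [(i, j), ...]; without it all
      atom pairs not appearing in a bond interact (no cutoff).

    A bonded term or nonbonded pair referencing an atom without LJ/charge
    parameters raises KeyError naming the term.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    comp = EnergyComponents()

    def _dist(i, j):
        return float(np.linalg.norm(coords[i] - coords[j]))

    for i, j, k, r0 in params.get("bonds", ()):
        comp.e_bond += k * (_dist(i, j) - r0) ** 2

    for i, j, k, k_theta, theta0_deg in params.get("angles", ()):
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        theta = math.acos(max(-1.0, min(1.0, cosang)))
        comp.e_angle += k_theta * (theta - math.radians(theta0_deg)) ** 2

    for i, j, k, l, k_phi, n, delta_deg in params.get("torsions", ()):
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = math.atan2(float(m1 @ n2), float(n1 @ n2))
        comp.e_torsion += k_phi * (1.0 + math.cos(n * phi - math.radians(delta_deg)))

    pairs = params.get("pairs")
    has_nonbonded = "lj" in params or "charges" in params
    if pairs is None and has_nonbonded:
        bonded = {frozenset((i, j)) for i, j, *_ in params.get("bonds", ())}
        n_atoms = len(coords)
        pairs = [
            (i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)
            if frozenset((i, j)) not in bonded
        ]
    for i, j in pairs or ():
        r = _dist(i, j)
        lj = params.get("lj")
        if lj is not None:
            try:
                eps_i, rmin_i = lj[i]
                eps_j, rmin_j = lj[j]
            except KeyError as exc:
                raise KeyError(f"missing LJ parameters for atom {exc} in pair ({i},{j})") from None
            eps = math.sqrt(eps_i * eps_j)
            rmin = rmin_i + rmin_j
            ratio6 = (rmin / r) ** 6
            comp.e_vdw += eps * (ratio6 ** 2 - 2.0 * ratio6)
        charges = params.get("charges")
        if charges is not None:
            try:
                qi, qj = charges[i], charges[j]
            except (KeyError, IndexError):
                raise KeyError(f"missing charge for pair ({i},{j})") from None
            comp.e_elec += COULOMB_CONSTANT * qi * qj / r
    return comp


# ---------------------------------------------------------------------------
# Solvation terms
# ---------------------------------------------------------------------------

def gb_polar(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
) -> float:
    """Generalized-Born polar solvation energy (Still pairwise form), kcal/mol.

    ΔG = −(k_e/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB with
    f_GB = sqrt(r² + a_i a_j exp(−r²/4a_i a_j)); the i = j self-terms reduce
    to the Born formula for an isolated ion.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    born_radii = np.asarray(born_radii, dtype=float)
    if np.any(born_radii <= 0):
        raise ValueError("Born radii must be positive")
    if len(charges) == 0 or not np.any(charges):
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff ** 2).sum(axis=-1)
    aa = born_radii[:, None] * born_radii[None, :]
    f_gb = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    qq = charges[:, None] * charges[None, :]
    prefactor = -0.5 * COULOMB_CONSTANT * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefactor * (qq / f_gb).sum())


def nonpolar_solvation(sasa_total: float, params: NonpolarParams | None = None) -> float:
    """Nonpolar solvation free energy γ·SASA + β (kcal/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    params = params or NonpolarParams()
    return params.gamma * sasa_total + params.beta


# ---------------------------------------------------------------------------
# Quasi-harmonic entropy (Schlitter upper bound)
# ---------------------------------------------------------------------------

def _kabsch_align(mobile: np.ndarray, reference: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted least-squares superposition of one snapshot onto another."""
    w = masses / masses.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mob_c @ rot.T


def schlitter_entropy(
    snapshots: np.ndarray,
    masses: np.ndarray,
    temperature: float = 310.0,
    align: bool = True,
) -> tuple[float, float]:
    """Configurational entropy from coordinate fluctuations.

    S = ½ k_B ln det[ I + (k_B T e²/ħ²) M^{1/2} σ M^{1/2} ], with σ the
    3N×3N covariance of the (optionally superposed) snapshot coordinates
    and M the diagonal mass matrix. Returns (S in kcal/mol/K, −T·S in
    kcal/mol). Snapshots in Å, masses in amu.
    """
    snapshots = np.asarray(snapshots, dtype=float)
    if snapshots.ndim != 3 or snapshots.shape[0] < 2:
        raise ValueError("need >= 2 snapshots of shape (n_snapshots, n_atoms, 3)")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")

    n_snap, n_atoms, _ = snapshots.shape
    if align:
        aligned = np.empty_like(snapshots)
        ref = snapshots[0]
        for k in range(n_snap):
            aligned[k] = _kabsch_align(snapshots[k], ref, masses)
        snapshots = aligned

    flat = snapshots.reshape(n_snap, 3 * n_atoms) * 1e-10  # Å → m
    sigma = np.cov(flat, rowvar=False, ddof=1).reshape(3 * n_atoms, 3 * n_atoms)
    m_sqrt = np.sqrt(np.repeat(masses * _AMU, 3))
    weighted = sigma * m_sqrt[:, None] * m_sqrt[None, :]
    alpha = _KB_J * temperature * _E_SQ / _HBAR ** 2
    sign, logdet = np.linalg.slogdet(np.eye(3 * n_atoms) + alpha * weighted)
    if sign <= 0:
        raise ValueError("covariance matrix produced a non-positive determinant")
    s_si = 0.5 * _KB_J * logdet                    # J/K per molecule
    s = s_si * _NA / _J_PER_KCAL                   # kcal/mol/K
    return s, -temperature * s


def schlitter_entropy_single_atom(
    mass_amu: float, sigma2_A2: float, temperature: float = 310.0
) -> float:
    """Closed form for one atom with isotropic per-axis variance s² (Å²):
    S = (3/2) k_B ln(1 + k_B T e² m s² / ħ²), in kcal/mol/K."""
    alpha = _KB_J * temperature * _E_SQ / _HBAR ** 2
    arg = 1.0 + alpha * mass_amu * _AMU * sigma2_A2 * 1e-20
    return 1.5 * _KB_J * math.log(arg) * _NA / _J_PER_KCAL


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def g_total(
    h_mm_avg: float, g_polar: float, g_nonpolar: float, minus_t_delta_s: float
) -> float:
    """G_total = H_MM + G_solv-p + G_solv-np + (−TΔS_conf), kcal/mol."""
    values = (h_mm_avg, g_polar, g_nonpolar, minus_t_delta_s)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("all components must be finite")
    return sum(values)


def binding_free_energy(
    g_complex: GTotalComponents,
    g_receptor: GTotalComponents,
    g_ligand: GTotalComponents,
) -> BindingFreeEnergy:
    """Component-wise ΔG_bind = G(complex) − G(receptor) − G(ligand).

    ΔH collects the enthalpic bundle (MM + both solvation terms); the
    entropic column is the difference of the species' −TΔS terms. The SD
    of ΔH propagates frame-wise SDs in quadrature.
    """
    temps = {g_complex.temperature, g_receptor.temperature, g_ligand.temperature}
    if len(temps) != 1:
        raise ValueError(f"temperature mismatch across species: {sorted(temps)}")

    def _enthalpy(g: GTotalComponents) -> float:
        return g.h_mm + g.g_solv_polar + g.g_solv_nonpolar

    delta_h = _enthalpy(g_complex) - _enthalpy(g_receptor) - _enthalpy(g_ligand)
    minus_tds = (
        g_complex.minus_t_delta_s - g_receptor.minus_t_delta_s - g_ligand.minus_t_delta_s
    )
    sd = math.sqrt(g_complex.h_mm_sd ** 2 + g_receptor.h_mm_sd ** 2 + g_ligand.h_mm_sd ** 2)
    return BindingFreeEnergy(delta_h=delta_h, minus_t_delta_s=minus_tds, delta_h_sd=sd)


def h_mm_average(
    energy_table, dt_ns: float | None = None, window_ns: float | None = None
) -> tuple[float, float]:
    """Mean and SD of the per-frame MM energy sum over the last window.

    ``energy_table`` is a pandas DataFrame with columns e_bond, e_angle,
    e_torsion, e_vdw, e_elec (one row per frame, e.g. read from the
    per-frame CSV interface). With ``window_ns`` unset, all frames count.
    """
    cols = ["e_bond", "e_angle", "e_torsion", "e_vdw", "e_elec"]
    totals = energy_table[cols].sum(axis=1).to_numpy(dtype=float)
    if window_ns is not None:
        if dt_ns is None or dt_ns <= 0:
            raise ValueError("window_ns requires a positive dt_ns")
        n_keep = max(1, int(round(window_ns / dt_ns)))
        totals = totals[-n_keep:]
    return float(totals.mean()), float(totals.std(ddof=0))
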