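# Methods

## Scope and data model

The package analyses protein–double-stranded-DNA complexes given as PDB
coordinate files, plus multi-frame coordinate trajectories for the
dendrimer–DNA post-processing path. Structures are held as a light
chain → residue → atom hierarchy; residues are classed as protein (the 20
standard amino acids), DNA (DA/DC/DG/DT and the legacy one-letter codes)
or other. Only the first model of a multi-model file is used for
single-structure analysis; multi-model files are read as trajectories.
Residue numbering is preserved exactly as in the input; all lengths are in
Å unless stated otherwise.

Masses are standard atomic weights and van der Waals radii the Bondi set.
Each DNA atom belongs to exactly one moiety: phosphate
{P, OP1/O1P, OP2/O2P, OP3}, sugar {C1'–C5', O4', O3', O5'}, base (all
remaining heavy atoms); hydrogens follow their heavy atom by name. The
bridging esters O3'/O5' are assigned to the sugar because they are part of
the deoxyribose ester linkage; the dictionaries are arguments of
`assign_moiety`, so the alternative (phosphate) convention is one keyword
away. This choice shifts a few percent of backbone hydrogen bonds between
the sugar and phosphate columns but cannot change any ranking the package
reports.

## Contact criteria

Hydrogen bonds follow the HBPLUS distance convention: donor–acceptor
heavy-atom distance ≤ 3.35 Å, plus H···A ≤ 2.7 Å when the donor carries an
explicit hydrogen. Crystal structures normally lack hydrogens, so the
heavy-atom criterion alone is the default path; the package never places
hydrogens (a deliberate divergence from HBPLUS, which builds them). An
optional D–H–A ≥ 90° angle filter exists for parity experiments but is off
by default, since the geometric definition used throughout rests on the
two distances only. Donor/acceptor dictionaries cover all side-chain sites
plus backbone N (donor, except proline) and O (acceptor); His ND1/NE2
count both ways, Cys SG is excluded as a weak donor.

Van der Waals contacts are interface heavy-atom pairs within 3.9 Å (the
HBPLUS non-bonded default; a sum-of-radii + 0.5 Å rule is selectable).
A pair that qualifies as a hydrogen bond is excluded from the vdW list, so
the two tables can be summed without double counting. Contact *counting*
(`count_contacts`, trajectory contact percentages) uses atom–atom pairs
within 3.5 Å strict; atom-pair counting was chosen over residue-pair
counting because typical per-system totals in the hundreds match the former.

The per-base donor/acceptor inventory ships a default table that counts
the free hydrogen-bonding valences each base retains after Watson–Crick
pairing — donor hydrogens and acceptor lone pairs reachable from the
grooves (G: O6, N7, N3 + N2-H = 4; A: N7, N3 + N6-H = 3; T: O2 (two lone
pairs) + O4 = 3; C: O2 + N4-H = 2). This reproduces the expected ordering
G > T = A > C with the T/A tie. The table is an argument, so a different
counting convention can be swapped in without touching the logic.

## Non-redundant resampling

Complexes are mapped to superfamilies through a user-supplied domain
table (complex, chain, residue range, superfamily); a complex whose
DNA-contacting residues fall outside every assigned domain is excluded,
mirroring the removal of proteins with unassigned interacting regions.
Ensemble size uses x = ⌈−ln(p)/f⌉ (461 at p = f = 0.01; the raw value is
460.5 and rounding up is the conservative choice). Each subset shuffles
the complex list and greedily admits any complex introducing no
already-seen superfamily. The subsets are therefore *maximal*; the
variable sizes this produces are consistent with the reported behaviour of
such samplers, though a fixed-size variant would also satisfy the
one-per-superfamily constraint. A complex spanning several superfamilies
blocks all of them (conservative reading of "one representative per
superfamily"). Sampling is driven by `numpy.random.SeedSequence.spawn`, so
a subset ensemble is byte-reproducible from its seed.

The homology backstop is a pluggable pairwise predicate; the shipped
default flags pairs whose 5-mer Jaccard similarity exceeds 0.5. This is a
deliberate stand-in for a real alignment search: it fires on long shared
segments (the signature of a shared domain) but not on uniformly scattered
point identity. Consequently the number of subsets dropped by this filter
is not comparable to what an alignment-based search would give, and no
quantitative claim is attached to it.

Aggregation is cell-wise mean and population SD (ddof = 0) across subsets;
with a single subset the SD is reported as zero with a warning rather than
NaN, keeping downstream CSVs well-formed.

## Propensity tables

Counts are tallied per amino acid × target, target ∈ {phosphate, sugar,
A, C, G, T}, with an optional coarse collapse of the four bases into one
column. Counts are deliberately *not* normalized by amino-acid abundance:
the natural abundance of residues at interfaces is part of the signal.
Percentages divide by the grand total of a contact kind, or by the
base-contact subtotal in `bases_only` mode. Ranking sorts amino acids by
total contacts, ties broken alphabetically (real tallies essentially never
tie; the rule just makes the function total).

## SASA, exposure and charge density

SASA is Shrake–Rupley with a 1.4 Å probe and 960 quasi-uniform (Fibonacci
lattice) test points per atom by default; 960 points give ≈0.1% quadrature
error on an isolated sphere and agree with an independent implementation
(biotite) to well under 1% on whole duplexes. Hydrogens get zero area and
do not occlude. Exactly coincident duplicate atoms (altloc artefacts) are
counted once, the copy with the lowest index owning the surface. Relative
exposure divides residue SASA by the theoretical maximum for that residue
type in an extended Gly-X-Gly tripeptide (Tien et al. 2013 values, shipped
as a table); termini can exceed 100%.

Charge density treats the molecule as a sphere of radius r_gyr:
density = N_exposed / 4π r_gyr² in e/nm², counting residues above a 50%
exposure threshold, classed positive {Arg, Lys}, negative {Asp, Glu},
neutral otherwise. Histidine is neutral by default (pKa ≈ 6) with a flag
to count it positive. The dendrimer variant takes (n_charges, r_gyr)
directly — a fully functionalized particle exposes all its terminal
charges, so no 3-D dendrimer model is needed.

## Trajectory observables

A trajectory is a coordinate stack over a static topology with a frame
spacing dt (ns) and an optional orthorhombic box; the minimum-image
convention applies only when a box is given (synthetic fixtures are
non-periodic). Observables: per-frame COM separation; per-frame radius of
gyration; an RDF about the reference selection's COM normalized by shell
volume and by the target's mean density inside the analysis sphere (so an
ideal gas gives g ≈ 1 and the histogram integrates back to the target
count); contact percentages by moiety at requested snapshots (nearest
frame); contact percentages by base pooled over a trailing window and
normalized over base contacts only; and dsDNA end-to-end shortening,
100 × (1 − L(t)/L_ref), with L the distance between the COMs of the two
terminal base pairs and L_ref supplied from a free-DNA run. Snapshots with
no contacts report zeros with a warning instead of NaNs.

## Energetics

The MM evaluator covers harmonic bonds k(r−r₀)² and angles k(θ−θ₀)²
(CHARMM convention, no ½), periodic torsions k(1+cos(nφ−δ)), 12-6
Lennard-Jones in ε/r_min form with Lorentz–Berthelot combination, and
Coulomb with k_e = 332.0636 kcal Å mol⁻¹ e⁻², no cutoff — adequate for the
toy parameterizations this package assembles, not a general force-field
engine. Externally computed per-frame energies are accepted as CSV
(frame, e_bond, e_angle, e_torsion, e_vdw, e_elec) and averaged over the
trailing window (default intent: the last 10 ns of a production run, via
`window_ns`), with the frame-wise SD reported as the ΔH uncertainty.

Polar solvation is the pairwise Still GB form with
f_GB = sqrt(r² + aᵢaⱼ exp(−r²/4aᵢaⱼ)), ε_in = 1, ε_out = 78.5, self-terms
included; a single ion reduces exactly to the Born formula, and infinitely
separated ions to the sum of their Born terms. Born radii are inputs; for
toy systems the intrinsic radius r_vdw − 0.09 Å is a reasonable default.
This is a simplification of production GB solvers (no integral-based
radius rescaling): the module's contract is the Born limit and
separability, not parity with a particular solver.

Nonpolar solvation is γ·SASA + β with γ = 0.00542 kcal mol⁻¹ Å⁻² and
β = 0.92 kcal mol⁻¹.

Entropy uses the Schlitter quasi-harmonic upper bound,
S = ½ k_B ln det[I + (k_B T e²/ħ²) M^{1/2} σ M^{1/2}] (e is Euler's
number), with σ the covariance of snapshot coordinates after mass-weighted
least-squares superposition onto the first snapshot (superposition removes
rigid-body motion, which would otherwise inflate σ; the alignment choice
is ours, as the estimator itself does not prescribe one). The
implementation reproduces the one-atom isotropic closed form
S = (3/2)k_B ln(1 + αms²) within Monte-Carlo error and is monotone in the
covariance scale. Temperature defaults to 310 K. ΔS_conf enters the
binding assembly as S(complex) − S(receptor) − S(ligand) under the
three-trajectory scheme, and ΔH bundles MM plus both solvation terms, so
ΔG = ΔH + (−TΔS).

## Synthetic data

The duplex builder places idealized planar bases (regular-polygon rings,
standard-ish bond lengths) paired so that every purine-N1–pyrimidine-N3
anchor distance is identical, on an ideal helix (rise 3.38 Å, twist 36°,
both configurable), with a plausible fixed-offset sugar–phosphate
backbone. Each phosphate carries formal charge −1; free 5'-OH ends give an
n-bp duplex 2(n−1) phosphates. The fidelity target is correct atom naming,
moiety membership and controllable inter-atomic distances — SASA
magnitudes, groove widths and backbone torsions are *not* realistic, and
nothing downstream depends on them.

Planted-contact complexes place a minimal probe residue (contact atom plus
a short scaffold) at an exact distance from a chosen DNA acceptor along
the direction with maximal clearance from everything else; a placement
whose best clearance would create a spurious contact is refused, so the
planted truth table is exactly recoverable by detection. Collections
sample per-complex contact counts from Poisson rates per amino acid (or
per amino-acid × target), attach superfamily labels with controlled
multiplicity, and emit the ground-truth table alongside.

What passing the planted-recovery tests shows: the detection, tallying,
resampling and ranking machinery is correct and unbiased on data whose
generating process is known. What it does not show: anything about the
actual contact statistics of crystal-structure collections, which depend
on a specific database snapshot, real domain assignments and real
homology searches. The headline dataset-scale percentages are therefore
exercised as format and closure checks plus planted-profile recovery, not
as numerical reproductions.

Approach trajectories interpolate the COM separation of two rigid random
blobs between given endpoints with optional Gaussian jitter on the
separation; endpoints are exact in the noiseless case. Gaussian ensembles
draw snapshots from a specified 3N-dimensional normal (scalar, diagonal or
full PSD covariance) for entropy validation. All generators are
deterministic under their seed.

## Problem sizes and numerical choices

Default test-suite sizes: 8–38 bp duplexes, collections of 12–32
complexes, 100-seed recovery ensembles, 500-subset sampler checks, 10⁵
snapshots for the entropy closed-form comparison — the whole suite runs in
a couple of minutes on one core, chosen so the statistical assertions
(≥ 99/100 recoveries at ≥ 3.5σ separations) have negligible flake
probability. SASA quadrature tolerance is 2% against a brute-force
point-count oracle on ≤ 10-atom systems; GB–Born agreement is asserted at
1e-6 relative; percentage closure at ±0.01. Degenerate inputs (zero
contacts, zero variance, single subset, empty selections) return zeros or
raise named errors as documented per function rather than propagating NaNs.

## Known limitations

- No hydrogen placement: explicit-H criteria apply only when the input
  provides hydrogens.
- No mmCIF reader; NMR multi-model files contribute only model 1 to
  single-structure analysis.
- The k-mer homology predicate is a stand-in; counts of dropped subsets
  are not comparable to alignment-based searches.
- The GB term uses fixed intrinsic Born radii; absolute solvation energies
  of polyatomic solutes will differ from production GBIS/OBC solvers.
- The B-DNA geometry is idealized; analyses sensitive to groove geometry
  should use real structures.
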