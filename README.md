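# pdnakit

Geometric survey of amino-acid–DNA contacts in protein–dsDNA complexes,
superfamily-non-redundant resampling of structure collections, a
protein-surface charge-density metric, and dendrimer–DNA trajectory
post-processing up to MM-GBSA binding free energies with quasi-harmonic
entropy.

The package is aimed at structural bioinformaticians and molecular
modellers who want to (i) quantify which amino acids dominate protein–DNA
interfaces and which DNA moieties (phosphate, deoxyribose, base) they
touch, and (ii) post-process coarse "biomimetic nanoparticle + DNA"
trajectories into the standard complexation observables and an end-point
binding free energy.

## What it computes

**Interface contacts.** Hydrogen bonds use the HBPLUS distance criteria: a
donor–acceptor pair counts when d(D···A) ≤ 3.35 Å, and additionally
d(H···A) ≤ 2.7 Å when an explicit donor hydrogen is present. Heavy-atom
pairs within 3.9 Å that do not qualify as hydrogen bonds are van der Waals
contacts; the two classes never double-count a pair. Every contact is
annotated by amino acid, base, and DNA moiety.

**Non-redundant resampling.** With one representative domain per
superfamily a single subset is small, so many are drawn. The ensemble size
comes from x = ⌈−ln(p)/f⌉, where p is the accepted probability of missing
the best subset and f the fraction of subsets that are best; p = f = 0.01
gives x = 461. Subsets are maximal greedy-after-shuffle draws in which no
superfamily appears twice, an optional homology predicate (default: 5-mer
Jaccard similarity > 0.5) drops subsets with residually similar members,
and statistics are reported as cell-wise mean ± SD across subsets.

**Charge density.** density = N_exposed-charges / (4π r_gyr²), in e/nm²,
where a residue is "exposed" when its SASA exceeds 50% of the residue's
reference maximum in an extended peptide (Shrake–Rupley, 1.4 Å probe).

**MM-GBSA.** For each species, G_total = H_MM + G_solv-p + G_solv-np − TΔS_conf
with H_MM averaged over the final trajectory window, G_solv-p the pairwise
Still Generalized-Born energy, G_solv-np = γ·SASA + β
(γ = 0.00542 kcal mol⁻¹ Å⁻², β = 0.92 kcal mol⁻¹), and S from the
Schlitter upper bound ½k_B ln det[I + (k_B T e²/ħ²) M^{1/2} σ M^{1/2}].
Binding: ΔG_bind = G_total(complex) − G_total(receptor) − G_total(ligand)
under the three-trajectory scheme.

## Worked example

```python
import numpy as np
from pdnakit import synthetic, contacts, propensity, nonredundancy, charge, energetics
from pdnakit.structure import net_formal_charge

# 38-bp model duplex: free 5'-OH ends -> 2*(38-1) phosphates, -74 e
dna = synthetic.build_bdna("GCCGCGAGGTGTCAGGGATTGCAGCCAGCATCTCGTCG")
print(len(dna.atoms()), net_formal_charge(dna))        # 1552 -74.0

# synthetic collection with a planted Arg>Lys>Ser>Thr contact profile
spec = synthetic.CollectionSpec(
    n_complexes=24,
    superfamily_labels=[f"sf{i:02d}" for i in range(12)],
    profile={"ARG": 3.0, "LYS": 1.5, "SER": 0.6, "THR": 0.1},
    seed=1,
)
coll = synthetic.generate_collection(spec)
records = [r for c in coll.complexes if c.has_interface
           for r in contacts.find_hbonds(c)]
print(len(records))                                    # 64
table = propensity.tally(records)
print(propensity.rank_amino_acids(table))              # ['ARG', 'LYS', 'SER', 'THR']

print(nonredundancy.required_subsets(0.01, 0.01))      # 461

d = charge.dendrimer_charge_density(n_charges=128, r_gyr_nm=2.5)
print(round(d.area_nm2, 2), round(d.density["positive"], 2))   # 78.54 1.63
```

The ranking recovers the planted preference order; 64 is the number of
planted donor–acceptor pairs the detector found (every planted contact is
placed at 3.0 Å, inside the 3.35 Å criterion). The dendrimer case treats a
generation-4 particle with 128 protonated terminal groups as a 2.5 nm
sphere: 78.54 nm² of surface and ≈1.6 charges/nm², roughly four times the
positive-charge density this metric gives for typical DNA-binding
proteins.

A small CLI wraps the per-structure utilities:

```bash
pdnakit charge-density --pdb complex.pdb --threshold 50
pdnakit hbonds --pdb complex.pdb
pdnakit sasa-report --pdb complex.pdb --out sasa.csv
```

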