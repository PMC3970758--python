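# ringgeom

Geometric analysis of ring-shaped (hexameric) helicase assemblies bound to
single-stranded DNA, for structural biologists working with MCM-family
N-terminal domain rings and similar oligomeric channels.

Crystal structures of the archaeal MCM N-terminal hexamer in complex with
oligo-dT revealed a distinctive binding architecture: the ssDNA circles the
interior of the ring roughly perpendicular to the central channel, with a
defined 5′→3′ polarity, engaging only the subunit interfaces that have
closed down around it. `ringgeom` packages the measurements behind those
observations so they can be applied to any user-supplied coordinate file
(PDB or mmCIF) — or to synthetic assemblies with exactly known ground truth.

## What it computes

* **Deviation from C<sub>n</sub> symmetry.** For a ring of chains
  c₁…c<sub>n</sub>, the concatenated subdomain Cα coordinates are
  superposed by least squares (Kabsch, proper rotations only) onto the
  one-step cyclic permutation c₂…c<sub>n</sub>c₁. The residual

  RMSD = √( (1/N) Σᵢ ‖R xᵢ + t − x<sub>π(i)</sub>‖² )

  is zero iff the ring is exactly C<sub>n</sub>-symmetric and grows with
  any distortion — the statistic that distinguishes a DNA-distorted ring
  from a symmetric apo ring. The fitted rotation's invariant line gives
  the channel axis, its angle ≈ 360°/n.
* **Channel radial profile.** Minimum distance from the channel axis to any
  selected atom, per axial bin — the closest-approach profile of a full
  cylindrical merge, computed directly — plus the narrowest point and
  whether a reference cylinder (default 20 Å diameter, B-form DNA) passes.
* **Interface engagement.** The Cα–Cα distance from a probe residue on one
  subunit to a partner residue on its counterclockwise neighbor (defaults
  201 → 127), classified engaged (< 7.5 Å), disengaged (> 8.4 Å) or
  intermediate — a one-number predictor of ssDNA occupancy at that
  interface — and its concordance with observed DNA.
* **ssDNA path geometry.** 5′→3′ angular polarity (clockwise /
  counterclockwise from a declared face), tilt of the DNA's best-fit plane
  from the channel-perpendicular plane, maximal runs of consecutively
  modeled nucleotides, per-subunit nucleotide assignment by heavy-atom
  contacts, and the full-occupancy capacity n<sub>subunits</sub> ×
  nt-per-subunit.
* **EMSA Hill fits.** Joint least-squares fit of
  I<sub>free</sub>/I₀ = K<sub>half</sub><sup>h</sup> /
  (K<sub>half</sub><sup>h</sup> + c<sup>h</sup>) and
  I<sub>bound</sub>/I₀ = c<sup>h</sup> /
  (K<sub>half</sub><sup>h</sup> + c<sup>h</sup>) to titration tables,
  returning K_half, the Hill coefficient h, standard errors and
  mutant/wild-type fold changes.

A synthetic module generates near-C₆ rings with controlled perturbations,
DNA paths of known handedness, and simulated titrations, all with ground
truth attached.

## Worked example

```python
from ringgeom import RingDefinition, permutation_rmsd, fit_titration
from ringgeom.synthetic import (SyntheticRingSpec, SubunitPerturbation,
                                make_ring, simulate_titration,
                                WT_SSDNA_LADDER)

# a hexamer with one subunit pushed 1 A radially outward
ring_def = RingDefinition(ordered_chains=list("ABCDEF"),
                          subdomain_range=(1, 30))
perts = [SubunitPerturbation(radial_shift=1.0)] + [SubunitPerturbation()] * 5
assembly, truth = make_ring(SyntheticRingSpec(perturbations=perts))
report = permutation_rmsd(assembly, ring_def)
print(f"permutation RMSD: {report.permutation_rmsd:.3f} A")
print(f"rotation angle:   {report.rotation_angle:.2f} deg")

# a simulated EMSA titration at the published WT concentration ladder
series = simulate_titration(WT_SSDNA_LADDER, k_half=6.8, h=2.0,
                            noise_sd=0.02, seed=11, label="WT ssDNA")
print(fit_titration(series).summary())
```

prints

```
permutation RMSD: 0.553 A
rotation angle:   60.00 deg
Hill binding fit [WT ssDNA]
============================================
parameter       estimate     std err
--------------------------------------------
K_half (uM)        6.777       0.117
h                   2.05      0.0541
--------------------------------------------
observations: 18    RSS: 0.004631    converged: True
```

The 1 Å radial displacement of one subunit registers as a 0.553 Å
deviation from sixfold symmetry (spread over the displaced subunit and its
permutation partner), while the fitted rotation stays at 60°; the noisy
titration recovers the true half-binding concentration of 6.8 µM within
its standard error.

The same analyses run from the shell:

```bash
ringgeom simulate --out ring.pdb --seed 3
ringgeom symmetry   --structure ring.pdb --chains A,B,C,D,E,F --subdomain 1-30
ringgeom interfaces --structure ring.pdb --chains A,B,C,D,E,F --probe 10:CA,20:CA
ringgeom dna        --structure ring.pdb --chains A,B,C,D,E,F \
                    --subdomain 1-30 --dna-chains M
ringgeom full       --config run.yaml
```

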