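# Methods

## The symmetry statistic

A ring of n identical subunits is exactly C_n-symmetric iff some rigid
rotation by 360°/n about some axis maps subunit i onto subunit i+1 for all
i. The deviation statistic operationalizes this: concatenate the subdomain
Cα coordinates of chains [c1…cn] and superpose them, with a single global
least-squares fit, onto the coordinates of the one-step permuted chain
list [c2…cn, c1]. The residual RMSD is the statistic. One global fit (not
the mean of per-chain fits) is used: averaging per-chain fits would hide
exactly the inter-subunit rearrangements the statistic is meant to expose.
Per-subunit residuals under the global fit are also reported; note a
single displaced subunit contributes to two residuals (its own, and the
neighbor mapped onto it by the permutation).

The superposition kernel is the standard SVD (Kabsch) solution restricted
to proper rotations (det = +1); protein chirality forbids reflections.
Near-collinear point sets are rejected rather than solved: the rotation
about the degenerate axis is unconstrained there and the statistic must
not depend on an ill-conditioned fit. The axis and angle of the fitted
rotation are read off the rotation matrix (the angle from the trace, the
axis from the antisymmetric part, falling back to the +1 eigenvector near
0°/180°); the reported axis point is the selection centroid projected onto
the rotation's invariant (screw) line, obtained by least squares on
(I − R)p = t⊥.

Multi-chain selections use author residue numbering and the intersection
rule: only residue numbers carrying the selected atom in *every* ring
chain enter the statistic, and dropped residues are logged. On real
structures with unmodeled residues this choice can perturb the statistic
in the second or third decimal relative to other trimming conventions;
the residue range of the superposition subdomain is likewise a user input
(for MCM N-domain rings, the OB-fold subdomain), so reported values should
always be quoted together with the range used.

## Channel axis and radial profile

Two axis constructions are provided. `permutation_rotation` uses the
rotation fitted by the symmetry statistic — the ring's pseudo-symmetry
axis, and the natural companion to the RMSD number. `inertia` takes the
principal direction of *smallest spatial variance* of the subdomain atom
cloud through its centroid: a flat ring is thinnest along its symmetry
axis. On near-symmetric rings the two agree to better than 2°; both are
constructions, and on real data they may differ from any particular
published rendering axis by a small rigid offset. Which end of the axis is
the C-terminal (ATPase) face cannot be inferred from an N-domain-only
model; it is declared in configuration (`c_face_sign`), never guessed.

The radial profile bins atoms by axial coordinate (default bin width
1.0 Å — finer than subdomain extent, coarser than coordinate noise) and
reports each bin's minimum distance to the axis. Because distance to the
axis is invariant under rotation about the axis, this equals the closest
approach of the union of all rotated copies of the structure (a
cylindrical merge); the explicit 72-copy merge is kept in the test suite
as an oracle. Atoms are treated as points; a uniform probe-radius offset
can be subtracted when an effective clearance is wanted. Empty bins carry
a null radius; the narrowest point is the occupied bin of minimal radius
(ties to smallest z); a bin passes a reference cylinder of diameter d iff
min_radius ≥ d/2.

## Interface engagement

The probe metric is a single Cα–Cα distance from residue A of subunit i to
residue B of its neighbor. Defaults (201 → 127, counterclockwise neighbor,
thresholds 7.5 / 8.4 Å) are configuration, not hard code, since the
residues are specific to the P. furiosus MCM N-domain. Ring order is
declared counterclockwise as viewed from the C-face, so the
counterclockwise neighbor of chain i is the next chain in the list; the
CLI echoes the resolved pairing. Classification is strict at both
thresholds: distances exactly equal to a threshold fall in the
intermediate class, because the engaged/disengaged rules are "less than"
and "exceeds". Concordance with DNA occupancy counts engaged-with-DNA and
disengaged-without-DNA as concordant; intermediate interfaces are reported
but excluded from the count by default, since an interface at intermediate
distance with weak density is evidence for neither side.

## ssDNA path geometry

Each nucleotide is represented by its C1′ atom (P when C1′ is unmodeled):
present in all modeled nucleotides and central in the nucleotide.
Polarity projects these points onto the plane normal to the channel axis
and sums signed angular increments between consecutive nucleotides, each
wrapped to (−180°, 180°] so no single step is ambiguous (consecutive
modeled nucleotides sweep far less than 180° in any plausible geometry).
Sign convention: with the viewing direction pointing from the chosen face
toward the viewer, positive sweep appears counterclockwise; clockwise is
negative sweep. Both the face (`c_face`/`n_face`) and the convention are
echoed in output to prevent sign confusion.

Planarity is the acute angle between the axis and the normal of the
total-least-squares plane through the reference points (smallest-singular-
vector of the centered coordinates): 0° means the DNA circles the ring
exactly perpendicular to the channel; a thin steep helix tends to 90°.

Stretches are maximal runs of consecutive residue numbers within one
chain; chains are never merged. Subunit assignment counts heavy-atom
pairs within a cutoff (default 4.5 Å, a standard heavy-atom contact
distance) between each nucleotide and each ring chain, assigns the
nucleotide to the chain with the most contacts (ties to the earlier chain
in ring order), and reports per-subunit counts; stability of the counts
under ±0.25 Å cutoff changes is asserted on the synthetic fixtures, not
guaranteed on arbitrary data.

## Hill binding fit

The EMSA model is the simultaneous pair
I_free/I0 = K^h/(K^h + c^h), I_bound/I0 = c^h/(K^h + c^h); the two
fractions sum to one exactly. Free and bound residuals are weighted
equally and fitted jointly by trust-region least squares. Initialization:
K_half at the concentration whose free fraction is nearest 0.5, h = 1;
bounds K_half > 0 and h ∈ (0.1, 10] — unbounded cooperativity diverges on
sparse ladders. Standard errors come from the Gauss–Newton covariance at
the optimum. Fits require ≥ 3 distinct positive concentrations and a
sampled transition (series that are essentially all-free or all-bound are
rejected as degenerate). Raw-intensity tables are normalized by the
no-protein lane. Fold changes between variants are reported as the ratio
of K_half values — the natural single-number comparison when h values are
not separately interpretable.

## Synthetic generators

The ring generator places n copies of a fixed 30-point pseudo-fold
template (deterministic, stored in code, so cross-version test values are
stable) at equal angles about +z at a 25 Å ring radius — the scale of an
MCM N-domain hexamer — and perturbs each subunit radially, tangentially,
axially and by twist, either explicitly or i.i.d. Gaussian from a seed.
Zero perturbation gives an exactly C_n assembly, and the generator returns
the construction axis and exact per-subunit transforms, so every
downstream statistic has an analytic expectation in the zero-noise case.
The DNA generator samples a circular or helical path of declared
handedness (sign of the angular step), radius, rise and gap set; the
titration generator evaluates the Hill model at a given ladder and adds
truncated-Gaussian noise to the fractions (no error model is implied by
the data being emulated; truncation simply respects [0, 1]).

What the synthetic data does *not* emulate: real protein folds, sequence,
side chains, crystallographic disorder, or correlated experimental error.
Passing tests therefore demonstrate correctness of the geometry and
fitting machinery under known ground truth, not agreement with any
particular deposited structure; real-structure measurements require the
user to supply coordinates and the subdomain/chain configuration.

## Problem sizes and numerical choices

Default test and reproduction runs use 6 × 30-point rings, 12–24
nucleotide paths, 9-concentration titrations with 200 noisy replicates at
2 % noise, and 200 random point sets against the superposition oracles —
sizes at which every brute-force oracle (dense rotation grid with simplex
refinement, 72-copy cylindrical merge, quaternion closed form) runs in
seconds while exercising the same code paths as full-size structures.
Tolerances: orthonormality and rank checks at 1e-8/1e-9; oracle agreement
at 1e-6 Å (closed forms) and 1e-3 Å (grid searches, limited by grid
refinement); noiseless Hill recovery at 1e-4 relative.
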