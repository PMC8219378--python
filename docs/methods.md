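# Methods

## The observables

### SASA and contact area

SASA is computed by the Shrake–Rupley construction: each atom's sphere of
radius *r* + *probe* carries a fixed golden-spiral lattice of quadrature
points (default 960; deterministic, no random orientation), and a point
is exposed iff it lies strictly outside every neighbouring atom's
inflated sphere. Per-atom area is the exposed fraction times
4π(*r* + *probe*)². Radii come from the Bondi element table with a 1.5 Å
fallback for unknown elements; bead models supply explicit per-name
radii. The probe defaults to 1.4 Å (the water-probe convention). At 960
points the isolated-sphere error is well under 1 %, and doubling the
point count moves a 50-atom cluster's total by < 0.5 %.

The contact area between disjoint groups A and B is
`(SASA_A + SASA_B − SASA_AB) / 2`, each term computed with the group
isolated — half the buried surface, so one interface is counted once and
the value matches per-molecule interface areas on the hundreds-of-Å²
scale. The difference of three quadratures can come out slightly
negative for adjacent but non-touching groups; values are reported
unclipped so distributions remain unbiased. SASA uses no periodic
images: groups are assumed compact ("made whole"), which is the standard
use on clustered molecules and a documented limitation for systems
spanning a periodic boundary.

### Superposition and RMSD

Kabsch superposition is solved by SVD of the covariance with the
reflection branch corrected by sign-flipping the smallest singular
vector, so the returned rotation is always proper. Fewer than three
points, or a collinear reference, raises a degeneracy error rather than
returning an arbitrary rotation. RMSD is unweighted (no mass weighting)
over the selected atoms; the alignment-frame observable superposes each
frame on the reference frame (default: the first frame, i.e. "with
respect to initial positions") using the alignment selection only, then
measures unfitted RMSD over the measurement selection. With alignment =
measurement the result is the Kabsch-minimal RMSD of that group, which
is how the dimer-helix-style stability observable is defined.

Distribution summaries use the *population* standard deviation: the
spread of a complete observable stream is a descriptive quantity, not an
estimator from a sample, and the choice makes test values exact.
Correlations (Pearson and Spearman, average-rank ties) require exactly
matching time grids — both series derive from the same frames in every
intended use, so interpolation is refused rather than silently applied.

### Lipid contacts and enrichment

A lipid molecule is a `(chain, residue id, residue name)` triple — the
PDB convention of one residue per lipid. A molecule is in contact with a
protein residue in a frame iff any of its atoms is within the cutoff
(default 5 Å, closed boundary, minimum image when the frame has a box)
of any atom of the residue. The per-residue profile is the mean count
over frames retained after discarding the first ⌈f·n⌉ frames (burn-in
fraction f, default 0.3 — the convention of discarding the initial 30 %
of a run before time-averaging); the contact map keeps the full
residue × time table, and summing its post-burn-in rows reproduces the
profile exactly. Enrichment of a lipid type (or set of types) is the
fraction of that type among contacting molecules divided by its fraction
among all lipid molecules in the selection; frames with no contacting
lipid are recorded as missing (NaN), never as zero, because the fraction
of an empty set is undefined and zeros would bias the average.

### Sequence census

Windows are given as inclusive residue-number ranges in the *reference*
sequence's ungapped numbering and converted to contiguous alignment-
column spans (interior reference-gap columns included, so insertions in
other sequences are seen). Positive residues are K, R and H — histidine
is counted positive because at an anionic inner leaflet it contributes
to membrane binding alongside Lys/Arg, and the rule is applied uniformly
to every sequence. Negative residues are D and E; gaps contribute
nothing, and any other character is an error. Tail length is the number
of non-gap residues strictly C-terminal to the alignment column of the
reference's catalytic-domain end. The long/short tail threshold has *no*
library default (the CLI suggests 8): there is no universally agreed
cutoff, so the caller must state one. The default exclusion list drops
the three Rhotekin-domain-bearing family members, whose C-terminal
architecture makes a tail-length comparison meaningless.

## The synthetic generator

The generator stands in for microsecond-scale membrane MD at desk scale.
It emulates exactly the features the observables need and no more:

- **Leaflet**: a square lattice (spacing 8 Å ≈ 64 Å² per lipid) of
  immobile one-bead lipids at z = 0, types planned by largest-remainder
  rounding from the target fractions (default 70:25:5 POPC:POPS:PIP2)
  and shuffled by the seeded generator. Charges 0/−1/−4 e respectively
  (nominal physiological net charges; only the ordering matters for the
  trend claims).
- **Domain**: a rigid Fibonacci-sphere shell (default 48 beads, radius
  12 Å) with the n beads nearest the −z pole forming the charged patch
  (default 12 beads × +1 e). Initial pose: patch facing the membrane,
  center one bond length above touching.
- **Tail**: a freely jointed chain of harmonic bonds (rest length 5 Å,
  k = 2 kT/Å²) from a fixed membrane anchor bead to the bottom shell
  bead. Short tail + charged patch is the RhoD-like condition; long
  (14-bead) tail + neutral surface is the RND1-like one.
- **Energy** (kT units at 300 K): screened Coulomb
  `E = (ℓ_B/ε_r-scaled) q_i q_j e^{−r/λ_D}/r` with the vacuum Bjerrum
  prefactor 560.74 Å/ε_r (7.0 Å in water) and Debye length 7.9 Å
  (150 mM monovalent salt); a purely repulsive quadratic soft core
  between protein beads and lipids and against the half-space z < 0; and
  the chain bonds. The Coulomb term is evaluated at
  `max(r, elec_min_distance)` (default 5.4 Å = bead + lipid radius):
  finite beads must not let opposite point charges collapse to r → 0,
  which would otherwise create unphysically deep (tens of kT) pinning
  wells and freeze all sampling.
- **Sampling**: Metropolis Monte Carlo — rigid domain translations
  (≤ 1 Å) and rotations (≤ 5°), per-tail-bead displacements and
  crankshaft rotations about the neighbour axis, all with symmetric
  proposals, so the stationary distribution is exactly Boltzmann. Move
  ΔE values use partial energy sums (only terms a move can change); the
  detailed-balance audit recomputes them against the full energy oracle.
  One seeded generator drives everything in documented order (lipid-type
  shuffle, then per-sweep proposals and acceptance draws): identical
  configs give bit-identical trajectories. Saved frames carry nominal
  times of 1 ns per sweep.

Because the stationary distribution is known, the sampler is validated
directly: with zero charges the domain-height distribution is compared
(two-sample KS) against an independent rejection sampler that draws each
bond vector from its exact radial density r²e^{−βk(r−b)²/2} (inverse-CDF
on a fine grid), the domain orientation uniformly, and accepts on the
repulsive terms.

### What the generator does *not* emulate

Lipids neither diffuse nor leave the plane (so enrichment can arise only
from the domain seeking anionic sites, not lipids migrating to the
protein); there is no explicit solvent, no upper leaflet, no plexin-like
binding partner constraining the domain, and no atomistic force field.
Passing tests therefore show that the *analysis machinery* recovers the
direction of patch-charge- and tail-length-driven membrane engagement in
a system where the truth is known — not that the model reproduces
absolute contact areas or kinetics of real membranes.

## Study conditions and numerical choices

The mechanism-contrast study uses 6 seeds per condition, 2000 sweeps,
a 225-lipid leaflet (15×15, 120×120×150 Å box), and SASA at 240
quadrature points for the per-frame area series (the ~2 % quadrature
noise is irrelevant to a directional contrast and keeps the study fast).
Contact, area and enrichment averages discard the first 30 % of frames;
the RMSD spread is summarized over the *full* series, because the drift
away from the initial pose during membrane capture is part of the
positional-fluctuation signal being compared. Contrasts are tested with
one-sided Mann-Whitney at α = 0.05 over per-seed means; the enrichment
excess over 1 with a one-sided one-sample t-test.

Ties and degenerate inputs: pair distances use closed cutoffs (≤), with
ties broken deterministically; largest-remainder rounding breaks
remainder ties in the fixed order POPC > POPS > PIP2; coincident
equal-radius atoms in SASA mutually occlude (the standard Shrake–Rupley
behaviour) rather than erroring; a cutoff exceeding half the shortest
box length is an error because minimum image is then ambiguous.

## Known limitations

- The RMSD-spread contrast (charged > neutral) is *not* reproduced by
  the synthetic model under the default conditions: the neutral
  long-tail domain tumbles and wanders freely on its leash, generating
  positional fluctuation comparable to the charged domain's
  bind-and-drift, whereas in the motivating biological system the
  neutral-patch GTPase is additionally held in place by its protein
  binding partner — a constraint this model deliberately omits. The
  corresponding acceptance check is left failing rather than weakened;
  the other four contrasts (contact area, contacting residues, anionic
  enrichment, area↔RMSD correlation) are recovered.
- SASA ignores periodic images; contact areas of groups spanning a box
  boundary are underestimated. The synthetic tether keeps the domain far
  from the lateral boundaries, so the study is unaffected.
- The MC time axis is sweep-indexed and nominal; no kinetic quantity
  should be read from it.
- Insertion codes and multi-altloc structures beyond "first altloc" are
  rejected rather than interpreted.
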