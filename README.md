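# memtether

Trajectory and sequence analysis of membrane-tethered GTPase-like
domains, built for the question of *how* a small GTPase engages the inner
membrane leaflet: through a positively charged surface patch held close
by a short lipidated tail, or loosely, on a long flexible anchor. The
package provides the analysis observables used to make that distinction
quantitative on molecular-dynamics-style trajectories, the sequence-level
census that generalizes it across the Rho family, and a coarse-grained
Monte Carlo generator of membrane-tethered-domain trajectories for
validating the whole pipeline end to end.

## Who it is for

Computational structural biologists analyzing protein–membrane MD
trajectories (multi-model PDB or a plain-text frame format) who need
contact areas, alignment-frame RMSD observables, per-residue lipid
contact statistics and lipid enrichment — and a fully synthetic,
seed-reproducible test bed in which the ground truth is known.

## What it computes

- **SASA and contact area** (`memtether.surface`). Shrake–Rupley
  solvent-accessible surface area with a deterministic golden-spiral
  quadrature; the interface area between two groups is the SASA
  difference `(SASA_A + SASA_B − SASA_AB) / 2` — half the surface buried
  on forming the contact. Slightly negative values for adjacent but
  non-touching groups are reported as-is (a known quadrature artefact of
  the difference).
- **Alignment-frame RMSD** (`memtether.positioning`). Each frame is
  superposed on a reference frame by Kabsch least-squares over an
  *alignment* selection, then the unfitted Cα RMSD of a *measurement*
  selection vs its initial position is taken: "where is the GTPase
  relative to the GAP domain" is align-on-GAP, measure-the-GTPase. When
  the two selections coincide the value is the Kabsch-minimal RMSD.
  Distribution summaries (mean, population SD, histogram) and
  Pearson/Spearman correlation between observables are included.
- **Lipid-contact metrics** (`memtether.membrane_metrics`). Per residue
  and frame, the number of lipid *molecules* with any atom within 5 Å of
  any atom of the residue (minimum-image, one residue per lipid);
  averaged after a burn-in fraction (default 0.3) into a per-residue
  profile, kept per-frame as a contact map, reduced to a contacting-
  residue count series, and split by lipid type into an enrichment ratio
  (fraction of a type among contacting lipids over its leaflet fraction).
- **Charged-residue census** (`memtether.seqcharge`). Over a Rho-family
  MSA: counts of K/R/H (positive; histidine counted positive because it
  contributes to binding an anionic leaflet) and D/E (negative) inside a
  membrane-interface window given in the reference sequence's ungapped
  numbering, plus each sequence's C-terminal tail length and a long/short
  classification at a caller-supplied threshold.
- **Synthetic trajectories** (`memtether.synthetic_data`). A Metropolis
  Monte Carlo model of a rigid bead-shell domain with a tunable charged
  polar patch, tethered to a fixed anchor in a lattice leaflet of
  POPC/POPS/PIP2 beads (0/−1/−4 e) through a freely jointed harmonic
  tail. Screened-Coulomb (Debye–Hückel) electrostatics in kT units,
  purely repulsive soft cores, exact Boltzmann stationary distribution,
  bit-reproducible under a seed. Composition and ion planners reproduce
  standard system-building arithmetic (largest-remainder lipid counts,
  150 mM salt sizing).

A thin CLI (`memtether simulate|metrics|census|fixtures`) orchestrates
simulate → metrics → TSV tables from YAML configs; the `examples/`
scripts show each capability from Python.

## Worked example

`python examples/simulate_and_measure.py` runs the charged-patch /
short-tail condition (12 beads at +1 e, 4 tail beads, 225-lipid leaflet,
2000 sweeps, seed 0) and prints:

```
simulated 2000 sweeps -> 51 frames, 278 beads
mean membrane contact area (post burn-in): 137.4 A^2
mean membrane-contacting residues:         4.17
anionic-lipid enrichment in contact shell: 1.83 (baseline fraction 0.30)
```

The domain binds the leaflet (~137 Å² of buried interface, ~4 beads in
lipid contact) and the lipids it touches are 1.8× enriched in POPS/PIP2
relative to their 30 % leaflet share — the electrostatic signature of
patch-driven membrane engagement. The same run with a neutral patch and
a 14-bead tail gives a contact area near zero. For the positional
observables, `python examples/rmsd_observables.py` prints

```
RMSD vs initial pose: mean 19.10 A, spread (population SD) 5.10 A over 51 frames
contact area vs RMSD: Pearson r = 0.48, Spearman rho = 0.25 (n = 51)
```

— frames with more membrane contact sit farther from the initial pose,
i.e. membrane engagement repositions the domain.

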