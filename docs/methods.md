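# Methods

## Model

`dynloop` simulates a chromosomal fibre as a totally flexible self-avoiding
polymer on a periodic cubic lattice, evolved with the classic 3D
bond-fluctuation method (BFM): each monomer occupies a 2×2×2 cube of
lattice sites, no two cubes may overlap, and every bond — backbone or loop
— must be one of the 108 vectors obtained from (2,0,0), (2,1,0), (2,1,1),
(2,2,1), (3,0,0), (3,1,0) by coordinate permutations and sign flips
(squared lengths {4, 5, 6, 9, 10}).  Excluding squared length 8 together
with single-site moves makes chain crossing impossible, so topology is
conserved without explicit entanglement bookkeeping.  An elementary move
picks a monomer and one of the 6 unit directions uniformly at random and
applies it iff the four advancing-face sites are empty and all incident
bonds remain allowed.  One Monte Carlo step (MCS) is N attempted moves.
Bending rigidity is deliberately absent: at the coarse-graining scale of
interest (a monomer representing hundreds of kb) the fibre is flexible.

On top of the backbone dynamics sits the dynamic-loop rule.  After every
MCS, two bookkeeping passes run:

1. **Dissociation** — every loop bond whose scheduled expiry time has been
   reached is removed.  Backbone bonds never break.
2. **Formation** — all *proximal* pairs (non-adjacent monomers whose
   separation is itself an allowed bond vector) are visited in a freshly
   shuffled order; a pair with free binding capacity on both monomers
   forms a bond with probability p_bond,ij, and a new bond gets a lifetime
   drawn from a Poisson distribution with mean T_bond (in MCS).

p_bond,ij comes in three flavours:

* **homogeneous** — one probability for every eligible pair (used for the
  warm-up equilibration phase);
* **contour-cutoff** ("adapted") — p_short when |i−j| ≤ c, p_long beyond;
  at full scale c = 50 of N = 1050 monomers (~5% of the chain), and the
  reduced presets scale c as round(0.05·N);
* **domain layout** ("domain-adapted") — the chain is an alternating
  sequence of equal blocks, linker–domain–…–linker (k looped domains,
  k+1 linkers, N = b(2k+1)); p_short applies inside a looped domain,
  p_long between looped domains, and linker monomers are inert.  A
  `linkers_loop` switch implements the alternative reading in which every
  block acts as a domain (same block → p_short, different blocks →
  p_long); the default keeps linkers inert.

The proximity criterion for loop candidacy is that the pair separation is
an allowed bond vector.  Any larger cutoff would nominate pairs whose
bond could not be represented on the lattice, so this is the natural BFM
notion of "contact".

### Choice of monomer representation

The single-site reading of the BFM ("no lattice site hosts two monomers")
and the classic 8-site variant differ only in microstructure; we commit to
the classic 8-site method because it is the standard, well-tested variant
whose restricted vector set provably prevents chain crossing.  Large-scale
observables (MSD exponents, compaction trends) are insensitive to this
choice.

## Run protocol

A run is: (1) grow a random self-avoiding walk; (2) equilibrate for
`equil1_mcs` with homogeneous looping at `homogeneous_p` (default: the
mean of p_short and p_long — a neutral warm start between the two target
regimes); (3) equilibrate for `equil2_mcs` under the target rule; (4)
production — save a conformation every `save_interval` MCS until
`n_conformations` snapshots exist, recording the squared radius of
gyration Rg² at every save.  Bonds formed in one phase are not cleared at
a phase switch; they expire naturally on their Poisson schedule.

Snapshot independence is gauged with the autocorrelation time τ_ac of the
Rg² series: the normalized autocorrelation function is fitted with an
exponential over its initial decay (lags with correlation above 0.05) and
runs whose save interval is below 5·τ_ac are flagged with thinning
guidance rather than aborted, since the schedule is fixed a priori.  The
estimate needs at least 50 saves and is skipped (with a note) for shorter
productions.

All randomness in a run derives from a single master seed: the master
generator issues one kernel seed per simulation segment in a fixed order,
so identical configurations reproduce bitwise-identical trajectories.

## Parameters and scales

| parameter | full scale | reduced (desk) scale | units |
|---|---|---|---|
| N | 1050 | 105 | monomers |
| L | 500 | 64 | lattice sites |
| short/long cutoff c | 50 | 5 | monomers |
| domain block b | 50 | 5 | monomers |
| T_bond | 8000 | 1000 | MCS |
| equilibration | 10⁸ + 10⁸ | 2×10⁴ + 8×10⁴ | MCS |
| save interval | 10⁷ | 4×10³ | MCS |
| conformations | ≥ 1000 | 30 | — |

The full-scale preset (`paper_preset`) is shipped as configuration but is
cluster-scale.  Tests and the acceptance script run the reduced preset
(`test_preset`): a 105-monomer chain, one tenth of full scale, with cutoff
and block size scaled to keep short loops at ~5% of the chain.

The bond lifetime deserves a note.  At full scale, T_bond = 8000 MCS is
tiny against the 10⁸-MCS equilibration (≈12 500 bond generations), so the
loop population is fully annealed.  A desk-scale run covers ~10⁵ MCS; at
T_bond = 8000 the loop configuration would be effectively quenched (~10
bond generations) and the ensemble non-stationary, which shows up as
enormous seed-to-seed scatter of the plateau MSD.  The reduced preset
therefore scales the lifetime to T_bond = 1000 MCS, preserving the regime
"bond lifetime ≪ run length ≪ structural memory of any single bond" (≈100
bond generations per run).  Steady-state loop numbers stay ample (tens of
concurrent bonds at the default probabilities).

`max_bonds_per_monomer` defaults to 1 — each monomer is a single binding
site, the simplest reading of pairwise monomer contacts; it is
configurable for sensitivity analyses.  A pair that stays proximal is
re-tried every MCS; with capacity 1 and moderate p this re-trial policy
only shortens the waiting time to bond formation.

## Observables

* **MSD profile** ⟨R²⟩(s): mean squared spatial distance between monomers
  s apart, averaged over all pairs and conformations, on coordinates
  unwrapped along the backbone (periodic images never corrupt distances).
  The SEM is computed over conformation-level means: pairs within one
  conformation are strongly correlated and would fake precision.
* **Plateau level**: the n_pairs-weighted mean of ⟨R²⟩ over the top
  tercile of separations (s ≥ ⌈2N/3⌉).  The plateau is the compaction
  readout; the estimator is fixed so values are comparable across runs.
  Profiles must cover s up to at least 0.8·N.
* **Normalized profiles**: ⟨R²⟩ and SEM divided by a reference plateau
  (MSD_ref), e.g. the plateau of a reference parameter cell.
* **Heat maps**: plateau level over a (p_short, p_long) grid.  Every cell
  reruns the full protocol with a seed derived as a SHA-256 hash of
  (base seed, p_short, p_long), making scans reproducible and
  order-independent; finished cells recorded in a manifest are skipped on
  resume, and per-cell failures are recorded without aborting the scan.
* **Loop counts**: n_short / n_long split at the contour cutoff, plus the
  loop-size histogram.

## FISH-style analyses

Experimental distance data enter as plain TSV tables of probe-pair
measurements (genomic distance g in Mb, 3D distance R in µm) — the
package deliberately consumes *distances*, not images; segmentation and
aberration correction are upstream concerns.  `msd_vs_genomic` aggregates
⟨R²⟩ per unique g with SEM and counts (singleton distances are dropped
with a warning).  Radial nuclear position is p_n = r_o/r_n, the distance
of a locus from the nuclear centre of gravity divided by the length of
the centre-through-locus line to the envelope: 0 at the centre, 1 at the
periphery.

The synthetic-table generator bridges simulation and microscopy format:
probes sit on chosen monomers, g = |i−j| × Mb-per-monomer, and the
measured distance is |scale·Δx + ε| with isotropic per-axis Gaussian
localisation noise ε (default σ ≤ 0.05 µm, the sub-50-nm accuracy class
of a good confocal localisation pipeline).  Consequently E[R²] acquires
an additive 3σ² term — the law-of-total-variance signature the tests
check.  What the generator does *not* emulate: probe volume (a BAC covers
~0.1–0.2 Mb, not a point), detection failures, chromatic offsets between
channels, or cell-cycle heterogeneity.  Passing round-trip tests
therefore validate the analysis arithmetic, not the microscopy.

## Numerical and implementation choices

* Inner loops are numba-compiled; all randomness inside a kernel segment
  comes from numba's global RNG seeded explicitly at segment entry.
* The excluded-volume test uses the site-occupancy lattice: moving a cube
  one step exposes exactly four face sites, which must be empty.  This is
  equivalent to the "no two cubes share a site" rule.
* Proximity queries use the anchor-site map as an exact spatial hash: for
  each monomer only the 54 sites one half-set of bond vectors away are
  probed.  The result provably equals the all-pairs scan (tested).
* Minimum-image arithmetic is exact for bonds (|component| ≤ 3 ≪ L/2).
* The autocorrelation fit uses a log-linear regression rather than a
  nonlinear fit: the fitted range is truncated at correlation 0.05, where
  log-space noise is still modest, and a closed-form fit keeps the
  estimator deterministic.
* Degenerate inputs fail loudly: SAW growth on an overfull lattice raises
  after bounded restarts; constant or short Rg² series refuse a τ_ac;
  domain layouts require N = b(2k+1).

## Compaction-trend conditions

The compaction-trend checks sweep p_short over {0.02, 0.08, 0.16} at
fixed p_long = 0.03 and p_long over {0.02, 0.05, 0.08} at fixed
p_short = 0.08, with eight seeds per cell and one-sided permutation tests
on the seed replicates.  Two features of the reduced chain dictate these
cells.  First, the spacing is wider than the full-scale figure grids:
desk-scale seed noise swamps adjacent full-scale values (0.03 vs 0.035).
Second, the 105-mer has a nearby collapse floor (a dense globule's
plateau is a few hundred lattice units²): at low fixed p_short the chain
sits on that floor and the p_long response saturates, so the p_long sweep
is run at p_short = 0.08, and its top cell stops at 0.08 because by
p_long = 0.16 the floor is reached again.  The long-loop trend uses
p_short ∈ {0.02, 0.06, 0.16} at p_long = 0.06.

## Known limitations

* The reduced scale is one tenth of the full-scale chain; absolute
  plateau values are not comparable to full-scale runs, only trend signs
  and ratios are.
* With 25 snapshots per run, τ_ac cannot be estimated per run (needs ≥50
  saves); independence at the reduced scale rests on the save interval
  being several bond lifetimes, checked empirically via stationarity
  tests.
* Loop formation probabilities are per-encounter, per-MCS; mapping them
  onto physical association constants would require a time calibration
  that the lattice model does not supply.
* No sequence specificity: loop anchors are uniform (or block-uniform),
  not motif-positioned, and loop formation is purely probabilistic, not
  energy-weighted.
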