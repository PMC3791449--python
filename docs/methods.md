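# Methods

## The measurement being modelled

One cysteinyl-peptide is bound to an AFM tip via a maleimide-silatrane
(MAS) linker and a second to mica via aminopropyl-silatrane (APS) plus a
3400 Da PEG tether. During retraction a transiently formed dimer loads the
cantilever until it ruptures. Each specific curve yields a rupture force
and, from a worm-like-chain (WLC) fit, a contour length composed of the
tether stack plus the stretched non-interacting N-terminal segments of both
monomers. Repeating at several retraction speeds gives a dynamic force
spectrum (DFS), from which zero-force kinetics are extrapolated; the
contour-length distribution localizes the interacting segment on the
peptide sequence.

## Models

**WLC elasticity.** The Marko–Siggia interpolation
F(x) = (k_BT/p)[¼(1−x/L_c)⁻² − ¼ + x/L_c] is used for fitting and
simulation. Persistence length is fitted within [0.1, 1.0] nm by default
(the tether is a PEG–peptide composite with no single literature value;
the bounds exclude degenerate fits), or can be held fixed.

**PEG two-state contour length.** Each monomer is planar (3.58 Å) or
helical (2.8 Å), Boltzmann-weighted by the conformational free-energy
difference ΔG = 3 k_BT (planar minus helical):
L = N_s·[L_planar/(e^ΔG+1) + L_helical/(e^−ΔG+1)]. With N_s = 77 this
gives 21.8 nm, matching the published 22.0 ± 0.9 nm within rounding.
Uncertainty is propagated from N_s = 77 ± 10 only, which gives ±2.8 nm —
the provenance of the smaller published ±0.9 nm is not reconstructable
from the printed constants, and the discrepancy is reported as is. The
`LinkerModel` default uses the nominal 22.0 nm so that the linker total
(PEG + MAS) is exactly 24.5 nm; the APS sits under the PEG on the mica
side and is recorded but not added, matching the published arithmetic
22.0 + 2.5 = 24.5.

**Bell kinetics and the rupture-force law.** The off-rate under force is
k(F) = k_off·exp(F·x_β/k_BT). At constant loading rate r the first-passage
(Evans–Ritchie) density is p(F) = k(F)/r · exp[(k_off·k_BT)/(x_β·r)·(1 −
e^{F·x_β/k_BT})], with mode F\* = (k_BT/x_β)·ln[x_β·r/(k_off·k_BT)],
clamped at zero below the near-equilibrium threshold rate k_off·k_BT/x_β.

**Barrier reconstruction.** ΔG = ln(ν/k_off) in units of k_BT with the
transition-state prefactor ν = k_BT/h. The working temperature defaults to
300 K: the temperature of the original experiments is unstated, and 300 K
is the room-temperature choice under which the published lifetime →
barrier-height chain (0.11 → 27.3, 0.53 → 28.8, 0.18 → 27.7, 0.63 → 29.0
k_BT) reproduces to one decimal; at 298 K the 0.11 s entry lands at 27.25
and rounds the wrong way. Both temperature and prefactor are configurable.

**Segment mapping.** Boundary residue = (L_c − 24.5 nm − 1.0 nm)/(2c),
with c = 0.41 nm/residue (Aβ40 family) or 0.40 (Aβ42 family). The factor 2
encodes the symmetric-dimer assumption — the non-interacting N-terminal
segments of *both* monomers stretch in series — and is what places the
canonical 33/42/57 nm contour-length clusters at ≈9/≈20/≈38 residues, in
line with their published ~10/~20/~35+ assignments. Profiles flag this
assumption in their metadata; fractional positions are reported unrounded.

## The synthetic instrument

The simulator is the package's testbed: it emulates the acquisition regime
(retraction speeds within 100–4000 nm/s, apparent loading rates ~10³–10⁴⁺
pN/s, rupture forces ~40–100 pN, contour lengths ~25–60 nm) with known
ground truth.

- *Mechanics.* A Hookean cantilever (default 30 pN/nm, a typical soft
  lever) in series with a single WLC of the event's total contour length
  and persistence 0.38 nm. The PEG chain at fixed ΔG has a
  force-independent contour length, and same-persistence WLCs in series at
  common tension extend exactly like one WLC with the summed contour
  length, so one chain represents the PEG + peptide stack — the same
  composite the pipeline fits.
- *Rupture.* Full curves integrate the inhomogeneous hazard k(F(t)) along
  the actual nonlinear ramp, so the loading-rate estimator is exercised
  against realistic curvature; the fast event-table route samples the
  constant-rate Evans–Ritchie law by exact inverse CDF. Below a rebind
  threshold (default 15 pN) the hazard is suppressed in curve simulation:
  with tip and surface still in proximity, transient dissociations at
  near-zero force re-form rather than registering as ruptures. Without
  this, the long low-force dwell of a soft tether produces a large
  population of sub-noise "ruptures" that no detector (and no experiment)
  would count.
- *Speeds.* The default grid is 500–4000 nm/s. At the lowest end of the
  instrument range (100 nm/s) the simulated bond leaves the ramp-dominated
  regime — the self-consistent most probable force falls below the
  detection floor — so the default grid starts where rupture forces land
  in the 40–100 pN window.
- *Noise and classes.* Gaussian force noise (sd 5 pN, typical thermal
  noise at these stiffnesses), contour-length scatter (sd 1.5 nm, standing
  in for anchoring heterogeneity), plus nonspecific curves (exponential
  adhesion within 15 nm, 3 nm decay) and blanks. Loading rates are derived
  from speed × the cantilever–tether series stiffness at the
  self-consistent rupture force (monotone fixed-point iteration).

What the simulator does **not** model: instrument drift beyond linear
baselines, multiple simultaneous tethers, rebinding above the threshold,
hydrodynamic drag, tip-geometry effects, or aggregation beyond the dimer.
Passing recovery tests therefore demonstrates estimator correctness under
these idealized conditions, not robustness to every artifact of real data.

## Estimators and numerical choices

- *Detection.* Candidates are force releases exceeding max(4 × robust
  noise sd, 15 pN) within 4 sampling intervals, evaluated on a 5-point
  boxcar-smoothed trace (a raw point-to-point statistic over thousands of
  noisy samples fires on noise extremes alone); indices are refined to the
  most attractive raw sample of the release edge. The 15 pN floor sits
  below the smallest reported force population and above baseline noise.
- *WLC fitting* runs from the last zero-force crossing (located on the
  smoothed trace) to the rupture point; boundary-pinned or non-convergent
  fits are flagged and excluded. The rupture force is the fitted model
  force at the rupture separation, suppressing single-sample noise.
- *Loading rate* is the slope of force vs time over the final 10% of
  pre-rupture samples (≥10 points). Multi-rupture curves are discarded
  entirely: the tethered-dimer geometry predicts one specific rupture.
- *Specificity window.* Contour lengths within [linker_total − 3 nm,
  linker_total + inter-terminus + 2·N·c + 5 nm].
- *Bin statistic.* The most probable force, not the mean: Bell–Evans
  theory concerns the distribution mode. The default `gaussian` estimator
  (maximum-likelihood Gaussian ⇒ sample mean) matches how rupture
  histograms are conventionally fitted, but on the left-skewed
  Evans–Ritchie law it sits ≈0.577·k_BT/x_β below the true mode; the
  constant offset leaves the slope (x_β) intact and inflates the
  extrapolated k_off by ≈e^0.577. The `evans_ritchie` estimator (per-bin
  maximum likelihood, mode from the closed form) is unbiased under the
  model and is what the parameter-recovery validation uses. Modal-force
  SEMs come from a seeded 500-resample bootstrap; the regression is
  weighted by 1/SEM² (unweighted mode available). Representative bin rate
  is the geometric mean, since the regression abscissa is ln r. Minimum
  bin occupancy defaults to 30 events.
- *Empirical mode* (for validation) is an average-shifted-histogram peak
  with parabolic refinement, kernel width 0.35 × sample sd — mode location
  tolerates a wide kernel far better than sampling noise on a flat top.
- *Profiles.* Fixed-bandwidth Gaussian kernel (2 residues) on a 0.1-residue
  grid, area-normalized. A profile whose maximum never exceeds 1.5 × the
  flat level 1/N carries no structure and is flagged unstructured. Peaks
  are interior local maxima with height ≥ 10% of the global maximum and
  prominence ≥ 2 × the pointwise KDE sampling sd (so noise wiggles are not
  called while minor clusters riding on larger flanks are); peaks closer
  than 4 residues merge. Masses clamped to the sequence boundaries are not
  called as peaks — a known limitation for anchors within ~2 residues of
  either terminus.
- *Replicates* pool as mean ± SEM across experiments. Pooling three
  replicates beats a randomly chosen single replicate in ~2/3 of
  experiments; it cannot be expected to beat the *best* of three (for
  unbiased errors that probability is only ≈0.37).
- *Determinism.* Every stage seed derives from the global seed and the
  stage name (CRC32); the pipeline analyzes the written TSV files rather
  than in-memory arrays, so re-runs and runs on re-read data are
  byte-identical.

## Problem sizes used in validation

Recovery experiments use 3 replicates × 6 log-spaced loading-rate bins
(500–20000 pN/s) × 150 events; end-to-end detection metrics use 250–500
simulated curves at specific fraction 0.3; anchor-mixture recovery uses
300 events; distribution oracles use 10⁵ draws. These sizes put Monte
Carlo error comfortably below the tolerances being asserted while keeping
the whole suite inside a coffee break on one core.

## Known limitations

- The exact published forms of the WLC, rupture-distribution, DFS and
  barrier equations were not recoverable from the source text; the
  canonical forms above are adopted and validated against every published
  number that can be recomputed (tether length, linker total, lifetime →
  barrier mapping, cluster → residue assignments).
- x_β and k_off from the full curve route inherit the Gaussian-mode bias
  and loading-rate estimation noise; the event-table route with the
  Evans–Ritchie estimator is the calibrated path.
- Whether the two monomers' non-interacting segments are equal in length
  (the factor 2) is an assumption; an asymmetric dimer would shift
  boundary assignments by up to a factor of 2.
- The per-residue conversions 0.41/0.40 nm are treated as peptide-specific
  calibration constants; their derivation relative to the commonly used
  0.38 nm is not documented in the source material.
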