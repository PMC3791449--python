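# dimerpull

Single-molecule force spectroscopy (SMFS) analysis of transient peptide
dimers, built around the amyloid-β (Aβ40/Aβ42 and C-terminal mutant)
dimer-dissociation experiment: an AFM tip and a mica surface are each
functionalized with one cysteinyl-peptide through a PEG tether, the tip is
repeatedly approached and retracted, and the rare curves in which a dimer
formed and ruptured are analyzed for rupture force and contour length.

`dimerpull` turns raw force–distance retraction curves into:

- **rupture-event tables** — baseline correction, rupture detection,
  worm-like-chain (WLC) fits, apparent loading rates, specificity filtering;
- **kinetics and energetics** — dynamic force spectroscopy (DFS): the most
  probable rupture force F\* per loading-rate bin, the Bell–Evans regression
  F\*(r) = (k_BT/x_β)·ln[x_β·r/(k_off·k_BT)], dimer lifetime τ = 1/k_off and
  barrier height ΔG = ln(k_BT/(h·k_off)) in units of k_BT;
- **interaction-segment maps** — measured contour length minus the tether
  stack (PEG + maleimide silatrane = 24.5 nm) minus the 1.0 nm
  inter-terminus gap, divided by 2 × the per-residue contour length
  (0.41 nm for Aβ40, 0.40 for Aβ42; both monomers' non-interacting
  N-terminal segments stretch in series), giving the boundary residue of
  the interacting segment; kernel-smoothed profiles with called peaks.

A synthetic-data module simulates the instrument end to end — PEG/WLC
tether mechanics against a Hookean cantilever, stochastic Bell-kinetics
rupture along the actual nonlinear force ramp, nonspecific adhesion and
blank curves, additive force noise — with a ground-truth manifest, so every
estimator is validated by parameter recovery.

## Worked example

```python
from dimerpull.cli_report import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=3), "run_demo")
```

or equivalently `dimerpull run --seed 3 --out run_demo`. This simulates 400
curves (ground truth k_off = 5.56 s⁻¹, x_β = 0.30 nm, anchors at residues
9/20/38 with weights 0.6/0.25/0.15), extracts events, fits the DFS spectrum
and maps the interaction segments. `run_demo/report.md` then reads:

```
Peptide: **abeta40** — 400 curves analysed, 164 events in the DFS regression.

| x_beta (nm) | 0.257 ± 0.014 |
| k_off (1/s) | 14.3 ± 2.3 |
| lifetime tau (s) | 0.07 ± 0.011 |
| barrier height (kBT) | 26.8 |
| DFS R^2 | 0.9971 |
| interaction-profile peaks (residue) | 8.3 |
```

The DFS spectrum is linear (R² ≈ 0.997, a single-barrier landscape); the
recovered barrier position is within ~15 % of the simulated truth, while
k_off — a zero-force extrapolation — is the noisier quantity, and the
default Gaussian bin statistic reads the skewed rupture-force distribution
slightly below its true mode, inflating it (see `docs/methods.md`). The
dominant interaction-profile peak sits at residue ≈ 8, the strongest anchor
of the simulated mixture; the two minor anchors blur under WLC-fit scatter
at this event count.

`dimerpull reproduce` prints the deterministic desk-checkable chain — the
PEG two-state tether length (21.8 nm vs the published 22.0 ± 0.9 nm), the
24.5 nm linker total, the five lifetime → barrier-height mappings
(0.11 → 27.3, 0.53 → 28.8, 0.18 → 27.7, 0.63 → 29.0, 0.11 → 27.3 k_BT) and
the contour-cluster → residue assignments (33 → ≈9, 42 → ≈20, 57 → ≈38) —
each next to its published value.

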