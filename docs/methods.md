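# Methods

## Model

Tissue is a homogeneous, isotropic 2D monodomain sheet

    dVm/dt = Deff * div(grad Vm) - (Iion + Is)

with `Vm` in mV, time in ms, currents in pA/pF (normalised by the whole-cell
capacitance Cm = 100 pF) and `Deff` the effective diffusivity in mm^2/ms
(the conductivity tensor divided by the surface-to-volume ratio and Cm,
collapsed to a scalar on the uniform grid).  Cellular kinetics are the
Courtemanche–Ramirez–Nattel human atrial model: 21 state variables per node
(Vm, 15 gates, and Nai, Ki, Cai plus the two SR calcium compartments).
Two parameter presets are built in:

| quantity            | control | persistent-AF scaler |
|---------------------|---------|----------------------|
| gNa (nS/pF)         | 7.8     | x 0.9                |
| gto                 | 0.1652  | x 0.3                |
| gCaL                | 0.1238  | x 0.5                |
| gK1                 | 0.09    | x 2.0                |
| gKur(V)             | sigmoid | x 0.5                |
| INaCa,max (pA/pF)   | 1600    | x 1.4                |
| Iup,max (mM/ms)     | 0.005   | x 1.25               |

gKur(V) = 0.005 + 0.05 / (1 + exp(-(V-15)/13)) nS/pF.  All other constants
are the published cell-model values.  The AF remodeling shortens APD90 from
about 298 ms to 186 ms at 1-Hz pacing (analysis/01), which is what lets
reentry persist.

## Numerics

* Operator splitting at a fixed step dt = 0.05 ms: explicit 5-point
  finite-difference Laplacian (zero-flux boundaries in the conservative
  finite-volume form, which preserves the spatial mean of a pure-diffusion
  field to rounding) plus a
  Rush–Larsen exponential update for the voltage-gated channels, forward
  Euler for Vm, the concentrations, and the Ca-release v-gate.
* All voltage-dependent rate expressions are pre-tabulated on a 0.05-mV
  grid and looked up nearest-entry; the two steep Ca-release activation
  sigmoids are tabulated against their flux argument the same way.  Table
  quantisation errors are far below the spatial discretisation error.
* Nernst potentials and the Nai-dependent Na/K-pump saturation are
  refreshed every 10 sub-steps (0.5 ms); intracellular concentrations move
  on second-to-minute timescales, and refresh cadences of 1 vs 10 steps
  change the AP by well under the dt discretisation error.
* The explicit diffusion step requires dt <= dx^2/(4 Deff); configurations
  violating 80% of that bound are rejected up front.
* The integrator reports the failure time if the field ever becomes
  non-finite rather than propagating NaNs.
* Removable singularities in the rate functions (e.g. the m-gate alpha at
  V = -47.13 mV) are replaced by their analytic limits in the tables.

## Geometry and protocols

The full-scale sheet is 600 x 600 nodes at dx = 0.25 mm (150 mm square)
with Deff = 0.1 mm^2/ms, giving a control planar conduction velocity of
0.43 mm/ms at 600-ms line pacing — inside the physiological atrial
0.4–0.6 mm/ms band (tissue conductivity is treated as a calibration
parameter; `tissue.calibrate_diffusivity` reproduces the calibration).  Node (row, col) has row 0 at the pacing edge; line stimuli
(-20 pA/pF, 2 ms, three node rows) propagate along +row.  Reentry is
initiated by the cross-field maneuver: after the final paced beat the
membrane potential on the half-sheet columns >= nx/2 is reset to 0 mV
against the repolarising planar wave, and the free end of the reset
boundary curls into a spiral.

### Scaled study conditions

The test-scale experiments run on a 200 x 200 node sheet (50 mm).  A sheet
that small holds less than one 600-ms pacing wavelength at the full-scale
diffusivity, so reentry cannot complete its first turn there; the scaled
study therefore reduces Deff to 0.015 mm^2/ms.  This is the standard
space-rescaling of reaction-diffusion systems (halving lengths maps D to
D/4): at Deff = 0.015 the persistent-AF wavelength at 600-ms pacing is
about 18 mm, making the sheet ~2.8 wavelengths wide — comparable to the
printed 150-mm configuration (~2.4 wavelengths).  Episodes run 10 s of
reentry after initiation; mapping uses the trailing 6 s.

The rescaling has a real cost.  Reducing D at fixed dx is mathematically
identical to coarsening dx at fixed D, so the 0.09-mm depolarisation
front is sampled by a 0.25-mm grid: conduction velocity falls ~35% below
the sqrt(D) prediction, and — more importantly — the spiral core changes
regime.  On the scaled sheet the sustained activity is a slow
(~3 rotations/s) spiral with a large linear-core hypermeander and no
peripheral wave breakup, rather than the fast (~11 Hz), tightly confined
mother rotor with fibrillatory conduction that the full 600 x 600
configuration produces.  The scaled sheet therefore demonstrates
initiation, long-lived reentry, the full mapping/classification/ablation
machinery, and the control-vs-remodeled contrast, but it does not
reproduce full-scale spatial-overlap orderings or ablation responses:
those depend on the confined-fast-rotor regime and require the printed
resolution (several hours of compute).  Alternative scalings were
explored — 160 x 160 and 240 x 240 sheets at intermediate diffusivities
fail to sustain reentry (the S2 traversal time falls below the
refractory period, or initiation is chaotically marginal) — and
200 x 200 at Deff = 0.015 is the configuration that initiates and
sustains reentry reproducibly.

## Mapping

* **DF**: per-node power spectrum of the de-meaned, Hann-windowed AP over
  the 6-s window, zero-padded to 0.05-Hz bins; DF = argmax power in
  0.5–20 Hz.  Nodes with < 5 mV dynamic range are flagged undefined.
* **Bipolar electrograms**: distal 3.5 x 2.0 mm and proximal 1.5 x 2.0 mm
  rectangular footprints, 1.0-mm edge gap; signal = mean AP over distal
  minus mean over proximal (the AP-averaging approximation, not an
  extracellular forward model).  ShEn/CFAE maps are computed on a 2-mm
  tile lattice and painted back to nodes.
* **ShEn**: amplitude histogram over mean +/- 3 SD in 50 uniform bins,
  -sum p log2 p.  The reference description of the statistic does not fix
  the binning; these values are explicit configuration.
* **CFAE-CL**: mean interval between local minima of the signal's time
  derivative over 6 s, with a depth threshold (20% of the window's deepest
  derivative) and a 30-ms refractory gap; fewer than two detections flags
  the tile undefined.
* **Phase**: analytic-signal (Hilbert) phase of the de-meaned AP
  (time-delay embedding available as an option).  PS detection sums
  wrapped phase differences around every 2 x 2 plaquette and marks
  windings of +/-2 pi; tracking links same-charge points greedily by
  nearest neighbour within a 2 mm-per-frame gate.
* **Mother rotor**: a tip trajectory qualifies when (i) its smallest
  enclosing circle (exact Welzl construction) has diameter <= half the
  600-ms pacing wavelength, (ii) it lasts > 5 s, and (iii) at least one
  other PS trajectory is born outside the rotor area (mean tip centre,
  max tip distance radius) during its life — peripheral wave breakup;
  stable reentry without breakup is not a mother rotor.  The breakup
  operationalisation (PS birth outside the rotor-area circle) is this
  package's quantification of a criterion that is usually stated only
  verbally.

## Areas and overlaps

The high-DF area uses the printed 9-Hz cut at full scale; on scaled sheets,
where absolute rates are lower, the cut adapts to 80% of the map's peak DF
(the same logic by which the printed cuts sit just below the rotor's peak:
9 Hz against 11.2–11.3 Hz peaks).  ShEn uses the upper and CFAE-CL the
lower 2.5% of nodes (rotor-sized areas); parameter-vs-parameter overlaps
use 10% areas.  Overlap of area A by area B is 100 |A and B| / |A|, with a
chi-square test on the 2 x 2 node contingency table (the simplest
association test consistent with masks of this size).  Percentile masks break ties by row-major
node order, making every mask bit-reproducible.

## Virtual ablation

Lesions clamp the membrane potential of the lesioned nodes to the resting
value permanently; lesioned tissue still couples diffusively as resting
tissue (a deliberate simplification: the lesion blocks excitation, not
diffusion).  DF- and ShEn-guided lesions take the top 5% of the
map, CFAE-guided the bottom 5%; PS-guided ablation walks the PS stream in
time order adding 1-mm disks (the catheter-tip scale) until 5% of the
domain is lesioned.  Outcomes over the follow-up window: *AF-terminated*
when no node exceeds -40 mV for 500 ms; *AT-converted* when activation at
probe sites is periodic with cycle-length coefficient of variation < 5%
over 10 consecutive beats; otherwise *AF-sustained*.  The -40 mV activity
cut and 5% CL variability are explicit configuration (unstated in the
source); follow-up shorter than 2 s is flagged indeterminate.

## Synthetic fixtures

Every analysis stage is testable without the PDE through fixtures that
return their own ground truth: Archimedean-spiral phase fields mapped
through an AP-like waveform (sharp upstroke, plateau, smooth
repolarisation — a sinusoidal option exists for exact phase-recovery
checks), biphasic deflection trains with prescribed intervals and seeded
jitter, and PS point streams with known segmentation.  Fixtures emulate
only the geometric and spectral structure the detectors consume, not
excitable-media dynamics: passing fixture tests validates the detectors,
while conclusions about fibrillation itself rest on the PDE runs.

## Problem sizes

The test suite and the acceptance script run the scaled study
(200 x 200, Deff 0.015, 10-s episode, 6-s maps, 2.5–3-s ablation
follow-ups); analysis drivers default to the same and expose `--full` for
the printed 600 x 600 / 30-s configuration, which reproduces the
full-scale numbers at several hours on one core.

## Known limitations

* Homogeneous isotropic tissue; no fibre orientation, no 3D atrial
  geometry (patient-specific atrial modelling is out of scope).
* Electrograms are AP averages; amplitudes and fine fractionation differ
  from extracellular-potential models.
* Scaled-sheet absolute rates (DF, CFAE-CL) sit below the full-scale
  values, and the scaled dynamical regime (hypermeandering slow spiral)
  inverts some full-scale spatial relationships; see the scaled-conditions
  section.
* Outcome classification within a ~3-s follow-up can miss terminations
  that need longer — full-scale terminations can take tens of seconds —
  and such runs read as AF-sustained.
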