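# rotormap

**2D in-silico atrial fibrillation: monodomain tissue simulation, rotor
mapping (PS / DF / ShEn / CFAE) and virtual ablation.**

Persistent atrial fibrillation (AF) is thought to be maintained by *mother
rotors* — spatiotemporally stable spiral waves whose wavefronts break up
peripherally and shower the atrium with fibrillatory wavelets.  Clinically,
candidate rotor sites are localised indirectly, through maps of dominant
frequency (DF), Shannon entropy (ShEn) of bipolar electrograms, or complex
fractionated atrial electrogram cycle length (CFAE-CL), and the competing
ablation strategies built on those maps have inconsistent outcomes.  This
package reproduces, in a controlled 2D substrate, the experiment those
strategies implicitly assume: simulate a persistent-AF tissue sheet, map
every parameter simultaneously at full spatial resolution, test which one
actually co-localises with the rotor, and ablate each target virtually.

It is aimed at computational electrophysiologists and methods researchers
who want a tested, reproducible reference implementation of the full chain
from ionic model to ablation outcome.

## Model and definitions

* **Tissue**: homogeneous isotropic monodomain sheet,
  `dVm/dt = Deff ∇²Vm − (Iion + Is)`, Courtemanche–Ramirez–Nattel human
  atrial kinetics (21 state variables per node), 600 × 600 nodes at 250 µm
  at full scale.  Persistent-AF remodeling scales the channel maxima:
  gNa ×0.9, gto ×0.3, gCaL ×0.5, gK1 ×2, gKur ×0.5, INaCa ×1.4, Iup ×1.25.
* **Reentry initiation**: cross-field stimulation — after line pacing at
  600 ms, Vm on half the sheet is reset to 0 mV against the repolarising
  wave; the free end of the reset boundary curls into a spiral.
* **Phase singularity (PS)**: ±2π winding of the analytic-signal phase
  around a 2 × 2 node plaquette; PS points are tracked into rotor-tip
  trajectories.
* **Mother rotor**: a tip trajectory confined within a circle of diameter
  λ/2 (λ = wavelength at 600-ms pacing) for longer than 5 s, with at least
  one peripheral wave breakup; stable reentry without breakup does not
  count.
* **Maps**: per-node DF (argmax of the 6-s power spectrum); per-electrode
  ShEn (amplitude-histogram entropy) and CFAE-CL (mean interval between
  derivative minima) from virtual bipolar electrograms (3.5 × 2.0 mm and
  1.5 × 2.0 mm rectangular poles, 1-mm gap).
* **Virtual ablation**: clamp 5% of the sheet to the resting potential —
  the highest-DF, highest-ShEn or lowest-CFAE-CL area, or 1-mm disks along
  the PS stream — then classify the outcome: AF sustained, AF terminated,
  or conversion to organised atrial tachycardia (AT).

See `docs/methods.md` for numerics, parameter defaults and the scaled
study conditions used by the tests.

## Worked example

The numbered drivers under `analysis/` run the study in sequence.  On the
scaled sheet (200 × 200 nodes, reduced diffusivity; see the methods note
for what the rescaling preserves and what it distorts):

```bash
$ python analysis/01_single_cell.py
control   rest  -80.86 mV   peak  27.02 mV   APD90  293.7 ms
peaf      rest  -83.74 mV   peak  26.56 mV   APD90  183.7 ms

AF remodeling shortens APD90 by 37% at 1-Hz pacing.
```

The AF-remodeled cell repolarises ~110 ms earlier — the shorter
wavelength that lets reentry fit inside a tissue sheet.

```bash
$ python analysis/02_conduction.py
control  D=0.100  CV 0.425 mm/ms   lambda  40.0 mm (band exceeds strip)
control  D=0.015  CV 0.114 mm/ms   lambda  31.3 mm
peaf     D=0.100  CV 0.392 mm/ms   lambda  40.0 mm (band exceeds strip)
peaf     D=0.015  CV 0.097 mm/ms   lambda  17.5 mm
```

At the full-scale diffusivity the control CV sits in the physiological
0.4–0.6 mm/ms band; at the scaled diffusivity the 50-mm sheet spans
about 2.8 persistent-AF wavelengths, comparable to the 150-mm sheet's
~2.4.  Initiating reentry and mapping the episode:

```bash
$ python analysis/03_af_episode.py          # ~8 min on one core
preset peaf: reset at 603 ms; CV 0.097 mm/ms; wavelength 18.3 mm
activity persisted 10.0 s of 10.0 s recorded (mean active fraction 0.32)

$ python analysis/04_maps_and_rotor.py
wavelength 18.3 mm (CV 0.097 mm/ms); DF area cut 3.80 Hz
2 PS trajectories; longest 10.0 s
mother rotor: duration 10.0 s, tip circle diameter 27.0 mm (limit 9.1 mm),
breakup=True, qualifies=False
```

A single spiral survives the whole 10-s episode.  On the scaled sheet it
is a *hypermeandering* rotor: its tip trajectory spans 27 mm, three times
the λ/2 confinement limit, so it does not qualify as a mother rotor — the
confined fast-rotor regime of the full 600 × 600 sheet needs the full
resolution (see the methods note).  The control preset, by contrast,
produces only short-lived or non-breaking reentry, so the
control-vs-remodeled contrast in the rotor classifier is reproduced at
this scale.  The overlap table and the four virtual-ablation arms
(`analysis/05_virtual_ablation.py`) complete the workflow; on the scaled
sheet the ShEn and CFAE extremes cluster over the meander region while
the DF map is nearly flat, and no 2.5-s lesion arm changes the outcome
class — both findings specific to the hypermeander regime, and both
reversed at full scale where the driver is fast and confined.

## Layout

```
src/rotormap/     library: ionic, kernels, tissue, electrogram, maps,
                  rotors, ablation, fixtures, config, pipeline, io, cli
analysis/         numbered narrative drivers (01 single cell ... 05 ablation)
tests/            pytest suite incl. end-to-end acceptance tests
scripts/          acceptance.py
docs/methods.md   model, numerics, parameter choices, limitations
```

A `rotormap` console command exposes the same workflow as verbs
(`simulate`, `map`, `rotor`, `ablate`, `report`, `fixtures`); run
`rotormap --help`.
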