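# exmquant

Quantification toolkit for expansion-microscopy images. It implements the
measurement pipeline used to validate iterative-expansion protocols against
molecular rulers, together with synthetic ground-truth generators so that
every stage is testable without real microscope data:

- **`exmquant.npc_symmetry`** — corner counting for ring-shaped particles
  with n-fold symmetry (nuclear-pore top views): image → point cloud,
  radial-outlier trimming, orientation estimation from the circular mean of
  the s-folded polar angles, equal-sector partition, activation counting,
  and the corners-per-particle histogram with Gaussian regression.
- **`exmquant.calibration`** — expansion-factor calibration against
  molecular-ruler presets (NUP96 107 nm, conoid 380 nm, *Chlamydomonas*
  basal body 225 nm, retina basal body 230 nm at half max), measurement
  correction, nucleus segmentation and the nucleus cross-section statistic
  (`sqrt(area)/gel expansion`), the antibody linkage-error model, and
  ring-diameter measurement (peak-to-peak or half-max conventions).
- **`exmquant.profiles`** — line profiles, FWHM, peak finding with
  parabolic sub-sample refinement, two-peak separation, polar transform
  with angular plot profile, angular/radial channel offsets, and
  total-least-squares fiber angles.
- **`exmquant.periodicity`** — one-sided power spectra (Parseval-exact
  without windowing), dominant-period detection in a period band with a
  permutation-null periodicity score, and pooled dot-interval statistics.
- **`exmquant.synthdata`** — seeded generators for ring particles with
  incomplete corner labeling, Gaussian-spot rendering, two-peak side-view
  profiles, jittered periodic dot chains, striped profiles, n-fold ring
  images, and non-overlapping elliptical nucleus masks.
- **`exmquant.io`** — TIFF/CSV/JSON readers and atomic writers; pixel size
  (nm) is mandatory because every downstream unit depends on it.

Conventions: nm everywhere internally (µm accepted at boundaries); the
physical coordinate of pixel `(i, j)` is `((j+0.5)·px, (i+0.5)·px)`; angles
from +x, counterclockwise.

## CLI

A single `exmquant` entry point with subcommands:

```sh
exmquant simulate npc --param-file cfg.json --seed 1 --n-particles 100 --out sim/
exmquant npc-count --in sim/pointclouds.csv --out npc/        # corner histogram
exmquant calibrate --ruler conoid --in measurements.csv --out cal/
exmquant ncs --gel-ef 1.0 --in mask.tif --pixel-size-nm 400 --out ncs/
exmquant profile fwhm --in profile.csv --out f/
exmquant periodicity intervals --in positions.csv --out per/
exmquant reproduce t5 --seed 1                                 # headline numbers
```

Every command writes a JSON report echoing the parameters and seed that
produced it; identical seeds give byte-identical outputs.

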