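# npfate

Correlative X-ray image analysis for tracking the fate of foliar-applied
nanoparticles (NPs) in plant leaves.

Nano-fertilizers are infiltrated into leaves as particle suspensions; over
the following days the particles may **aggregate**, **disperse**,
**dissolve**, or **translocate**, and each process leaves a distinct joint
signature in three imaging modalities:

* **scanning SAXS** (small-angle X-ray scattering) — per-point detector
  frames are azimuthally regrouped into I(q, θ) and reduced to total
  scattering and scattering-anisotropy maps; the Guinier approximation
  I(q) ≈ I₀·exp(−q²R_g²/3) links I₀ to particle concentration and R_g to
  particle size,
* **micro-CT** — NP-densified regions segmented by Otsu thresholds within
  the leaf; the segmentation threshold tracks cluster packing density and
  the NP volume fraction tracks dispersion,
* **XRF elemental maps** — mobile nutrients (P) leave the treated region
  while immobile tracers (Ce, Eu) stay, separating dissolution from
  translocation.

A rule table turns per-modality up/down/stable trends into a process call:

| process       | SAXS | CT     | XRF (signature element) |
|---------------|------|--------|-------------------------|
| aggregation   | ↓    | ↑      | →                       |
| dispersion    | ↑    | ↓      | →                       |
| dissolution   | ↓    | →      | →                       |
| translocation | ↓    | ↓      | ↓                       |

The package is aimed at beamline users and image-analysis developers who
need a tested, scriptable version of this pipeline. Because beamline data
are bulky and scarce, a **phantom generator** produces synthetic frames,
mesh scans, dilution series, CT volumes and element maps with the
statistical structure the analysis assumes, so the whole chain runs and is
validated offline. See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
import numpy as np
from npfate import (BeamGeometry, CTGeometry, Curve1D, dose_per_exposure,
                    guinier_fit, magnification, effective_voxel)

# Guinier fit of a nano-hydroxyapatite solution curve
q = np.linspace(0.0015, 0.0044, 40)
curve = Curve1D(q=q, intensity=7845 * np.exp(-q**2 * 297.0**2 / 3))
fit = guinier_fit(curve, q_window=(0.0015, 0.0044))
print(f"Rg = {fit.rg:.1f} A, I0 = {fit.i_zero:.0f}")
# -> Rg = 297.0 A, I0 = 7845
# I0 scales with concentration: a 5-fold dilution drops it ~5-fold,
# while Rg stays put until the particles dissolve.

# Dose of one 50 ms exposure of a focused 20.129 keV microbeam
beam = BeamGeometry(energy_kev=20.129, sample_detector_mm=8000,
                    pixel_um=300, beam_center=(0, 0),
                    photon_flux=1e13, exposure_time_s=0.05,
                    spot_area_um2=2500, mass_attenuation_cm2_g=0.56)
print(f"{dose_per_exposure(beam)/1e3:.1f} kGy")
# -> 36.1 kGy  (far above the ~4 kGy onset of radiation damage)

# Cone-beam micro-CT geometry
geom = CTGeometry(source_detector_cm=92, source_object_cm=16,
                  detector_pixel_um=16)
print(f"M = {magnification(geom):.1f}, voxel = {effective_voxel(geom):.2f} um")
# -> M = 5.8, voxel = 2.78 um
```

End-to-end on synthetic data, from the shell:

```bash
npfate simulate --out-dir run --mode dissolution --days 0,1,3 --seed 3
npfate maps run/scan_day0.h5 --out-prefix run/day0
npfate dose                   # prints the 36.1 kGy figure above
npfate geometry               # prints the cone-beam numbers above
npfate classify --saxs 100,50 --ct 100,100 --xrf 100,100
# -> trends: saxs=down ct=stable xrf=stable
# -> process: dissolution
```

Subcommands: `simulate`, `reduce`, `maps`, `guinier`, `ct`, `xrf`,
`classify`, `dose`, `geometry`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch by running the package: the dose per exposure of
the published beamline setting (in kGy), and the median radius of gyration
recovered by the weighted Guinier fit from 100 noisy synthetic replicates
of the baseline nano-hydroxyapatite solution curve (in Å), writing both to
the JSON file given by `--out`.
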