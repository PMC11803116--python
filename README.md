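# dsppol

Double Stokes polarimetry (DSP) for second-harmonic-generation (SHG)
microscopy of chiral fibers such as collagen.

Polarimetric SHG microscopy probes the second-order susceptibility of
fibrillar tissue voxel by voxel. For a fiber with C6 symmetry the
molecular tensor has four independent components, reducible to an achiral
ratio and a complex chiral ratio. DSP recovers the ultrastructure
**without any fitting**: thirty-six intensity images (six incident × six
analyzed polarization states) are combined into SHG Stokes vectors, eleven
closed-form polarimetric parameters, and finally per-pixel maps of

- **δ** — in-image-plane fiber orientation,
- **R** — effective achiral susceptibility ratio
  `R = (χ_zzz/χ_zxx) cos²α + (1 + 2 χ_xxz/χ_zxx) sin²α`,
- **C** — effective chiral ratio magnitude `C = (|χ_xyz|/χ_zxx) sin α`
  (signed: it carries the fiber polarity through the tilt α),
- **Δ** — retardance between the chiral and achiral susceptibility
  components (`χ_xyz = |χ_xyz| e^{iΔ}`).

The package contains the complete chain needed to validate the method on
synthetic data with known ground truth:

| module | what it does |
| --- | --- |
| `dsppol.tensor` | C6 chiral susceptibility model, laboratory-frame tensor |
| `dsppol.forward` | SHG field/Stokes simulator, birefringence, Poisson counting noise |
| `dsppol.filtering` | Stokes assembly, intensity / pure-state / circular-consistency filters |
| `dsppol.parameters` | the eleven DSP parameters, measured-side and closed-form |
| `dsppol.inversion` | analytic inversion to δ, R, C, Δ with branch and quadrant logic |
| `dsppol.pipo` | 8×8 polarization-in/polarization-out simulation and batched least-squares fit (the independent baseline) |
| `dsppol.phantoms` | longitudinal / oblique tendon-like phantoms with ground truth |
| `dsppol.io`, `dsppol.cli` | TIFF+JSON stacks, CSV summaries, `dsppol` command line |

## Worked example

Simulate an obliquely cut tendon-like phantom (fibers tilted ±30° out of
the image plane in polarity bands, broad in-plane orientations, Poisson
noise at ~200 counts gain) and invert it:

```bash
dsppol phantom oblique.tif --preset oblique --size 64 --seed 11 --gain 200
dsppol invert oblique.tif maps.tif
```

prints

```
      map  count    median        iqr
delta_deg   3963  0.060405  80.710249
        R   3970  1.944653   0.072815
    c_cos   3970  0.086746   0.197847
    c_sin   3970  0.087617   0.197660
        C   3970  0.129350   0.282230
Delta_deg   3970 40.007298 179.630364
    sigma   3970  0.060090   0.136952
```

Reading this: 3970 of 4096 pixels survive the intensity and consistency
filters. The recovered median R of 1.94 sits at the ground truth 1.95 for
the 30° tilt (`1.6 cos²30° + 3 sin²30°`). The broad `delta_deg` IQR
reflects the preset's deliberately wide orientation ramp. `c_cos` and
`c_sin` have medians near +0.09 with IQRs spanning both signs — the
polarity bands: pixels tilted one way carry C ≈ +0.14, the other way
C ≈ −0.14 (`0.283 · sin(±30°)`), with Δ = ±45° correspondingly (the
`Delta_deg` median of 40° is a mixture statistic of the two polarity
populations, not a fiber property).

The same pipeline runs from Python:

```python
import numpy as np
from dsppol import (MolecularSusceptibility, PhantomSpec, RunConfig,
                    generate_phantom, process_stack)

spec = PhantomSpec(preset="oblique", shape=(64, 64), gain=200.0, noise_seed=11)
stack, truth = generate_phantom(spec)
images, params, maps = process_stack(stack, RunConfig())
print(np.nanmedian(maps.R[maps.masks["R"]]))   # ~1.94
```

A PIPO baseline (`dsppol pipo-fit`) fits the same forward model to 64-image
linear-polarization stacks per pixel and agrees with the closed-form
inversion to 1e-6 on noise-free data.

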