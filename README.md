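# sfdiskin

Spatial frequency domain imaging (SFDI) of layered skin: recover 2-D maps
of seven physiological and optical skin parameters — total hemoglobin
concentration (THb), oxygen saturation (StO2), melanin content, reduced
scattering coefficient μs′, scattering power b, surface roughness α, and
epidermal thickness h — from modulated visible-light reflectance images,
and analyse their spatiotemporal dynamics (reactive hyperemia, paced
breathing).

The package is aimed at biomedical-optics researchers who want a complete,
self-consistent desk implementation of the layered-skin SFDI pipeline:
demodulation, forward model, three inversion engines, digital phantoms,
accuracy metrics, and hemodynamic time-series analysis.

## The model in brief

Sinusoidal fringes I_DC(0) + I_AC(0)·cos(2π f_x x + φ) at three phases
(0°, 120°, 240°) and three wavelengths (623, 540, 460 nm) are demodulated
exactly:

    I_DC = (I₁+I₂+I₃)/3,   I_AC = (√2/3)·√((I₁−I₂)²+(I₂−I₃)²+(I₃−I₁)²)

giving six absolute MTF observables per pixel (DC and AC per wavelength).
The two-layer skin (melanin-absorbing epidermis of thickness h over a
hemoglobin-absorbing dermis) is mapped to an equivalent homogeneous medium
through the mean probing depth L(q, λ) of the structured light:

    μa,eq·L = μa,epi·h + μa,dermis·(L−h)

with μs′(λ) = μs′(540)·(λ/540)^(−b), Q = √(q²+3μa μt′), and a
roughness-scaled extrapolation length l = α·l₀(μt′). Diffuse reflectance
follows the diffusion-approximation SFD form
Rd(q) = 3A a′/((Q/μt′+1)(Q/μt′+3A)), A = 1/(3 l μt′).

Inversion engines:

* **pixel-wise** — bounded least squares of the six-channel error per
  pixel (physiological-range bounds, seeded multistart, degeneracy diagnostics);
* **p-SFDI** — k-means clustering of MTF vectors, one fit per centroid,
  first-order Jacobian correction per pixel (~100× fewer fits);
* **SFDI-net** — a compact U-Net-style CNN (12-24-48/24-12 channels, tanh,
  MSE + per-channel total-variation loss) trained on forward-rendered
  random-field phantoms; inference is a single forward pass.

See `docs/methods.md` for assumptions, parameter ranges, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from sfdiskin import (AcquisitionGeometry, ChromophoreTable, FitConfig,
                      PhantomSpec, fit_image, render_phantom)

geom, table = AcquisitionGeometry(), ChromophoreTable.default()
truth, clean = render_phantom(PhantomSpec(n=12, mode="two_region", seed=0),
                              geom, table)
maps = fit_image(clean, FitConfig(seed=1), geom, table)
print(f"max per-pixel squared error: {maps.objective.max():.2e}")
print(f"THb background: fit {maps.channel('thb')[0, 0]:.5f} mM, "
      f"true {truth.channel('thb')[0, 0]:.5f} mM")
```

prints

```
max per-pixel squared error: 3.92e-20
THb background: fit 0.00683 mM, true 0.00652 mM
```

i.e. on a noiseless nevus-on-skin phantom the pixel-wise fit reproduces
the measured MTF to machine precision; the recovered THb sits within ~5%
of truth even though seven unknowns from six observations leave a
degeneracy valley along which α, h and melanin can drift at zero residual
(see `docs/methods.md`).

The `examples/` directory has one short narrative script per capability:
forward model, demodulation, pixel-wise inversion, p-SFDI, CNN training,
phantom evaluation (MAPE/SSIM), and breathing-wave dynamics. A thin CLI
(`sfdiskin --help`) exposes the same pipeline as `simulate`, `demodulate`,
`invert`, `train`, `predict`, `evaluate` and `dynamics` subcommands.

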