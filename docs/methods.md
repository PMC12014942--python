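# Methods

`sfdiskin` recovers two-dimensional maps of seven skin parameters from
spatially modulated visible-light reflectance: total hemoglobin
concentration THb (mM), oxygen saturation StO2, depth-integrated epidermal
melanin content (mM·mm), the reduced scattering coefficient μs′ at 540 nm
(mm⁻¹), the scattering power b, a surface-roughness factor α, and the
epidermal thickness h (mm). This note documents the model, the numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## Forward model

**Demodulation.** The scene is illuminated with fringes
I_DC(0) + I_AC(0)·cos(2π f_x x + φ) at φ = 0°, 120°, 240° and three RGB
wavelengths (623, 540, 460 nm), f_x = 0.2 mm⁻¹. Three equally spaced phases
make the demodulation algebraically exact for any spatial phase:
I_DC = (I₁+I₂+I₃)/3 and I_AC = (√2/3)·√((I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²).
The prefactor √2/3 is forced by requiring that a pure sinusoid's amplitude
is recovered exactly. Dividing by the source amplitudes gives the absolute
modulation transfer function (MTF) per pixel: six observables
(DC and AC at three wavelengths). Calibration of the source amplitudes and
projector nonlinearity is hardware-specific and assumed done upstream.

**Two-layer skin and the equivalent medium.** The epidermis (thickness h,
melanin absorption) sits on a dermis (hemoglobin absorption); scattering
follows the power law μs′(λ) = μs′(540)·(λ/540)^(−b) in both layers.
Chromophore absorption is linear in concentration:
μa,dermis = ε_Hb·C_Hb + ε_HbO2·C_HbO2, and the epidermal contribution is
the depth-integrated product ε_mel·(melanin content), i.e. μa,epi·h without
separately resolving melanin concentration and thickness. The bundled
extinction table (natural-log convention, mm⁻¹ mM⁻¹) is converted from a
standard compilation and is user-replaceable via CSV.

For structured light of angular frequency q = 2π f_x, the mean probing
depth of the two-exponential depth profile
I(q,z) = ((1+Ql)e^(−μt′z) − (1+μt′l)e^(−Qz))², with μt′ = μa+μs′,
Q = √(q² + 3μa μt′) and extrapolation length l, is the intensity-weighted
first moment L(q,λ) = ∫zI dz / ∫I dz. The closed form is evaluated in an
algebraically equivalent, cancellation-free arrangement: the textbook
moment-sum ratio is a 0/0 at Q = μt′ (the profile vanishes identically
there), so the common (Q−μt′)² factor is removed analytically and the
expression is smooth for all arguments. A quadrature oracle verifies the
closed form to 1e−6 relative over the physiological grid.

The bilayer is mapped to a homogeneous medium equivalent in total
absorption over the probing depth:
μa,eq·L = μa,epi·h + μa,dermis·(L−h),
which is implicit because L is evaluated in the equivalent medium itself
(μt′ and l depend on μa,eq). It is solved by damped fixed-point iteration
(damping 0.8, initial guess μa,dermis, relative tolerance 1e−13, ≤200
iterations — tight enough that the absolute equivalence residual is below
1e−10). Degenerate limits hold exactly: h→0 with no melanin, and matched
layers (μa,epi = μa,dermis), both collapse to the dermal absorption. The
mapping is flagged invalid when L ≤ h (the probing depth does not reach the
dermis); this does not occur inside the physiological parameter box at
these wavelengths.

**Reflectance.** The model MTF is the diffusion-approximation
spatial-frequency-domain diffuse reflectance
Rd(q) = 3A a′ / ((Q/μt′+1)(Q/μt′+3A)) with a′ = μs′/μt′ and the boundary
constant tied to the extrapolation length by A = 1/(3 l μt′). Surface
roughness scales the smooth-boundary extrapolation length linearly:
l = α·(2/3)·((1+R_eff)/(1−R_eff))/μt′ with R_eff = 0.493 (relative
refractive index 1.4), so α = 1 recovers the conventional
A = (1−R_eff)/(2(1+R_eff)). The exact reflectance model and
extrapolation-length formula behind the original measurements are not fully
specified in the literature this package follows; the forms above are
documented stand-ins used identically in the forward and inverse paths, so
all phantom-based validation is internally consistent. The reflectance
closed form is kept behind a single function and is straightforward to
swap.

## Inversion

**Pixel-wise fitting** minimizes the six-channel squared error
Σᵢ (MTF_AC(λᵢ)−mtf_AC(λᵢ))² + (MTF_DC(λᵢ)−mtf_DC(λᵢ))² per pixel by
bounded least squares (scipy trust-region reflective) over the
physiological box. Seven unknowns against six observations are
underdetermined: the zero-residual set is generically a one-dimensional
valley, dominated by trade-offs among α, h and melanin. The package does
not pretend to resolve this; it makes the output reproducible (three
multistarts — the bounds centroid plus two seeded draws; ties broken by
objective then by parameter-vector norm; the per-pixel start policy is a
pure function of the seed, so identical measurements give identical
results) and reports the per-pixel final objective so degeneracy is
visible. With α and h fixed, the remaining five parameters are identifiable
and recovered to <1% from noiseless data. Duplicate measured vectors are
memoized, which makes piecewise-constant phantoms cheap without changing
any result. A compiled (numba) transcription of the scalar forward model
drives the fitter; a test pins it to the vectorized numpy reference at
1e−12.

**p-SFDI** accelerates inversion by k-means clustering of the per-pixel
MTF 6-vectors (k = 20 by default), one bounded fit per centroid, and a
first-order correction per pixel:
params = centroid params + J⁺·(pixel MTF − centroid MTF), with J the
forward Jacobian at the centroid solution (central differences, step 1e−4
of each bound width) and J⁺ its Tikhonov-damped pseudo-inverse (damping
1e−6), clipped to bounds. When a cluster is numerically constant the
centroid is snapped to its nearest member so the centroid fit sees
bit-identical input to the pixels — without this, ULP-level differences
move the underdetermined fit along its degeneracy valley and the
"pixel-at-centroid" identity would fail. Ill-conditioned corrections fall
back to plain centroid assignment and are flagged. The first-order scheme
is a documented reconstruction of the published idea, not a line-by-line
reimplementation of the original.

**CNN (SFDI-net).** A compact U-Net-style regressor maps n×n×6 MTF stacks
to n×n×7 parameter maps: two 1×1-convolution + tanh blocks per level with
12, 24, 48 encoder channels, two 2×2 max-pool downsamplings, a mirrored
decoder (24, 12) with 2×2 transposed-convolution upsampling and skip
concatenations, and a 1×1 + tanh output head. The source description of the
convolutions ("1×1 kernels, stride 2") is internally inconsistent with the
stated pooling-based downsampling (stride-2 convolutions would shrink
128×128 below 1×1 before the third level), so convolutions here are
stride 1 with kernel size configurable (default 1×1, a 3×3 option for more
spatial context); pooling alone downsamples. Outputs live in (−1,1) by the
tanh head and are mapped to physical units by a fixed per-channel affine
normalization over the physiological box (the original scaling is
unstated; fixed bounds were chosen over dataset min-max so the mapping is
data-independent). Inputs are mapped by x → 2x−1.

The network, backpropagation and Adam optimizer are implemented directly on
numpy arrays; with 1×1 kernels every convolution is a per-pixel linear map,
so the whole model (~13k parameters) trains in minutes on one CPU and is
bit-reproducible for a fixed seed.

Loss: L = (1/7n²)·Σ(ŷ−y)² + (1/7n²)·Σ_k w_k Σ_ij (|∂ĵ_x| + |∂ŷ_y|), an
anisotropic per-channel total-variation penalty with weights
(THb 1.0e−7, StO2 2.5e−7, melanin 5.0e−8, μs′ 1.0e−8, b 1.0e−7, α 1.0e−8,
h 2.0e−6). Training: Adam, learning rate 5.5e−4, batch 32, seeded 90/10
train/validation split, best-validation-epoch weights restored. A known
limitation: with targets normalized to [−1,1], these TV weights make the
penalty ~1e−9 of the MSE term, so the TV-on/TV-off distinction is a
consistent but tiny pressure — the smoothing *direction* is reproducible
(TV-on output total variation is strictly lower), but no large accuracy
trade-off can arise from weights of this magnitude.

Pooled R² (per-channel means as baseline, pooled over channels and pixels,
computed on normalized maps so channels weigh equally) is the headline
accuracy metric.

## Synthetic data

Phantoms are parameter maps rendered through the same forward model and
corrupted with per-channel Gaussian noise at a prescribed amplitude SNR
(σ = RMS(channel)/10^(SNR/20); default 50 dB). Three geometries:

* **two_region** — an elliptical inclusion whose default parameters are a
  melanocytic nevus (THb 0.00697 mM, StO2 0.601, melanin 0.761 mM·mm,
  μs′ 0.838, b −0.213, α 0.453, h 0.130 mm) against surrounding forearm
  skin (0.00652, 0.643, 0.598, 1.174, 0.373, 0.696, 0.144) — a realistic
  contrast pair;
* **logo** — rasterized text as the inclusion mask (the original logo
  geometry is unpublished);
* **random_field** — per-channel smoothed Gaussian random fields
  (correlation length 8 px, toroidal boundary), rank-mapped through the
  normal CDF to span the physiological box with a 2% safety margin. This is
  the CNN training corpus generator: channels are mutually independent and
  cover the box essentially uniformly.

Temporal phantoms: *hyperemia* (flat baseline; THb level and StO2 declining
linearly during occlusion; exponential overshoot-and-recovery after
release, time constant 30 s, overshoot 25% — plausibility choices, the
protocol's functional form is not published; melanin and h constant
throughout) and *breathing* (a travelling sinusoidal THb oscillation,
default 5 cycles/min, 10% amplitude, propagating at a set speed with a
linear spatial phase gradient).

What the synthetic experiments show: that each pipeline stage is correct
and self-consistent (generator and inverter share the forward model by
construction, so noiseless round trips must close), and that the CNN can
learn the inverse mapping from data alone. What they do not show: accuracy
on real skin — real MTF images carry calibration residuals, surface
curvature, cross-channel contamination and spatially correlated noise that
the generator does not emulate, and real parameter fields are mutually
correlated rather than independent.

## Dynamics analysis

ROI traces are per-frame spatial means over rectangular regions.
Low-frequency hemodynamic oscillations are isolated by subtracting a
least-squares polynomial (default degree 3 — enough to remove slow
physiological drift without touching a 5/min oscillation; configurable).
Cycle averaging folds the trace modulo the respiration period. Phase lags
between regions are located at the peak of the normalized cross-correlation
with parabolic sub-sample refinement (the original estimator is unstated);
positive lag means the second trace lags the first. The respiratory wave
velocity is distance/lag; successive-lag reading (each ROI lags its
upstream neighbour) is adopted because it uniquely reproduces the published
velocity arithmetic from the published ROI spacing.

## Problem sizes and reproducibility

Default experiment scales, chosen as desk-scale study conditions: training
corpus 1248 pairs (+64 held out) of 64×64 random-field phantoms at 50 dB —
the corpus size mirrors the scale of the assembled experimental dataset the
architecture was designed for, at a reduced image size; 40 training epochs
for the learning benchmark; the noisy method-comparison phantom is 24×24
over 5 noise seeds; the breathing sequence is 3 fps × 3 min at 32×32 with
0.12 mm/pixel so that ROIs 1.92 mm apart fit the field of view. Every
random draw (phantoms, noise, multistarts, splits, shuffles) flows from
explicit integer seeds; training is single-precision but deterministic for
a fixed seed and thread configuration.

## Known limitations

* The reflectance model and extrapolation-length formula are documented
  stand-ins (see above); absolute MTF values are therefore internally
  consistent rather than instrument-matched.
* Seven-from-six underdetermination is intrinsic; pixel-wise α/h/melanin
  estimates are degenerate without spatial context or priors. The CNN
  mitigates but does not remove this.
* The TV penalty at the documented weights is a negligible fraction of the
  loss; only its direction, not a large accuracy trade-off, is testable.
* One AC spatial frequency and exactly three wavelengths; no sub-diffusive
  high-frequency corrections; flat-surface, normal-incidence geometry only.
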