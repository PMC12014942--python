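"""Digital tissue phantoms: synthetic skin scenes rendered through the
forward model.

A phantom is a set of per-pixel skin parameter maps (the ground truth)
forward-rendered into a clean 6-channel MTF stack, optionally corrupted with
per-channel Gaussian noise at a prescribed SNR.  Three geometries:

* ``two_region`` — an elliptical inclusion over a uniform background, with
  default parameter values matching a melanocytic nevus and its surrounding
  forearm skin (higher melanin and THb, lower scattering in the nevus);
* ``logo`` — rendered text (default "SFDI") as the inclusion mask;
* ``random_field`` — independent smoothed Gaussian random fields per
  channel, rank-mapped to span the physiological parameter box; this is the
  training-corpus generator for the CNN.

Temporal modes emulate reactive hyperemia (cuff occlusion and release) and
paced-breathing hemodynamic oscillations travelling across the field of
view.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .demodulation import MTFStack
from .inversion import ParameterMaps
from .optics import (AcquisitionGeometry, ChromophoreTable, InvalidInputError,
                     PARAM_NAMES, SkinParameterSet, forward_mtf,
                     param_bounds_arrays)

__all__ = ["NEVUS_PARAMS", "SURROUND_PARAMS", "PhantomSpec", "TemporalSpec",
           "render_phantom", "add_noise", "temporal_sequence",
           "random_parameter_maps", "make_corpus"]

#: Mean parameter values of a forearm melanocytic nevus and the surrounding
#: skin (pixel-wise inversion averages) — a realistic contrast pair.
NEVUS_PARAMS = SkinParameterSet(thb=0.00697, sto2=0.601, melanin=0.761,
                                musp540=0.838, b=-0.213, alpha=0.453, h=0.130)
SURROUND_PARAMS = SkinParameterSet(thb=0.00652, sto2=0.643, melanin=0.598,
                                   musp540=1.174, b=0.373, alpha=0.696, h=0.144)


@dataclass
class PhantomSpec:
    """Geometry + per-region parameters + noise level of one phantom."""

    n: int = 128
    mode: str = "two_region"            # two_region | logo | random_field
    foreground: SkinParameterSet = NEVUS_PARAMS
    background: SkinParameterSet = SURROUND_PARAMS
    text: str = "SFDI"                  # logo mode
    corr_length: float = 8.0            # random_field mode, pixels
    margin: float = 0.02                # random_field: stay this fraction
                                        # inside the parameter box
    snr_db: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise InvalidInputError("phantom size too small")
        if self.snr_db <= 0:
            raise InvalidInputError("SNR must be positive (dB)")

    def foreground_mask(self) -> np.ndarray:
        if self.mode == "two_region":
            yy, xx = np.mgrid[0:self.n, 0:self.n]
            cy = cx = (self.n - 1) / 2
            return (((yy - cy) / (0.30 * self.n)) ** 2
                    + ((xx - cx) / (0.42 * self.n)) ** 2) <= 1.0
        if self.mode == "logo":
            return _text_mask(self.n, self.text)
        raise InvalidInputError(f"mode {self.mode!r} has no region mask")


def _text_mask(n: int, text: str) -> np.ndarray:
    """Rasterize ``text`` into a centred boolean n x n mask."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(1, 1), dpi=n)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_axis_off()
    ax.text(0.5, 0.5, text, ha="center", va="center",
            fontsize=72 / max(1, len(text) // 2), fontweight="bold",
            family="sans-serif")
    canvas.draw()
    rgba = np.asarray(canvas.buffer_rgba())
    return rgba[:n, :n, 0] < 128


def random_parameter_maps(n: int, seed: int, corr_length: float = 8.0,
                          margin: float = 0.02) -> np.ndarray:
    """Independent smoothed Gaussian random fields per parameter channel,
    rank-mapped (normal CDF) to uniformly span the physiological box with a
    small safety margin.  Returns an (n, n, 7) array."""
    lo, hi = param_bounds_arrays()
    span = hi - lo
    lo_eff = lo + margin * span
    hi_eff = hi - margin * span
    rng = np.random.default_rng(seed)
    out = np.empty((n, n, 7))
    for c in range(7):
        f = gaussian_filter(rng.standard_normal((n, n)), corr_length,
                            mode="wrap")
        f = (f - f.mean()) / max(f.std(), 1e-12)
        u = ndtr(f)  # ~uniform(0, 1)
        out[..., c] = lo_eff[c] + u * (hi_eff[c] - lo_eff[c])
    return out


def render_phantom(spec: PhantomSpec, geom: AcquisitionGeometry,
                   table: ChromophoreTable
                   ) -> tuple[ParameterMaps, MTFStack]:
    """Evaluate the forward model per pixel: (truth maps, clean MTF stack)."""
    if spec.mode == "random_field":
        truth = random_parameter_maps(spec.n, spec.seed, spec.corr_length,
                                      spec.margin)
        mtf = forward_mtf(truth, geom, table)
    else:
        mask = spec.foreground_mask()
        truth = np.where(mask[..., None], spec.foreground.as_array(),
                         spec.background.as_array())
        fg_mtf = forward_mtf(spec.foreground, geom, table)
        bg_mtf = forward_mtf(spec.background, geom, table)
        mtf = np.where(mask[..., None], fg_mtf, bg_mtf)
    return (ParameterMaps(truth),
            MTFStack(mtf, wavelengths=tuple(geom.wavelengths)))


def add_noise(mtf: MTFStack | np.ndarray, snr_db: float, seed: int = 0
              ) -> MTFStack | np.ndarray:
    """Add zero-mean Gaussian noise per channel with
    sigma = RMS(channel) / 10^(snr_db/20) (amplitude SNR convention)."""
    if not np.isfinite(snr_db):
        return mtf
    data = mtf.data if isinstance(mtf, MTFStack) else np.asarray(mtf, float)
    rng = np.random.default_rng(seed)
    rms = np.sqrt(np.mean(data ** 2, axis=(0, 1)))
    sigma = rms / 10 ** (snr_db / 20.0)
    noisy = data + sigma * rng.standard_normal(data.shape)
    if isinstance(mtf, MTFStack):
        return MTFStack(noisy, wavelengths=mtf.wavelengths, idc0=mtf.idc0,
                        iac0=mtf.iac0)
    return noisy


# ---------------------------------------------------------------------------
# temporal phantoms
# ---------------------------------------------------------------------------

@dataclass
class TemporalSpec:
    """Time-course specification for a dynamic phantom.

    ``hyperemia`` follows the cuff protocol: baseline, occlusion (StO2
    declines while THb stays level), release (THb/StO2 overshoot, then
    exponential return to baseline); melanin and epidermal thickness are held
    constant throughout.  ``breathing`` superimposes a travelling sinusoidal
    THb oscillation at the paced respiration rate, with a spatial phase
    gradient set by a propagation direction and speed.
    """

    mode: str = "breathing"             # breathing | hyperemia
    fps: float = 3.0                    # 1 fps (hyperemia) or 3 fps typical
    duration_s: float = 180.0
    # hyperemia segments (seconds from start)
    t_occlusion: float = 90.0
    t_release: float = 250.0
    sto2_drop: float = 0.35             # fractional StO2 decline at end of occlusion
    overshoot: float = 0.25             # fractional THb/StO2 overshoot at release
    recovery_tau: float = 30.0          # s
    # breathing
    frequency_hz: float = 5.0 / 60.0    # five breaths per minute
    amplitude_frac: float = 0.10        # fractional THb oscillation amplitude
    direction: tuple[float, float] = (0.0, 1.0)   # (dy, dx), unit-normalized
    speed_mm_s: float = 3.84            # propagation speed of the wave
    pixel_pitch_mm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise InvalidInputError("fps and duration must be positive")
        if self.mode == "hyperemia" and not self.t_occlusion < self.t_release:
            raise InvalidInputError("segment times must be ordered")
        if self.frequency_hz <= 0:
            raise InvalidInputError("breathing frequency must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _hyperemia_factors(tspec: TemporalSpec, t: float) -> tuple[float, float]:
    """Multiplicative (THb, StO2) modulation factors of the cuff protocol
    relative to baseline: flat baseline; during occlusion THb stays level
    while StO2 declines linearly by ``sto2_drop``; after release both
    overshoot and relax exponentially back to baseline."""
    if t < tspec.t_occlusion:
        return 1.0, 1.0
    if t < tspec.t_release:
        frac = (t - tspec.t_occlusion) / (tspec.t_release - tspec.t_occlusion)
        return 1.0, 1.0 - tspec.sto2_drop * frac
    dt = t - tspec.t_release
    decay = math.exp(-dt / tspec.recovery_tau)
    # the post-release deficit decays while the overshoot bump rises and falls
    bump = tspec.overshoot * 4.0 * decay * (1.0 - decay)
    f_thb = 1.0 + tspec.overshoot * decay
    f_sto2 = 1.0 - tspec.sto2_drop * decay + bump
    return f_thb, f_sto2


def temporal_sequence(tspec: TemporalSpec, base: PhantomSpec,
                      geom: AcquisitionGeometry, table: ChromophoreTable
                      ) -> list[tuple[float, ParameterMaps, MTFStack]]:
    """Render a dynamic phantom: one (time, truth maps, noisy MTF) per frame."""
    truth0, _ = render_phantom(base, geom, table)
    base_maps = truth0.data
    lo, hi = param_bounds_arrays()
    frames = []
    n = base.n
    if tspec.mode == "breathing":
        dy, dx = tspec.direction
        nrm = math.hypot(dy, dx)
        dy, dx = dy / nrm, dx / nrm
        yy, xx = np.mgrid[0:n, 0:n]
        proj_mm = (yy * dy + xx * dx) * tspec.pixel_pitch_mm
        delay = proj_mm / tspec.speed_mm_s  # seconds
    for k, t in enumerate(tspec.times):
        maps = base_maps.copy()
        if tspec.mode == "hyperemia":
            f_thb, f_sto2 = _hyperemia_factors(tspec, float(t))
            maps[..., 0] = np.clip(base_maps[..., 0] * f_thb, lo[0], hi[0])
            maps[..., 1] = np.clip(base_maps[..., 1] * f_sto2, lo[1], hi[1])
        else:
            phase = 2 * math.pi * tspec.frequency_hz * (t - delay)
            osc = 1.0 + tspec.amplitude_frac * np.sin(phase)
            maps[..., 0] = np.clip(base_maps[..., 0] * osc, lo[0], hi[0])
        mtf = forward_mtf(maps, geom, table)
        mtf = add_noise(mtf, base.snr_db, seed=base.seed + 1000 + k)
        frames.append((float(t), ParameterMaps(maps),
                       MTFStack(mtf, wavelengths=tuple(geom.wavelengths))))
    return frames


def make_corpus(n_pairs: int, n: int, geom: AcquisitionGeometry,
                table: ChromophoreTable, snr_db: float = 50.0,
                corr_length: float = 8.0, seed: int = 0
                ) -> list[tuple[MTFStack, ParameterMaps]]:
    """Generate ``n_pairs`` random-field (MTF, truth) training pairs; the
    MTF stacks carry noise at ``snr_db`` (pass ``numpy.inf`` for clean)."""
    pairs = []
    for i in range(n_pairs):
        spec = PhantomSpec(n=n, mode="random_field", corr_length=corr_length,
                           snr_db=snr_db if np.isfinite(snr_db) else 50.0,
                           seed=seed + i)
        truth, clean = render_phantom(spec, geom, table)
        noisy = add_noise(clean, snr_db, seed=seed + i) \
            if np.isfinite(snr_db) else clean
        pairs.append((noisy, truth))
    return pairs
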