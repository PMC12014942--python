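"""Three-phase sinusoidal demodulation of SFDI fringe images.

Each wavelength is acquired three times with the projected fringe pattern
shifted by 0, 120 and 240 degrees.  For intensities I1, I2, I3 the DC and AC
amplitudes follow from the algebraically exact three-phase identities

    IDC = (I1 + I2 + I3) / 3
    IAC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

and the (absolute) modulation transfer function is the reflected amplitude
normalized by the source amplitude, MTF = I / I(0).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import AcquisitionGeometry, InvalidInputError, channel_names

__all__ = ["PhaseTriplet", "MTFStack", "demodulate", "mtf_from_amplitudes",
           "synthesize_triplet"]

_SQRT2_3 = np.sqrt(2.0) / 3.0


@dataclass
class PhaseTriplet:
    """Three fringe images of one wavelength at phases 0, 2pi/3, 4pi/3."""

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    wavelength: float = 540.0
    phases: tuple[float, float, float] = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)

    def __post_init__(self):
        self.i1, self.i2, self.i3 = (np.asarray(a, dtype=float)
                                     for a in (self.i1, self.i2, self.i3))
        if not (self.i1.shape == self.i2.shape == self.i3.shape):
            raise InvalidInputError("phase images must share one shape")

    @property
    def images(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.i1, self.i2, self.i3


@dataclass
class MTFStack:
    """n x n x 6 stack of demodulated MTF values.

    Channel order: DC at each geometry wavelength (623, 540, 460 by default)
    followed by AC at the same wavelengths.  ``idc0`` / ``iac0`` record the
    per-wavelength source illumination amplitudes the stack was normalized by.
    """

    data: np.ndarray
    wavelengths: tuple[float, float, float] = (623.0, 540.0, 460.0)
    idc0: tuple[float, float, float] = (1.0, 1.0, 1.0)
    iac0: tuple[float, float, float] = (1.0, 1.0, 1.0)
    qc_mask: np.ndarray | None = None  # True where a pixel was saturated/zero

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[-1] != 6:
            raise InvalidInputError(
                f"MTF stack must be (n, m, 6), got {self.data.shape}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return (tuple(f"{int(w)}-DC" for w in self.wavelengths)
                + tuple(f"{int(w)}-AC" for w in self.wavelengths))

    @property
    def shape(self):
        return self.data.shape


def demodulate(triplet: PhaseTriplet) -> tuple[np.ndarray, np.ndarray]:
    """Demodulate a three-phase triplet into (IDC, IAC) amplitude maps.

    Exact for any pure sinusoid sampled at three equally spaced phases,
    independent of the spatial phase of the fringes.
    """
    i1, i2, i3 = triplet.images
    idc = (i1 + i2 + i3) / 3.0
    iac = _SQRT2_3 * np.sqrt((i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2)
    return idc, iac


def demodulation_qc_mask(triplet: PhaseTriplet, saturation: float = np.inf
                         ) -> np.ndarray:
    """True where any phase image is zero-valued or at/above saturation;
    such pixels are demodulated as-is, not imputed."""
    i1, i2, i3 = triplet.images
    bad = (i1 <= 0) | (i2 <= 0) | (i3 <= 0)
    if np.isfinite(saturation):
        bad |= (i1 >= saturation) | (i2 >= saturation) | (i3 >= saturation)
    return bad


def mtf_from_amplitudes(idc, iac, idc0: float, iac0: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Absolute MTF maps: reflected amplitudes normalized by the source
    amplitudes IDC(0), IAC(0)."""
    if idc0 <= 0 or iac0 <= 0:
        raise InvalidInputError("source amplitudes must be positive")
    return np.asarray(idc, dtype=float) / idc0, np.asarray(iac, dtype=float) / iac0


def synthesize_triplet(mtf_dc, mtf_ac, geom: AcquisitionGeometry,
                       idc0: float = 1.0, iac0: float = 1.0,
                       pixel_pitch: float | None = None,
                       wavelength: float = 540.0,
                       spatial_phase: float = 0.0) -> PhaseTriplet:
    """Render the three fringe images a camera would record over a sample
    with the given DC/AC MTF maps.

    Fringes run along the image x-axis (second array axis):
    Ik(x, y) = mtf_dc*IDC0 + mtf_ac*IAC0*cos(2*pi*fx*x*pitch + phi0 + phi_k).
    ``demodulate`` recovers (mtf_dc*IDC0, mtf_ac*IAC0) exactly.
    """
    mtf_dc = np.asarray(mtf_dc, dtype=float)
    mtf_ac = np.asarray(mtf_ac, dtype=float)
    if mtf_dc.shape != mtf_ac.shape:
        raise InvalidInputError("DC and AC maps must share one shape")
    pitch = geom.pixel_pitch if pixel_pitch is None else pixel_pitch
    if pitch <= 0:
        raise InvalidInputError("pixel pitch must be positive")
    x = np.arange(mtf_dc.shape[1]) * pitch
    carrier = 2 * np.pi * geom.fx * x + spatial_phase  # shape (ncols,)
    images = [mtf_dc * idc0 + mtf_ac * iac0 * np.cos(carrier + phik)
              for phik in geom.phases]
    return PhaseTriplet(*images, wavelength=wavelength, phases=tuple(geom.phases))


def demodulate_stack(triplets: list[PhaseTriplet],
                     geom: AcquisitionGeometry,
                     idc0=(1.0, 1.0, 1.0), iac0=(1.0, 1.0, 1.0)) -> MTFStack:
    """Demodulate one triplet per geometry wavelength into an MTF stack."""
    if len(triplets) != 3:
        raise InvalidInputError("expected one triplet per wavelength (3)")
    n0 = triplets[0].i1.shape
    dc_maps, ac_maps, qc = [], [], np.zeros(n0, dtype=bool)
    for t, d0, a0 in zip(triplets, idc0, iac0):
        idc, iac = demodulate(t)
        mdc, mac = mtf_from_amplitudes(idc, iac, d0, a0)
        dc_maps.append(mdc)
        ac_maps.append(mac)
        qc |= demodulation_qc_mask(t)
    data = np.stack(dc_maps + ac_maps, axis=-1)
    return MTFStack(data, wavelengths=tuple(geom.wavelengths),
                    idc0=tuple(idc0), iac0=tuple(iac0), qc_mask=qc)
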