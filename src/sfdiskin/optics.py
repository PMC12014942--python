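"""Two-layer skin forward optics for spatial frequency domain imaging (SFDI).

The skin is modelled as a thin, purely melanin-absorbing epidermis of
thickness ``h`` on top of a hemoglobin-absorbing dermis.  For spatially
modulated light of angular spatial frequency ``q = 2*pi*fx`` the bilayer is
mapped onto an equivalent homogeneous turbid medium whose absorption
coefficient is defined self-consistently through the mean probing depth
``L(q, lambda)``:

    mua_eq * L = mua_epi * h + mua_derm * (L - h)

with ``L`` evaluated in the equivalent medium itself.  Diffuse reflectance of
the equivalent medium (the modulation transfer function, MTF) is computed
with the standard diffusion-approximation spatial-frequency-domain form with
an extrapolated boundary; surface roughness enters as a dimensionless factor
``alpha`` scaling the smooth-surface extrapolation length.

All lengths are mm, coefficients mm^-1, concentrations mM, wavelengths nm,
spatial frequency cycles/mm (``q`` in rad/mm).  Every function broadcasts
over numpy arrays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "R_EFF",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "PHYSIO_BOUNDS",
    "param_bounds_arrays",
    "InvalidInputError",
    "ConvergenceError",
    "SkinParameterSet",
    "HomogeneousOptics",
    "ChromophoreTable",
    "AcquisitionGeometry",
    "reduced_scattering",
    "dermis_mua",
    "epidermis_absorbance",
    "extrapolation_length",
    "probing_depth",
    "homogeneous_mtf",
    "equivalent_mua",
    "forward_mtf",
    "CHANNEL_NAMES",
]

#: Effective internal reflection coefficient for a relative refractive index
#: of 1.4 at the tissue--air boundary.  Documented constant; the smooth-surface
#: extrapolation length is l0 = (2/3) * (1 + R_EFF) / (1 - R_EFF) / mut.
R_EFF = 0.493

# Channel order of parameter maps (and of every 7-vector in this package).
PARAM_NAMES = ("thb", "sto2", "melanin", "musp540", "b", "alpha", "h")
PARAM_UNITS = ("mM", "fraction", "mM*mm", "mm^-1", "-", "-", "mm")

#: Physiological / optical parameter ranges for forearm skin
#: (Fitzpatrick phototypes III-IV); used as fitting bounds and as the
#: normalization box for the CNN.
PHYSIO_BOUNDS = {
    "thb": (0.0005, 0.0249),
    "sto2": (0.31, 0.97),
    "melanin": (0.40, 1.50),
    "musp540": (0.29, 2.37),
    "b": (-1.50, 1.50),
    "alpha": (0.10, 1.50),
    "h": (0.05, 0.19),
}


def param_bounds_arrays() -> tuple[np.ndarray, np.ndarray]:
    """Return (low, high) bound arrays in :data:`PARAM_NAMES` order."""
    lo = np.array([PHYSIO_BOUNDS[k][0] for k in PARAM_NAMES])
    hi = np.array([PHYSIO_BOUNDS[k][1] for k in PARAM_NAMES])
    return lo, hi


class InvalidInputError(ValueError):
    """Raised when a physical precondition on an input is violated."""


class ConvergenceError(RuntimeError):
    """Raised when the equivalent-medium fixed point fails to converge."""


@dataclass(frozen=True)
class SkinParameterSet:
    """The seven physical parameters of one pixel of skin.

    Parameters
    ----------
    thb : float
        Total hemoglobin concentration C_Hb + C_HbO2, mM.
    sto2 : float
        Oxygen saturation C_HbO2 / THb, fraction in [0, 1].
    melanin : float
        Depth-integrated epidermal melanin content, mM*mm.
    musp540 : float
        Reduced scattering coefficient at the 540 nm reference, mm^-1.
    b : float
        Scattering power (exponent of the wavelength power law).
    alpha : float
        Surface-roughness factor scaling the extrapolation length
        (alpha = 1 is a smooth boundary).
    h : float
        Epidermal thickness, mm.
    """

    thb: float
    sto2: float
    melanin: float
    musp540: float
    b: float
    alpha: float
    h: float

    def __post_init__(self):
        if not (self.thb >= 0 and 0 <= self.sto2 <= 1 and self.melanin >= 0
                and self.musp540 > 0 and self.alpha > 0 and self.h > 0):
            raise InvalidInputError(f"unphysical skin parameters: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "SkinParameterSet":
        x = np.asarray(x, dtype=float)
        if x.shape != (7,):
            raise InvalidInputError(f"expected a 7-vector, got shape {x.shape}")
        return cls(*(float(v) for v in x))

    def in_physiological_range(self) -> bool:
        return all(PHYSIO_BOUNDS[k][0] <= getattr(self, k) <= PHYSIO_BOUNDS[k][1]
                   for k in PARAM_NAMES)


@dataclass(frozen=True)
class HomogeneousOptics:
    """Optical coefficients of the equivalent homogeneous medium."""

    mua: float
    musp: float
    l: float

    def __post_init__(self):
        if not (self.mua >= 0 and self.musp > 0 and self.l > 0):
            raise InvalidInputError(f"unphysical optics: {self}")

    @property
    def mut(self) -> float:
        """Transport coefficient mut = mua + musp, mm^-1."""
        return self.mua + self.musp

    def Q(self, q):
        """Effective attenuation sqrt(q^2 + 3*mua*mut), mm^-1."""
        return np.sqrt(np.asarray(q, dtype=float) ** 2 + 3.0 * self.mua * self.mut)


class ChromophoreTable:
    """Molar extinction coefficients (natural log, mm^-1 mM^-1) per wavelength.

    Loaded from a CSV with columns ``wavelength_nm, eps_hb, eps_hbo2,
    eps_melanin``; a bundled three-wavelength table (623/540/460 nm) is the
    default.
    """

    def __init__(self, wavelengths, eps_hb, eps_hbo2, eps_melanin):
        self.wavelengths = tuple(float(w) for w in wavelengths)
        self._hb = dict(zip(self.wavelengths, map(float, eps_hb)))
        self._hbo2 = dict(zip(self.wavelengths, map(float, eps_hbo2)))
        self._mel = dict(zip(self.wavelengths, map(float, eps_melanin)))
        if any(v <= 0 for d in (self._hb, self._hbo2, self._mel) for v in d.values()):
            raise InvalidInputError("extinction coefficients must be positive")

    @classmethod
    def from_csv(cls, path=None) -> "ChromophoreTable":
        if path is None:
            path = resources.files("sfdiskin.data") / "chromophores.csv"
        with open(str(path)) as fh:
            lines = [ln.strip() for ln in fh
                     if ln.strip() and not ln.lstrip().startswith("#")]
        header = [c.strip() for c in lines[0].split(",")]
        cols = {name: [] for name in header}
        for ln in lines[1:]:
            for name, val in zip(header, ln.split(",")):
                cols[name].append(float(val))
        return cls(cols["wavelength_nm"], cols["eps_hb"], cols["eps_hbo2"],
                   cols["eps_melanin"])

    @classmethod
    def default(cls) -> "ChromophoreTable":
        return cls.from_csv()

    def _get(self, d, lam):
        try:
            return d[float(lam)]
        except KeyError:
            raise KeyError(
                f"wavelength {lam} nm not in chromophore table "
                f"(available: {self.wavelengths})") from None

    def eps_hb(self, lam) -> float:
        return self._get(self._hb, lam)

    def eps_hbo2(self, lam) -> float:
        return self._get(self._hbo2, lam)

    def eps_melanin(self, lam) -> float:
        return self._get(self._mel, lam)

    def as_arrays(self, wavelengths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eps_hb, eps_hbo2, eps_melanin) arrays for the given wavelengths."""
        hb = np.array([self.eps_hb(w) for w in wavelengths])
        hbo2 = np.array([self.eps_hbo2(w) for w in wavelengths])
        mel = np.array([self.eps_melanin(w) for w in wavelengths])
        return hb, hbo2, mel


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Illumination geometry: RGB wavelengths, one AC spatial frequency,
    three equally spaced phases."""

    wavelengths: tuple[float, float, float] = (623.0, 540.0, 460.0)
    fx: float = 0.2
    phases: tuple[float, float, float] = (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    pixel_pitch: float = 0.05  # mm / pixel, used when synthesizing fringes

    def __post_init__(self):
        if len(self.wavelengths) != 3 or len(self.phases) != 3:
            raise InvalidInputError("exactly 3 wavelengths and 3 phases required")
        if self.fx <= 0:
            raise InvalidInputError("fx must be positive")

    @property
    def q(self) -> float:
        """Angular spatial frequency 2*pi*fx, rad/mm."""
        return 2 * math.pi * self.fx

    @classmethod
    def from_yaml(cls, path=None) -> "AcquisitionGeometry":
        import yaml
        if path is None:
            path = resources.files("sfdiskin.data") / "default_geometry.yaml"
        with open(str(path)) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            wavelengths=tuple(float(w) for w in cfg["wavelengths_nm"]),
            fx=float(cfg["fx_per_mm"]),
            phases=tuple(math.radians(float(p)) for p in cfg["phases_deg"]),
            pixel_pitch=float(cfg.get("pixel_pitch_mm", 0.05)),
        )


#: Fixed channel order of every MTF 6-vector / stack.
def channel_names(geom: AcquisitionGeometry | None = None) -> tuple[str, ...]:
    wl = geom.wavelengths if geom is not None else (623, 540, 460)
    return tuple(f"{int(w)}-DC" for w in wl) + tuple(f"{int(w)}-AC" for w in wl)


CHANNEL_NAMES = channel_names()


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def reduced_scattering(musp540, b, lam):
    """Power-law reduced scattering musp(lam) = musp540 * (lam/540)^(-b)."""
    musp540 = np.asarray(musp540, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(musp540 <= 0) or np.any(lam <= 0):
        raise InvalidInputError("musp540 and lam must be positive")
    return musp540 * (lam / 540.0) ** (-np.asarray(b, dtype=float))


def dermis_mua(thb, sto2, lam, table: ChromophoreTable):
    """Dermal absorption from hemoglobin:
    eps_Hb*C_Hb + eps_HbO2*C_HbO2 with C_Hb = thb*(1-sto2), C_HbO2 = thb*sto2."""
    thb = np.asarray(thb, dtype=float)
    sto2 = np.asarray(sto2, dtype=float)
    return table.eps_hb(lam) * thb * (1.0 - sto2) + table.eps_hbo2(lam) * thb * sto2


def epidermis_absorbance(melanin, lam, table: ChromophoreTable):
    """Depth-integrated epidermal absorbance eps_mel * melanin content
    (the dimensionless product mua_epidermis * h)."""
    return table.eps_melanin(lam) * np.asarray(melanin, dtype=float)


def smooth_extrapolation_length(mut):
    """Smooth-boundary extrapolation length l0 = (2/3)(1+R_eff)/(1-R_eff)/mut."""
    return (2.0 / 3.0) * (1.0 + R_EFF) / (1.0 - R_EFF) / np.asarray(mut, dtype=float)


def extrapolation_length(alpha, mut):
    """Extrapolation length of a rough boundary: alpha * l0(mut), mm."""
    alpha = np.asarray(alpha, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if np.any(alpha <= 0) or np.any(mut <= 0):
        raise InvalidInputError("alpha and mut must be positive")
    return alpha * smooth_extrapolation_length(mut)


def _probing_depth_raw(q, mua, musp, l):
    """Mean probing depth of structured light, intensity-weighted first moment
    of the two-exponential depth profile
    I(q, z) = ((1+Q l) e^(-mut z) - (1+mut l) e^(-Q z))^2.

    Evaluated in an algebraically equivalent, cancellation-free form (the
    textbook ratio of moment sums is 0/0 at Q = mut; here the common (Q-mut)^2
    factor is removed analytically, so the expression is smooth everywhere).
    """
    m = mua + musp
    Q = np.sqrt(q * q + 3.0 * mua * m)
    s = Q - m
    c = 1.0 + m * l
    num = (c * c * (6.0 * m * m + 6.0 * m * s + s * s)
           + 2.0 * c * l * Q * Q * (4.0 * m + s)
           + l * l * Q * Q * (m + Q) * (m + Q))
    den = (c * c + 2.0 * c * l * Q
           + l * l * (2.0 * m * m + 3.0 * m * s + s * s)) * 2.0 * m * Q * (Q + m)
    return num / den


def probing_depth(q, optics: HomogeneousOptics):
    """Mean probing depth L(q) of structured light in the medium, mm."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise InvalidInputError("q must be non-negative")
    if np.all(q == 0) and optics.mua == 0:
        raise InvalidInputError("probing depth diverges at q=0 in a "
                                "non-absorbing medium")
    L = _probing_depth_raw(q, optics.mua, optics.musp, optics.l)
    if not np.all(np.isfinite(L)):
        raise InvalidInputError("numerically degenerate probing depth")
    return L if L.shape else float(L)


def _homogeneous_mtf_raw(q, mua, musp, l):
    """Diffusion-approximation SFD diffuse reflectance Rd(q).

    Rd = 3 A a' / ((Q/mut + 1)(Q/mut + 3A)) with a' = musp/mut and the
    boundary constant tied to the extrapolation length by A = 1/(3 l mut)
    (for a smooth boundary, alpha = 1, this reduces to the conventional
    A = (1 - R_eff) / (2 (1 + R_eff))).
    """
    mut = mua + musp
    Q = np.sqrt(q * q + 3.0 * mua * mut)
    A = 1.0 / (3.0 * l * mut)
    ap = musp / mut
    x = Q / mut
    return 3.0 * A * ap / ((x + 1.0) * (x + 3.0 * A))


def homogeneous_mtf(q, optics: HomogeneousOptics):
    """Model MTF (diffuse reflectance) of the equivalent medium at frequency q."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise InvalidInputError("q must be non-negative")
    Rd = _homogeneous_mtf_raw(q, optics.mua, optics.musp, optics.l)
    return Rd if Rd.shape else float(Rd)


# ---------------------------------------------------------------------------
# equivalent-medium mapping
# ---------------------------------------------------------------------------

_FP_TOL = 1e-13
_FP_MAX_ITER = 200
_FP_DAMPING = 0.8


def _equivalent_mua_arrays(mua_derm, mel_absorbance, musp, alpha, h, q,
                           tol=_FP_TOL, max_iter=_FP_MAX_ITER,
                           full_output=False):
    """Vectorized damped fixed-point solve of
    mua * L(mua) = mel_absorbance + mua_derm * (L(mua) - h)
    where L is the probing depth of the equivalent medium itself
    (mut = mua + musp, l = alpha * l0(mut))."""
    mua_derm, mel, musp, alpha, h = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mua_derm, mel_absorbance,
                                               musp, alpha, h)))
    mua = np.maximum(mua_derm, 1e-6).astype(float).copy()
    converged = np.zeros(mua.shape, dtype=bool)
    for _ in range(max_iter):
        mut = mua + musp
        l = alpha * smooth_extrapolation_length(mut)
        L = _probing_depth_raw(q, mua, musp, l)
        target = (mel + mua_derm * (L - h)) / L
        target = np.maximum(target, 1e-12)
        step = target - mua
        converged = np.abs(step) <= tol * np.maximum(np.abs(mua), 1e-12)
        if np.all(converged):
            mua = target
            break
        mua = mua + _FP_DAMPING * step
    else:
        if not np.all(np.abs(target - mua) <= 100 * tol * np.maximum(np.abs(mua), 1e-12)):
            raise ConvergenceError("equivalent-medium fixed point did not converge")
    if full_output:
        mut = mua + musp
        l = alpha * smooth_extrapolation_length(mut)
        L = _probing_depth_raw(q, mua, musp, l)
        residual = np.abs(mua * L - (mel + mua_derm * (L - h)))
        return mua, {"L": L, "residual": residual, "mapping_valid": L > h}
    return mua


def equivalent_mua(params: SkinParameterSet, q, lam, table: ChromophoreTable,
                   full_output: bool = False):
    """Equivalent homogeneous absorption coefficient of the bilayer at (q, lam).

    Solves the implicit absorption-equivalence relation by damped fixed-point
    iteration starting from the dermal absorption.  With ``full_output=True``
    also returns a dict with the probing depth ``L``, the absolute residual of
    the equivalence relation, and a ``mapping_valid`` flag (False where
    ``L <= h``, i.e. the probing depth does not reach below the epidermis).
    """
    musp = reduced_scattering(params.musp540, params.b, lam)
    mua_d = dermis_mua(params.thb, params.sto2, lam, table)
    mel = epidermis_absorbance(params.melanin, lam, table)
    out = _equivalent_mua_arrays(mua_d, mel, musp, params.alpha, params.h, q,
                                 full_output=full_output)
    if full_output:
        mua, info = out
        return float(mua), {k: (float(v) if np.ndim(v) == 0 else v)
                            for k, v in info.items()}
    return float(out)


# ---------------------------------------------------------------------------
# forward MTF
# ---------------------------------------------------------------------------

def _forward_mtf_arrays(p, geom: AcquisitionGeometry, table: ChromophoreTable):
    """Forward model on a stacked parameter array of shape (..., 7).

    Returns an array of shape (..., 6) in the fixed channel order
    (DC at each wavelength in geometry order, then AC).
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 7:
        raise InvalidInputError(f"expected (..., 7) parameters, got {p.shape}")
    thb, sto2, mel_c, musp540, b, alpha, h = np.moveaxis(p, -1, 0)
    out = np.empty(p.shape[:-1] + (6,), dtype=float)
    qs = (0.0, geom.q)
    for i, lam in enumerate(geom.wavelengths):
        musp = reduced_scattering(musp540, b, lam)
        mua_d = dermis_mua(thb, sto2, lam, table)
        mel = epidermis_absorbance(mel_c, lam, table)
        for j, q in enumerate(qs):
            mua = _equivalent_mua_arrays(mua_d, mel, musp, alpha, h, q)
            mut = mua + musp
            l = alpha * smooth_extrapolation_length(mut)
            out[..., 3 * j + i] = _homogeneous_mtf_raw(q, mua, musp, l)
    return out


def forward_mtf(params, geom: AcquisitionGeometry, table: ChromophoreTable):
    """Model MTF 6-vector (or (..., 6) stack) for skin parameters.

    ``params`` may be a :class:`SkinParameterSet` or an array of shape
    (..., 7) in :data:`PARAM_NAMES` channel order.
    """
    if isinstance(params, SkinParameterSet):
        return _forward_mtf_arrays(params.as_array(), geom, table)
    return _forward_mtf_arrays(params, geom, table)
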