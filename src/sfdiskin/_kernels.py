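"""Compiled scalar kernels for the per-pixel fitting hot path.

The public, vectorized numpy implementation in :mod:`sfdiskin.optics` is the
reference; these numba kernels re-code the identical formulas as scalar loops
so that a least-squares fit (hundreds of model evaluations per pixel) runs at
compiled speed.  A unit test asserts parity between the two paths.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .optics import R_EFF

_L0C = (2.0 / 3.0) * (1.0 + R_EFF) / (1.0 - R_EFF)


@njit(cache=True, fastmath=False)
def _probing_depth_scalar(q, mua, musp, l):
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


@njit(cache=True, fastmath=False)
def _mtf_scalar(q, mua, musp, l):
    mut = mua + musp
    Q = np.sqrt(q * q + 3.0 * mua * mut)
    A = 1.0 / (3.0 * l * mut)
    ap = musp / mut
    x = Q / mut
    return 3.0 * A * ap / ((x + 1.0) * (x + 3.0 * A))


@njit(cache=True, fastmath=False)
def _equivalent_mua_scalar(mua_derm, mel, musp, alpha, h, q, tol, max_iter):
    mua = mua_derm if mua_derm > 1e-6 else 1e-6
    for _ in range(max_iter):
        mut = mua + musp
        l = alpha * _L0C / mut
        L = _probing_depth_scalar(q, mua, musp, l)
        target = (mel + mua_derm * (L - h)) / L
        if target < 1e-12:
            target = 1e-12
        step = target - mua
        astep = step if step >= 0 else -step
        ref = mua if mua > 1e-12 else 1e-12
        if astep <= tol * ref:
            return target
        mua = mua + 0.8 * step
    return mua


@njit(cache=True, fastmath=False)
def forward_mtf6(p, q_ac, lams, eps_hb, eps_hbo2, eps_mel, out):
    """Fill ``out`` (length 6) with (DC x3, AC x3) model MTF values for the
    parameter 7-vector ``p`` = (thb, sto2, melanin, musp540, b, alpha, h)."""
    thb, sto2, mel_c, musp540, b, alpha, h = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    for i in range(3):
        musp = musp540 * (lams[i] / 540.0) ** (-b)
        mua_d = eps_hb[i] * thb * (1.0 - sto2) + eps_hbo2[i] * thb * sto2
        mel = eps_mel[i] * mel_c
        for j in range(2):
            q = 0.0 if j == 0 else q_ac
            mua = _equivalent_mua_scalar(mua_d, mel, musp, alpha, h, q,
                                         1e-13, 200)
            mut = mua + musp
            l = alpha * _L0C / mut
            out[3 * j + i] = _mtf_scalar(q, mua, musp, l)
    return out


@njit(cache=True, fastmath=False)
def residuals6(p, measured, q_ac, lams, eps_hb, eps_hbo2, eps_mel, out):
    forward_mtf6(p, q_ac, lams, eps_hb, eps_hbo2, eps_mel, out)
    for k in range(6):
        out[k] = out[k] - measured[k]
    return out
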