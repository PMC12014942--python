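"""Accuracy harness for recovered parameter maps: region-wise MAPE with
absolute-error spread, whole-image SSIM, and method-versus-method reports."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .inversion import ParameterMaps
from .optics import InvalidInputError, PARAM_NAMES

__all__ = ["RegionSet", "mape", "ssim", "compare_methods", "SSIM_WIN_SIZE"]

#: SSIM window size used throughout (documented constant; data range is the
#: ground-truth max - min per map).
SSIM_WIN_SIZE = 7


@dataclass
class RegionSet:
    """Named boolean masks over the image grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise InvalidInputError("all region masks must share one shape")
        for name, m in self.masks.items():
            if not np.any(m):
                raise InvalidInputError(f"region {name!r} is empty")

    @classmethod
    def from_foreground(cls, fg_mask: np.ndarray) -> "RegionSet":
        return cls({"logo": fg_mask, "background": ~fg_mask,
                    "whole": np.ones_like(fg_mask, dtype=bool)})

    def __getitem__(self, name):
        return self.masks[name]

    def names(self):
        return list(self.masks)


def mape(pred, truth, mask=None) -> tuple[float, float]:
    """Mean absolute percentage error over a mask, plus the standard
    deviation of the absolute error in native units.

    Pixels with zero truth are excluded from the percentage mean (they make
    the relative error undefined) but still counted in the absolute-error
    spread.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    abs_err = np.abs(pred[mask] - truth[mask])
    t = truth[mask]
    nz = t != 0
    if not np.any(nz):
        raise InvalidInputError("truth is zero everywhere on the mask")
    pct = float(np.mean(abs_err[nz] / np.abs(t[nz])) * 100.0)
    return pct, float(abs_err.std())


def ssim(pred, truth) -> float:
    """Structural similarity index with a 7-pixel window and data range set
    by the ground truth (max - min)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise InvalidInputError("maps must share one shape")
    drange = float(truth.max() - truth.min())
    if drange == 0:
        drange = max(abs(float(truth.max())), 1e-12)
    return float(structural_similarity(truth, pred, win_size=SSIM_WIN_SIZE,
                                       data_range=drange))


def compare_methods(predictions: dict[str, ParameterMaps | np.ndarray],
                    truth: ParameterMaps | np.ndarray,
                    regions: RegionSet) -> pd.DataFrame:
    """Per-method x per-channel x per-region MAPE (and absolute-error STD)
    plus whole-image SSIM, as a tidy table.

    ``predictions`` maps method names (e.g. ``pixelwise``, ``psfdi``,
    ``net``) to recovered parameter maps.
    """
    t = truth.data if isinstance(truth, ParameterMaps) else np.asarray(truth)
    rows = []
    for method, pred in predictions.items():
        p = pred.data if isinstance(pred, ParameterMaps) else np.asarray(pred)
        if p.shape != t.shape:
            raise InvalidInputError(f"{method}: shape mismatch")
        for ci, ch in enumerate(PARAM_NAMES):
            for rname in regions.names():
                pct, std = mape(p[..., ci], t[..., ci], regions[rname])
                rows.append({"method": method, "channel": ch,
                             "region": rname, "metric": "mape_pct",
                             "value": pct, "abs_err_std": std})
            rows.append({"method": method, "channel": ch, "region": "whole",
                         "metric": "ssim",
                         "value": ssim(p[..., ci], t[..., ci]),
                         "abs_err_std": np.nan})
    return pd.DataFrame(rows)


def report_text(df: pd.DataFrame) -> str:
    """Human-readable pivot of a compare_methods table (MAPE with STD per
    region, SSIM on the whole image), with the SSIM constants in the
    header."""
    lines = [f"# SSIM: win_size={SSIM_WIN_SIZE}, data_range=truth max-min"]
    for metric in ("mape_pct", "ssim"):
        sub = df[df.metric == metric]
        piv = sub.pivot_table(index=["region", "method"], columns="channel",
                              values="value", sort=False)
        piv = piv.reindex(columns=list(PARAM_NAMES))
        lines.append(f"\n== {metric} ==")
        lines.append(piv.to_string(float_format=lambda v: f"{v:.3f}"))
    return "\n".join(lines)
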