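"""Evaluate inversion accuracy on a noisy digital phantom: MAPE per region
and SSIM per channel, comparing pixel-wise fitting with p-SFDI.

Run:  python examples/06_phantom_evaluation.py   (~1 min)
"""
import numpy as np

from sfdiskin import (AcquisitionGeometry, ChromophoreTable, FitConfig,
                      PhantomSpec, RegionSet, add_noise, compare_methods,
                      fit_image, psfdi_fit, render_phantom)
from sfdiskin.evaluation import report_text

geom = AcquisitionGeometry()
table = ChromophoreTable.default()

spec = PhantomSpec(n=16, mode="two_region", snr_db=50.0, seed=0)
truth, clean = render_phantom(spec, geom, table)
noisy = add_noise(clean, 50.0, seed=1)
noisy.data = np.clip(noisy.data, 1e-6, 1.5)

cfg = FitConfig(seed=1)
print("fitting (pixel-wise, then p-SFDI with k=20)...")
preds = {
    "pixelwise": fit_image(noisy, cfg, geom, table),
    "psfdi": psfdi_fit(noisy, 20, cfg, geom, table),
}
regions = RegionSet.from_foreground(spec.foreground_mask())
df = compare_methods(preds, truth, regions)
print(report_text(df))
print("\nMAPE rows: mean |error|/truth per region; SSIM rows: structural "
      "similarity\nof each channel map to the truth.  THb, StO2 and h are "
      "most noise-sensitive\nin per-pixel fitting because they are weakly "
      "constrained per pixel.")
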