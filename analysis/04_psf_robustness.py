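"""Partial-volume experiment: summed vs mean SBR under PSF widening.

Sweeps the PSF from 4 to 12 mm FWHM on a noise-free phantom with the
fixed 0.08 threshold-ROI procedure and records the brainstem summed SBR,
mean SBR and ROI size.  The summed measure should drift far less than the
mean, which is diluted as the same threshold admits a growing, fainter
ROI — the rationale for summing voxel SBRs in the first place.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import numpy as np
import pandas as pd

from sertquant import build_label_volume, default_phantom_spec, simulate_counts
from sertquant.io import write_table
from sertquant.pipeline import quantify_subject

TAU = 0.08


def main() -> None:
    rows = []
    for fwhm in (4.0, 6.0, 7.0, 8.0, 10.0, 12.0):
        spec = default_phantom_spec(psf_fwhm=fwhm)
        labels, masks = build_label_volume(spec)
        counts = simulate_counts(labels, spec, poisson=False)
        boundary = int(np.nonzero(masks["pons"])[2].max())
        m = quantify_subject(counts, masks, TAU, boundary)
        rows.append(
            {
                "psf_fwhm_mm": fwhm,
                "brainstem_summed_sbr": m["brainstem_summed_sbr"],
                "brainstem_mean_sbr": m["brainstem_mean_sbr"],
                "roi_voxels": m["brainstem_voxels"],
            }
        )
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    write_table(ROOT / "results" / "psf_robustness.csv", df.round(4))
    print(df.round(3).to_string(index=False))
    lo, hi = df.iloc[0], df.iloc[-1]
    rel = lambda c: abs(hi[c] - lo[c]) / lo[c] * 100
    print(f"4 -> 12 mm FWHM: summed SBR changes {rel('brainstem_summed_sbr'):.1f}% "
          f"vs mean SBR {rel('brainstem_mean_sbr'):.1f}% "
          "(summed voxel-based SBR is the more partial-volume-robust estimate)")


if __name__ == "__main__":
    main()
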