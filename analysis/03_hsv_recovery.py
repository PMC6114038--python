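"""Validate hypoxic-subvolume segmentation against the designed cores.

For 20 noise seeds at the default PET noise (sigma 0.05 SUV) this computes
the Dice coefficient between the segmented HSV-T and the true hypoxic core
at baseline, plus the volume error. Writes results/hsv_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from petmr_hypoxia.pet import segment_hsv
from petmr_hypoxia.phantom import PhantomSpec, design_week, synthesize_pet

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec = PhantomSpec()
    t2, s0, fmiso_true, _, masks = design_week(spec, 0)
    gtv, nt, core = masks["GTV-T"], masks["NT"], masks["hypoxic-truth-T"]
    rows = []
    for seed in range(20):
        img = synthesize_pet(fmiso_true, spec.pet_noise_sigma, seed=seed,
                             geometry=spec.grid)
        hsv = segment_hsv(img, gtv, nt, factor=spec.threshold_factor)
        dice = 2 * np.sum(hsv.mask & core.mask) / (hsv.n_voxels + core.n_voxels)
        rows.append({"seed": seed, "dice": dice,
                     "hsv_ml": hsv.volume_ml(), "true_ml": core.volume_ml()})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "hsv_recovery.csv", index=False, float_format="%.5f")
    print(df.describe().loc[["mean", "min", "max"]].to_string())
    print(f"\nminimum Dice over 20 seeds: {df.dice.min():.4f} (claim: > 0.9)")


if __name__ == "__main__":
    main()
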