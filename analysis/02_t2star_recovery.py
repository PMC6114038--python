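"""Characterize T2* estimation accuracy of the censored log-linear fit.

Sweeps first-echo SNR at the three tissue-range T2* values and writes
results/t2star_recovery.csv with the median absolute relative error, the
valid-voxel fraction and the median number of echoes surviving the 5x
noise-floor censoring.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from petmr_hypoxia.phantom import synthesize_multiecho
from petmr_hypoxia.relaxometry import compute_t2star_map, default_echo_times

OUT = Path(__file__).resolve().parents[1] / "results"
TE = default_echo_times()
S0 = 1000.0
N_VOXELS = 1500


def main() -> None:
    rng = np.random.default_rng(2)
    rows = []
    for snr in (20.0, 30.0, 50.0, 100.0):
        for t2 in (15.0, 18.0, 21.0):
            sigma = S0 * np.exp(-TE[0] / t2) / snr
            s = synthesize_multiecho(np.full((N_VOXELS, 1, 1), t2),
                                     np.full((N_VOXELS, 1, 1), S0), TE, sigma,
                                     seed=rng)
            m = compute_t2star_map(s, sigma)
            err = np.abs(m.t2star[m.valid] - t2) / t2
            rows.append({
                "first_echo_snr": snr, "t2star_ms": t2,
                "median_abs_rel_error": float(np.median(err)),
                "valid_fraction": float(m.valid.mean()),
                "median_echoes_used": float(np.median(m.n_echoes_used[m.valid])),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "t2star_recovery.csv", index=False, float_format="%.5f")
    print(df.to_string(index=False))
    ok = df[df.first_echo_snr >= 30]["median_abs_rel_error"].max()
    print(f"\nworst median error at SNR >= 30: {100 * ok:.2f}% "
          f"(precision claim: < 5%)")


if __name__ == "__main__":
    main()
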