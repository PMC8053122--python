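#!/usr/bin/env python
"""Confidence bands for a compactness (radius-of-gyration-like) density.

Generates a stationary correlated scalar trajectory mimicking a gyration
radius series (bimodal marginal: compact vs extended conformations,
integrated autocorrelation time 15 samples), estimates tau with the
self-consistent window, and computes the correlation-aware bootstrap 95%
band of its binned density.  Writes results/rg_density_band.csv and a
metadata JSON.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps

from dropletkd.bootstrap import RgSample, autocorrelation_time, bootstrap_pdf
from dropletkd.synth import make_correlated_samples

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 131
TAU_TRUTH = 15.0
N_POINTS = 50_000


class BimodalRg:
    """Two-component normal mixture in nm: compact (1.1) and extended (1.9)."""

    comps = (sps.norm(1.1, 0.12), sps.norm(1.9, 0.25))
    weights = (0.55, 0.45)

    def ppf(self, u):
        grid = np.linspace(0.5, 3.2, 4001)
        cdf = sum(w * c.cdf(grid) for w, c in zip(self.weights, self.comps))
        return np.interp(u, cdf, grid)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sample = make_correlated_samples(BimodalRg(), tau=TAU_TRUTH,
                                     n=N_POINTS, seed=SEED)
    tau_hat = autocorrelation_time(sample.values)
    print(f"integrated autocorrelation time: {tau_hat:.1f} samples "
          f"(generator truth {TAU_TRUTH:g})")
    ci = bootstrap_pdf(RgSample(sample.values, tau_hat), n_boot=2000,
                       seed=SEED + 1)
    pd.DataFrame({"bin_center_nm": ci.bin_centers, "p_hat": ci.p_hat,
                  "lo": ci.lo, "hi": ci.hi}).to_csv(
        OUT / "rg_density_band.csv", index=False)
    meta = {"tau": tau_hat, "n_boot": ci.n_boot, "n_per": ci.n_per,
            "seed": SEED, "n_points": N_POINTS}
    (OUT / "rg_density_band.meta.json").write_text(json.dumps(meta, indent=2))
    integral = float(np.sum(ci.p_hat * np.diff(ci.bin_edges)))
    width = float(np.mean(ci.hi - ci.lo))
    print(f"density integral {integral:.6f}; mean 95% band width "
          f"{width:.4f} /nm over {ci.p_hat.size} bins")


if __name__ == "__main__":
    main()
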