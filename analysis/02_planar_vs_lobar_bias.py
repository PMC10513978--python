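#!/usr/bin/env python
"""Quantify the planar template's lobar bias against the 3D methods.

Runs the same cohort as 01 through the imaging chain (5 mm FWHM blur,
Poisson noise at 5·10⁶ counts, attenuated anterior/posterior reprojection)
and quantifies each phantom with the planar equal-thirds template and with
3D lobar counting on exact ("automated") and fissure-perturbed ("manual")
label maps.

Writes results/method_bias.csv and prints the per-lobe mean signed error of
each method against ground truth.  The expected pattern: the planar method
inflates the right middle lobe by tens of points and deflates the right
superior/inferior lobes, while both 3D methods stay within ~1–2 points and
whole-lung estimates agree across all methods.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import vqlobes as vq
from vqlobes.distribution import REGION_NAMES

N_PHANTOMS = 20
SEED = 1


def main() -> int:
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    manual_model = vq.DEFAULT_OBSERVER_MODELS["manual_3d"]

    rows = []
    for j in range(N_PHANTOMS):
        phantom = vq.build_phantom(vq.sample_spec(rng))
        result = vq.quantify_phantom(
            phantom, "V", imaging_seed=1000 + j,
            manual_model=manual_model, manual_rng=2000 + j)
        truth = result.pop("truth")
        for method, dist in result.items():
            for region in REGION_NAMES:
                rows.append({
                    "phantom": j, "method": method, "region": region,
                    "estimate": dist.region(region),
                    "truth": truth.region(region),
                    "error": dist.region(region) - truth.region(region),
                })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "method_bias.csv", index=False)

    summary = (table.groupby(["method", "region"])["error"]
               .mean().unstack("region")[list(REGION_NAMES)].round(1))
    print(f"mean signed error vs truth (%), {N_PHANTOMS} phantoms, "
          "ventilation:")
    print(summary.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
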