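#!/usr/bin/env python
"""Build the phantom cohort and tabulate its ground-truth lobar anatomy.

Draws a cohort of digital thorax phantoms from the default population
ranges, rasterises them at the clinical SPECT grid (128³, 3.3 mm), and
writes the per-phantom ground-truth lobar fractions — the reference against
which both quantification methods are judged downstream.

Writes results/cohort_truth.csv and prints the cohort means: with the
default geometry the right-lobe volume shares sit near 39/18/43 % of the
right lung, i.e. a middle lobe far smaller than an axial third.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import vqlobes as vq

N_PHANTOMS = 20
SEED = 1


def main() -> None:
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    rows = []
    for j in range(N_PHANTOMS):
        phantom = vq.build_phantom(vq.sample_spec(rng))
        for tracer in ("V", "Q"):
            row = {"phantom": j, "tracer": tracer}
            row.update(vq.true_lobar_fractions(phantom, tracer).as_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cohort_truth.csv", index=False)

    means = table.query("tracer == 'V'").drop(columns=["phantom", "tracer"]).mean()
    print(f"cohort of {N_PHANTOMS} phantoms (seed {SEED}); "
          "ventilation truth means (%):")
    print(means.round(1).to_string())
    right = means[["RUL", "RML", "RLL"]]
    shares = (100 * right / right.sum()).round(1)
    print("right-lobe shares of the right lung (%):")
    print(shares.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
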