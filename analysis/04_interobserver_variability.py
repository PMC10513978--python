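#!/usr/bin/env python
"""Interobserver variability of the three quantification methods.

Three simulated readers re-quantify ten phantoms with each method; observer
disagreement enters only through geometry (planar template placement jitter,
manual fissure-tracing jitter; the automated segmentation is deterministic).
Reports the mean relative standard deviation (RSD, %) of each region's
estimate across readers, averaged over phantoms.

Expected pattern: automated RSD = 0 everywhere; planar RSD largest overall;
the manual method's largest lobe RSD falls on the right middle lobe, whose
bounding horizontal fissure is the least reproducible.  Writes
results/observer_rsd.csv.
"""

import sys
from pathlib import Path

import numpy as np

import vqlobes as vq
from vqlobes.observers import run_observer_study

N_PHANTOMS = 10
N_OBSERVERS = 3
SEED = 1


def main() -> int:
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    phantoms = [vq.build_phantom(vq.sample_spec(rng))
                for _ in range(N_PHANTOMS)]
    study = run_observer_study(phantoms, n_observers=N_OBSERVERS,
                               tracers=("V", "Q"), seed=SEED)
    study.summary.to_csv(out_dir / "observer_rsd.csv", index=False)

    for tracer in ("V", "Q"):
        view = (study.summary.query("tracer == @tracer")
                .pivot(index="region", columns="method", values="mean_rsd"))
        print(f"=== tracer {tracer}: mean interobserver RSD (%) over "
              f"{N_PHANTOMS} phantoms, {N_OBSERVERS} observers ===")
        print(view.round(1).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
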