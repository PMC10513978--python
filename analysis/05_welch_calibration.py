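#!/usr/bin/env python
"""Calibration of the Welch ANOVA under variance heterogeneity.

Null simulation: three groups of n=43 drawn from normals with a common mean
(25) and standard deviations 3, 5 and 8 — the heteroscedastic regime the
Welch correction targets.  Over 10,000 replicates the empirical type-I
error at α = 0.05 should sit at 5% within the binomial 3σ band
[4.1%, 5.9%].

Writes results/welch_calibration.json.
"""

import json
import sys
from pathlib import Path

from vqlobes.stats import welch_null_rejection_rate

SEED = 1


def main() -> int:
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)
    rate = welch_null_rejection_rate(
        n_replicates=10_000, group_sizes=(43, 43, 43), mean=25.0,
        sds=(3.0, 5.0, 8.0), alpha=0.05, seed=SEED)
    payload = {"n_replicates": 10_000, "alpha": 0.05,
               "empirical_type_I_percent": rate,
               "binomial_3sigma_band_percent": [4.1, 5.9]}
    (out_dir / "welch_calibration.json").write_text(
        json.dumps(payload, indent=1))
    print(f"empirical type-I error: {rate:.2f}% "
          f"(nominal 5%, 3σ band [4.1, 5.9])")
    return 0


if __name__ == "__main__":
    sys.exit(main())
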