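#!/usr/bin/env python
"""Region-wise Welch-ANOVA comparison of the three quantification methods.

Runs the full study driver (43 phantoms, both tracers, all three methods)
and writes the comparison tables: per region and tracer, each method's mean,
95% CI and range, plus the Welch heteroscedastic ANOVA p-value across
methods at α = 0.05.

Expected pattern: p ≪ 0.05 for the three right-lung lobes (the planar
template disagrees with both 3D methods there) and p ≫ 0.05 for the left
lobes and whole lungs.  Writes the full report bundle under
results/study/.
"""

import sys

import vqlobes as vq

SEED = 1


def main() -> int:
    config = vq.StudyConfig(n_phantoms=43, seed=SEED)
    result = vq.run_pipeline(config, out_dir="results/study")
    for tracer, table in result.comparisons.items():
        print(f"=== tracer {tracer}: Welch ANOVA across methods ===")
        view = (table.drop_duplicates("Region")
                [["Region", "F", "df1", "df2", "p", "significant"]])
        print(view.round(4).to_string(index=False))
        means = table.pivot(index="Region", columns="Method", values="Mean")
        print(means.round(1).to_string())
    print("report bundle written to results/study/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
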