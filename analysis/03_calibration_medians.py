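#!/usr/bin/env python
"""Monte-Carlo recovery of the published green-channel linearity.

Generates 500 measurement-level calibration tables per light source (the
published green line plus Gaussian residuals at the packaged noise level)
and reports the median fitted R^2 -- which reproduces the published values
0.9313 (Mini-LED), 0.8984 (halogen), 0.7809 (deuterium) to within ~0.01.

Output: results/calibration_medians.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bilistrip.calibration import fit_line
from bilistrip.synthetic import (
    LIGHT_SOURCES,
    default_concentration_series,
    generate_calibration_table,
    response_preset,
)

OUT = Path("results/calibration_medians.csv")
N = 500
SEED = 1


def main() -> None:
    concs = default_concentration_series()
    rows = []
    for light in LIGHT_SOURCES:
        preset = response_preset(light, "G")
        r2s = np.array([
            fit_line(generate_calibration_table(concs, preset,
                                                seed=SEED * 1000 + i), "G").r_squared
            for i in range(1, N + 1)])
        rows.append({"light_source": light,
                     "slope": preset.slope,
                     "intercept": preset.intercept,
                     "residual_sd": preset.residual_sd,
                     "median_r2": np.median(r2s),
                     "r2_q05": np.quantile(r2s, 0.05),
                     "r2_q95": np.quantile(r2s, 0.95),
                     "n_tables": N})
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.round(4).to_string(index=False))
    print(f"\nwritten to {OUT}")


if __name__ == "__main__":
    main()
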