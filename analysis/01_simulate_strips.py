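#!/usr/bin/env python
"""Generate the synthetic strip-image set that stands in for the study photos.

Renders 12 test-paper images per light source (D2 lamp, halogen lamp,
Mini-LED) over the 0.1-2.0 mg/dL calibration series, with strip-to-strip
common-mode variability and per-pixel sensor noise, and writes the manifest
the downstream analysis consumes.

Output: results/fixtures/*.png + *.json sidecars + manifest.csv
"""

from pathlib import Path

import pandas as pd

from bilistrip.pipeline import make_fixtures

OUT = Path("results/fixtures")
SEED = 1


def main() -> None:
    manifest_path = make_fixtures(OUT, seed=SEED)
    manifest = pd.read_csv(manifest_path)
    print(f"wrote {len(manifest)} strip images to {OUT}/ (seed {SEED})")
    print(manifest.groupby("light_source")["concentration_mg_dl"]
          .agg(["count", "min", "max"]))


if __name__ == "__main__":
    main()
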