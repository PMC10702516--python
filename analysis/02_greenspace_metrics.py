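"""Greenspace metrics (GVI, NDVI, ratio) at the point scale and five buffers.

Recreates the same city as 01_simulate_city.py, aggregates the metrics to
every spatial scale, and writes per-scale summary statistics and IQRs —
the exposure contrasts the effect estimates are expressed per — to
results/greenspace_iqr.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from greensar.greenspace import build_greenspace_table, compute_iqr
from greensar.synthetic_city import SyntheticCityConfig, generate_city

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    city = generate_city(SyntheticCityConfig(seed=SEED))
    gs = build_greenspace_table(city.points, city.gvi, city.ndvi, city.points)

    rows = []
    for scale, sub in gs.groupby("scale", sort=False):
        for m in ("gvi", "ndvi", "ratio"):
            v = sub[m].to_numpy()
            v = v[np.isfinite(v)]
            rows.append({"scale": scale, "metric": m, "mean": v.mean(),
                         "sd": v.std(ddof=1), "min": v.min(), "max": v.max(),
                         "iqr": compute_iqr(v)})
    out = pd.DataFrame(rows).round(4)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out.to_csv(results / "greenspace_iqr.csv", index=False)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    gs.to_csv(scratch / "greenspace_scales.csv", index=False)

    print(out.to_string(index=False))
    print("\nnote how buffer averaging shrinks the exposure contrast (IQR) "
          "as the radius grows")


if __name__ == "__main__":
    main()
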