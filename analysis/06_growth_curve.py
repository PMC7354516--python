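#!/usr/bin/env python
"""One-step growth-curve analysis of the bundled synthetic YerA41-shaped curve.

Normalizes both titer series to the 0-min untreated value (the number of
infected cells) and reads off the eclipse, latent and rise periods and the
burst size. Writes results/tables/growth_params.json.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from phagesub.datasets import YERA41_GROWTH_CURVE
from phagesub.growth import GrowthCurve, normalize_curve, estimate_params

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pfu-table", type=Path, default=None,
                    help="optional TSV (time_min, pfu_untreated[, pfu_chloroform])")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if args.pfu_table:
        import pandas as pd
        df = pd.read_csv(args.pfu_table, sep="\t")
        curve = GrowthCurve(df["time_min"].astype(float).tolist(),
                            df["pfu_untreated"].astype(float).tolist(),
                            df["pfu_chloroform"].astype(float).tolist()
                            if "pfu_chloroform" in df else None)
    else:
        d = YERA41_GROWTH_CURVE
        curve = GrowthCurve(list(d["time_min"]), list(d["pfu_untreated"]),
                            list(d["pfu_chloroform"]))
    params = estimate_params(normalize_curve(curve))
    out = asdict(params)
    with open(args.outdir / "growth_params.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
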