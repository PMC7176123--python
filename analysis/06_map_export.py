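"""Join model-B spatial odds onto district polygons for choropleth mapping.

Builds a simple lattice GeoJSON matching the simulated geography (one unit
square per district) and annotates each polygon with the posterior median
spatial odds and exceedance probability per condition.
"""

import json
from pathlib import Path

import pandas as pd

from cvdmap.diagnostics import export_map_layer

FIT = Path(__file__).resolve().parent.parent / "results" / "fit"
OUT = Path(__file__).resolve().parent.parent / "results" / "maps"


def lattice_geojson(codes, cols=8):
    feats = []
    for i, code in enumerate(codes):
        r, c = divmod(i, cols)
        ring = [[c, -r], [c + 1, -r], [c + 1, -r - 1], [c, -r - 1], [c, -r]]
        feats.append({"type": "Feature", "properties": {"id": code},
                      "geometry": {"type": "Polygon", "coordinates": [ring]}})
    return {"type": "FeatureCollection", "features": feats}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    odds = pd.read_csv(FIT / "spatial_odds_model_B.csv")
    odds["code"] = odds["code"].astype(str)
    codes = odds["code"].unique()
    base = OUT / "districts.geojson"
    base.write_text(json.dumps(lattice_geojson(codes)))
    for disease, sub in odds.groupby("disease"):
        out = OUT / f"spatial_odds_{disease}.geojson"
        export_map_layer(
            sub[["code", "odds_median", "odds_low", "odds_high", "exceedance_prob"]],
            base, out,
        )
        print(f"{disease}: wrote {out.name} "
              f"(median odds {sub['odds_median'].min():.2f}-{sub['odds_median'].max():.2f})")


if __name__ == "__main__":
    main()
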