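"""Delineate seasonal ranges from the occurrence records.

Reads the occurrence table and land polygon from the input bundle, builds a
dynamic alpha hull per season (95% inclusion, 50-km point buffer, clipped to
land), derives the year-round overlap and season-only remainders, and writes
results/seasonal_ranges.geojson plus an area table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape
import shapely

from isomove import AlbersEqualArea, PipelineConfig, seasonal_ranges
from isomove.ranges import read_occurrences_csv, write_ranges_geojson

ROOT = Path(__file__).resolve().parents[1]


def project_geojson_feature(path: Path, albers: AlbersEqualArea):
    geom = shape(json.loads(path.read_text())["geometry"])

    def _tx(coords):
        arr = np.asarray(coords)
        x, y = albers.forward(arr[:, 0], arr[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(shapely.segmentize(geom, 0.25), _tx)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.data / "config.yaml")
    albers = AlbersEqualArea(cfg.albers_lat1, cfg.albers_lat2, cfg.albers_lat0, cfg.albers_lon0)
    records = read_occurrences_csv(args.data / "occurrences.csv")
    land = project_geojson_feature(args.data / "land.geojson", albers)

    ranges = seasonal_ranges(records, cfg, land=land, albers=albers)
    args.out.mkdir(parents=True, exist_ok=True)
    write_ranges_geojson(ranges, args.out / "seasonal_ranges.geojson")
    areas = pd.Series(ranges.areas_km2, name="area_km2").round(0)
    areas.to_csv(args.out / "range_areas.csv", header=True, index_label="region")

    print(f"{len(records)} occurrence records")
    for season, hull in ranges.hulls.items():
        print(
            f"  {season:14s} alpha {hull.alpha_km if np.isfinite(hull.alpha_km) else 'hull':>8} km, "
            f"inclusion {hull.inclusion:.3f}, area {ranges.areas_km2[f'{season}_hull']:,.0f} km2"
        )
    print(f"year-round (summer ∩ winter): {ranges.areas_km2['year_round']:,.0f} km2")
    print(f"autumn-only: {ranges.areas_km2['autumn_only']:,.0f} km2")
    print(
        f"winter-only: {ranges.areas_km2['winter_only']:,.0f} km2 "
        f"({ranges.notes['winter_only']})"
    )
    print(f"wrote {args.out / 'seasonal_ranges.geojson'} and range_areas.csv")


if __name__ == "__main__":
    main()
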