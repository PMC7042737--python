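"""Generate the synthetic study scene every later stage consumes.

Writes the understory field, forest mask, settlements, LiDAR point cloud,
breeding table and ground-truth record under scratch/scene/ (large rasters and the
point cloud are working artifacts, not reported tables).  The scene
mimics the study conditions: a 12.5 m grid, an understory field with mean
~13% and SD ~6%, sparse settlements, and breeding outcomes drawn from the
published coefficient set with year/breeder random intercepts.
"""

import json
from pathlib import Path

import numpy as np

from understory_hsm import RunConfig, Raster, io, synth

OUT = Path(__file__).resolve().parents[1] / "scratch" / "scene"
SEED = 20201450
EXTENT = (5000.0, 5000.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=SEED)
    scene = synth.generate_landscape(EXTENT, cfg, seed=SEED, settlement_intensity=0.4)
    pts = synth.generate_point_cloud(
        scene.understory, scene.forest_mask, pulse_density=0.5, seed=SEED
    )
    nests = synth.generate_nests(
        scene, n_nests=900, n_years=16, seed=SEED, n_renest=5, n_treated=11
    )

    io.write_raster(scene.understory, OUT / "understory_truth.asc")
    io.write_raster(
        Raster(scene.forest_mask.astype(float), scene.spec), OUT / "forest_mask.asc"
    )
    io.write_points_geojson(scene.settlements, OUT / "settlements.geojson")
    io.write_point_cloud(pts, OUT / "points.xyz")
    io.write_nest_table(nests, OUT / "nests.csv")
    truth = {
        "glmm": scene.glmm_truth,
        "jay": list(scene.jay_truth),
        "breakpoint_m": scene.true_breakpoint,
        "managed_split_x": scene.managed_split_x,
        "seed": SEED,
        "extent_m": list(EXTENT),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))

    print(f"scene written to {OUT}")
    print(f"  {len(pts):,} LiDAR returns at 0.5 pts/m^2")
    print(f"  {len(scene.settlements)} settlements, {len(nests)} breeding events")
    print(f"  understory field mean {scene.understory.values.mean():.1f}%")


if __name__ == "__main__":
    main()
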