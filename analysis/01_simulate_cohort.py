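#!/usr/bin/env python
"""Simulate a cohort of synthetic nuclei with two chromatin organisations.

Two groups of four nuclei each emulate the qualitative contrast between
euchromatin-like and heterochromatin-like blink patterns:

* ``dispersed``  — clutches scattered around many weakly clustered sites
  (aggregation radius 1200 nm), emulating the punctate, homogeneous pattern
  of an active mark;
* ``aggregated`` — the same clutch budget packed around few tight sites
  (aggregation radius 100 nm), emulating condensed heterochromatin domains
  whose clutches chain into large aggregates.

Each nucleus is a frame-stamped localisation table (20 frames) at a raw
global density of ~0.0012 blinks/nm², slightly above the 0.001 blinks/nm²
homogenisation target so the density homogenisation stage has frames to trim.
Raw tables are large and therefore written under scratch/cohort/ together
with the pipeline config; downstream scripts consume them from there.
"""

from pathlib import Path

import numpy as np
import yaml

import clutchmap as cm

OUT = Path("scratch/cohort")
RAW_DENSITY = 0.0012           # pre-homogenisation blink density (blinks/nm^2)
BLINKS_PER_CLUTCH = 30
BACKGROUND_FRACTION = 0.30
GROUPS = {"dispersed": 1200.0, "aggregated": 100.0}  # aggregation radius (nm)
N_PER_GROUP = 4
N_FRAMES = 20


def simulate_nucleus(nucleus_id: str, agg_radius: float, seed: int) -> dict:
    roi = cm.make_nucleus(
        cm.NucleusShapeSpec(base_radius=1600, irregularity=0.25, n_vertices=64, seed=seed)
    )
    n_blinks = RAW_DENSITY * roi.area
    n_clutches = int(round(n_blinks * (1 - BACKGROUND_FRACTION) / BLINKS_PER_CLUTCH))
    spec = cm.ClutchPatternSpec(
        n_clutches=n_clutches,
        clutch_radius=40.0,
        blinks_per_clutch=BLINKS_PER_CLUTCH,
        background_fraction=BACKGROUND_FRACTION,
        aggregation_radius=agg_radius,
        seed=seed + 1,
    )
    blinks, _ = cm.sample_clutch_pattern(roi, spec)
    table = cm.stamp_frames(blinks, n_frames=N_FRAMES, seed=seed + 2)
    loc_path = OUT / f"{nucleus_id}.csv"
    roi_path = OUT / f"{nucleus_id}_roi.csv"
    cm.write_localisations(table, loc_path)
    cm.write_roi_csv(roi, roi_path)
    print(
        f"  {nucleus_id}: area {roi.area/1e6:.2f} um^2, {n_clutches} clutches, "
        f"{len(blinks)} blinks"
    )
    return {
        "nucleus_id": nucleus_id,
        "localisations": str(loc_path),
        "roi": str(roi_path),
        "group": nucleus_id.rsplit("_", 1)[0],
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    seed = 100
    for group, agg_radius in GROUPS.items():
        print(f"group {group} (aggregation radius {agg_radius:.0f} nm):")
        for i in range(N_PER_GROUP):
            manifest.append(simulate_nucleus(f"{group}_{i+1}", agg_radius, seed))
            seed += 10
    config = {"manifest": manifest, "seed": 0}
    (OUT / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    print(f"\nwrote {len(manifest)} nuclei and config -> {OUT}/config.yaml")


if __name__ == "__main__":
    main()
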