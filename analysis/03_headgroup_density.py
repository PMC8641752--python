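#!/usr/bin/env python
"""Headgroup occupancy grids for the WT and quad-mutant patches.

Exports VMD-compatible OpenDX volumes, the midplane cross-section slab (the
density-cloud view through the membrane core) and the voxel counts above a
50% occupancy isolevel.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from derlintools.density import density_grid, grid_slab, threshold_mask, write_opendx
from derlintools.structio import select_headgroups
from derlintools.synthetic import build_bilayer_spec, generate_trajectory

OUT = Path(__file__).resolve().parents[1] / "results" / "density"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--voxel-size", type=float, default=0.1)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    summary = {}
    for preset in ("DFM1_WT", "DFM1_QUAD"):
        spec = build_bilayer_spec(preset)
        traj = generate_trajectory(spec, args.seed)
        sel = select_headgroups(traj.frames[0])
        grid = density_grid(traj, sel.indices, voxel_size=args.voxel_size)
        stem = preset.lower()
        write_opendx(grid, OUT / f"{stem}.dx")
        grid.nonzero_to_csv(OUT / f"{stem}_nonzero.csv")

        # membrane-core slab: |z - midplane| <= 1.2 nm; headgroups only enter
        # it where thinning pulls the leaflet surfaces inward
        mid_z = float(np.mean(grid.voxel_centers(2)))
        slab = grid_slab(grid, "z", mid_z, 2.4)
        pd.DataFrame(slab).to_csv(OUT / f"{stem}_core_slab.csv", index=False)
        mask = threshold_mask(grid, 0.5)
        summary[preset] = {
            "n_headgroups": int(len(sel)),
            "grid_shape": list(grid.shape),
            "core_slab_counts": int(slab.sum()),
            "voxels_above_iso_0.5": mask.n_voxels,
        }
        print(
            f"{preset:10s} membrane-core headgroup count={slab.sum():6d} "
            f"(thinning pulls headgroups into the core)"
        )
    with open(OUT / "density_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"\nwrote OpenDX volumes and slabs under {OUT}")


if __name__ == "__main__":
    main()
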