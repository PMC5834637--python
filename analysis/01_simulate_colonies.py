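#!/usr/bin/env python
"""Simulate a study island and characterise its spatial structure.

Generates one synthetic island — clustered sub-colonies with hard-core
nest spacing plus a sparse, spatially random artifact field — renders the
orthomosaic, and summarises the nearest-neighbour distance distributions
that the downstream spatial filter relies on.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import pengcensus as pc
from pengcensus import io as pio
from pengcensus.evaluation import make_study_island


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    layout, ortho, artifacts = make_study_island(args.seed)
    pio.write_layout_csv(args.out / "island_truth.csv", layout, artifacts)
    pio.write_raster(args.out / "island.tif", ortho)

    nest_nn = pc.nn_distances(layout.nests)
    art_nn = pc.nn_distances(artifacts)
    summary = pd.DataFrame({
        "class": ["nest", "artifact"],
        "n": [layout.n_nests, len(artifacts)],
        "nn_median_m": [np.median(nest_nn), np.median(art_nn)],
        "nn_q10_m": [np.percentile(nest_nn, 10), np.percentile(art_nn, 10)],
        "nn_q90_m": [np.percentile(nest_nn, 90), np.percentile(art_nn, 90)],
    })
    summary.to_csv(args.out / "nn_distance_summary.csv", index=False)

    print(f"island: {layout.n_nests} nests in "
          f"{len(np.unique(layout.subcolony_id))} sub-colonies, "
          f"{len(artifacts)} artifacts; min nest spacing "
          f"{layout.min_pairwise_distance():.2f} m")
    print(summary.to_string(index=False))
    print("Nest NN distances sit an order of magnitude below the artifact "
          "NN distances — the separation the spatial filter exploits.")


if __name__ == "__main__":
    main()
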