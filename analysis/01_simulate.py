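#!/usr/bin/env python
"""Generate the ground-truth validation movie and a basal-concentration series.

Writes the two-channel TIFF stacks to scratch/ (large, binary) and the
planted-event ground truth (JSON parameters + analytic feature CSV) to
results/simulation/.
"""

import argparse
from pathlib import Path

from astroca.io import write_ground_truth, write_movie
from astroca.scenarios import basal_movie, validation_movie

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    movie, geom, gt, hill = validation_movie(seed=args.seed)
    paths = write_movie(movie, ROOT / "scratch" / "simulation", stem="validation")
    truth = write_ground_truth(gt, ROOT / "results" / "simulation")
    print(f"validation movie: {movie.green.shape} at {1/movie.frame_interval:g} fps, "
          f"{geom.n_cells} cells, {len(gt.events)} planted events")
    print(f"  stacks -> {paths['green']}, {paths['red']}")
    print(f"  ground truth -> {truth['features']}")
    print(gt.true_features[["event_id", "max_size", "duration", "distance",
                            "max_slope", "peak_dff"]].round(3).to_string(index=False))

    for b in (0.0, 50.0, 55.0):
        m, g, h = basal_movie(b, seed=args.seed)
        write_movie(m, ROOT / "scratch" / "simulation", stem=f"basal_{b:g}nM")
    print("basal series (0/50/55 nM) written to scratch/simulation/")


if __name__ == "__main__":
    main()
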