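"""Disk formats: TIFF stacks, ground-truth JSON/CSV, event and histogram tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .feature_stats import FeatureHistogram
from .ratiometric import TwoChannelMovie
from .synthetic import GroundTruth

__all__ = [
    "write_movie",
    "read_movie",
    "write_ground_truth",
    "write_event_table",
    "write_histogram",
]


def write_movie(movie: TwoChannelMovie, out_dir: str | Path, stem: str = "movie") -> dict:
    """Write one multi-page TIFF per channel plus a JSON calibration sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "green": out / f"{stem}_green.tif",
        "red": out / f"{stem}_red.tif",
        "meta": out / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["green"], movie.green, photometric="minisblack")
    tifffile.imwrite(paths["red"], movie.red, photometric="minisblack")
    paths["meta"].write_text(
        json.dumps(
            {"pixel_size_um": movie.pixel_size, "frame_interval_s": movie.frame_interval},
            indent=2,
        )
    )
    return {k: str(v) for k, v in paths.items()}


def read_movie(out_dir: str | Path, stem: str = "movie") -> TwoChannelMovie:
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}_meta.json").read_text())
    return TwoChannelMovie(
        green=tifffile.imread(out / f"{stem}_green.tif"),
        red=tifffile.imread(out / f"{stem}_red.tif"),
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
    )


def write_ground_truth(gt: GroundTruth, out_dir: str | Path, stem: str = "truth") -> dict:
    """Planted-event parameters as JSON, analytic features as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = [
        {
            "cell_id": ev.cell_id,
            "onset_frame": ev.onset_frame,
            "offset_frame": ev.offset_frame,
            "peak_ca_nM": ev.peak_ca,
            "rise_frames": ev.rise_frames,
            "decay_tau_s": ev.decay_tau,
            "footprint_px": [len(fp) for fp in ev.footprints],
        }
        for ev in gt.events
    ]
    jpath = out / f"{stem}_events.json"
    cpath = out / f"{stem}_features.csv"
    jpath.write_text(json.dumps(meta, indent=2))
    gt.true_features.to_csv(cpath, index=False)
    return {"events": str(jpath), "features": str(cpath)}


def write_event_table(table, out_dir: str | Path) -> str:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"events_{table.recording_id}.csv"
    table.to_dataframe().to_csv(path, index=False)
    return str(path)


def write_histogram(hist: FeatureHistogram, out_dir: str | Path, group: str) -> dict:
    """CSV matrix (levels x bins) plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"hist_{group}_{hist.feature}"
    cpath = out / f"{stem}.csv"
    pd.DataFrame(
        hist.freq,
        index=[f"L{lv:g}" for lv in hist.levels],
        columns=[f"b{i:02d}" for i in range(hist.freq.shape[1])],
    ).to_csv(cpath)
    jpath = out / f"{stem}.json"
    jpath.write_text(
        json.dumps(
            {
                "feature": hist.feature,
                "levels": list(hist.levels),
                "bin_edges": np.asarray(hist.bin_edges).tolist(),
            },
            indent=2,
        )
    )
    return {"csv": str(cpath), "meta": str(jpath)}
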