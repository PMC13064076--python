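"""Multi-threshold event detection (MTED).

Ca2+ events are segmented independently at each level of a ladder of
dF/F_R thresholds: the movie is binarized at the level, spatiotemporal
connected components are labeled (26-neighborhood in x, y, t by default),
tiny components are discarded, and four features are computed per event:

* max_size — peak instantaneous suprathreshold area, um^2;
* duration — (last - first + 1) frames x frame interval, s;
* distance — maximum displacement of the intensity-weighted event centroid
  from its position on the first frame, um (not total path length);
* max_slope — maximal consecutive-frame increase of the footprint-mean
  dF/F_R, 1/s (footprint mean rather than single-pixel max, for robustness).

Events are analyzed over the complete cell, with no subcellular
compartment assignment; per-cell frequencies divide by the supplied cell
count (cell counting is input metadata, not automated segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .ratiometric import DffMovie

__all__ = [
    "DEFAULT_LADDER",
    "ThresholdLadder",
    "CaEvent",
    "EventTable",
    "detect_events",
    "event_features",
    "threshold_profile",
]

#: Default dF/F_R threshold ladder spanning 0.5-20 and including the
#: levels singled out for per-level analyses (2, 5, 10).
DEFAULT_LADDER = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0)

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: np.ones((3, 3, 3), dtype=bool),
}


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly increasing dF/F_R levels at which events are segmented."""

    levels: tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if len(lv) == 0:
            raise ValueError("ladder must contain at least one level")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("ladder levels must be strictly increasing")
        if lv[0] <= 0:
            raise ValueError("ladder levels must be positive")
        object.__setattr__(self, "levels", lv)


@dataclass
class CaEvent:
    """One spatiotemporal Ca2+ event at a given threshold level."""

    event_id: int
    threshold: float
    first_frame: int
    last_frame: int
    max_size: float
    duration: float
    distance: float
    max_slope: float
    n_voxels: int
    single_frame: bool = False


@dataclass
class EventTable:
    """All events of one recording, grouped by threshold level."""

    recording_id: str
    condition: str
    n_cells: int
    duration_recorded: float
    pixel_size: float
    frame_interval: float
    n_frames: int
    events: list[CaEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for ev in self.events:
            if ev.first_frame < 0 or ev.last_frame >= self.n_frames:
                raise ValueError("event frame span outside the recording")

    def at_level(self, level: float) -> list[CaEvent]:
        return [ev for ev in self.events if ev.threshold == level]

    def levels(self) -> list[float]:
        return sorted({ev.threshold for ev in self.events})

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "event_id", "threshold", "first_frame", "last_frame",
            "max_size", "duration", "distance", "max_slope",
            "n_voxels", "single_frame",
        ]
        df = pd.DataFrame([vars(ev) for ev in self.events], columns=cols)
        df.insert(0, "recording_id", self.recording_id)
        df.insert(1, "condition", self.condition)
        df.insert(2, "n_cells", self.n_cells)
        return df


def event_features(
    component: np.ndarray,
    dff: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    threshold: float,
    frame_offset: int = 0,
    event_id: int = 0,
) -> CaEvent:
    """Feature extraction for one labeled voxel set.

    ``component`` is a boolean (T', H', W') array (a crop is fine as long as
    ``dff`` is cropped identically and ``frame_offset`` maps crop frame 0 to
    the recording frame index).  A single-frame component has no defined
    slope; it is reported as 0 and flagged.
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("component is empty")
    frames = np.where(component.any(axis=(1, 2)))[0]
    first, last = int(frames[0]), int(frames[-1])

    max_area = 0
    centroids = []
    means = []
    for f in range(first, last + 1):
        m = component[f]
        k = int(m.sum())
        if k == 0:
            # 26-connectivity guarantees contiguous frames, but guard anyway
            centroids.append(centroids[-1])
            means.append(means[-1])
            continue
        max_area = max(max_area, k)
        vals = dff[f][m]
        w = vals.sum()
        rr, cc = np.nonzero(m)
        if w > 0:
            centroids.append(np.array([(rr * vals).sum() / w, (cc * vals).sum() / w]))
        else:
            centroids.append(np.array([rr.mean(), cc.mean()]))
        means.append(float(vals.mean()))

    centroids = np.asarray(centroids)
    disp = float(np.linalg.norm(centroids - centroids[0], axis=1).max()) * pixel_size
    single = last == first
    slope = 0.0 if single else float(np.diff(means).max() / frame_interval)
    return CaEvent(
        event_id=event_id,
        threshold=float(threshold),
        first_frame=first + frame_offset,
        last_frame=last + frame_offset,
        max_size=float(max_area) * pixel_size**2,
        duration=(last - first + 1) * frame_interval,
        distance=disp,
        max_slope=slope,
        n_voxels=int(component.sum()),
        single_frame=single,
    )


def detect_events(
    dff: DffMovie,
    ladder: ThresholdLadder | None = None,
    min_area: int = 4,
    min_frames: int = 2,
    connectivity: int = 26,
    n_cells: int = 1,
    recording_id: str = "rec",
    condition: str = "Ctrl",
) -> EventTable:
    """Segment and measure events at every level of the threshold ladder.

    At each level the movie is binarized at ``dff >= level`` within the valid
    mask, components are labeled under the requested (x, y, t) connectivity,
    and components that never reach ``min_area`` pixels in a single frame or
    span fewer than ``min_frames`` frames are discarded as noise.
    """
    if ladder is None:
        ladder = ThresholdLadder()
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = _STRUCTURES[connectivity]

    table = EventTable(
        recording_id=recording_id,
        condition=condition,
        n_cells=n_cells,
        duration_recorded=dff.duration,
        pixel_size=dff.pixel_size,
        frame_interval=dff.frame_interval,
        n_frames=dff.n_frames,
    )
    if not dff.mask.any():
        import logging

        logging.getLogger(__name__).warning("detect_events: empty analysis mask")
        return table

    # NaNs outside the mask must binarize to False at every level
    filled = np.where(dff.mask[None, :, :], dff.dff, -np.inf)
    eid = 0
    for level in ladder.levels:
        binary = filled >= level
        labels, n = ndi.label(binary, structure=structure)
        if n == 0:
            continue
        for idx, sl in enumerate(ndi.find_objects(labels), start=1):
            comp = labels[sl] == idx
            n_fr = sl[0].stop - sl[0].start
            if n_fr < min_frames:
                continue
            if int(comp.sum(axis=(1, 2)).max()) < min_area:
                continue
            ev = event_features(
                comp,
                dff.dff[sl],
                dff.pixel_size,
                dff.frame_interval,
                threshold=level,
                frame_offset=sl[0].start,
                event_id=eid,
            )
            table.events.append(ev)
            eid += 1
    return table


def threshold_profile(table: EventTable, ladder: ThresholdLadder | None = None) -> pd.DataFrame:
    """Per-level event counts (scaled per cell) and feature summaries."""
    if ladder is None:
        ladder = ThresholdLadder()
    rows = []
    for level in ladder.levels:
        evs = table.at_level(level)
        n = len(evs)
        row = dict(
            threshold=level,
            n_events=n,
            events_per_cell=n / table.n_cells,
        )
        for feat in ("max_size", "duration", "distance", "max_slope"):
            vals = np.array([getattr(e, feat) for e in evs])
            for q, tag in ((0.25, "q25"), (0.5, "median"), (0.75, "q75")):
                row[f"{feat}_{tag}"] = float(np.quantile(vals, q)) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
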