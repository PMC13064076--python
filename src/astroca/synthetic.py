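"""Synthetic two-channel astrocyte movies with known ground truth.

Every downstream stage (normalization, event detection, volume-fraction
analysis, decomposition) is validated against movies whose morphology,
kinetics and rendering are fully specified here, so the analytic feature
values of each planted event are available as an oracle.

Morphology: each cell is a soma disc (relative occupied volume vf = 1)
with radiating thin processes whose vf decays linearly from 0.6 at the
soma edge to 0.05 at the tip.  This guarantees pixels across the full
volume-fraction range, including the <= 12.5 % peripheral band used for
basal-Ca2+ analysis.

Kinetics: a planted event rises linearly to its peak concentration over
``rise_frames`` frames, then decays exponentially (time constant
``decay_tau``) back toward basal; outside the event window concentration
is exactly basal.

Rendering: with 1:1 GCaMP6s/tdTomato stoichiometry, both channels are
proportional to per-pixel expression (gain x vf); the green channel is
additionally modulated by the Hill brightness B(ca).  Optional spectral
crosstalk and Poisson/Gaussian noise complete the forward model; the
noiseless render is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import HillParams, brightness, dff_of_ca
from .ratiometric import MixingMatrix, TwoChannelMovie

__all__ = [
    "VolumeMap",
    "PlantedEvent",
    "GroundTruth",
    "NoiseModel",
    "make_cell_geometry",
    "square_event",
    "event_ca_trace",
    "simulate_calcium",
    "render_fluorescence",
]


@dataclass
class VolumeMap:
    """Per-pixel relative occupied volume and cell labels.

    ``vf`` is in [0, 1] with 1 at the thickest soma; ``cell_labels`` is 0 on
    background and the (1-based) cell id elsewhere.  Soma centers/radii are
    kept so event footprints can be placed inside cells programmatically.
    """

    vf: np.ndarray
    cell_labels: np.ndarray
    pixel_size: float
    soma_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    soma_radius_px: float = 0.0

    def __post_init__(self) -> None:
        if self.vf.shape != self.cell_labels.shape:
            raise ValueError("vf and cell_labels must share shape")
        if np.any((self.vf < 0) | (self.vf > 1)):
            raise ValueError("vf must lie in [0, 1]")
        if np.any((self.vf == 0) != (self.cell_labels == 0)):
            raise ValueError("vf must be 0 exactly on background")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.cell_labels[self.cell_labels > 0])))


@dataclass
class PlantedEvent:
    """A fully specified Ca2+ event: per-frame footprints and kinetics.

    ``footprints`` holds one (k, 2) integer (row, col) pixel array per frame
    of the window [onset_frame, offset_frame].  Concentration is uniform
    across the footprint at any frame.
    """

    cell_id: int
    onset_frame: int
    offset_frame: int
    peak_ca: float
    footprints: list[np.ndarray]
    rise_frames: int = 2
    decay_tau: float = 1.5

    def __post_init__(self) -> None:
        if self.onset_frame > self.offset_frame:
            raise ValueError("onset_frame must be <= offset_frame")
        if len(self.footprints) != self.n_frames:
            raise ValueError("need one footprint per frame of the event window")
        if any(len(fp) == 0 for fp in self.footprints):
            raise ValueError("footprints must be nonempty on every frame")
        if self.rise_frames < 1:
            raise ValueError("rise_frames must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1

    def center_path(self, pixel_size: float) -> np.ndarray:
        """Per-frame footprint centroid in micrometers, (n_frames, 2)."""
        return np.array([fp.mean(axis=0) for fp in self.footprints]) * pixel_size

    def rise_rate(self, basal_ca: float, frame_interval: float) -> float:
        """Mean concentration slope of the rise phase, nM/s."""
        return (self.peak_ca - basal_ca) / (self.rise_frames * frame_interval)


@dataclass
class GroundTruth:
    """Planted events plus their analytic feature values.

    ``true_features`` has one row per event: max_size (um^2), duration (s),
    distance (um, max centroid displacement from the first frame) and
    max_slope (1/s, largest consecutive-frame increase of the footprint-mean
    dF/F_R inside the event window).
    """

    events: list[PlantedEvent]
    true_features: pd.DataFrame


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: Poisson on photon-scaled intensities, then Gaussian.

    ``photons_per_unit`` converts fluorescence units to expected photon
    counts; ``read_sigma`` is the camera read noise in fluorescence units.
    """

    photons_per_unit: float = 1.0
    read_sigma: float = 0.0


def make_cell_geometry(
    n_cells: int,
    fov: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    seed: int = 0,
    soma_radius: float = 6.0,
    n_processes: int = 6,
    process_length: tuple[float, float] = (15.0, 35.0),
    process_vf: tuple[float, float] = (0.6, 0.05),
    max_tries: int = 5000,
) -> VolumeMap:
    """Place non-overlapping soma discs with radiating processes.

    ``soma_radius`` and ``process_length`` are in micrometers.  Somata are
    placed by rejection sampling with a separation of at least two soma
    diameters; a placement error is raised when the field of view cannot
    accommodate ``n_cells``.  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = fov
    r_px = soma_radius / pixel_size
    margin = int(np.ceil(r_px)) + 2
    if 2 * margin >= min(h, w):
        raise ValueError(f"fov {fov} too small for soma radius {soma_radius} um")

    centers: list[tuple[float, float]] = []
    min_sep = 4.0 * r_px
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_cells} non-overlapping somata in fov {fov}"
            )
        tries += 1
        # integer soma centers keep footprint-in-cell reasoning exact
        c = (
            float(round(rng.uniform(margin, h - margin))),
            float(round(rng.uniform(margin, w - margin))),
        )
        if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= min_sep for o in centers):
            centers.append(c)

    vf = np.zeros(fov, dtype=np.float64)
    labels = np.zeros(fov, dtype=np.int32)
    rows, cols = np.ogrid[:h, :w]
    for cid, (cy, cx) in enumerate(centers, start=1):
        soma = (rows - cy) ** 2 + (cols - cx) ** 2 <= r_px**2
        vf[soma] = 1.0
        labels[soma] = cid
        # thin processes: 1-px random walks outward with linearly decaying vf
        v0, v1 = process_vf
        for j in range(n_processes):
            ang = 2 * np.pi * (j + rng.uniform(-0.25, 0.25)) / n_processes
            length_px = rng.uniform(*process_length) / pixel_size
            n_steps = max(int(length_px), 2)
            y, x = cy + r_px * np.sin(ang), cx + r_px * np.cos(ang)
            for s in range(n_steps):
                ang += rng.normal(0.0, 0.08)
                y += np.sin(ang)
                x += np.cos(ang)
                r, c = int(round(y)), int(round(x))
                if not (0 <= r < h and 0 <= c < w):
                    break
                if labels[r, c] not in (0, cid):
                    break
                val = v0 + (v1 - v0) * s / (n_steps - 1)
                if labels[r, c] == 0 or vf[r, c] < val:
                    vf[r, c] = max(vf[r, c], val)
                labels[r, c] = cid
    return VolumeMap(
        vf=vf,
        cell_labels=labels,
        pixel_size=pixel_size,
        soma_centers=np.asarray(centers),
        soma_radius_px=r_px,
    )


def square_event(
    cell_id: int,
    center: tuple[int, int],
    half_width: int,
    onset_frame: int,
    n_frames: int,
    peak_ca: float,
    rise_frames: int = 2,
    decay_tau: float = 1.5,
    velocity: tuple[float, float] = (0.0, 0.0),
) -> PlantedEvent:
    """Convenience constructor: a square footprint, optionally translating.

    ``velocity`` is in pixels per frame; the footprint translates rigidly so
    the centroid path is exactly linear.
    """
    cy, cx = center
    side = np.arange(-half_width, half_width + 1)
    base = np.array([(r, c) for r in side for c in side])
    fps = []
    for f in range(n_frames):
        off = np.array([round(velocity[0] * f), round(velocity[1] * f)], dtype=int)
        fps.append(base + np.array([cy, cx]) + off)
    return PlantedEvent(
        cell_id=cell_id,
        onset_frame=onset_frame,
        offset_frame=onset_frame + n_frames - 1,
        peak_ca=peak_ca,
        footprints=fps,
        rise_frames=rise_frames,
        decay_tau=decay_tau,
    )


def event_ca_trace(ev: PlantedEvent, basal_ca: float, frame_interval: float) -> np.ndarray:
    """Concentration (nM) at each frame of the event window.

    Linear rise to ``peak_ca`` over ``rise_frames`` frames, then exponential
    decay of the suprabasal component with time constant ``decay_tau``.
    """
    amp = ev.peak_ca - basal_ca
    trace = np.empty(ev.n_frames, dtype=float)
    for i in range(ev.n_frames):
        if i < ev.rise_frames:
            trace[i] = basal_ca + amp * (i + 1) / ev.rise_frames
        else:
            dt = (i - ev.rise_frames + 1) * frame_interval
            trace[i] = basal_ca + amp * np.exp(-dt / ev.decay_tau)
    return trace


def _true_features(
    events: list[PlantedEvent],
    hill: HillParams,
    pixel_size: float,
    frame_interval: float,
) -> pd.DataFrame:
    rows = []
    for eid, ev in enumerate(events):
        areas = np.array([len(fp) for fp in ev.footprints])
        path = ev.center_path(pixel_size)
        disp = np.linalg.norm(path - path[0], axis=1).max() if len(path) > 1 else 0.0
        trace = event_ca_trace(ev, hill.basal_ca, frame_interval)
        dff = dff_of_ca(trace, hill)
        slope = float(np.diff(dff).max() / frame_interval) if len(dff) > 1 else 0.0
        rows.append(
            dict(
                event_id=eid,
                cell_id=ev.cell_id,
                onset_frame=ev.onset_frame,
                offset_frame=ev.offset_frame,
                peak_ca=ev.peak_ca,
                peak_dff=float(dff.max()),
                max_size=float(areas.max()) * pixel_size**2,
                duration=ev.n_frames * frame_interval,
                distance=float(disp),
                max_slope=slope,
            )
        )
    df = pd.DataFrame(rows)
    if len(df) and (df[["max_size", "duration", "distance", "max_slope"]] < 0).any().any():
        raise AssertionError("true features must be nonnegative")
    return df


def simulate_calcium(
    geometry: VolumeMap,
    event_specs: list[PlantedEvent],
    hill: HillParams,
    n_frames: int,
    frame_interval: float,
) -> tuple[np.ndarray, GroundTruth]:
    """Concentration movie (nM) from planted events over a basal floor.

    Concentration equals ``hill.basal_ca`` outside every event; within an
    event window the footprint follows :func:`event_ca_trace`.  Overlapping
    events combine by maximum.  Raises if a footprint leaves its cell's
    pixels or the frame range.
    """
    h, w = geometry.vf.shape
    ca = np.full((n_frames, h, w), float(hill.basal_ca), dtype=np.float64)
    for ev in event_specs:
        if ev.offset_frame >= n_frames or ev.onset_frame < 0:
            raise ValueError("event window outside the recording")
        if not ev.peak_ca > hill.basal_ca:
            raise ValueError("peak_ca must exceed basal_ca")
        trace = event_ca_trace(ev, hill.basal_ca, frame_interval)
        for i, fp in enumerate(ev.footprints):
            r, c = fp[:, 0], fp[:, 1]
            if np.any((r < 0) | (r >= h) | (c < 0) | (c >= w)):
                raise ValueError("event footprint outside the field of view")
            if np.any(geometry.cell_labels[r, c] != ev.cell_id):
                raise ValueError(
                    f"footprint of event in cell {ev.cell_id} leaves the cell mask"
                )
            f = ev.onset_frame + i
            ca[f, r, c] = np.maximum(ca[f, r, c], trace[i])
    gt = GroundTruth(
        events=list(event_specs),
        true_features=_true_features(
            event_specs, hill, geometry.pixel_size, frame_interval
        ),
    )
    return ca, gt


def render_fluorescence(
    ca_movie: np.ndarray,
    geometry: VolumeMap,
    hill: HillParams,
    expression_gain: float = 100.0,
    red_coeff: float = 1.0,
    crosstalk: MixingMatrix | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    frame_interval: float = 0.2,
) -> TwoChannelMovie:
    """Forward render a concentration movie into a two-channel recording.

    green = gain * vf * B(ca), red = gain * vf * red_coeff (time-invariant:
    tdTomato carries no Ca2+ dependence), mixed by ``crosstalk`` and
    degraded by ``noise`` if given.  The noiseless render is deterministic.
    """
    if ca_movie.shape[1:] != geometry.vf.shape:
        raise ValueError("ca_movie and geometry must share spatial shape")
    vf = geometry.vf
    green = expression_gain * vf[None, :, :] * brightness(ca_movie, hill)
    red = np.broadcast_to(
        expression_gain * red_coeff * vf, ca_movie.shape
    ).copy()
    if crosstalk is not None:
        m = crosstalk.matrix
        green, red = m[0, 0] * green + m[0, 1] * red, m[1, 0] * green + m[1, 1] * red
    if noise is not None:
        rng = np.random.default_rng(seed)
        p = noise.photons_per_unit
        if p > 0:
            green = rng.poisson(green * p) / p
            red = rng.poisson(red * p) / p
        if noise.read_sigma > 0:
            green = green + rng.normal(0.0, noise.read_sigma, green.shape)
            red = red + rng.normal(0.0, noise.read_sigma, red.shape)
        green = np.clip(green, 0, None)
        red = np.clip(red, 0, None)
    return TwoChannelMovie(
        green=green.astype(np.float32),
        red=red.astype(np.float32),
        pixel_size=geometry.pixel_size,
        frame_interval=frame_interval,
    )
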