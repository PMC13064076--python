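"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: flood fill is a plain
BFS, the baseline envelope is a literal percentile loop, and event features
are re-derived from the rendered concentration movie rather than from the
plant parameters.
"""

from collections import deque
from itertools import product

import numpy as np

from astroca.hill import dff_of_ca

_OFFSETS = {
    26: [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[frozenset]:
    """BFS connected components of a boolean (T, H, W) array as voxel sets."""
    offs = _OFFSETS[connectivity]
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    shape = mask.shape
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        comp = []
        while q:
            v = q.popleft()
            comp.append(v)
            for o in offs:
                u = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= u[i] < shape[i] for i in range(3)) and mask[u] and not seen[u]:
                    seen[u] = True
                    q.append(u)
        comps.append(frozenset(comp))
    return comps


def brute_percentile_envelope(trace: np.ndarray, window: int, percentile: float) -> float:
    """Minimum over all sliding windows of the window percentile."""
    return min(
        np.percentile(trace[s : s + window], percentile)
        for s in range(len(trace) - window + 1)
    )


def features_from_concentration(ca_movie, event, hill, pixel_size, frame_interval):
    """Re-measure one planted event directly from the concentration movie.

    Works frame by frame over the event's window: suprabasal pixels give the
    area and centroid, the Hill model converts the (uniform) concentration
    into the footprint-mean dF/F_R whose consecutive differences give the
    slope.  Independent of GroundTruth bookkeeping.
    """
    areas, centroids, means = [], [], []
    for i, f in enumerate(range(event.onset_frame, event.offset_frame + 1)):
        frame = ca_movie[f]
        supra = frame > hill.basal_ca
        rr, cc = np.nonzero(supra)
        areas.append(len(rr))
        centroids.append(np.array([rr.mean(), cc.mean()]))
        means.append(float(dff_of_ca(frame[supra].mean(), hill)))
    centroids = np.asarray(centroids)
    disp = float(np.linalg.norm(centroids - centroids[0], axis=1).max()) * pixel_size
    slope = float(np.diff(means).max() / frame_interval) if len(means) > 1 else 0.0
    return dict(
        max_size=max(areas) * pixel_size**2,
        duration=len(areas) * frame_interval,
        distance=disp,
        max_slope=slope,
    )
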