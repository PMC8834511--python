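"""One-call 4D tracking pipeline: enhance, segment, filter, measure, link."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import (
    CellObservation,
    Movie4D,
    SegmentationParams,
    Track,
    apply_drift_correction,
    enhance_particles,
    estimate_drift,
    filter_by_volume,
    link_tracks,
    measure_frame,
    segment_cells,
)

__all__ = ["TrackingResult", "track_movie"]


@dataclass
class TrackingResult:
    tracks: list[Track]
    observations_per_frame: list[list[CellObservation]]
    drift_um: np.ndarray | None
    segments: list[np.ndarray]


def track_movie(
    movie: Movie4D,
    cell_radius_um: float = 5.0,
    min_volume_um3: float = 150.0,
    gate_um: float = 15.0,
    min_track_length: int = 5,
    drift_correction: bool = True,
    params: SegmentationParams | None = None,
) -> TrackingResult:
    """Run the full segmentation-and-tracking chain on one movie.

    Steps: particle enhancement (band-pass), per-frame watershed
    segmentation, volume filtering (debris removal), morphometric
    measurement, optional global drift correction, and gated optimal
    linking with the short-track exclusion.
    """
    enhanced = enhance_particles(movie, cell_radius_um)
    segments = segment_cells(enhanced, params, reference=movie)
    segments = filter_by_volume(segments, min_volume_um3, movie.voxel_size_um)
    obs = [
        measure_frame(segments[t], t, movie.voxel_size_um, movie.intensity[t])
        for t in range(movie.n_frames)
    ]
    drift = None
    if drift_correction and movie.n_frames >= 2:
        centroids = [
            np.array([o.centroid_um for o in frame]).reshape(-1, 3) for frame in obs
        ]
        drift = estimate_drift(centroids)
        obs = apply_drift_correction(obs, drift)
    tracks = link_tracks(
        obs,
        gate_um=gate_um,
        excluded_timepoints=movie.excluded_timepoints,
        min_length=min_track_length,
    )
    return TrackingResult(
        tracks=tracks, observations_per_frame=obs, drift_um=drift, segments=segments
    )
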