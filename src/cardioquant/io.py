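"""File round trips for sections, movies, class maps and tables.

Sections are 8-bit RGB TIFF/PNG with a JSON sidecar carrying the pixel size;
movies are multi-page TIFF in (t, z, y, x) order, 16-bit, with a sidecar
carrying voxel size, frame interval and excluded timepoints; truth/track
tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .histology import ClassMap, SectionImage
from .tracking import Movie4D, Track

__all__ = [
    "write_section",
    "read_section",
    "write_class_map",
    "read_class_map",
    "write_movie",
    "read_movie",
    "tracks_to_dataframe",
    "write_tracks",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_section(path: str | Path, section: SectionImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, section.pixels)
    meta = {
        "pixel_size_um": section.pixel_size_um,
        "section_id": section.section_id,
        "heart_id": section.heart_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    if section.exclusion_mask is not None:
        tifffile.imwrite(
            path.with_name(path.stem + "_mask.tif"),
            section.exclusion_mask.astype(np.uint8),
        )


def read_section(path: str | Path) -> SectionImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    mask_path = path.with_name(path.stem + "_mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return SectionImage(
        pixels=tifffile.imread(path),
        pixel_size_um=float(meta["pixel_size_um"]),
        exclusion_mask=mask,
        section_id=meta.get("section_id", ""),
        heart_id=meta.get("heart_id", ""),
    )


def write_class_map(path: str | Path, cmap: ClassMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, cmap.labels.astype(np.uint8))
    _sidecar(path).write_text(json.dumps({"pixel_size_um": cmap.pixel_size_um}))


def read_class_map(path: str | Path) -> ClassMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return ClassMap(
        labels=tifffile.imread(path), pixel_size_um=float(meta["pixel_size_um"])
    )


def write_movie(path: str | Path, movie: Movie4D) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.intensity, metadata={"axes": "TZYX"})
    meta = {
        "voxel_size_um": list(movie.voxel_size_um),
        "frame_interval_min": movie.frame_interval_min,
        "excluded_timepoints": sorted(movie.excluded_timepoints),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_movie(path: str | Path) -> Movie4D:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    if data.ndim == 3:  # single z-plane written without the z axis
        data = data[:, None]
    return Movie4D(
        intensity=data,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        frame_interval_min=float(meta["frame_interval_min"]),
        excluded_timepoints=frozenset(meta.get("excluded_timepoints", ())),
    )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t": int(tr.t[i]),
                    "z_um": tr.centroids_um[i, 0],
                    "y_um": tr.centroids_um[i, 1],
                    "x_um": tr.centroids_um[i, 2],
                    "volume_um3": tr.volumes_um3[i],
                    "surface_area_um2": tr.surface_areas_um2[i],
                    "sphericity": tr.sphericities[i],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "t", "z_um", "y_um", "x_um",
            "volume_um3", "surface_area_um2", "sphericity",
        ],
    )


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)
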