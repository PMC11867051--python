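"""File round-trips: TIFF movies with a JSON sidecar, HDF5 label volumes.

Movies are written as one multi-page TIFF per channel (page = frame; the
static vessel channel is a single page) plus a JSON metadata sidecar with
the pixel size, frame interval, puff onset frame and channel roles.
Volumes go to HDF5 with an unsigned-integer dataset ``labels``, physical
attributes, and the label map stored as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .synthetic import (
    GroundTruthMovie,
    LabeledVolume,
    TwoChannelMovie,
)


def write_movie(movie: TwoChannelMovie, directory, prefix: str = "movie") -> dict:
    """Write fluo4/sr101 TIFFs plus the metadata sidecar; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "glial": d / f"{prefix}_fluo4.tif",
        "vessel": d / f"{prefix}_sr101.tif",
        "meta": d / f"{prefix}_meta.json",
    }
    tifffile.imwrite(paths["glial"], movie.glial.astype(np.float32))
    tifffile.imwrite(paths["vessel"], movie.vessel.astype(np.float32))
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "puff_onset_frame": movie.puff_onset_frame,
        "channels": {"fluo4": "glial calcium indicator", "sr101": "vessel label"},
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_movie(glial_path, vessel_path, meta_path) -> TwoChannelMovie:
    meta = json.loads(Path(meta_path).read_text())
    glial = tifffile.imread(glial_path).astype(float)
    vessel = tifffile.imread(vessel_path).astype(float)
    if vessel.ndim == 3:  # tolerate a (1, H, W) or repeated-page vessel stack
        vessel = vessel[0]
    return TwoChannelMovie(
        glial=glial,
        vessel=vessel,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        puff_onset_frame=int(meta["puff_onset_frame"]),
    )


def write_volume(volume: LabeledVolume, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=volume.labels.astype(np.uint16))
        f.attrs["voxel_size_um"] = list(volume.voxel_size_um)
        f.attrs["vessel_axis"] = volume.vessel_axis
        f.attrs["depth_axis"] = volume.depth_axis
        f.attrs["depth_offset_um"] = volume.depth_offset_um
        f.attrs["label_map"] = json.dumps(
            {str(k): v for k, v in volume.label_map.items()}
        )
    return path


def read_volume(path) -> LabeledVolume:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        label_map = {
            int(k): v for k, v in json.loads(f.attrs["label_map"]).items()
        }
        return LabeledVolume(
            labels=labels,
            label_map=label_map,
            voxel_size_um=tuple(float(v) for v in f.attrs["voxel_size_um"]),
            vessel_axis=int(f.attrs["vessel_axis"]),
            depth_axis=int(f.attrs["depth_axis"]),
            depth_offset_um=float(f.attrs["depth_offset_um"]),
        )


def write_ground_truth(truth, path) -> Path:
    """Serialise a ground-truth record (movie or volume) to JSON."""
    path = Path(path)

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialise {type(o)}")

    path.write_text(json.dumps(dataclasses.asdict(truth), default=default, indent=2))
    return path
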