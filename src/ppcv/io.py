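"""File formats: multi-page TIFF stacks with JSON sidecar manifests,
CSV profiles/cohorts, JSON configs and results.

The device's native format is proprietary, so the open interchange format
for a DART volume is a multi-page TIFF (one float32 page per B-scan) plus
a sidecar JSON manifest carrying the scan geometry, the generation seeds,
and — for phantoms — the ground-truth volumes and per-slice areas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError
from .geometry import ScanGeometry
from .network import GroundTruth
from .render import BScanStack
from .segmentation import SliceAreaProfile


def sidecar_path(stack_path) -> Path:
    return Path(stack_path).with_suffix(".json")


def write_stack(stack: BScanStack, path, ground_truth: GroundTruth | None = None) -> Path:
    """Write the stack as a multi-page TIFF and its manifest alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.images, photometric="minisblack")
    manifest = {
        "geometry": stack.geometry.to_dict(),
        "metadata": stack.metadata,
    }
    if ground_truth is not None:
        manifest["ground_truth"] = {
            "capillary_volume_um3": ground_truth.capillary_volume_um3,
            "large_vessel_volume_um3": ground_truth.large_vessel_volume_um3,
            "slice_areas_um2": ground_truth.slice_areas_um2.tolist(),
        }
    sidecar_path(path).write_text(json.dumps(manifest, indent=2))
    return path


def read_stack(path, geometry: ScanGeometry | None = None) -> BScanStack:
    """Read a multi-page TIFF stack; geometry comes from the sidecar
    manifest unless given explicitly."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such stack: {path}")
    metadata: dict = {}
    if geometry is None:
        sp = sidecar_path(path)
        if not sp.exists():
            raise FormatError(
                f"missing geometry: no sidecar manifest {sp.name}; required fields: "
                "lateral_extent_mm, n_ascans, axial_extent_mm, axial_pixel_um, "
                "n_slices, slice_spacing_um, quadrant")
        manifest = json.loads(sp.read_text())
        geometry = ScanGeometry.from_dict(manifest["geometry"])
        metadata = manifest.get("metadata", {})
    images = tifffile.imread(path)
    images = np.atleast_3d(images)
    if images.ndim == 3 and images.shape[0] != geometry.n_slices:
        raise FormatError(
            f"stack {path.name} has {images.shape[0]} pages but geometry "
            f"declares n_slices = {geometry.n_slices}")
    return BScanStack(images, geometry, metadata)


def read_ground_truth(path) -> GroundTruth | None:
    sp = sidecar_path(path)
    if not sp.exists():
        return None
    manifest = json.loads(sp.read_text())
    gt = manifest.get("ground_truth")
    if gt is None:
        return None
    return GroundTruth(gt["capillary_volume_um3"], gt["large_vessel_volume_um3"],
                       np.asarray(gt["slice_areas_um2"]))


def write_profile(profile: SliceAreaProfile, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "slice_index": np.arange(len(profile)),
        "x_um": profile.positions_um,
        "area_um2": profile.areas_um2,
    })
    df.to_csv(path, index=False)
    return path


def read_profile(path) -> SliceAreaProfile:
    df = pd.read_csv(path)
    for col in ("x_um", "area_um2"):
        if col not in df.columns:
            raise FormatError(f"profile CSV missing column {col!r}")
    x = df["x_um"].to_numpy(dtype=float)
    if len(x) < 2:
        raise FormatError("profile needs at least 2 slices")
    dh = float(x[1] - x[0])
    return SliceAreaProfile(df["area_um2"].to_numpy(dtype=float), x, dh)


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "eye", "age_years", "sex", "group", "quadrant",
                "timepoint", "ppcv_um3"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
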