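"""Readers and writers for the on-disk formats.

Conventions: object-space coordinates in mm, image measurements in px
with a 0-based pixel-center origin, angles serialized in degrees
(radians internally).  Calibration files must declare their units; there
is no implicit conversion.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CalibrationFormatError
from .geometry import (
    CameraModel,
    GridDistortion,
    IdentityDistortion,
    PointCloud,
    PolynomialDistortion,
    Pose,
)

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_beads_csv",
    "write_beads_csv",
    "read_calibration",
    "write_calibration",
    "read_pose_track",
    "write_pose_track",
    "read_targets_csv",
    "write_targets_csv",
    "read_image",
    "write_image",
]


# ---------------------------------------------------------------------------
# point clouds


def read_point_cloud(path, beads_path=None) -> PointCloud:
    """Load a point cloud from vertex-only PLY or X,Y,Z CSV (mm).

    ``beads_path`` optionally names a beads CSV whose coordinates are
    matched to the nearest cloud points to form the bead subset; a
    mismatch above 1e-3 mm (beyond single-precision PLY storage noise)
    errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float)
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("X", "Y", "Z"):
            if col not in df.columns:
                raise CalibrationFormatError(f"{path}: missing column {col!r}")
        pts = df[["X", "Y", "Z"]].to_numpy(dtype=float)
    else:
        raise CalibrationFormatError(f"{path}: unsupported point-cloud format {path.suffix!r}")
    if not np.all(np.isfinite(pts)):
        bad = int(np.nonzero(~np.isfinite(pts).all(axis=1))[0][0])
        raise CalibrationFormatError(f"{path}: non-finite coordinates at row {bad}")
    bead_indices = None
    if beads_path is not None:
        beads = read_beads_csv(beads_path)
        from scipy.spatial import cKDTree

        d, idx = cKDTree(pts).query(beads)
        if np.any(d > 1e-3):
            raise CalibrationFormatError(f"{beads_path}: bead coordinates not present in the cloud")
        bead_indices = idx
    return PointCloud(pts, bead_indices)


def write_point_cloud(path, cloud: PointCloud) -> None:
    """Write a cloud as vertex-only PLY (ascii) or X,Y,Z CSV."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        trimesh.PointCloud(cloud.points).export(str(path), file_type="ply")
    elif path.suffix.lower() == ".csv":
        pd.DataFrame(cloud.points, columns=["X", "Y", "Z"]).to_csv(path, index=False, float_format="%.17g")
    else:
        raise CalibrationFormatError(f"{path}: unsupported point-cloud format {path.suffix!r}")


def read_beads_csv(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("id", "X", "Y", "Z"):
        if col not in df.columns:
            raise CalibrationFormatError(f"{path}: missing column {col!r}")
    return df.sort_values("id")[["X", "Y", "Z"]].to_numpy(dtype=float)


def write_beads_csv(path, beads: np.ndarray) -> None:
    beads = np.atleast_2d(np.asarray(beads, dtype=float))
    df = pd.DataFrame(beads, columns=["X", "Y", "Z"])
    df.insert(0, "id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# calibration


_REQUIRED_CAMERA_FIELDS = ("XC", "YC", "ZC", "omega", "phi", "kappa", "xp", "yp", "c")


def _parse_distortion(block, path):
    if block is None:
        return IdentityDistortion()
    kind = block.get("type", "none")
    if kind == "none":
        return IdentityDistortion()
    if kind == "poly":
        try:
            return PolynomialDistortion(block["coeffs_x"], block["coeffs_y"])
        except KeyError as e:
            raise CalibrationFormatError(f"{path}: poly distortion missing {e.args[0]!r}") from e
    if kind == "grid":
        try:
            return GridDistortion(block["x"], block["y"], block["dx"], block["dy"])
        except KeyError as e:
            raise CalibrationFormatError(f"{path}: grid distortion missing {e.args[0]!r}") from e
    raise CalibrationFormatError(f"{path}: unknown distortion type {kind!r}")


def read_calibration(path) -> list[CameraModel]:
    """Load a two-camera calibration file (JSON or YAML).

    Layout: ``{"units": {"object": "mm", "image": "px"}, "angle_unit":
    "deg"|"rad", "cameras": [{XC.., distortion: {...}}, ...]}``.  Units
    must be declared and be mm/px; angles are converted to radians if
    declared in degrees.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    units = data.get("units")
    if not units or units.get("object") != "mm" or units.get("image") != "px":
        raise CalibrationFormatError(f"{path}: units must be declared as object=mm, image=px")
    angle_unit = data.get("angle_unit")
    if angle_unit not in ("deg", "rad"):
        raise CalibrationFormatError(f"{path}: angle_unit must be 'deg' or 'rad'")
    cams = []
    for i, block in enumerate(data.get("cameras", [])):
        for field in _REQUIRED_CAMERA_FIELDS:
            if field not in block:
                raise CalibrationFormatError(f"{path}: camera {i} missing field {field!r}")
        ang = [float(block[k]) for k in ("omega", "phi", "kappa")]
        if angle_unit == "deg":
            ang = list(np.deg2rad(ang))
        cams.append(
            CameraModel(
                XC=float(block["XC"]),
                YC=float(block["YC"]),
                ZC=float(block["ZC"]),
                omega=ang[0],
                phi=ang[1],
                kappa=ang[2],
                xp=float(block["xp"]),
                yp=float(block["yp"]),
                c=float(block["c"]),
                distortion=_parse_distortion(block.get("distortion"), path),
                name=block.get("name", f"cam{i + 1}"),
            )
        )
    if not cams:
        raise CalibrationFormatError(f"{path}: no cameras defined")
    return cams


def write_calibration(path, cameras: Sequence[CameraModel]) -> None:
    """Write cameras as JSON/YAML (angles in degrees, identity distortion
    noted as type none; structured providers are not serialized back)."""
    path = Path(path)
    data = {
        "units": {"object": "mm", "image": "px"},
        "angle_unit": "deg",
        "cameras": [
            {
                "name": cam.name or f"cam{i + 1}",
                "XC": float(cam.XC),
                "YC": float(cam.YC),
                "ZC": float(cam.ZC),
                "omega": float(np.rad2deg(cam.omega)),
                "phi": float(np.rad2deg(cam.phi)),
                "kappa": float(np.rad2deg(cam.kappa)),
                "xp": float(cam.xp),
                "yp": float(cam.yp),
                "c": float(cam.c),
                "distortion": {"type": "none"},
            }
            for i, cam in enumerate(cameras)
        ],
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# pose tracks and targets


_POSE_COLUMNS = ["epoch", "Xt", "Yt", "Zt", "omega", "phi", "kappa"]


def write_pose_track(path, records: Sequence[dict]) -> None:
    """Write per-epoch registration results.

    Each record: ``{"epoch": int, "pose": Pose, "lam": float|None,
    "rms_2d": float, "converged": bool}``.  Angles go out in degrees.
    """
    rows = []
    any_lam = any(r.get("lam") is not None for r in records)
    for r in records:
        p: Pose = r["pose"]
        row = {
            "epoch": r["epoch"],
            "Xt": p.Xt,
            "Yt": p.Yt,
            "Zt": p.Zt,
            "omega": float(np.rad2deg(p.omega)),
            "phi": float(np.rad2deg(p.phi)),
            "kappa": float(np.rad2deg(p.kappa)),
        }
        if any_lam:
            row["lambda"] = r.get("lam")
        row["rms_2d"] = r.get("rms_2d")
        row["converged"] = bool(r.get("converged", True))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_pose_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _POSE_COLUMNS:
        if col not in df.columns:
            raise CalibrationFormatError(f"{path}: missing column {col!r}")
    return df


def pose_from_row(row) -> Pose:
    return Pose.from_degrees(row["Xt"], row["Yt"], row["Zt"], row["omega"], row["phi"], row["kappa"])


def write_targets_csv(path, rows: Sequence[dict]) -> None:
    """Targets CSV: camera_id, epoch, x_px, y_px, a_px, b_px, theta_rad."""
    pd.DataFrame(rows, columns=["camera_id", "epoch", "x_px", "y_px", "a_px", "b_px", "theta_rad"]).to_csv(
        path, index=False
    )


def read_targets_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("camera_id", "epoch", "x_px", "y_px"):
        if col not in df.columns:
            raise CalibrationFormatError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# images


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF as stored integers."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(str(path))
    import imageio.v3 as iio

    return iio.imread(str(path))


def write_image(path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a grayscale image; float inputs in [0, 1] are quantized to
    the requested bit depth."""
    path = Path(path)
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.floating):
        if bit_depth == 8:
            img = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        else:
            img = np.clip(np.round(img * 65535), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), img)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), img)
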