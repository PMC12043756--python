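"""I/O for the pipeline's standard formats.

Label volumes are NIfTI-1 integer images with a voxel-to-world affine; the
world frame is always RAS in millimetres, and every mesh and landmark in this
package lives in world mm (never voxel units).  Files stored in other axis
conventions (e.g. LPS-ordered arrays) are reoriented on load; world
coordinates are unaffected by that reorientation.

Surfaces are extracted by marching cubes at iso-level 0.5 on the binarized
label, keeping the largest connected component so that stray speckle voxels
cannot create phantom apertures.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from skimage import measure

#: Slice-thickness inclusion criterion for source imaging (mm).
MAX_VOXEL_MM = 1.0


class LabelVolumeError(ValueError):
    pass


@dataclass
class LabelVolume:
    """An integer label grid with a voxel-to-world (RAS mm) affine.

    Voxel centers sit at integer indices under the affine; labels are
    non-negative integers, mutually exclusive by construction.
    """

    data: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise LabelVolumeError(f"label data must be integer, got {self.data.dtype}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise LabelVolumeError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def meets_slice_criterion(self) -> bool:
        """True when every voxel dimension is <= 1 mm."""
        return bool(np.all(self.voxel_size <= MAX_VOXEL_MM + 1e-9))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)


def write_label_volume(volume: LabelVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.affine)
    img.header.set_data_dtype(np.int16)
    if volume.label_names:
        img.header["descrip"] = json.dumps(
            {str(k): v for k, v in volume.label_names.items()}
        )[:79].encode()
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI label volume, reorienting the array to RAS if needed."""
    img = nib.load(str(path))
    if np.issubdtype(img.get_data_dtype(), np.floating):
        raise LabelVolumeError(
            f"{path}: floating-point data is not a label volume (expected integers)"
        )
    if nib.aff2axcodes(img.affine) != ("R", "A", "S"):
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.int64)
    vol = LabelVolume(data=data, affine=np.asarray(img.affine, dtype=float))
    if not vol.meets_slice_criterion:
        warnings.warn(
            f"{path}: voxel size {vol.voxel_size} mm exceeds the {MAX_VOXEL_MM} mm "
            "slice-thickness criterion required for reliable 3D simulation",
            stacklevel=2,
        )
    return vol


class AbsentLabelError(KeyError):
    pass


def extract_surface(volume: LabelVolume, label: int) -> trimesh.Trimesh:
    """Closed world-mm surface of one label (marching cubes at 0.5).

    The largest connected component is returned; the number of discarded
    components is recorded in ``mesh.metadata['n_discarded_components']``.
    """
    mask = volume.data == label
    if not mask.any():
        raise AbsentLabelError(
            f"label {label} absent; available labels: {volume.labels_present()}"
        )
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo pad
    world = volume.voxel_to_world(verts)
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=False)
    parts = mesh.split(only_watertight=False)
    n_discarded = 0
    if len(parts) > 1:
        areas = [p.area for p in parts]
        mesh = parts[int(np.argmax(areas))]
        n_discarded = len(parts) - 1
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["n_discarded_components"] = n_discarded
    return mesh


# ---------------------------------------------------------------------------
# meshes


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in {".ply", ".stl"}:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mesh.export(str(path))


def read_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return mesh


# ---------------------------------------------------------------------------
# landmarks (JSON and Slicer-style FCSV, both RAS mm)


def write_landmarks_json(landmarks: dict[str, np.ndarray], path) -> None:
    Path(path).write_text(
        json.dumps({k: [float(x) for x in np.asarray(v)] for k, v in landmarks.items()}, indent=2)
    )


def read_landmarks_json(path) -> dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def write_landmarks_fcsv(landmarks: dict[str, np.ndarray], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        writer = csv.writer(fh)
        for i, (name, p) in enumerate(landmarks.items(), start=1):
            p = np.asarray(p, dtype=float)
            writer.writerow(
                [f"F-{i}", f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}",
                 0, 0, 0, 1, 1, 1, 0, name, "", ""]
            )


def read_landmarks_fcsv(path) -> dict[str, np.ndarray]:
    """Parse a Slicer fiducial CSV; LPS files are converted to RAS."""
    landmarks: dict[str, np.ndarray] = {}
    lps = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line and ("LPS" in line or line.endswith("= 0")):
                    lps = "LPS" in line
                continue
            fields = next(csv.reader([line]))
            x, y, z = float(fields[1]), float(fields[2]), float(fields[3])
            name = fields[11] if len(fields) > 11 and fields[11] else fields[0]
            if lps:
                x, y = -x, -y
            landmarks[name] = np.array([x, y, z])
    return landmarks
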