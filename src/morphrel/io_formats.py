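"""Readers and writers for the volume, mesh, lookup-table and session-table formats.

Volumes are NIfTI-1 (``.nii``/``.nii.gz``) or FreeSurfer MGZ, handled by
nibabel.  Meshes are ASCII/binary PLY (via trimesh), OFF (parsed here, since
the format is trivial and strictness about non-triangular faces is part of the
contract), or FreeSurfer binary triangle surfaces (via nibabel.freesurfer).
Region lookup tables are two-column TSVs; the FreeSurfer color-LUT dialect is
accepted with its RGBA columns ignored.  Session measurements travel as
long-format CSV with columns ``subject, session, metric, value``.

Conventions: voxel indices are 0-based, world coordinates come from the NIfTI
affine, and all mesh coordinates are in mm world space.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh


class FormatError(ValueError):
    """File cannot be parsed as the requested format."""


class CompletenessError(ValueError):
    """A subjects x sessions design is missing cells."""


class EmptySelectionError(ValueError):
    """A label selection matched no voxels."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation volume (0 = background)."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size_mm: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label volume data must be integer-typed")
        if self.data.min(initial=0) < 0:
            raise ValueError("label codes must be >= 0")
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be 3 positive components")

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.data)


@dataclass
class BinaryMask:
    """Boolean 3D occupancy grid with a physical voxel size (mm)."""

    data: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.voxel_size_mm = np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be positive")

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class SurfaceMesh:
    """Closed triangle mesh in mm coordinates, counter-clockwise outward faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be V x 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be F x 3 triangles")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise IndexError("face references a vertex index out of range")
        if self.faces.size and np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("degenerate face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class RegionLookup:
    """Mapping of integer label codes to region names."""

    entries: list[tuple[int, str]]

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        names = [n for _, n in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be unique")
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ValueError("region names must be unique and non-empty")

    def name_of(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(code)

    @property
    def codes(self) -> list[int]:
        return [c for c, _ in self.entries]


@dataclass
class SessionMatrix:
    """Complete n_subjects x k_sessions matrix of one metric."""

    values: np.ndarray
    subject_ids: list[str]
    session_ids: list[str]
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 sessions")
        if len(self.subject_ids) != n or len(self.session_ids) != k:
            raise ValueError("id lists must match matrix shape")
        if np.any(~np.isfinite(self.values)):
            raise CompletenessError("matrix contains missing/non-finite cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_sessions(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Volume IO
# ---------------------------------------------------------------------------

_INTEGRAL_TOL = 1e-6


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1 or MGZ segmentation as an integer LabelVolume.

    Float-stored volumes are accepted only when every value is integral within
    1e-6, which is common NIfTI practice for label maps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise FormatError(f"cannot read {path} as NIfTI/MGZ: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded), initial=0.0) > _INTEGRAL_TOL:
            raise TypeError(f"{path} stores non-integral float values; not a label volume")
        data = rounded.astype(np.int32)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return LabelVolume(data=data.astype(np.int32), affine=np.asarray(img.affine), voxel_size_mm=zooms)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a LabelVolume as NIfTI-1 (extension decides .nii/.nii.gz)."""
    img = nib.Nifti1Image(vol.data.astype(np.int32), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size_mm))
    nib.save(img, str(path))


def mask_from_labels(vol: LabelVolume, labels: Iterable[int]) -> BinaryMask:
    """Binary mask of the voxels whose label is in ``labels``."""
    labels = set(int(v) for v in labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    data = np.isin(vol.data, sorted(labels))
    if not data.any():
        raise EmptySelectionError(f"no voxel carries any of the labels {sorted(labels)}")
    return BinaryMask(data=data, voxel_size_mm=vol.voxel_size_mm)


# ---------------------------------------------------------------------------
# Mesh IO
# ---------------------------------------------------------------------------

_FS_TRIANGLE_MAGIC = 16777214  # 0xFFFFFE


def _read_off(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            arity = int(tokens[pos])
            if arity != 3:
                raise FormatError(f"{path}: non-triangular face with {arity} vertices")
            faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
            pos += 1 + arity
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed OFF file: {exc}") from exc
    return SurfaceMesh(vertices=verts, faces=np.array(faces, dtype=np.int64))


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> SurfaceMesh:
    # header sanity check: trimesh silently fans out polygonal faces, but the
    # contract here is triangles-only
    with open(path, "rb") as fh:
        header = fh.read(4)
    if header != b"ply\n" and header[:3] != b"ply":
        raise FormatError(f"{path}: not a PLY file")
    loaded = trimesh.load(str(path), file_type="ply", process=False)
    if not isinstance(loaded, trimesh.Trimesh) or loaded.faces.shape[1] != 3:
        raise FormatError(f"{path}: PLY does not contain a triangle mesh")
    return SurfaceMesh(vertices=np.asarray(loaded.vertices), faces=np.asarray(loaded.faces))


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a triangle mesh from PLY, OFF or FreeSurfer binary surface."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        return _read_off(path)
    if suffix == ".ply":
        return _read_ply(path)
    # FreeSurfer binary surface (lh.pial etc. have no reliable suffix)
    try:
        with open(path, "rb") as fh:
            magic = int.from_bytes(fh.read(3), "big")
        if magic != _FS_TRIANGLE_MAGIC:
            raise FormatError(
                f"{path}: magic {magic:#x} is not a FreeSurfer triangle surface"
            )
        verts, faces = nib.freesurfer.read_geometry(str(path))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read {path} as a surface: {exc}") from exc
    return SurfaceMesh(vertices=np.asarray(verts, dtype=float), faces=np.asarray(faces))


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    # binary little-endian with double vertex properties: trimesh's exporter
    # downcasts to float32, which breaks sub-micron round-tripping at brain
    # coordinate magnitudes
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {len(mesh.vertices)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(mesh.faces)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    faces = np.empty((len(mesh.faces), 13), dtype=np.uint8)
    faces[:, 0] = 3
    faces[:, 1:] = mesh.faces.astype("<i4").view(np.uint8).reshape(len(mesh.faces), 12)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
        fh.write(faces.tobytes())


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a mesh as PLY (binary little-endian, double precision), OFF, or
    FreeSurfer binary surface (float32 by format definition)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        _write_off(mesh, path)
    elif suffix == ".ply":
        _write_ply(mesh, path)
    else:
        nib.freesurfer.write_geometry(str(path), mesh.vertices, mesh.faces)


# ---------------------------------------------------------------------------
# Region lookup tables
# ---------------------------------------------------------------------------

def read_region_lookup(path: str | Path) -> RegionLookup:
    """Read a region lookup TSV (columns code, name) or a FreeSurfer color LUT.

    FreeSurfer LUT lines look like ``17  Left-Hippocampus  220 216 20 0``;
    the RGBA columns are ignored.
    """
    entries: list[tuple[int, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[\t ]+", line)
            if parts[0].lower() in {"code", "label", "index"}:
                continue  # header row
            if len(parts) < 2:
                raise FormatError(f"lookup line needs at least code and name: {raw!r}")
            try:
                code = int(parts[0])
            except ValueError as exc:
                raise FormatError(f"bad label code in lookup: {parts[0]!r}") from exc
            entries.append((code, parts[1]))
    return RegionLookup(entries=entries)


def write_region_lookup(lookup: RegionLookup, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("code\tname\n")
        for code, name in lookup.entries:
            fh.write(f"{code}\t{name}\n")


# ---------------------------------------------------------------------------
# Session tables
# ---------------------------------------------------------------------------

_SESSION_COLUMNS = ["subject", "session", "metric", "value"]


def read_session_table(path: str | Path | io.TextIOBase) -> list[SessionMatrix]:
    """Read a long-format measurement CSV into one SessionMatrix per metric.

    The design must be complete: every subject measured in every session for
    every metric, exactly once.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _SESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"session table missing columns {missing_cols}")
    df = df.astype({"subject": str, "session": str, "metric": str})
    dupes = df.duplicated(subset=["subject", "session", "metric"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValueError(
            f"duplicate measurement for subject={row.subject!r} "
            f"session={row.session!r} metric={row.metric!r}"
        )
    matrices = []
    for metric, sub in df.groupby("metric", sort=True):
        wide = sub.pivot(index="subject", columns="session", values="value")
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        if wide.isna().any().any():
            i, j = np.argwhere(wide.isna().values)[0]
            raise CompletenessError(
                f"metric {metric!r}: subject {wide.index[i]!r} is missing "
                f"session {wide.columns[j]!r}"
            )
        matrices.append(
            SessionMatrix(
                values=wide.values,
                subject_ids=list(wide.index),
                session_ids=list(wide.columns),
                metric_name=str(metric),
            )
        )
    return matrices


def write_session_table(matrices: Sequence[SessionMatrix], path: str | Path) -> None:
    """Write SessionMatrix objects back to the long CSV dialect."""
    rows = []
    for m in matrices:
        for i, subj in enumerate(m.subject_ids):
            for j, sess in enumerate(m.session_ids):
                rows.append((subj, sess, m.metric_name, m.values[i, j]))
    pd.DataFrame(rows, columns=_SESSION_COLUMNS).to_csv(path, index=False)
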