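"""EMDB-SFF segmentation I/O (HDF5 container, v0.8-style layout).

Covers the subset of the schema the preprocessor needs: lattice
segmentations (zlib-compressed, base64-wrapped byte streams), triangle
meshes, and per-segment biological annotation (name, description, colour,
external references).  Shape primitives, software lists and non-identity
transforms are out of scope; a file declaring a non-identity lattice
transform is rejected rather than silently mis-registered.

Segments without a colour receive a deterministic golden-angle palette
colour keyed by segment id, so repeated preprocessing runs agree.
"""

from __future__ import annotations

import base64
import colorsys
import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import (
    DanglingLatticeError,
    InvalidSegmentationError,
    InvalidSffError,
    UnsupportedModeError,
)

SFF_VERSION = "0.8.0"

#: lattice "mode" strings (declared element type) -> numpy dtype
_LATTICE_MODES = {
    "uint8": np.uint8,
    "uint16": np.uint16,
    "uint32": np.uint32,
    "int8": np.int8,
    "int16": np.int16,
    "int32": np.int32,
}

_GOLDEN_ANGLE = 137.50776405003785  # degrees


def default_colour(segment_id: int) -> tuple[float, float, float, float]:
    """Deterministic fallback RGBA for segments without a stored colour."""
    hue = (segment_id * _GOLDEN_ANGLE) % 360.0 / 360.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.65, 0.9)
    return (round(r, 6), round(g, 6), round(b, 6), 1.0)


def smallest_label_dtype(max_label: int) -> np.dtype:
    """Smallest unsigned integer dtype that holds ``max_label``."""
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    return np.dtype(np.uint64)


@dataclass
class Lattice:
    """A 3D label array; label 0 is reserved for background."""

    lattice_id: int
    data: np.ndarray
    mode: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise InvalidSegmentationError("lattice data must be 3D")
        if arr.size and arr.min() < 0:
            raise InvalidSegmentationError("lattice labels must be non-negative")
        dt = smallest_label_dtype(int(arr.max()) if arr.size else 0)
        self.data = arr.astype(dt)
        if not self.mode:
            self.mode = str(dt)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Mesh:
    """Triangle mesh; vertices in Angstrom, triangles index vertices."""

    mesh_id: int
    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int32).reshape(-1, 3)
        n = len(self.vertices)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise InvalidSegmentationError("triangle index outside [0, vertex count)")
            t = self.triangles
            degenerate = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
            if degenerate.any():
                raise InvalidSegmentationError("degenerate triangle (repeated vertex index)")


@dataclass
class ExternalReference:
    resource: str
    accession: str
    label: str = ""


@dataclass
class Segment:
    """One annotated biological object within a segmentation."""

    segment_id: int
    kind: str  # "lattice" | "mesh"
    lattice_id: int | None = None
    label_value: int | None = None
    mesh_ids: list[int] = field(default_factory=list)
    name: str = ""
    description: str = ""
    colour: tuple[float, float, float, float] | None = None
    external_references: list[ExternalReference] = field(default_factory=list)

    def resolved_colour(self) -> tuple[float, float, float, float]:
        return self.colour if self.colour is not None else default_colour(self.segment_id)


@dataclass
class SegmentationSet:
    """Lattices and/or meshes plus the segments annotating them."""

    name: str = ""
    lattices: list[Lattice] = field(default_factory=list)
    meshes: list[Mesh] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`InvalidSegmentationError` on broken cross-references."""
        seen: set[int] = set()
        lattice_ids = {l.lattice_id for l in self.lattices}
        mesh_ids = {m.mesh_id for m in self.meshes}
        for seg in self.segments:
            if seg.segment_id in seen:
                raise InvalidSegmentationError(f"duplicate segment_id {seg.segment_id}")
            seen.add(seg.segment_id)
            if seg.kind == "lattice":
                if seg.lattice_id not in lattice_ids:
                    raise DanglingLatticeError(
                        f"segment {seg.segment_id} references missing lattice {seg.lattice_id}"
                    )
                if not seg.label_value or seg.label_value <= 0:
                    raise InvalidSegmentationError(
                        f"segment {seg.segment_id}: lattice label value must be > 0"
                    )
            elif seg.kind == "mesh":
                missing = set(seg.mesh_ids) - mesh_ids
                if missing:
                    raise InvalidSegmentationError(
                        f"segment {seg.segment_id} references missing meshes {sorted(missing)}"
                    )
            else:
                raise InvalidSegmentationError(f"unknown segment kind {seg.kind!r}")


# --- serialization ---------------------------------------------------------


def _encode_lattice_bytes(data: np.ndarray) -> bytes:
    # schema convention: C-order byte stream, zlib-compressed, base64-wrapped
    return base64.b64encode(zlib.compress(np.ascontiguousarray(data).tobytes()))


def _decode_lattice_bytes(blob: bytes, mode: str, size: tuple[int, int, int]) -> np.ndarray:
    if mode not in _LATTICE_MODES:
        raise UnsupportedModeError(f"unsupported lattice mode {mode!r}")
    try:
        raw = zlib.decompress(base64.b64decode(blob))
        arr = np.frombuffer(raw, dtype=_LATTICE_MODES[mode]).reshape(size)
    except Exception as exc:
        raise InvalidSffError(f"cannot decode lattice byte stream: {exc}") from exc
    return arr.copy()


def write_sff(seg: SegmentationSet, path) -> None:
    """Write a schema-conforming .hff readable by :func:`read_sff`."""
    seg.validate()
    with h5py.File(path, "w") as f:
        f.attrs["version"] = SFF_VERSION
        f.attrs["name"] = seg.name
        lat_root = f.create_group("lattice_list")
        for lat in seg.lattices:
            g = lat_root.create_group(str(lat.lattice_id))
            g.attrs["id"] = lat.lattice_id
            g.attrs["mode"] = str(lat.data.dtype)
            g.attrs["size"] = lat.dims
            g.create_dataset("data", data=np.void(_encode_lattice_bytes(lat.data)))
        mesh_root = f.create_group("mesh_list")
        for mesh in seg.meshes:
            g = mesh_root.create_group(str(mesh.mesh_id))
            g.attrs["id"] = mesh.mesh_id
            g.create_dataset("vertices", data=mesh.vertices)
            g.create_dataset("triangles", data=mesh.triangles)
        seg_root = f.create_group("segment_list")
        for s in seg.segments:
            g = seg_root.create_group(str(s.segment_id))
            g.attrs["id"] = s.segment_id
            g.attrs["kind"] = s.kind
            if s.kind == "lattice":
                tdv = g.create_group("three_d_volume")
                tdv.attrs["lattice_id"] = s.lattice_id
                tdv.attrs["value"] = s.label_value
                # identity transform only; declared explicitly
                tdv.attrs["transform_id"] = 0
            else:
                g.create_dataset("mesh_ids", data=np.asarray(s.mesh_ids, dtype=np.int64))
            bio = g.create_group("biological_annotation")
            bio.attrs["name"] = s.name
            bio.attrs["description"] = s.description
            refs = bio.create_group("external_references")
            for i, ref in enumerate(s.external_references):
                r = refs.create_group(str(i))
                r.attrs["resource"] = ref.resource
                r.attrs["accession"] = ref.accession
                r.attrs["label"] = ref.label
            if s.colour is not None:
                g.create_dataset("colour", data=np.asarray(s.colour, dtype=np.float64))
        # identity transform list (4x4); non-identity rejected on read
        f.create_dataset("transform_list/0", data=np.eye(4))


def read_sff(path) -> SegmentationSet:
    """Read an EMDB-SFF .hff file written in the supported layout."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise InvalidSffError(f"not an HDF5 container: {path}") from exc
    with f:
        try:
            out = _read_sff_open(f)
        except KeyError as exc:
            raise InvalidSffError(f"malformed SFF container: missing {exc}") from exc
    out.validate()
    return out


def _read_sff_open(f: h5py.File) -> SegmentationSet:
    for name, ds in f.get("transform_list", {}).items():
        mat = np.asarray(ds)
        if mat.shape in ((4, 4), (3, 4)) and not np.allclose(
            mat[:3], np.eye(4)[:3], atol=1e-12
        ):
            raise InvalidSffError(f"non-identity lattice transform {name!r} is not supported")

    lattices = []
    for key, g in f.get("lattice_list", {}).items():
        mode = str(g.attrs["mode"])
        size = tuple(int(v) for v in g.attrs["size"])
        blob = bytes(np.asarray(g["data"]).tobytes())
        lattices.append(Lattice(int(g.attrs["id"]), _decode_lattice_bytes(blob, mode, size), mode))

    meshes = [
        Mesh(int(g.attrs["id"]), np.asarray(g["vertices"]), np.asarray(g["triangles"]))
        for g in f.get("mesh_list", {}).values()
    ]

    segments = []
    for g in f.get("segment_list", {}).values():
        sid = int(g.attrs["id"])
        kind = str(g.attrs["kind"])
        bio = g["biological_annotation"]
        refs = [
            ExternalReference(
                str(r.attrs["resource"]), str(r.attrs["accession"]), str(r.attrs["label"])
            )
            for _, r in sorted(bio["external_references"].items(), key=lambda kv: int(kv[0]))
        ]
        colour = tuple(float(v) for v in g["colour"]) if "colour" in g else None
        seg = Segment(
            segment_id=sid,
            kind=kind,
            name=str(bio.attrs["name"]),
            description=str(bio.attrs["description"]),
            colour=colour,
            external_references=refs,
        )
        if kind == "lattice":
            tdv = g["three_d_volume"]
            seg.lattice_id = int(tdv.attrs["lattice_id"])
            seg.label_value = int(tdv.attrs["value"])
        elif kind == "mesh":
            seg.mesh_ids = [int(v) for v in np.asarray(g["mesh_ids"])]
        else:
            raise InvalidSffError(f"unknown segment kind {kind!r}")
        segments.append(seg)
    segments.sort(key=lambda s: s.segment_id)
    lattices.sort(key=lambda l: l.lattice_id)
    meshes.sort(key=lambda m: m.mesh_id)
    return SegmentationSet(
        name=str(f.attrs.get("name", "")), lattices=lattices, meshes=meshes, segments=segments
    )


def validate_against_volume(seg: SegmentationSet, grid) -> list[str]:
    """Compatibility report between a segmentation and a volume grid.

    Returns a list of human-readable problems; an empty list means the
    pair can be preprocessed together.
    """
    report: list[str] = []
    for lat in seg.lattices:
        if tuple(lat.dims) != tuple(grid.dims):
            report.append(
                f"dims mismatch: lattice {lat.lattice_id} is {lat.dims}, volume is {grid.dims}"
            )
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.dims) * np.asarray(grid.voxel_size)
    for mesh in seg.meshes:
        if mesh.vertices.size == 0:
            continue
        outside = (mesh.vertices < lo - 1e-9) | (mesh.vertices > hi + 1e-9)
        n_out = int(outside.any(axis=1).sum())
        if n_out:
            report.append(
                f"vertex outside box: mesh {mesh.mesh_id} has {n_out} vertices "
                f"outside [{lo.tolist()}, {hi.tolist()}]"
            )
    return report
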