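"""The internal database: chunked, compressed multiscale entries on disk.

Each entry lives under ``{root}/{source}/{entry_id}/`` as a set of Zarr
arrays (default 64x64x64 chunks, gzip-compressed) holding the volume and
segmentation-lattice pyramids plus single-resolution meshes, with two
sidecar JSON documents:

* ``metadata.json`` — dims/stats per level, voxel size, origin, factors,
  lattice label histograms, mesh inventory, format version;
* ``annotations.json`` — the per-segment biological annotations.

Sidecar JSON (rather than array attributes) keeps the documents diffable
and lets the query service return them verbatim.  The layout is a stable
contract, versioned through ``format_version``.  Single-writer,
many-reader; no locking is attempted.
"""

from __future__ import annotations

import json
import logging
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import zarr

from .errors import CorruptEntryError, EntryExistsError, NotFoundError
from .multiscale import LevelPlan, build_pyramid, level_dims, plan_levels
from .sff_io import Mesh, SegmentationSet
from .volume_io import VolumeGrid

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"
DEFAULT_CHUNK = (64, 64, 64)

_KEY_RE = re.compile(r"[^a-z0-9_-]+")


def sanitize_key(key: str) -> str:
    """Normalise a source/entry key to ``[a-z0-9_-]``."""
    out = _KEY_RE.sub("-", key.lower()).strip("-")
    if not out:
        raise ValueError(f"key {key!r} sanitizes to an empty string")
    return out


@dataclass
class MultiscaleEntry:
    """One database entry: pyramids + metadata + annotations.

    ``volume_levels`` / ``lattice_levels`` map downsampling factor to an
    array (possibly a lazily-read Zarr array after :func:`load_entry`).
    """

    source: str
    entry_id: str
    volume_levels: dict[int, np.ndarray]
    metadata: dict
    annotations: list[dict] = field(default_factory=list)
    lattice_levels: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)
    meshes: list[Mesh] = field(default_factory=list)


def build_entry(
    source: str,
    entry_id: str,
    grid: VolumeGrid,
    segmentation: SegmentationSet | None = None,
    plan: LevelPlan | None = None,
    min_extent: int | None = None,
    max_total_voxels: int | None = None,
) -> MultiscaleEntry:
    """Preprocess a volume (+ optional segmentation) into an entry.

    Builds the level plan from the volume dims, downsamples volume and
    every lattice with the same factors (lattices whose dims would drop
    below one voxel keep only the feasible prefix of the plan), computes
    per-level stats/histograms and assembles metadata and annotations.
    """
    kwargs = {}
    if min_extent is not None:
        kwargs["min_extent"] = min_extent
    if max_total_voxels is not None:
        kwargs["max_total_voxels"] = max_total_voxels
    if plan is None:
        plan = plan_levels(grid.dims, **kwargs)
    vol = build_pyramid(grid.data, plan, kind="volume")

    lattice_levels: dict[int, dict[int, np.ndarray]] = {}
    lattice_stats: dict[int, dict[int, dict]] = {}
    meshes: list[Mesh] = []
    annotations: list[dict] = []
    seg_name = ""
    if segmentation is not None:
        segmentation.validate()
        seg_name = segmentation.name
        for lat in segmentation.lattices:
            lp = build_pyramid(lat.data, plan, kind="lattice")
            lattice_levels[lat.lattice_id] = lp["levels"]
            lattice_stats[lat.lattice_id] = lp["stats"]
        meshes = list(segmentation.meshes)
        for s in segmentation.segments:
            annotations.append(
                {
                    "segment_id": s.segment_id,
                    "kind": s.kind,
                    "lattice_id": s.lattice_id,
                    "label_value": s.label_value,
                    "mesh_ids": list(s.mesh_ids),
                    "name": s.name,
                    "description": s.description,
                    "colour": list(s.resolved_colour()),
                    "external_references": [
                        {"resource": r.resource, "accession": r.accession, "label": r.label}
                        for r in s.external_references
                    ],
                }
            )

    factors = list(plan.factors)
    metadata = {
        "format_version": FORMAT_VERSION,
        "source": source,
        "entry_id": entry_id,
        "segmentation_name": seg_name,
        "dims": list(grid.dims),
        "voxel_size": list(grid.voxel_size),
        "origin": list(grid.origin),
        "factors": factors,
        "dims_per_level": {str(f): list(level_dims(grid.dims, f)) for f in factors},
        "volume_stats": {str(f): vol["stats"][f] for f in factors},
        "lattice_ids": sorted(lattice_levels),
        "lattice_histograms": {
            str(lid): {str(f): {str(k): v for k, v in hists[f].items()} for f in hists}
            for lid, hists in lattice_stats.items()
        },
        "meshes": [
            {
                "mesh_id": m.mesh_id,
                "vertex_count": int(len(m.vertices)),
                "triangle_count": int(len(m.triangles)),
            }
            for m in meshes
        ],
    }
    return MultiscaleEntry(
        source=source,
        entry_id=entry_id,
        volume_levels=vol["levels"],
        metadata=metadata,
        annotations=annotations,
        lattice_levels=lattice_levels,
        meshes=meshes,
    )


# --- persistence -----------------------------------------------------------


def _entry_dir(root, source: str, entry_id: str) -> Path:
    return Path(root) / sanitize_key(source) / sanitize_key(entry_id)


def _write_array(group: zarr.Group, path: str, data: np.ndarray, chunks) -> None:
    if data.ndim == 3:
        arr_chunks = tuple(min(c, s) for c, s in zip(chunks, data.shape))
    else:
        arr_chunks = tuple(max(1, s) for s in data.shape)
    a = group.create_array(
        path,
        shape=data.shape,
        chunks=arr_chunks,
        dtype=data.dtype,
        compressors=zarr.codecs.GzipCodec(level=5),
        overwrite=True,
    )
    a[...] = data


def save_entry(
    entry: MultiscaleEntry, root, overwrite: bool = False, chunks=DEFAULT_CHUNK
) -> Path:
    """Persist an entry under ``root``; raises if it exists and not overwrite."""
    edir = _entry_dir(root, entry.source, entry.entry_id)
    if edir.exists():
        if not overwrite:
            raise EntryExistsError(
                f"entry exists: {entry.source}/{entry.entry_id} (pass overwrite=True to replace)"
            )
        shutil.rmtree(edir)
    group = zarr.open_group(str(edir), mode="a")
    for f, arr in entry.volume_levels.items():
        _write_array(group, f"volume/{f}", np.asarray(arr), chunks)
    for lid, levels in entry.lattice_levels.items():
        for f, arr in levels.items():
            _write_array(group, f"segmentation/{lid}/{f}", np.asarray(arr), chunks)
    for mesh in entry.meshes:
        _write_array(group, f"mesh/{mesh.mesh_id}/vertices", mesh.vertices, chunks)
        _write_array(group, f"mesh/{mesh.mesh_id}/triangles", mesh.triangles, chunks)
    (edir / "metadata.json").write_text(json.dumps(entry.metadata, indent=1))
    (edir / "annotations.json").write_text(json.dumps(entry.annotations, indent=1))
    return edir


def load_entry(source: str, entry_id: str, root) -> MultiscaleEntry:
    """Open a stored entry with lazily-read arrays.

    Box reads on the returned arrays touch only the intersecting chunks.
    Raises :class:`NotFoundError` for unknown entries and
    :class:`CorruptEntryError` when metadata and arrays disagree.
    """
    edir = _entry_dir(root, source, entry_id)
    meta_path = edir / "metadata.json"
    if not meta_path.exists():
        raise NotFoundError(f"not found: entry {source}/{entry_id} under {root}")
    try:
        metadata = json.loads(meta_path.read_text())
        annotations = json.loads((edir / "annotations.json").read_text())
        group = zarr.open_group(str(edir), mode="r")
    except (OSError, ValueError) as exc:
        raise CorruptEntryError(f"corrupt entry {source}/{entry_id}: {exc}") from exc

    factors = [int(f) for f in metadata["factors"]]
    volume_levels: dict[int, np.ndarray] = {}
    for f in factors:
        try:
            volume_levels[f] = group[f"volume/{f}"]
        except KeyError as exc:
            raise CorruptEntryError(
                f"corrupt entry: metadata lists volume factor {f} but the array is missing"
            ) from exc
    lattice_levels: dict[int, dict[int, np.ndarray]] = {}
    for lid in metadata.get("lattice_ids", []):
        per = {}
        for f in sorted(int(k) for k in metadata["lattice_histograms"][str(lid)]):
            try:
                per[f] = group[f"segmentation/{lid}/{f}"]
            except KeyError as exc:
                raise CorruptEntryError(
                    f"corrupt entry: lattice {lid} factor {f} array is missing"
                ) from exc
        lattice_levels[int(lid)] = per
    meshes = []
    for rec in metadata.get("meshes", []):
        mid = rec["mesh_id"]
        try:
            meshes.append(
                Mesh(mid, np.asarray(group[f"mesh/{mid}/vertices"]), np.asarray(group[f"mesh/{mid}/triangles"]))
            )
        except KeyError as exc:
            raise CorruptEntryError(f"corrupt entry: mesh {mid} arrays missing") from exc
    return MultiscaleEntry(
        source=metadata["source"],
        entry_id=metadata["entry_id"],
        volume_levels=volume_levels,
        metadata=metadata,
        annotations=annotations,
        lattice_levels=lattice_levels,
        meshes=meshes,
    )


def list_entries(root) -> list[tuple[str, str]]:
    """Enumerate well-formed entries, sorted; malformed dirs are logged."""
    root = Path(root)
    out: list[tuple[str, str]] = []
    if not root.exists():
        return out
    for src_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for entry_dir in sorted(p for p in src_dir.iterdir() if p.is_dir()):
            if (entry_dir / "metadata.json").exists():
                out.append((src_dir.name, entry_dir.name))
            else:
                logger.warning("skipping malformed entry directory %s", entry_dir)
    return out


def remove_entry(source: str, entry_id: str, root) -> None:
    edir = _entry_dir(root, source, entry_id)
    if not (edir / "metadata.json").exists():
        raise NotFoundError(f"not found: entry {source}/{entry_id} under {root}")
    shutil.rmtree(edir)
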