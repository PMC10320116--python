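"""Metadata and size-budgeted box queries over stored entries.

A client asks for a half-open voxel box ``[lo, hi)`` in original
(factor-1) coordinates together with a point budget ``max_points``: the
maximum number of values it is willing to receive.  The service picks
the smallest (finest) pyramid factor whose level-space box fits the
budget — so responses degrade gracefully to coarser levels for large
regions — and packs the result into a BinaryCIF payload.

Volume values travel through the default lossy chain (255-step interval
quantization over the level's [min, max], then delta + integer packing);
label and mesh-index channels use lossless integer chains, and mesh
vertex coordinates are shipped as raw float64 bytes, so segmentation
responses decode exactly.

The HTTP surface is a thin WSGI app over the same service object:

* ``GET /v1/{source}/{id}/metadata``
* ``GET /v1/{source}/{id}/volume/box/{x0},{y0},{z0}/{x1},{y1},{z1}?max_points=N``
* ``GET /v1/{source}/{id}/segmentation/{lattice_id}/box/...?max_points=N``
* ``GET /v1/{source}/{id}/mesh``

Errors are returned as JSON ``{"error": {"code", "message"}}``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import bcif_codec as bcif
from .errors import (
    EmptyRegionError,
    InvalidBudgetError,
    NotFoundError,
    VolsegError,
)
from .store import MultiscaleEntry, load_entry

DEFAULT_MAX_POINTS = 10**6
QUANTIZATION_STEPS = 255


@dataclass
class BoxQuery:
    """A half-open box [lo, hi) in factor-1 voxel coordinates plus a budget."""

    source: str
    entry_id: str
    channel: str = "volume"  # "volume" | "lattice" | "meshes"
    lattice_id: int | None = None
    lo: tuple[int, int, int] = (0, 0, 0)
    hi: tuple[int, int, int] | None = None  # None = whole grid
    max_points: int = DEFAULT_MAX_POINTS


@dataclass
class SliceResult:
    """The data actually returned for a box query."""

    source: str
    entry_id: str
    channel: str
    factor: int
    level_lo: tuple[int, int, int]
    level_dims: tuple[int, int, int]
    values: np.ndarray
    stats: dict
    budget_exceeded: bool = False
    lattice_id: int | None = None
    metadata: dict = field(default_factory=dict)


def choose_level(box_dims, factors, max_points: int) -> tuple[int, bool]:
    """Smallest factor whose downsampled box fits the budget.

    Returns ``(factor, budget_exceeded)``; when even the coarsest level
    overruns the budget the largest factor is returned with the flag set.
    """
    if max_points <= 0:
        raise InvalidBudgetError(f"invalid budget: max_points={max_points}")
    if not factors:
        raise ValueError("factors must be non-empty")
    for f in factors:
        n = math.prod(math.ceil(d / f) for d in box_dims)
        if n <= max_points:
            return f, False
    return factors[-1], True


class VolsegService:
    """Query facade over one database root."""

    def __init__(self, db_root):
        self.db_root = db_root

    def _entry(self, source: str, entry_id: str) -> MultiscaleEntry:
        return load_entry(source, entry_id, self.db_root)

    def get_metadata(self, source: str, entry_id: str) -> dict:
        """Verbatim metadata.json + annotations.json content."""
        entry = self._entry(source, entry_id)
        return {"metadata": entry.metadata, "annotations": entry.annotations}

    def query_box(self, q: BoxQuery) -> SliceResult:
        entry = self._entry(q.source, q.entry_id)
        dims = tuple(entry.metadata["dims"])
        factors = [int(f) for f in entry.metadata["factors"]]

        lo = tuple(max(0, int(v)) for v in q.lo)
        hi_req = q.hi if q.hi is not None else dims
        hi = tuple(min(d, int(v)) for v, d in zip(hi_req, dims))
        if any(a >= b for a, b in zip(lo, hi)):
            raise EmptyRegionError(f"empty region: box [{q.lo}, {q.hi}) clamped to {dims} is empty")
        box_dims = tuple(b - a for a, b in zip(lo, hi))

        if q.channel == "volume":
            levels = entry.volume_levels
        elif q.channel == "lattice":
            if q.lattice_id not in entry.lattice_levels:
                raise NotFoundError(f"not found: lattice {q.lattice_id} in {q.source}/{q.entry_id}")
            levels = entry.lattice_levels[q.lattice_id]
            factors = sorted(levels)
        else:
            raise NotFoundError(f"not found: unknown channel {q.channel!r}")

        factor, exceeded = choose_level(box_dims, factors, q.max_points)
        level_lo = tuple(a // factor for a in lo)
        level_hi = tuple(math.ceil(b / factor) for b in hi)
        arr = levels[factor]
        values = np.asarray(
            arr[level_lo[0] : level_hi[0], level_lo[1] : level_hi[1], level_lo[2] : level_hi[2]]
        )
        if q.channel == "volume":
            stats = entry.metadata["volume_stats"][str(factor)]
        else:
            stats = entry.metadata["lattice_histograms"][str(q.lattice_id)][str(factor)]
        return SliceResult(
            source=q.source,
            entry_id=q.entry_id,
            channel=q.channel,
            factor=factor,
            level_lo=level_lo,
            level_dims=values.shape,
            values=values,
            stats=stats,
            budget_exceeded=exceeded,
            lattice_id=q.lattice_id,
            metadata=entry.metadata,
        )

    def query_meshes(self, source: str, entry_id: str):
        entry = self._entry(source, entry_id)
        if not entry.meshes:
            raise NotFoundError(f"not found: entry {source}/{entry_id} has no meshes")
        return entry

    # --- BinaryCIF assembly ------------------------------------------------

    def build_response(self, result, annotations: list[dict] | None = None) -> bytes:
        """Pack a SliceResult (or mesh entry) into BinaryCIF bytes."""
        if isinstance(result, SliceResult):
            if result.channel == "volume":
                block = self._volume_block(result)
            else:
                block = self._lattice_block(result, annotations or [])
        else:  # MultiscaleEntry with meshes
            block = self._mesh_block(result, annotations or [])
        return bcif.serialize([block])

    def _info_category(self, r: SliceResult) -> bcif.Category:
        md = r.metadata
        names = [
            "source", "entry_id", "channel", "factor", "budget_exceeded",
            "level_x0", "level_y0", "level_z0", "level_nx", "level_ny", "level_nz",
            "orig_nx", "orig_ny", "orig_nz",
        ]
        values = [
            r.source, r.entry_id, r.channel, r.factor, int(r.budget_exceeded),
            *r.level_lo, *r.level_dims, *md["dims"],
        ]
        cols = [
            bcif.Column("field", bcif.encode_string_column(names)),
            bcif.Column("value", bcif.encode_string_column([str(v) for v in values])),
        ]
        extra = {
            "voxel_size": md["voxel_size"],
            "origin": md["origin"],
            "factors": md["factors"],
            "stats": r.stats,
        }
        cols.append(bcif.Column("detail_json", bcif.encode_string_column([json.dumps(extra)] * len(names))))
        return bcif.Category("_volume_info", len(names), cols)

    def _volume_block(self, r: SliceResult) -> bcif.DataBlock:
        flat = np.asarray(r.values, dtype=np.float64).ravel()
        lo, hi = float(r.stats["min"]), float(r.stats["max"])
        if hi > lo:
            payload = bcif.encode_float_array(flat, quantize=(lo, hi, QUANTIZATION_STEPS))
        else:
            # degenerate interval (constant level): ship raw float32, lossless
            payload = bcif.encode_float_array(flat.astype(np.float32))
        data_cat = bcif.Category("_volume_data", flat.size, [bcif.Column("values", payload)])
        return bcif.DataBlock("VOLUME", [self._info_category(r), data_cat])

    def _lattice_block(self, r: SliceResult, annotations: list[dict]) -> bcif.DataBlock:
        flat = np.asarray(r.values, dtype=np.int64).ravel()
        payload = bcif.encode_int_array(flat, run_length=True, delta=True)
        data_cat = bcif.Category("_segmentation_data", flat.size, [bcif.Column("values", payload)])
        segs = [
            a for a in annotations
            if a.get("kind") == "lattice" and a.get("lattice_id") == r.lattice_id
        ]
        table = bcif.Category(
            "_segment_table",
            len(segs),
            [
                bcif.Column("segment_id", bcif.encode_int_array([s["segment_id"] for s in segs], delta=True)),
                bcif.Column("label_value", bcif.encode_int_array([s["label_value"] for s in segs], delta=True)),
                bcif.Column("lattice_id", bcif.encode_int_array([s["lattice_id"] for s in segs])),
                bcif.Column("name", bcif.encode_string_column([s["name"] for s in segs])),
                bcif.Column("colour", bcif.encode_string_column([json.dumps(s["colour"]) for s in segs])),
            ],
        )
        return bcif.DataBlock("SEGMENTATION", [self._info_category(r), data_cat, table])

    def _mesh_block(self, entry: MultiscaleEntry, annotations: list[dict]) -> bcif.DataBlock:
        mesh_ids, vx, vy, vz = [], [], [], []
        t_mesh, t0, t1, t2 = [], [], [], []
        for m in entry.meshes:
            mesh_ids.extend([m.mesh_id] * len(m.vertices))
            vx.append(m.vertices[:, 0]); vy.append(m.vertices[:, 1]); vz.append(m.vertices[:, 2])
            t_mesh.extend([m.mesh_id] * len(m.triangles))
            t0.append(m.triangles[:, 0]); t1.append(m.triangles[:, 1]); t2.append(m.triangles[:, 2])
        cat = np.concatenate
        vert = bcif.Category(
            "_mesh_vertex",
            len(mesh_ids),
            [
                bcif.Column("mesh_id", bcif.encode_int_array(mesh_ids, run_length=True)),
                bcif.Column("x", bcif.encode_float_array(cat(vx) if vx else np.zeros(0))),
                bcif.Column("y", bcif.encode_float_array(cat(vy) if vy else np.zeros(0))),
                bcif.Column("z", bcif.encode_float_array(cat(vz) if vz else np.zeros(0))),
            ],
        )
        tri = bcif.Category(
            "_mesh_triangle",
            len(t_mesh),
            [
                bcif.Column("mesh_id", bcif.encode_int_array(t_mesh, run_length=True)),
                bcif.Column("v0", bcif.encode_int_array(cat(t0) if t0 else [], delta=True)),
                bcif.Column("v1", bcif.encode_int_array(cat(t1) if t1 else [], delta=True)),
                bcif.Column("v2", bcif.encode_int_array(cat(t2) if t2 else [], delta=True)),
            ],
        )
        mesh_segs = [a for a in annotations if a.get("kind") == "mesh"]
        table = bcif.Category(
            "_segment_table",
            len(mesh_segs),
            [
                bcif.Column("segment_id", bcif.encode_int_array([s["segment_id"] for s in mesh_segs], delta=True)),
                bcif.Column("name", bcif.encode_string_column([s["name"] for s in mesh_segs])),
                bcif.Column("mesh_ids", bcif.encode_string_column([json.dumps(s["mesh_ids"]) for s in mesh_segs])),
            ],
        )
        return bcif.DataBlock("MESHES", [vert, tri, table])


# --- WSGI application ------------------------------------------------------


def _json_response(start_response, status: str, payload: dict) -> list[bytes]:
    body = json.dumps(payload).encode()
    start_response(status, [("Content-Type", "application/json"), ("Content-Length", str(len(body)))])
    return [body]


def _parse_triple(text: str) -> tuple[int, int, int]:
    parts = [int(p) for p in text.split(",")]
    if len(parts) != 3:
        raise ValueError(f"expected x,y,z triple, got {text!r}")
    return tuple(parts)


def make_wsgi_app(db_root):
    """Build a WSGI app exposing the query endpoints for one database."""
    service = VolsegService(db_root)

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "")
        query = dict(
            p.split("=", 1) for p in environ.get("QUERY_STRING", "").split("&") if "=" in p
        )
        try:
            parts = [p for p in path.split("/") if p]
            if len(parts) < 4 or parts[0] != "v1":
                raise NotFoundError(f"not found: no route for {path}")
            source, entry_id = parts[1], parts[2]
            max_points = int(query.get("max_points", DEFAULT_MAX_POINTS))
            if parts[3] == "metadata" and len(parts) == 4:
                return _json_response(start_response, "200 OK", service.get_metadata(source, entry_id))
            if parts[3] == "mesh" and len(parts) == 4:
                entry = service.query_meshes(source, entry_id)
                body = service.build_response(entry, entry.annotations)
                start_response("200 OK", [("Content-Type", "application/octet-stream")])
                return [body]
            if parts[3] == "volume" and len(parts) == 7 and parts[4] == "box":
                q = BoxQuery(source, entry_id, "volume",
                             lo=_parse_triple(parts[5]), hi=_parse_triple(parts[6]),
                             max_points=max_points)
            elif parts[3] == "segmentation" and len(parts) == 8 and parts[5] == "box":
                q = BoxQuery(source, entry_id, "lattice", lattice_id=int(parts[4]),
                             lo=_parse_triple(parts[6]), hi=_parse_triple(parts[7]),
                             max_points=max_points)
            else:
                raise NotFoundError(f"not found: no route for {path}")
            result = service.query_box(q)
            annotations = service.get_metadata(source, entry_id)["annotations"]
            body = service.build_response(result, annotations)
            start_response("200 OK", [("Content-Type", "application/octet-stream")])
            return [body]
        except NotFoundError as exc:
            return _json_response(start_response, "404 Not Found",
                                  {"error": {"code": exc.code, "message": str(exc)}})
        except (VolsegError, ValueError) as exc:
            code = getattr(exc, "code", "bad request")
            return _json_response(start_response, "400 Bad Request",
                                  {"error": {"code": code, "message": str(exc)}})

    return app


def serve(db_root, host: str = "127.0.0.1", port: int = 9000):  # pragma: no cover
    """Run the WSGI app with the stdlib reference server (blocking)."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, make_wsgi_app(db_root)) as httpd:
        httpd.serve_forever()
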