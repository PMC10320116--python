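"""Synthetic volumes, segmentations and meshes for the ingest pipeline.

Everything here is seed-deterministic: the same :class:`FixtureSpec`
always produces bit-identical arrays and byte-identical files, so tests
and demos never need to download repository data.  Volumes are sums of
isotropic Gaussian blobs plus optional Gaussian noise (a crude stand-in
for a low-pass-filtered density map); lattice segmentations are
non-overlapping digital spheres (voxel centre strictly inside the
radius); meshes are subdivided icosahedra projected onto a sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import PlacementFailedError
from .sff_io import (
    ExternalReference,
    Lattice,
    Mesh,
    Segment,
    SegmentationSet,
    default_colour,
    write_sff,
)
from .volume_io import VolumeGrid, write_map


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed fixes every output."""

    dims: tuple[int, int, int] = (64, 64, 64)
    n_blobs: int = 4
    n_segments: int = 3
    seed: int = 0
    noise_sigma: float = 0.05
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_blob_volume(spec: FixtureSpec) -> VolumeGrid:
    """Sum of seeded Gaussian blobs plus Gaussian noise."""
    if any(d < 4 for d in spec.dims):
        raise ValueError(f"dims must be >= 4 per axis, got {spec.dims}")
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    data = np.zeros(spec.dims, dtype=np.float64)
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", sparse=True
    )
    width = max(2.0, min(spec.dims) / 8.0)
    for _ in range(spec.n_blobs):
        centre = rng.uniform(0, np.asarray(spec.dims) - 1)
        amplitude = rng.uniform(0.5, 2.0)
        r2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
        data += amplitude * np.exp(-r2 / (2 * width**2))
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, spec.dims)
    return VolumeGrid(
        data=data.astype(np.float32), voxel_size=spec.voxel_size, origin=spec.origin
    )


def digital_sphere_mask(dims, centre, radius: float) -> np.ndarray:
    """Voxels whose centre lies strictly within ``radius`` of ``centre``."""
    x, y, z = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]),
        indexing="ij", sparse=True,
    )
    r2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
    return r2 < radius**2


def make_sphere_segmentation(
    spec: FixtureSpec, grid: VolumeGrid, max_retries: int = 200
) -> SegmentationSet:
    """Non-overlapping digital spheres labelled 1..n with annotations.

    Sphere centres are drawn uniformly; a draw that would overlap an
    earlier (smaller-labelled) sphere is retried up to ``max_retries``
    times before :class:`PlacementFailedError` is raised.
    """
    if tuple(spec.dims) != tuple(grid.dims):
        raise ValueError("spec dims must match the volume grid")
    rng = np.random.default_rng(spec.seed + 1)
    dims = np.asarray(spec.dims)
    radius = max(2.0, min(spec.dims) / 8.0)
    labels = np.zeros(spec.dims, dtype=np.uint8 if spec.n_segments < 256 else np.uint16)
    for k in range(1, spec.n_segments + 1):
        for _ in range(max_retries):
            centre = rng.uniform(radius, dims - 1 - radius)
            mask = digital_sphere_mask(spec.dims, centre, radius)
            if not (labels[mask] > 0).any():
                labels[mask] = k
                break
        else:
            raise PlacementFailedError(
                f"placement failed: could not fit sphere {k} of {spec.n_segments} "
                f"(radius {radius}) after {max_retries} tries"
            )
    segments = [
        Segment(
            segment_id=k,
            kind="lattice",
            lattice_id=0,
            label_value=k,
            name=f"segment_{k}",
            description=f"synthetic digital sphere {k}",
            colour=default_colour(k),
            external_references=[
                ExternalReference("GO", f"GO:{7000000 + k:07d}", f"synthetic term {k}")
            ],
        )
        for k in range(1, spec.n_segments + 1)
    ]
    return SegmentationSet(
        name=f"synthetic segmentation (seed {spec.seed})",
        lattices=[Lattice(0, labels)],
        segments=segments,
    )


# --- icosphere -------------------------------------------------------------

_PHI = (1.0 + 5.0**0.5) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int32,
)


def make_icosphere(subdivisions: int = 0, mesh_id: int = 0, radius: float = 1.0,
                   centre=(0.0, 0.0, 0.0)) -> Mesh:
    """Unit icosahedron subdivided ``s`` times; V = 10*4^s + 2, T = 20*4^s."""
    if not 0 <= subdivisions <= 4:
        raise ValueError("subdivisions must be in [0, 4]")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts_list = list(map(tuple, verts))
        index = {v: i for i, v in enumerate(verts_list)}
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint_cache:
                m = verts[a] + verts[b]
                m /= np.linalg.norm(m)
                index_new = len(verts_list)
                verts_list.append(tuple(m))
                midpoint_cache[key] = index_new
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(verts_list, dtype=np.float64)
        faces = np.asarray(new_faces, dtype=np.int32)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    verts = verts * radius + np.asarray(centre, dtype=np.float64)
    return Mesh(mesh_id=mesh_id, vertices=verts, triangles=faces)


def make_entry_files(spec: FixtureSpec, out_dir, with_mesh: bool = True):
    """Write a matching (map, sff) preprocessor input pair.

    The mesh (one icosphere centred in the volume, radius a quarter of
    the smallest physical extent) is attached as an extra mesh-kind
    segment so both segmentation kinds flow through the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = make_blob_volume(spec)
    seg = make_sphere_segmentation(spec, grid)
    if with_mesh:
        extent = np.asarray(spec.dims) * np.asarray(spec.voxel_size)
        centre = np.asarray(spec.origin) + extent / 2.0
        sphere = make_icosphere(
            subdivisions=1, mesh_id=0, radius=float(extent.min()) / 4.0, centre=centre
        )
        seg.meshes.append(sphere)
        seg.segments.append(
            Segment(
                segment_id=spec.n_segments + 1,
                kind="mesh",
                mesh_ids=[0],
                name=f"segment_{spec.n_segments + 1}",
                description="synthetic icosphere surface",
                colour=default_colour(spec.n_segments + 1),
                external_references=[
                    ExternalReference("GO", f"GO:{7000000 + spec.n_segments + 1:07d}",
                                      "synthetic term")
                ],
            )
        )
    map_path = out_dir / f"fixture_{spec.seed}.mrc"
    sff_path = out_dir / f"fixture_{spec.seed}.hff"
    write_map(grid, map_path, mode=2)
    write_sff(seg, sff_path)
    return map_path, sff_path
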