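# Methods

## Pipeline model

`volseg` treats a dataset as one *entry* in an internal database:
a volume pyramid, zero or more segmentation-lattice pyramids, zero or
more single-resolution triangle meshes, and two JSON documents (metadata
and per-segment annotations). Queries are stateless reads against this
store; nothing is computed per request beyond slicing and encoding.

## Canonical volume frame

MRC/CCP4 files may store axes in any of the six (MAPC, MAPR, MAPS)
permutations. On read the array is permuted to a canonical `[x][y][z]`
index order; all external coordinates (query boxes, lattice dims) are
0-based, half-open, in this frame. Voxel size is `cell length / sample
count` per crystallographic axis. The origin is taken from the ORIGIN
header words when any is nonzero, otherwise from
`NXSTART/NYSTART/NZSTART × voxel_size` (the two conventions coexist in
deposited maps; ORIGIN wins because it is the one modern writers fill).
Header statistics are always recomputed from the data — deposited maps
frequently carry stale values. Modes 0/1/2 are read and written; mode 6
(uint16) is read-only. Endianness follows the machine stamp, with a
byte-swap fallback that engages only when the straight parse is
implausible (non-positive or absurd dims) and the swapped header is
plausible.

## EMDB-SFF subset

The reader/writer covers the schema branches the pipeline consumes:
lattice byte-streams (zlib-compressed, base64-wrapped, C order), mesh
vertex/triangle arrays, and per-segment biological annotation (name,
description, colour, external references). Shape primitives, software
lists and non-identity transforms are out of scope; a file declaring a
non-identity lattice transform is rejected outright, because silently
mis-registering a segmentation is worse than refusing it. The written
`version` field is `0.8.0`, the schema generation this layout follows.
Labels are held in the smallest unsigned dtype that fits the maximum
label (memory; behaviour is dtype-invariant). Segments lacking a colour
get a deterministic golden-angle palette colour keyed by segment id so
repeated preprocessing runs agree exactly.

## Downsampling

* **Intensities:** 2×2×2 arithmetic box mean. Output dims are
  `ceil(dim/2)`; boundary blocks average only existing voxels (no
  padding values are invented). On even dims the global mean is
  conserved to ~1e-6 relative (float32 accumulation in float64).
* **Labels:** 2×2×2 majority vote; ties break to the smallest label, so
  results do not depend on iteration order. Background 0 votes like any
  label. The label set of a coarser level is always a subset of the
  finer level's.

Box mean and majority vote were chosen as the most defensible isotropic
kernels: averaging preserves integrated density, and voting preserves
label identity where interpolation would fabricate nonexistent labels.
Both are isolated behind `multiscale` so alternative kernels can be
swapped without touching the store or server.

### Level planning

Factors are powers of two starting at 1. A coarser level is appended
while the current finest level still holds at least
`pyramid.max_total_voxels` voxels (an exclusive cap: a level strictly
under the cap terminates the plan) and halving would not shrink the
largest axis below `pyramid.min_extent`. Defaults:
`min_extent = 32`, `max_total_voxels = 2²² ≈ 4.2 M voxels` — i.e. maps
under ~160³ stay single-level by default, which is the right call for
interactive streaming but can be overridden per run
(`--min-extent/--max-voxels` on the CLI, keyword arguments in
`build_entry`).

## Storage layout

`{root}/{source}/{entry_id}/volume/{factor}`,
`.../segmentation/{lattice_id}/{factor}`, `.../mesh/{mesh_id}/{vertices,triangles}`
as Zarr v3 arrays (64³ chunks, gzip), plus `metadata.json` and
`annotations.json` sidecars. Sidecar JSON rather than array attributes:
the documents are diffable and the server returns them verbatim. Keys
are sanitized to `[a-z0-9_-]`; `format_version` in metadata versions the
layout. Two segmentations of one map are two entries sharing nothing but
their (identical) volume arrays — this is what makes side-by-side
comparison of segmentations trivial. Single-writer, many-reader; no
locking.

## BinaryCIF encoding

Standard composable codecs (delta, run-length, 1/2-byte integer packing,
fixed-point, interval quantization, string dictionary) over a
MessagePack container (`encoder`, `version`, `dataBlocks`). Integer
chains are lossless by construction and property-tested as such;
the lossy float steps obey `|err| ≤ 0.5/factor` (fixed point) and
`|err| ≤ (hi−lo)/(2(steps−1))` (interval quantization). Default chains:

* volume floats → interval quantization, 255 steps over the served
  level's `[min, max]` → delta → integer packing (worst-case error
  `(max−min)/508`, roughly 1 byte/voxel on the wire);
* labels → run-length → delta → integer packing;
* mesh vertices → raw float64 bytes (lossless); triangle indices →
  delta → packing (lossless).

A constant volume level (degenerate quantization interval) is shipped as
raw float32 instead — lossless and unambiguous. Packing width is chosen
by measuring the candidate packed sizes; plain 32-bit storage is kept
when packing would not help. 32-bit overflow anywhere in an integer
chain raises rather than wrapping.

## Query semantics

The budget is expressed in *points* (returned values), not bytes, which
keeps the contract codec-independent; a byte budget can be layered on
top by dividing by bytes-per-point. Level selection takes the smallest
factor whose level-space box fits the budget; if none fits, the coarsest
level is returned with `budget_exceeded` set (the client still gets the
best available approximation). The level-space box is
`[⌊lo/f⌋, ⌈hi/f⌉)` — it always covers the requested region. Selection
is monotone: a larger budget never yields a coarser factor. Default
budget when omitted: 10⁶ points.

The HTTP surface is a thin WSGI application (stdlib `wsgiref`) over the
same service object; errors are structured JSON with the package's
stable error codes. Authentication, caching and CORS are out of scope.

## Synthetic data

The fixtures module generates all test inputs programmatically:

* volumes: a sum of `n_blobs` isotropic Gaussians (width `min(dims)/8`,
  amplitudes 0.5–2) plus Gaussian noise (default σ = 0.05) — emulating a
  smooth low-pass-filtered density with shot noise;
* lattice segmentations: non-overlapping digital spheres (voxel centre
  strictly inside the radius, so counts are reproducible), labels 1..n,
  each with a generated name, palette colour and one synthetic external
  reference ("GO", synthetic accession);
* meshes: subdivided icosahedra (V = 10·4ˢ+2, T = 20·4ˢ) projected onto
  the sphere.

Everything is seed-deterministic down to the output bytes (fixed MRC
label, HDF5 without timestamps). What these fixtures do **not** emulate:
anisotropic voxels, real molecular density correlations, segmentation
errors, multi-lattice files, very large grids. Passing tests therefore
demonstrate the correctness of the machinery (formats, pyramids, codecs,
budget logic), not robustness to every dialect quirk found in deposited
data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 64³
end-to-end entries (with `min_extent=8`, `max_voxels=4096` to force a
4-level pyramid), 8³ oracle grids × 100 seeds, 1000-array codec sweeps,
and >10⁴ level-selection cases — sizes chosen so the whole suite runs in
seconds on one CPU while still exercising odd dims, edge blocks and every
codec path. Comparisons against brute-force oracles are exact for
integer data and use 1e-6 absolute/relative tolerance for float
accumulation differences. Degenerate inputs (empty arrays, empty boxes,
constant fields) have explicit, tested behaviour throughout.

## Known limitations

* No crystallographic symmetry expansion; non-P1 spacegroups are read
  but ignored.
* EMDB-SFF XML/JSON encodings and shape-primitive segmentations are not
  parsed; application-specific formats (Amira/iMod/Segger) are assumed
  to be converted to EMDB-SFF upstream.
* Meshes are stored single-resolution (no decimation pyramid).
* The store is a local filesystem layout; no object-store backend.
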