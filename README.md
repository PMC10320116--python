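# volseg

Server-side machinery for streaming large 3D imaging volumes and their
segmentations to interactive viewers. Cryo-EM, volume-EM and light-microscopy
maps routinely reach gigavoxel sizes; a browser client cannot download them
whole, but it can render a region at the resolution its point budget allows.
`volseg` implements the pipeline that makes this possible:

1. **Preprocess** a density map (CCP4/MRC `.map`/`.mrc`/`.ccp4`) together with
   an optional segmentation (EMDB-SFF `.hff`, lattice and/or mesh kinds, with
   per-segment biological annotations) into a **multiscale database entry**:
   chunked, compressed Zarr arrays holding the original grid plus a pyramid of
   2×-downsampled levels, with per-level statistics and the annotations as
   sidecar JSON.
2. **Query** any half-open voxel box `[lo, hi)` with a *point budget*
   `max_points`. The service picks the smallest downsampling factor `f` such
   that `∏ᵢ ⌈(hiᵢ−loᵢ)/f⌉ ≤ max_points` and returns that level's slice — so
   responses always fit the client's budget, degrading resolution instead of
   failing.
3. **Encode** responses as BinaryCIF: CIF-style categories whose columns are
   compressed by composable codecs (delta, run-length, integer packing,
   fixed-point, interval quantization, string dictionaries) inside a
   MessagePack container. Label and mesh channels decode exactly; volume
   intensities use 255-step interval quantization over the level's
   `[min, max]`, giving a worst-case error of `(max−min)/508`.

Downsampling uses a 2×2×2 box mean for intensities and a 2×2×2 majority vote
for labels (ties to the smallest label), so the global mean is conserved on
even dims and no spurious label values are ever invented.

Intended users: groups hosting their own volume/segmentation collections, and
anyone needing a self-contained, testable implementation of the
map → multiscale store → size-budgeted BinaryCIF pipeline.

## Worked example

Everything below uses synthetic inputs generated by the package itself
(a 64³ volume of Gaussian blobs, three digital-sphere segments, one
icosphere mesh):

```sh
$ volseg fixtures --dims 64 --segments 3 --seed 7 --out fix
wrote fix/fixture_7.mrc and fix/fixture_7.hff

$ volseg preprocess --map fix/fixture_7.mrc --sff fix/fixture_7.hff \
    --source custom --id demo --db db --min-extent 8 --max-voxels 4096
stored custom/demo at db/custom/demo (levels [1, 2, 4, 8])

$ volseg query --db db custom demo --box 0 0 0 64 64 64 \
    --max-points 100000 --out slice.bcif
wrote 34499 bytes (factor 2, 32768 values, budget_exceeded=False)

$ volseg query --db db custom demo --channel lattice --lattice-id 0 \
    --box 0 0 0 64 64 64 --max-points 1000000 --out labels.bcif
wrote 7651 bytes (factor 1, 262144 values, budget_exceeded=False)
```

The full 64³ box holds 262 144 voxels. With a budget of 100 000 points the
server serves factor 2 (32 768 values, 34 499 bytes on the wire instead of
1 MiB raw). The label query fits the budget at full resolution and
compresses to 7 651 bytes because run-length + delta + integer packing
collapse the large background runs. Decoding in Python:

```python
from volseg import bcif_codec as bc
import numpy as np

block = bc.deserialize(open("slice.bcif", "rb").read())[0]
cats = {c.name: c for c in block.categories}
vals = np.asarray(bc.decode_column(cats["_volume_data"].columns[0].payload))
print("decoded", vals.size, "values; mean %.4f" % vals.mean())
# decoded 32768 values; mean 0.1114
```

`volseg serve --db db --port 9000` exposes the same queries over HTTP
(`GET /v1/{source}/{id}/metadata`, `.../volume/box/x0,y0,z0/x1,y1,z1?max_points=N`,
`.../segmentation/{lattice_id}/box/...`, `.../mesh`).

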