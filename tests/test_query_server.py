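"""Level selection, box queries, BinaryCIF responses, and the WSGI surface."""

import json
import math
from io import BytesIO

import numpy as np
import pytest

from volseg import bcif_codec as bc
from volseg import fixtures as fx
from volseg.errors import EmptyRegionError, InvalidBudgetError, NotFoundError
from volseg.multiscale import LevelPlan
from volseg.query_server import (
    BoxQuery,
    VolsegService,
    choose_level,
    make_wsgi_app,
)
from volseg.store import build_entry, save_entry


def brute_force_choose(box_dims, factors, max_points):
    fits = [f for f in factors
            if math.prod(math.ceil(d / f) for d in box_dims) <= max_points]
    return (min(fits), False) if fits else (max(factors), True)


@pytest.fixture(scope="module")
def db(tmp_path_factory):
    root = tmp_path_factory.mktemp("db")
    spec = fx.FixtureSpec(dims=(32, 32, 32), n_blobs=3, n_segments=2, seed=5)
    grid = fx.make_blob_volume(spec)
    seg = fx.make_sphere_segmentation(spec, grid)
    seg.meshes.append(fx.make_icosphere(1, mesh_id=0, radius=8.0, centre=(16, 16, 16)))
    seg.segments.append(fx.Segment(segment_id=50, kind="mesh", mesh_ids=[0], name="shell"))
    entry = build_entry("emdb", "q1", grid, seg, plan=LevelPlan((1, 2, 4)))
    save_entry(entry, root)
    flat = build_entry("custom", "flat",
                       fx.make_blob_volume(fx.FixtureSpec(dims=(16, 16, 16), n_blobs=0,
                                                          noise_sigma=0.0, seed=1)),
                       plan=LevelPlan((1, 2)))
    save_entry(flat, root)
    return {"root": root, "grid": grid, "seg": seg}


@pytest.fixture()
def service(db):
    return VolsegService(db["root"])


# --- choose_level ----------------------------------------------------------


def test_choose_level_examples():
    assert choose_level((64, 64, 64), [1, 2, 4], 300000) == (1, False)
    assert choose_level((64, 64, 64), [1, 2, 4], 100000) == (2, False)
    assert choose_level((64, 64, 64), [1, 2], 10) == (2, True)


def test_choose_level_invalid_budget():
    with pytest.raises(InvalidBudgetError):
        choose_level((4, 4, 4), [1], 0)


def test_choose_level_exhaustive_against_brute_force():
    """>= 10^4 (box, budget) cases against a brute-force minimal-factor search."""
    factors = [1, 2, 4, 8]
    budgets = [1, 7, 63, 64, 100, 512, 1000, 4096, 10**5, 10**7]
    cases = 0
    for dx in range(1, 11):
        for dy in range(2, 70, 6):
            for dz in range(3, 90, 9):
                for b in budgets:
                    assert choose_level((dx, dy, dz), factors, b) == \
                        brute_force_choose((dx, dy, dz), factors, b)
                    cases += 1
    assert cases >= 10**4


def test_choose_level_monotone_in_budget(rng):
    factors = [1, 2, 4, 8]
    for _ in range(300):
        dims = tuple(int(v) for v in rng.integers(1, 100, size=3))
        b1, b2 = sorted(int(v) for v in rng.integers(1, 10**6, size=2))
        f1, _ = choose_level(dims, factors, b1)
        f2, _ = choose_level(dims, factors, max(b2, b1))
        assert f2 <= f1


# --- metadata / query_box --------------------------------------------------


def test_metadata_echo(service, db):
    doc = service.get_metadata("emdb", "q1")
    assert doc["metadata"]["factors"] == [1, 2, 4]
    names = {a["name"] for a in doc["annotations"]}
    assert {"segment_1", "segment_2", "shell"} <= names
    with pytest.raises(NotFoundError):
        service.get_metadata("emdb", "nope")


def test_full_box_generous_budget_is_identity(service, db):
    r = service.query_box(BoxQuery("emdb", "q1", "volume", max_points=10**8))
    assert r.factor == 1 and not r.budget_exceeded
    assert np.array_equal(r.values, db["grid"].data)


def test_corner_box_matches_slice_oracle(service, db):
    r = service.query_box(BoxQuery("emdb", "q1", "volume", lo=(0, 0, 0), hi=(2, 2, 2),
                                   max_points=10**6))
    assert r.factor == 1
    assert np.array_equal(r.values, db["grid"].data[:2, :2, :2])


def test_budget_forces_coarser_level_constant_volume(service):
    r = service.query_box(BoxQuery("custom", "flat", "volume", max_points=600))
    assert r.factor == 2
    assert np.all(r.values == r.values.flat[0])


def test_budget_respected_unless_flagged(service, rng):
    for _ in range(20):
        budget = int(rng.integers(1, 40000))
        r = service.query_box(BoxQuery("emdb", "q1", "volume", max_points=budget))
        assert r.values.size <= budget or r.budget_exceeded


def test_lattice_query_exact(service, db):
    r = service.query_box(BoxQuery("emdb", "q1", "lattice", lattice_id=0, max_points=10**8))
    assert np.array_equal(r.values, db["seg"].lattices[0].data)
    with pytest.raises(NotFoundError):
        service.query_box(BoxQuery("emdb", "q1", "lattice", lattice_id=7))


def test_empty_region_rejected(service):
    with pytest.raises(EmptyRegionError):
        service.query_box(BoxQuery("emdb", "q1", "volume", lo=(40, 0, 0), hi=(50, 2, 2)))


def test_level_box_covers_request(service):
    """floor/ceil level mapping always covers the requested region."""
    r = service.query_box(BoxQuery("emdb", "q1", "volume", lo=(3, 5, 7), hi=(19, 21, 23),
                                   max_points=300))
    f = r.factor
    assert r.level_lo == (3 // f, 5 // f, 7 // f)
    assert all(lo + n >= math.ceil(hi / f)
               for lo, n, hi in zip(r.level_lo, r.level_dims, (19, 21, 23)))


# --- responses -------------------------------------------------------------


def _decode(payload):
    block = bc.deserialize(payload)[0]
    return block, {c.name: c for c in block.categories}


def test_volume_response_decodes_within_codec_bound(service, db):
    r = service.query_box(BoxQuery("emdb", "q1", "volume", max_points=10**8))
    block, cats = _decode(service.build_response(r, []))
    values = np.asarray(bc.decode_column(cats["_volume_data"].columns[0].payload))
    assert cats["_volume_data"].row_count == r.values.size
    bound = (r.stats["max"] - r.stats["min"]) / 508
    assert np.abs(values - r.values.ravel()).max() <= bound + 1e-12


def test_constant_volume_response_is_lossless(service):
    r = service.query_box(BoxQuery("custom", "flat", "volume", max_points=10**8))
    block, cats = _decode(service.build_response(r, []))
    values = np.asarray(bc.decode_column(cats["_volume_data"].columns[0].payload))
    assert np.array_equal(values.astype(np.float32), r.values.ravel())


def test_lattice_response_decodes_exactly(service, db):
    ann = service.get_metadata("emdb", "q1")["annotations"]
    r = service.query_box(BoxQuery("emdb", "q1", "lattice", lattice_id=0, max_points=10**8))
    block, cats = _decode(service.build_response(r, ann))
    values = np.asarray(bc.decode_column(cats["_segmentation_data"].columns[0].payload))
    assert np.array_equal(values.reshape(r.values.shape), db["seg"].lattices[0].data)
    table = bc.category_as_dict(cats["_segment_table"])
    assert table["name"] == ["segment_1", "segment_2"]
    assert np.asarray(table["label_value"]).tolist() == [1, 2]


def test_mesh_response_intact(service, db):
    entry = service.query_meshes("emdb", "q1")
    ann = service.get_metadata("emdb", "q1")["annotations"]
    block, cats = _decode(service.build_response(entry, ann))
    vert = bc.category_as_dict(cats["_mesh_vertex"])
    tri = bc.category_as_dict(cats["_mesh_triangle"])
    mesh = db["seg"].meshes[0]
    assert cats["_mesh_vertex"].row_count == len(mesh.vertices)
    assert np.array_equal(np.asarray(vert["x"]), mesh.vertices[:, 0])
    got_tris = np.stack([tri["v0"], tri["v1"], tri["v2"]], axis=1)
    assert np.array_equal(got_tris, mesh.triangles)
    assert int(np.asarray(got_tris).max()) < len(mesh.vertices)
    with pytest.raises(NotFoundError):
        service.query_meshes("custom", "flat")


# --- WSGI surface ----------------------------------------------------------


def _call(app, path, query=""):
    status_headers = {}

    def start_response(status, headers):
        status_headers["status"] = status

    environ = {"PATH_INFO": path, "QUERY_STRING": query, "REQUEST_METHOD": "GET",
               "wsgi.input": BytesIO()}
    body = b"".join(app(environ, start_response))
    return status_headers["status"], body


def test_http_metadata_endpoint(db):
    app = make_wsgi_app(db["root"])
    status, body = _call(app, "/v1/emdb/q1/metadata")
    assert status == "200 OK"
    assert json.loads(body)["metadata"]["factors"] == [1, 2, 4]


def test_http_volume_box_endpoint(db):
    app = make_wsgi_app(db["root"])
    status, body = _call(app, "/v1/emdb/q1/volume/box/0,0,0/32,32,32", "max_points=100")
    assert status == "200 OK"
    block = bc.deserialize(body)[0]
    names = [c.name for c in block.categories]
    assert "_volume_data" in names and "_volume_info" in names


def test_http_segmentation_and_mesh_endpoints(db):
    app = make_wsgi_app(db["root"])
    status, body = _call(app, "/v1/emdb/q1/segmentation/0/box/0,0,0/32,32,32")
    assert status == "200 OK"
    assert {"_segmentation_data", "_segment_table"} <= {
        c.name for c in bc.deserialize(body)[0].categories}
    status, body = _call(app, "/v1/emdb/q1/mesh")
    assert status == "200 OK"
    assert "_mesh_vertex" in {c.name for c in bc.deserialize(body)[0].categories}


def test_http_errors_are_structured_json(db):
    app = make_wsgi_app(db["root"])
    status, body = _call(app, "/v1/emdb/missing/metadata")
    assert status == "404 Not Found"
    assert json.loads(body)["error"]["code"] == "not found"
    status, body = _call(app, "/v1/emdb/q1/volume/box/0,0,0/32,32,32", "max_points=0")
    assert status == "400 Bad Request"
    assert json.loads(body)["error"]["code"] == "invalid budget"
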