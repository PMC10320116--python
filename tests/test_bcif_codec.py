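"""BinaryCIF encodings: losslessness, error bounds, container round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volseg import bcif_codec as bc
from volseg.errors import (
    BcifError,
    FixedPointOverflowError,
    InvalidPackingError,
    InvalidQuantizationError,
    UnsupportedVersionError,
)

int32s = st.integers(min_value=-(2**31), max_value=2**31 - 1)
int_arrays = st.lists(int32s, max_size=60)


# --- delta -----------------------------------------------------------------


def test_delta_example():
    deltas, origin = bc.encode_delta([1, 2, 3])
    assert deltas.tolist() == [0, 1, 1] and origin == 1


def test_delta_empty():
    deltas, origin = bc.encode_delta([])
    assert deltas.size == 0 and origin == 0
    assert bc.decode_delta(deltas, origin).size == 0


@settings(max_examples=300, derandomize=True)
@given(int_arrays)
def test_delta_roundtrip(values):
    deltas, origin = bc.encode_delta(values)
    assert bc.decode_delta(deltas, origin).tolist() == values


# --- run length ------------------------------------------------------------


def test_rle_examples():
    pairs, n = bc.encode_rle([1, 1, 1, 2, 2])
    assert pairs.tolist() == [1, 3, 2, 2] and n == 5
    pairs, n = bc.encode_rle([5])
    assert pairs.tolist() == [5, 1] and n == 1


@settings(max_examples=300, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=4), max_size=80))
def test_rle_roundtrip(values):
    pairs, n = bc.encode_rle(values)
    assert bc.decode_rle(pairs, n).tolist() == values


# --- integer packing -------------------------------------------------------


def test_packing_examples():
    assert bc.pack_integers([1200], 1, True).tolist() == [255, 255, 255, 255, 180]
    assert bc.pack_integers([100], 1, True).tolist() == [100]


def test_packing_invalid_width():
    with pytest.raises(InvalidPackingError):
        bc.pack_integers([1], 3, True)


def test_packing_zero_and_bound_multiples():
    for vals in ([0], [255], [510], [-128], [127], [0, 255, 0]):
        for bc_width in (1, 2):
            unsigned = min(vals) >= 0
            packed = bc.pack_integers(vals, bc_width, unsigned)
            got = bc.unpack_integers(packed, bc_width, unsigned, len(vals))
            assert got.tolist() == vals, (vals, bc_width, unsigned)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(min_value=-(2**20), max_value=2**20), max_size=30),
       st.sampled_from([1, 2]))
def test_packing_roundtrip_signed(values, byte_count):
    packed = bc.pack_integers(values, byte_count, unsigned=False)
    assert bc.unpack_integers(packed, byte_count, False, len(values)).tolist() == values


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=2**20), max_size=30),
       st.sampled_from([1, 2]))
def test_packing_roundtrip_unsigned(values, byte_count):
    packed = bc.pack_integers(values, byte_count, unsigned=True)
    assert bc.unpack_integers(packed, byte_count, True, len(values)).tolist() == values


# --- fixed point / interval quantization -----------------------------------


def test_fixed_point_examples():
    assert bc.encode_fixed_point([1.001, 2.5], 1000).tolist() == [1001, 2500]
    assert bc.encode_fixed_point([3.0, -4.0], 1).tolist() == [3, -4]


def test_fixed_point_error_bound(rng):
    values = rng.uniform(-10, 10, size=2000)
    codes = bc.encode_fixed_point(values, 1000)
    back = bc.decode_fixed_point(codes, 1000)
    assert np.abs(back - values).max() <= 0.5 / 1000 + 1e-12


def test_fixed_point_overflow():
    with pytest.raises(FixedPointOverflowError):
        bc.encode_fixed_point([1e9], 1e6)


def test_interval_quantization_endpoints_and_constant():
    codes = bc.encode_interval_quantization([0.0, 1.0], 0.0, 1.0, 255)
    assert codes.tolist() == [0, 254]
    const = bc.encode_interval_quantization([0.3] * 5, 0.0, 1.0, 100)
    assert len(set(const.tolist())) == 1


def test_interval_quantization_error_bound(rng):
    lo, hi, steps = -3.0, 7.0, 255
    values = rng.uniform(lo, hi, size=2000)
    codes = bc.encode_interval_quantization(values, lo, hi, steps)
    back = bc.decode_interval_quantization(codes, lo, hi, steps)
    assert np.abs(back - values).max() <= (hi - lo) / (2 * (steps - 1)) + 1e-12


def test_interval_quantization_invalid():
    with pytest.raises(InvalidQuantizationError):
        bc.encode_interval_quantization([0.0], 0.0, 1.0, 1)
    with pytest.raises(InvalidQuantizationError):
        bc.encode_interval_quantization([0.0], 2.0, 1.0, 10)


# --- string arrays ---------------------------------------------------------


def test_string_array_example():
    data, offsets, indices = bc.encode_string_array(["a", "b", "a"])
    assert data == "ab"
    assert offsets.tolist() == [0, 1, 2]
    assert indices.tolist() == [0, 1, 0]


def test_string_array_absent_values():
    data, offsets, indices = bc.encode_string_array([None, None])
    assert indices.tolist() == [-1, -1]
    assert bc.decode_string_array(data, offsets, indices) == [None, None]


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.one_of(st.none(), st.text(max_size=6)), max_size=30))
def test_string_array_roundtrip(values):
    data, offsets, indices = bc.encode_string_array(values)
    assert bc.decode_string_array(data, offsets, indices) == values


# --- composed chains -------------------------------------------------------


@settings(max_examples=250, derandomize=True)
@given(st.lists(st.integers(min_value=-(2**25), max_value=2**25), max_size=50),
       st.booleans(), st.booleans())
def test_integer_chains_lossless(values, delta, run_length):
    enc = bc.encode_int_array(values, delta=delta, run_length=run_length)
    assert np.asarray(bc.decode_column(enc)).tolist() == values


def test_many_random_chain_roundtrips(rng):
    """1000 random arrays through the default label chain, all exact."""
    for _ in range(1000):
        n = int(rng.integers(0, 50))
        values = rng.integers(-1000, 1000, size=n).tolist()
        enc = bc.encode_int_array(values, delta=True, run_length=True)
        assert np.asarray(bc.decode_column(enc)).tolist() == values


def test_quantized_float_chain_bound(rng):
    values = rng.normal(size=500)
    lo, hi = float(values.min()), float(values.max())
    enc = bc.encode_float_array(values, quantize=(lo, hi, 255))
    back = np.asarray(bc.decode_column(enc))
    assert np.abs(back - values).max() <= (hi - lo) / 508 + 1e-12


def test_raw_float_chain_is_lossless(rng):
    values = rng.normal(size=100).astype(np.float32)
    enc = bc.encode_float_array(values)
    assert np.array_equal(np.asarray(bc.decode_column(enc), dtype=np.float32), values)


def test_rle_friendly_raster_compresses():
    """A label raster with few runs must beat raw 4-byte storage."""
    raster = np.repeat([0, 1, 0, 2, 0, 3, 0, 4], 500)
    enc = bc.encode_int_array(raster, delta=True, run_length=True)
    assert len(enc["data"]) < raster.size * 4


# --- container -------------------------------------------------------------


def _one_block():
    col = bc.Column("values", bc.encode_int_array([3, 1, 4, 1, 5], delta=True))
    return bc.DataBlock("TEST", [bc.Category("_numbers", 5, [col])])


def test_container_roundtrip_empty():
    assert bc.deserialize(bc.serialize([])) == []


def test_container_roundtrip_one_category():
    blocks = bc.deserialize(bc.serialize([_one_block()]))
    assert blocks[0].header == "TEST"
    cat = blocks[0].categories[0]
    assert cat.name == "_numbers" and cat.row_count == 5
    assert np.asarray(bc.decode_column(cat.columns[0].payload)).tolist() == [3, 1, 4, 1, 5]


def test_truncated_container_rejected():
    raw = bc.serialize([_one_block()])
    with pytest.raises(BcifError):
        bc.deserialize(raw[: len(raw) // 2])


def test_version_mismatch_rejected():
    import msgpack

    doc = msgpack.unpackb(bc.serialize([]), raw=False)
    doc["version"] = "9.0.0"
    with pytest.raises(UnsupportedVersionError):
        bc.deserialize(msgpack.packb(doc))


def test_garbage_bytes_rejected():
    with pytest.raises(BcifError):
        bc.deserialize(b"\xc1\xc1\xc1")
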