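"""BinaryCIF columnar encoding and container serialization.

BinaryCIF represents CIF-style categories as columns of typed arrays,
each compressed by a chain of composable encodings and shipped inside a
MessagePack map.  The encodings implemented here are the standard ones:

* ``Delta`` — successive differences (first element stored as 0, the
  start value kept as ``origin``);
* ``RunLength`` — (value, count) pairs for label-like rasters;
* ``IntegerPacking`` — folds 32-bit integers into 1- or 2-byte lanes by
  emitting repeated type-bound values followed by the remainder;
* ``FixedPoint`` — ``round(v * factor)`` for floats with a known scale;
* ``IntervalQuantization`` — linear quantization of floats onto
  ``steps`` codes over ``[lo, hi]``;
* ``StringArray`` — dictionary encoding with an offset table;
* ``ByteArray`` — the terminal encoding producing little-endian bytes.

Integer chains are lossless; the two float encodings carry the usual
half-step error bounds (``0.5/factor`` and ``(hi-lo)/(2(steps-1))``).
All integer paths enforce a 32-bit limit and refuse rather than wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import msgpack
import numpy as np

from .errors import (
    BcifError,
    FixedPointOverflowError,
    InvalidPackingError,
    InvalidQuantizationError,
    UnsupportedVersionError,
)

ENCODER = "volseg-bcif 0.1.0"
VERSION = "0.3.0"

_I32_MIN, _I32_MAX = -(2**31), 2**31 - 1

# BinaryCIF numeric type codes
_TYPE_CODES = {
    np.dtype(np.int8): 1,
    np.dtype(np.int16): 2,
    np.dtype(np.int32): 3,
    np.dtype(np.uint8): 4,
    np.dtype(np.uint16): 5,
    np.dtype(np.uint32): 6,
    np.dtype(np.float32): 32,
    np.dtype(np.float64): 33,
}
_CODE_DTYPES = {v: k for k, v in _TYPE_CODES.items()}


def _as_int32(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and (arr.min() < _I32_MIN or arr.max() > _I32_MAX):
        raise BcifError("values exceed the 32-bit integer range")
    return arr.astype(np.int64)


# --- primitive encodings ---------------------------------------------------


def encode_delta(values) -> tuple[np.ndarray, int]:
    """Successive differences; returns (deltas with deltas[0]=0, origin)."""
    arr = _as_int32(values)
    if arr.size == 0:
        return np.zeros(0, dtype=np.int64), 0
    out = np.empty_like(arr)
    out[0] = 0
    out[1:] = np.diff(arr)
    return out, int(arr[0])


def decode_delta(deltas, origin: int) -> np.ndarray:
    arr = np.asarray(deltas, dtype=np.int64)
    if arr.size == 0:
        return arr
    return np.cumsum(arr) + origin


def encode_rle(values) -> tuple[np.ndarray, int]:
    """Collapse runs into flattened (value, count) pairs; returns source length."""
    arr = _as_int32(values)
    n = arr.size
    if n == 0:
        return np.zeros(0, dtype=np.int64), 0
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [n])))
    out = np.empty(2 * starts.size, dtype=np.int64)
    out[0::2] = arr[starts]
    out[1::2] = lengths
    return out, n


def decode_rle(pairs, src_size: int) -> np.ndarray:
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.size % 2:
        raise BcifError("run-length stream has an odd number of elements")
    out = np.repeat(arr[0::2], arr[1::2])
    if out.size != src_size:
        raise BcifError(f"run-length stream expands to {out.size}, expected {src_size}")
    return out


def _packing_bounds(byte_count: int, unsigned: bool) -> tuple[int, int]:
    if byte_count not in (1, 2):
        raise InvalidPackingError(f"invalid packing width {byte_count} (expected 1 or 2)")
    bits = 8 * byte_count
    if unsigned:
        return 0, (1 << bits) - 1
    return -(1 << (bits - 1)), (1 << (bits - 1)) - 1


def pack_integers(values, byte_count: int, unsigned: bool) -> np.ndarray:
    """Fold 32-bit integers into 1/2-byte lanes via repeated bound values.

    Each value v becomes floor(|v|/B) copies of the relevant bound B
    (upper for v >= 0, lower for v < 0) followed by the remainder.
    """
    lower, upper = _packing_bounds(byte_count, unsigned)
    arr = _as_int32(values)
    if unsigned and arr.size and arr.min() < 0:
        raise InvalidPackingError("negative values cannot be packed unsigned")
    out: list[int] = []
    for v in arr.tolist():
        bound = upper if v >= 0 else lower
        reps, rem = divmod(abs(v), abs(bound))
        out.extend([bound] * reps)
        out.append(rem if v >= 0 else -rem)
    dtype = {(1, True): np.uint8, (1, False): np.int8, (2, True): np.uint16, (2, False): np.int16}[
        (byte_count, unsigned)
    ]
    return np.asarray(out, dtype=dtype)


def unpack_integers(packed, byte_count: int, unsigned: bool, src_size: int) -> np.ndarray:
    lower, upper = _packing_bounds(byte_count, unsigned)
    arr = np.asarray(packed, dtype=np.int64)
    out = np.empty(src_size, dtype=np.int64)
    i = j = 0
    acc = 0
    while i < arr.size:
        v = int(arr[i])
        acc += v
        # only the type bounds continue a value; for unsigned packing the
        # lower bound is 0, which is a perfectly ordinary terminal value
        if v != upper and (unsigned or v != lower):
            if j >= src_size:
                raise BcifError("packed stream longer than declared source size")
            out[j] = acc
            acc = 0
            j += 1
        i += 1
    if j != src_size:
        raise BcifError(f"packed stream decodes to {j} values, expected {src_size}")
    return out


def best_packing(values) -> tuple[int, bool] | None:
    """Pick the (byte_count, unsigned) pair minimising packed byte size.

    Returns None when plain 32-bit storage is at least as small.
    """
    arr = _as_int32(values)
    if arr.size == 0:
        return None
    best: tuple[int, tuple[int, bool]] | None = None
    unsigned_ok = arr.min() >= 0
    for byte_count in (1, 2):
        for unsigned in ((True, False) if unsigned_ok else (False,)):
            lower, upper = _packing_bounds(byte_count, unsigned)
            bound = np.where(arr >= 0, upper, abs(lower))
            n_elems = int((np.abs(arr) // bound).sum()) + arr.size
            size = n_elems * byte_count
            if best is None or size < best[0]:
                best = (size, (byte_count, unsigned))
    if best is None or best[0] >= arr.size * 4:
        return None
    return best[1]


def encode_fixed_point(values, factor: float) -> np.ndarray:
    """round(v * factor) as 32-bit integers; decode divides by factor."""
    if factor <= 0:
        raise FixedPointOverflowError("fixed-point factor must be positive")
    arr = np.asarray(values, dtype=np.float64)
    scaled = np.round(arr * factor)
    if scaled.size and (scaled.min() < _I32_MIN or scaled.max() > _I32_MAX):
        raise FixedPointOverflowError("fixed-point overflow past 32-bit after scaling")
    return scaled.astype(np.int64)


def decode_fixed_point(codes, factor: float) -> np.ndarray:
    return np.asarray(codes, dtype=np.float64) / factor


def encode_interval_quantization(values, lo: float, hi: float, steps: int) -> np.ndarray:
    """Quantize floats onto ``steps`` codes over [lo, hi] (values clamped)."""
    if steps < 2:
        raise InvalidQuantizationError(f"invalid quantization: steps={steps} < 2")
    if not lo < hi:
        raise InvalidQuantizationError(f"invalid quantization interval [{lo}, {hi}]")
    arr = np.clip(np.asarray(values, dtype=np.float64), lo, hi)
    return np.round((arr - lo) / (hi - lo) * (steps - 1)).astype(np.int64)


def decode_interval_quantization(codes, lo: float, hi: float, steps: int) -> np.ndarray:
    return np.asarray(codes, dtype=np.float64) / (steps - 1) * (hi - lo) + lo


def encode_string_array(values) -> tuple[str, np.ndarray, np.ndarray]:
    """Dictionary-encode strings: (concatenated data, offsets, indices).

    ``None`` entries become index -1 (absent value).
    """
    unique: dict[str, int] = {}
    indices = np.empty(len(values), dtype=np.int64)
    order: list[str] = []
    for i, v in enumerate(values):
        if v is None:
            indices[i] = -1
            continue
        if v not in unique:
            unique[v] = len(order)
            order.append(v)
        indices[i] = unique[v]
    data = "".join(order)
    offsets = np.zeros(len(order) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in order], out=offsets[1:])
    return data, offsets, indices


def decode_string_array(data: str, offsets, indices) -> list[str | None]:
    offsets = np.asarray(offsets, dtype=np.int64)
    strings = [data[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1)]
    return [None if i < 0 else strings[i] for i in np.asarray(indices, dtype=np.int64)]


# --- encoding chains -------------------------------------------------------


def _smallest_int_dtype(arr: np.ndarray) -> np.dtype:
    if arr.size == 0:
        return np.dtype(np.int32)
    lo, hi = int(arr.min()), int(arr.max())
    if lo >= 0:
        for dt in (np.uint8, np.uint16, np.uint32):
            if hi <= np.iinfo(dt).max:
                return np.dtype(dt)
    else:
        for dt in (np.int8, np.int16, np.int32):
            info = np.iinfo(dt)
            if info.min <= lo and hi <= info.max:
                return np.dtype(dt)
    raise BcifError("integer array exceeds 32-bit range")


def _byte_array_step(arr: np.ndarray, dtype: np.dtype) -> tuple[bytes, dict]:
    data = np.ascontiguousarray(arr.astype(dtype)).astype(dtype.newbyteorder("<")).tobytes()
    return data, {"kind": "ByteArray", "type": _TYPE_CODES[dtype]}


def encode_int_array(values, *, delta: bool = False, run_length: bool = False) -> dict:
    """Encode an integer array with an optional RLE -> Delta -> Packing chain."""
    arr = _as_int32(values)
    encodings: list[dict] = []
    if run_length:
        arr, n = encode_rle(arr)
        encodings.append({"kind": "RunLength", "srcType": 3, "srcSize": n})
    if delta:
        arr, origin = encode_delta(arr)
        encodings.append({"kind": "Delta", "origin": origin, "srcType": 3})
    packing = best_packing(arr)
    if packing is not None:
        byte_count, unsigned = packing
        src_size = arr.size
        arr = pack_integers(arr, byte_count, unsigned)
        encodings.append(
            {
                "kind": "IntegerPacking",
                "byteCount": byte_count,
                "isUnsigned": unsigned,
                "srcSize": src_size,
            }
        )
        data, ba = _byte_array_step(arr, arr.dtype)
    else:
        data, ba = _byte_array_step(arr, _smallest_int_dtype(arr))
    encodings.append(ba)
    return {"data": data, "encoding": encodings}


def encode_float_array(
    values,
    *,
    fixed_factor: float | None = None,
    quantize: tuple[float, float, int] | None = None,
    delta: bool = True,
) -> dict:
    """Encode floats either losslessly (raw bytes) or via a lossy front step."""
    arr = np.asarray(values)
    if fixed_factor is None and quantize is None:
        dtype = np.dtype(np.float32) if arr.dtype == np.float32 else np.dtype(np.float64)
        data, ba = _byte_array_step(arr, dtype)
        return {"data": data, "encoding": [ba]}
    encodings: list[dict] = []
    if quantize is not None:
        lo, hi, steps = quantize
        ints = encode_interval_quantization(arr, lo, hi, steps)
        encodings.append(
            {"kind": "IntervalQuantization", "min": lo, "max": hi, "numSteps": steps, "srcType": 33}
        )
    else:
        ints = encode_fixed_point(arr, fixed_factor)
        encodings.append({"kind": "FixedPoint", "factor": fixed_factor, "srcType": 33})
    tail = encode_int_array(ints, delta=delta)
    # chain order is outermost-first: float step, then the integer chain
    return {"data": tail["data"], "encoding": encodings + tail["encoding"]}


def encode_string_column(values) -> dict:
    data, offsets, indices = encode_string_array(values)
    offsets_enc = encode_int_array(offsets, delta=True)
    indices_enc = encode_int_array(indices, delta=False)
    return {
        "data": indices_enc["data"],
        "encoding": [
            {
                "kind": "StringArray",
                "stringData": data,
                "offsets": offsets_enc["data"],
                "offsetEncoding": offsets_enc["encoding"],
                "dataEncoding": indices_enc["encoding"],
            }
        ],
    }


def decode_column(encoded: dict):
    """Decode a {"data", "encoding"} payload by unwinding the chain."""
    data: Any = encoded["data"]
    encoding = encoded["encoding"]
    if encoding and encoding[0].get("kind") == "StringArray":
        e = encoding[0]
        offsets = _decode_chain(e["offsets"], e["offsetEncoding"])
        indices = _decode_chain(data, e["dataEncoding"])
        return decode_string_array(e["stringData"], offsets, indices)
    return _decode_chain(data, encoding)


def _decode_chain(data: Any, encoding: list[dict]) -> np.ndarray:
    for e in reversed(encoding):
        kind = e.get("kind")
        if kind == "ByteArray":
            dtype = _CODE_DTYPES.get(int(e["type"]))
            if dtype is None:
                raise BcifError(f"unknown ByteArray type code {e['type']}")
            data = np.frombuffer(data, dtype=dtype.newbyteorder("<")).astype(
                np.int64 if dtype.kind in "iu" else np.float64
            )
        elif kind == "IntegerPacking":
            data = unpack_integers(data, int(e["byteCount"]), bool(e["isUnsigned"]), int(e["srcSize"]))
        elif kind == "Delta":
            data = decode_delta(data, int(e["origin"]))
        elif kind == "RunLength":
            data = decode_rle(data, int(e["srcSize"]))
        elif kind == "FixedPoint":
            data = decode_fixed_point(data, float(e["factor"]))
        elif kind == "IntervalQuantization":
            data = decode_interval_quantization(
                data, float(e["min"]), float(e["max"]), int(e["numSteps"])
            )
        else:
            raise BcifError(f"unknown encoding kind {kind!r}")
    return data


# --- container model -------------------------------------------------------


@dataclass
class Column:
    name: str
    payload: dict  # {"data": bytes, "encoding": [...]}
    mask: dict | None = None


@dataclass
class Category:
    name: str
    row_count: int
    columns: list[Column] = field(default_factory=list)


@dataclass
class DataBlock:
    header: str
    categories: list[Category] = field(default_factory=list)


def serialize(blocks: list[DataBlock]) -> bytes:
    """Pack data blocks into the MessagePack container."""
    doc = {
        "encoder": ENCODER,
        "version": VERSION,
        "dataBlocks": [
            {
                "header": b.header,
                "categories": [
                    {
                        "name": c.name,
                        "rowCount": c.row_count,
                        "columns": [
                            {"name": col.name, "data": col.payload, "mask": col.mask}
                            for col in c.columns
                        ],
                    }
                    for c in b.categories
                ],
            }
            for b in blocks
        ],
    }
    return msgpack.packb(doc, use_bin_type=True)


def deserialize(raw: bytes) -> list[DataBlock]:
    """Unpack a container; raises on truncation or version mismatch."""
    try:
        doc = msgpack.unpackb(raw, raw=False, strict_map_key=False)
    except Exception as exc:
        raise BcifError(f"invalid bcif container: {exc}") from exc
    if not isinstance(doc, dict) or "dataBlocks" not in doc:
        raise BcifError("invalid bcif container: missing dataBlocks")
    version = str(doc.get("version", ""))
    if version.split(".")[0] != VERSION.split(".")[0]:
        raise UnsupportedVersionError(f"unsupported version {version!r} (supported {VERSION})")
    blocks = []
    for b in doc["dataBlocks"]:
        cats = []
        for c in b.get("categories", []):
            cols = [
                Column(col["name"], col["data"], col.get("mask"))
                for col in c.get("columns", [])
            ]
            cats.append(Category(c["name"], int(c["rowCount"]), cols))
        blocks.append(DataBlock(b.get("header", ""), cats))
    return blocks


def category_as_dict(cat: Category) -> dict[str, Any]:
    """Decode every column of a category into a name -> array/list mapping."""
    return {col.name: decode_column(col.payload) for col in cat.columns}
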