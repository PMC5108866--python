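"""QR-code signatures for sequence records.

Each record is serialised into an open, versioned payload —
``SEQDIGIT/1|<id>|<description>|<residues>`` — and rendered as a standard
QR symbol, so any conforming reader recovers the exact record.  The payload
format is injective (the separator is forbidden inside id and description),
and payloads longer than a single symbol's capacity are split into indexed
parts that reassemble exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _qrcodec
from ._qrcodec import QRCodecError
from .seqio import SeqRecord

__all__ = [
    "QRPayload",
    "QRSymbol",
    "PayloadError",
    "FORMAT_TAG",
    "SEPARATOR",
    "encode_payload",
    "parse_payload",
    "make_symbol",
    "decode_symbol",
    "chunk_payload",
    "reassemble_chunks",
    "symbol_to_png",
]

FORMAT_TAG = "SEQDIGIT/1"
SEPARATOR = "|"
PART_TAG = "SEQDIGITPART/1"
#: fixed-width part header: TAG|iiii|nnnn|  (see :func:`chunk_payload`)
_PART_HEADER_LEN = len(PART_TAG) + 1 + 4 + 1 + 4 + 1


class PayloadError(ValueError):
    pass


@dataclass(frozen=True)
class QRPayload:
    """Serialised record: a versioned, '|'-separated byte string."""

    record_id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        for label, value in (("id", self.record_id), ("description", self.description)):
            if SEPARATOR in value:
                raise PayloadError(
                    f"record {label} may not contain {SEPARATOR!r}: {value!r}")
        if not self.record_id:
            raise PayloadError("record id must be non-empty")

    def to_bytes(self) -> bytes:
        return SEPARATOR.join(
            (FORMAT_TAG, self.record_id, self.description, self.residues)
        ).encode("ascii")

    def __len__(self) -> int:
        return len(self.to_bytes())

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_bytes()).hexdigest()


@dataclass(frozen=True)
class QRSymbol:
    """A rendered QR symbol: boolean module matrix (True = dark)."""

    matrix: np.ndarray = field(repr=False)
    version: int = 0
    ec_level: str = "L"
    mask: int = 0

    @property
    def side(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        if self.side != 17 + 4 * self.version:
            raise PayloadError(
                f"matrix side {self.side} inconsistent with version {self.version}")


def encode_payload(record: SeqRecord) -> QRPayload:
    """Serialise a record; injective over (id, description, residues)."""
    return QRPayload(record_id=record.id, description=record.description,
                     residues=record.residues)


def parse_payload(data: bytes) -> QRPayload:
    """Inverse of :meth:`QRPayload.to_bytes`."""
    try:
        text = data.decode("ascii")
    except UnicodeDecodeError as exc:
        raise PayloadError(f"payload is not ASCII: {exc}") from exc
    parts = text.split(SEPARATOR, 3)
    if len(parts) != 4 or parts[0] != FORMAT_TAG:
        raise PayloadError(f"not a {FORMAT_TAG} payload")
    return QRPayload(record_id=parts[1], description=parts[2], residues=parts[3])


def make_symbol(payload: QRPayload | bytes, ec_level: str = "L") -> QRSymbol:
    """Render a payload as the smallest sufficient QR symbol.

    Deterministic for a fixed payload and level.  Raises if the payload
    exceeds single-symbol capacity (chunk it first).
    """
    data = payload.to_bytes() if isinstance(payload, QRPayload) else bytes(payload)
    if not data:
        raise PayloadError("empty payload")
    matrix, version, mask = _qrcodec.encode_bytes(data, level=ec_level)
    return QRSymbol(matrix=matrix, version=version, ec_level=ec_level, mask=mask)


def decode_symbol(symbol: QRSymbol | np.ndarray) -> QRPayload:
    """Decode a symbol's module matrix back to its payload fields."""
    matrix = symbol.matrix if isinstance(symbol, QRSymbol) else symbol
    return parse_payload(_qrcodec.decode_matrix(matrix))


def single_symbol_capacity(ec_level: str = "L") -> int:
    """Byte capacity of the largest (version 40) symbol at a level."""
    return _qrcodec.capacity_bytes(40, ec_level)


def chunk_payload(payload: QRPayload | bytes, capacity: int | None = None,
                  ec_level: str = "L") -> list[bytes]:
    """Split a payload into single-symbol parts carrying (index, n_parts).

    Part format: ``SEQDIGITPART/1|iiii|nnnn|<body>`` with fixed 4-digit
    zero-padded index fields, so every part has the same header overhead
    and the body concatenation equals the original payload byte-for-byte.
    A payload within capacity is returned as a single untagged part.
    """
    data = payload.to_bytes() if isinstance(payload, QRPayload) else bytes(payload)
    if capacity is None:
        capacity = single_symbol_capacity(ec_level)
    if capacity <= _PART_HEADER_LEN:
        raise PayloadError(
            f"capacity {capacity} does not exceed header overhead {_PART_HEADER_LEN}")
    if len(data) <= capacity:
        return [data]
    usable = capacity - _PART_HEADER_LEN
    n_parts = -(-len(data) // usable)
    if n_parts > 9999:
        raise PayloadError("payload needs more than 9999 parts")
    out = []
    for i in range(n_parts):
        body = data[i * usable:(i + 1) * usable]
        header = f"{PART_TAG}{SEPARATOR}{i:04d}{SEPARATOR}{n_parts:04d}{SEPARATOR}"
        out.append(header.encode("ascii") + body)
    return out


def reassemble_chunks(parts: list[bytes]) -> bytes:
    """Rebuild the original payload from parts, in any order."""
    if len(parts) == 1 and not parts[0].startswith(PART_TAG.encode()):
        return parts[0]
    seen: dict[int, bytes] = {}
    n_expected = None
    for part in parts:
        head = part[:_PART_HEADER_LEN].decode("ascii", errors="replace")
        fields = head.split(SEPARATOR)
        if len(fields) != 4 or fields[0] != PART_TAG:
            raise PayloadError(f"malformed part header {head!r}")
        idx, total = int(fields[1]), int(fields[2])
        if n_expected is None:
            n_expected = total
        elif total != n_expected:
            raise PayloadError("parts disagree on total count")
        if idx in seen:
            raise PayloadError(f"duplicate part index {idx}")
        seen[idx] = part[_PART_HEADER_LEN:]
    if n_expected is None or set(seen) != set(range(n_expected)):
        missing = sorted(set(range(n_expected or 0)) - set(seen))
        raise PayloadError(f"missing part indices {missing}")
    return b"".join(seen[i] for i in range(n_expected))


def symbol_to_png(symbol: QRSymbol, path, scale: int = 4, border: int = 4) -> None:
    """Write a symbol as a PNG (dark modules black, quiet zone included)."""
    from matplotlib.image import imsave

    mat = symbol.matrix
    side = mat.shape[0]
    canvas = np.ones((side + 2 * border, side + 2 * border), dtype=float)
    canvas[border:border + side, border:border + side] = 1.0 - mat.astype(float)
    canvas = np.kron(canvas, np.ones((scale, scale)))
    imsave(path, canvas, cmap="gray", vmin=0.0, vmax=1.0)
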