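"""Memory-efficient stock membership via a bloom filter.

A bloom filter stores set membership in an m-bit array probed by k hash
functions: inserted identifiers always answer True (no false negatives),
while a non-inserted identifier answers True with a tunable false-positive
probability.  Sizing uses the textbook optimum for a target false-positive
rate p at capacity n:

    m = ceil(-n * ln(p) / (ln 2)^2),   k = max(1, round((m / n) * ln 2))

so the repository default (p = 0.01) reproduces the ~1% rate expected of a
compound-stock filter.  False positives only ever inflate apparent stock
membership — a systematic overestimate of solve metrics, never an
underestimate.

Hashing is seeded blake2b with double hashing (h1 + i*h2 mod m), fixed
little-endian byte order, so bit positions and serialized filters are
identical across platforms.  Identifier canonicalization is the caller's
duty: the filter hashes raw strings.
"""

from __future__ import annotations

import hashlib
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "BloomFilter",
    "build_filter",
    "save_filter",
    "load_filter",
    "build_from_lines",
    "DEFAULT_FPR",
    "FormatError",
]

#: Default design false-positive rate (~1%).
DEFAULT_FPR = 0.01

_MAGIC = b"RMBL"
_VERSION = 1
# magic, version, m (u64), k (u32), hash_seed (u64), n_inserted (u64) — LE.
_HEADER = struct.Struct("<4sBQIQQ")


class FormatError(ValueError):
    """Raised when a serialized filter is malformed."""


@dataclass
class BloomFilter:
    """An m-bit array probed by k seeded hash functions."""

    m: int
    k: int
    hash_seed: int = 0
    n_inserted: int = 0
    bits: bytearray = field(default_factory=bytearray)

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 1:
            raise ValueError("m and k must be >= 1")
        nbytes = (self.m + 7) // 8
        if not self.bits:
            self.bits = bytearray(nbytes)
        elif len(self.bits) != nbytes:
            raise ValueError("bit array length does not match m")

    def _positions(self, item: str) -> list[int]:
        digest = hashlib.blake2b(
            item.encode("utf-8"),
            digest_size=16,
            salt=self.hash_seed.to_bytes(8, "little"),
        ).digest()
        h1 = int.from_bytes(digest[:8], "little")
        h2 = int.from_bytes(digest[8:], "little") | 1
        return [(h1 + i * h2) % self.m for i in range(self.k)]

    def add(self, item: str) -> None:
        """Set the k bit positions for ``item``; idempotent."""
        for pos in self._positions(item):
            self.bits[pos >> 3] |= 1 << (pos & 7)
        self.n_inserted += 1

    def update(self, items: Iterable[str]) -> None:
        for item in items:
            self.add(item)

    def contains(self, item: str) -> bool:
        """True for every added item; true for a non-added item with
        probability approximately the design false-positive rate."""
        for pos in self._positions(item):
            if not self.bits[pos >> 3] & (1 << (pos & 7)):
                return False
        return True

    __contains__ = contains

    def popcount(self) -> int:
        """Number of set bits (bounded by k * n_inserted)."""
        return int.from_bytes(self.bits, "little").bit_count()

    def estimate_fpr(self, probes: Sequence[str]) -> float:
        """Empirical false-positive rate: the fraction of ``probes`` (which
        must not have been inserted) answered True."""
        if not probes:
            raise ValueError("estimate_fpr requires at least one probe")
        return sum(self.contains(p) for p in probes) / len(probes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BloomFilter):
            return NotImplemented
        return (
            self.m == other.m
            and self.k == other.k
            and self.hash_seed == other.hash_seed
            and self.n_inserted == other.n_inserted
            and self.bits == other.bits
        )


def build_filter(
    capacity: int, target_fpr: float = DEFAULT_FPR, hash_seed: int = 0
) -> BloomFilter:
    """An empty filter optimally sized for ``capacity`` items at
    ``target_fpr``."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target_fpr must be in (0, 1)")
    ln2 = math.log(2.0)
    m = math.ceil(-capacity * math.log(target_fpr) / (ln2 * ln2))
    k = max(1, round((m / capacity) * ln2))
    return BloomFilter(m=m, k=k, hash_seed=hash_seed)


def build_from_lines(
    lines: Iterable[str], capacity: int, target_fpr: float = DEFAULT_FPR, hash_seed: int = 0
) -> BloomFilter:
    """Build and fill a filter from an iterable of identifier lines
    (whitespace-stripped; empty lines skipped)."""
    filt = build_filter(capacity, target_fpr, hash_seed)
    for line in lines:
        item = line.strip()
        if item:
            filt.add(item)
    return filt


def save_filter(filt: BloomFilter, path: Union[str, Path]) -> None:
    """Binary format: magic "RMBL", version byte, m, k, hash_seed,
    n_inserted (fixed-width little-endian), then the raw bit array."""
    header = _HEADER.pack(
        _MAGIC, _VERSION, filt.m, filt.k, filt.hash_seed, filt.n_inserted
    )
    Path(path).write_bytes(header + bytes(filt.bits))


def load_filter(path: Union[str, Path]) -> BloomFilter:
    """Load a filter saved by :func:`save_filter`; bit-identical round trip."""
    data = Path(path).read_bytes()
    if len(data) < _HEADER.size:
        raise FormatError("truncated bloom file (header incomplete)")
    magic, version, m, k, hash_seed, n_inserted = _HEADER.unpack_from(data)
    if magic != _MAGIC:
        raise FormatError(f"bad magic {magic!r}; not a bloom stock file")
    if version != _VERSION:
        raise FormatError(f"unsupported bloom file version {version}")
    nbytes = (m + 7) // 8
    payload = data[_HEADER.size :]
    if len(payload) != nbytes:
        raise FormatError("truncated bloom file (bit array incomplete)")
    return BloomFilter(
        m=m, k=k, hash_seed=hash_seed, n_inserted=n_inserted, bits=bytearray(payload)
    )
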