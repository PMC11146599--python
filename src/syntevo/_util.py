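"""Shared low-level helpers: base encoding, interval arithmetic, rounding, seeds."""

from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

# Base encoding: A=0, C=1, G=2, T=3, N=4.  Complement maps N to N.
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (A=0,C=1,G=2,T=3, other=N=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(seq)))


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as figures and tables usually print."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(master_seed: int, *labels) -> int:
    """Deterministic child seed from a master seed and a label path.

    Independent of traversal order; stable across platforms and sessions.
    Result is bounded below 2**31 so it is safe for any RNG constructor.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for lab in labels:
        h.update(b"\x00")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def subtract_intervals(
    span: tuple[int, int], covered: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pieces of half-open ``span`` not covered by the sorted disjoint ``covered``."""
    start, end = span
    out = []
    cur = start
    for cs, ce in covered:
        if ce <= cur:
            continue
        if cs >= end:
            break
        if cs > cur:
            out.append((cur, min(cs, end)))
        cur = max(cur, ce)
        if cur >= end:
            break
    if cur < end:
        out.append((cur, end))
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
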