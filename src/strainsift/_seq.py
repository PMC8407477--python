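"""Low-level nucleotide encoding helpers shared by the simulator and the mapper.

Sequences are stored internally as uint8 code arrays (A=0, C=1, G=2, T=3);
complementation is then ``3 - code``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)

_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string into a uint8 code array.

    Raises ValueError on any character outside {A,C,G,T}.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    if codes.size and codes.max() > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"invalid nucleotide {bad!r}; alphabet is A/C/G/T")
    return codes


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BYTE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of every overlapping k-mer (base-4, first base most significant).

    Returns an int64 array of length ``len(codes) - k + 1`` (empty if shorter).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows.astype(np.int64) @ powers


def kmers_at(codes_2d: np.ndarray, offsets: np.ndarray, k: int) -> np.ndarray:
    """k-mer values at the given column offsets of a (n_reads, L) code matrix.

    Returns an (n_reads, len(offsets)) int64 array.
    """
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    cols = offsets[:, None] + np.arange(k)[None, :]  # (n_offsets, k)
    sub = codes_2d[:, cols]  # (n_reads, n_offsets, k)
    return sub.astype(np.int64) @ powers
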