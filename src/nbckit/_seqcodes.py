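"""Integer 2-bit encodings for DNA k-mers.

A k-mer over {A,C,G,T} maps to an integer in [0, 4**k) with A=0, C=1,
G=2, T=3, most significant base first. Windows containing any other
character are flagged invalid rather than encoded.
"""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"

_LUT = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def base_codes(sequence: str) -> np.ndarray:
    """Per-base codes 0..3; anything outside {A,C,G,T} becomes 4."""
    raw = sequence.encode("ascii", errors="replace")
    return _LUT[np.frombuffer(raw, dtype=np.uint8)]


def window_codes(sequence: str, n: int) -> np.ndarray:
    """Codes of all valid length-n windows, in sequence order.

    Windows touching a non-ACGT character are dropped.
    """
    vals = base_codes(sequence)
    m = len(vals) - n + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    bad = np.concatenate(([0], np.cumsum(vals > 3)))
    valid = (bad[n:] - bad[:-n]) == 0
    clean = np.where(vals > 3, 0, vals)
    codes = np.zeros(m, dtype=np.int64)
    for i in range(n):
        codes = codes * 4 + clean[i : i + m]
    return codes[valid]


def encode_kmer(kmer: str) -> int:
    """Encode a single unambiguous k-mer; raises on bad characters."""
    code = 0
    for ch in kmer:
        v = _LUT[ord(ch)] if ord(ch) < 256 else 4
        if v > 3:
            raise ValueError(f"invalid base {ch!r} in k-mer {kmer!r}")
        code = code * 4 + int(v)
    return code


def decode_kmer(code: int, n: int) -> str:
    return "".join(_BASES[(code >> (2 * (n - 1 - i))) & 3] for i in range(n))


def complement_table() -> dict[int, str]:  # pragma: no cover - trivial
    return _COMPLEMENT
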