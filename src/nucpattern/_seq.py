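"""Low-level sequence encoding shared across modules.

Bases are encoded as uint8: A=0, C=1, G=2, T=3; anything else (N,
ambiguity codes) becomes 4.  W = {A, T}, S = {C, G}.
"""
from __future__ import annotations

import numpy as np

NCP_LEN = 147
DYAD_INDEX = 73  # 0-based centre of a 147-bp frame

A, C, G, T, OTHER = 0, 1, 2, 3, 4

_LUT = np.full(256, OTHER, dtype=np.uint8)
for _b, _code in (("A", A), ("C", C), ("G", G), ("T", T)):
    _LUT[ord(_b)] = _code
    _LUT[ord(_b.lower())] = _code

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = np.array([T, G, C, A, OTHER], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (vectorised, case-insensitive)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def is_w(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of weak (A/T) bases."""
    return (codes == A) | (codes == T)


def is_s(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of strong (C/G) bases."""
    return (codes == C) | (codes == G)


def ww_starts(codes: np.ndarray) -> np.ndarray:
    """Mask over dinucleotide start positions: True where (i, i+1) is WW."""
    w = is_w(codes)
    return w[..., :-1] & w[..., 1:]


def ss_starts(codes: np.ndarray) -> np.ndarray:
    s = is_s(codes)
    return s[..., :-1] & s[..., 1:]


def dinuc_class_starts(codes: np.ndarray, dinuc_class: str) -> np.ndarray:
    cls = dinuc_class.upper()
    if cls == "WW":
        return ww_starts(codes)
    if cls == "SS":
        return ss_starts(codes)
    raise ValueError(f"unknown dinucleotide class {dinuc_class!r}; expected 'WW' or 'SS'")
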