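"""Low-level DNA sequence utilities.

Sequences are plain Python strings over the alphabet A/C/G/T. For numeric
work they are encoded as uint8 arrays with A=0, C=1, G=2, T=3, so that the
complement of base ``b`` is ``3 - b`` and a k-mer maps to a base-4 integer
with the first base most significant (lexicographic order on strings equals
numeric order on codes).
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3).

    Raises ValueError if the sequence contains characters outside A/C/G/T
    (case-insensitive).
    """
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = sorted(set(seq[i] for i in np.nonzero(arr > 3)[0][:10]))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid(seq: str) -> bool:
    """True if the sequence is nonempty and contains only A/C/G/T."""
    if not seq:
        return False
    arr = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    return bool((arr <= 3).all())


def gc_fraction(seq: str) -> float:
    arr = encode(seq)
    return float(((arr == 1) | (arr == 2)).mean()) if arr.size else 0.0


def kmer_to_code(kmer: str) -> int:
    """Base-4 integer code of a k-mer (first base most significant)."""
    arr = encode(kmer).astype(np.int64)
    code = 0
    for d in arr:
        code = code * 4 + int(d)
    return code


def code_to_kmer(code: int, k: int) -> str:
    digits = np.empty(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        digits[i] = code % 4
        code //= 4
    return decode(digits)


def codes_to_digits(codes: np.ndarray, k: int) -> np.ndarray:
    """(n,) base-4 codes -> (n, k) digit matrix, most-significant first."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        out[:, i] = codes % 4
        codes = codes // 4
    return out


def digits_to_codes(digits: np.ndarray) -> np.ndarray:
    digits = np.asarray(digits, dtype=np.int64)
    pow4 = 4 ** np.arange(digits.shape[1] - 1, -1, -1, dtype=np.int64)
    return digits @ pow4


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse-complement on base-4 k-mer codes."""
    digits = codes_to_digits(codes, k)
    return digits_to_codes(3 - digits[:, ::-1])


def codes_to_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """(n,) codes -> numpy array of fixed-width byte strings (dtype S<k>)."""
    digits = codes_to_digits(codes, k)
    ascii_mat = _DECODE[digits]
    return ascii_mat.reshape(-1).view(f"S{k}").copy() if k > 0 else np.array([], dtype="S1")


def window_codes(seq_or_arr, l: int) -> np.ndarray:
    """Base-4 codes of all length-``l`` windows of a sequence, 5'->3'.

    Returns an empty array when the sequence is shorter than ``l``.
    """
    arr = encode(seq_or_arr) if isinstance(seq_or_arr, str) else np.asarray(seq_or_arr)
    n = arr.size - l + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, l).astype(np.int64)
    pow4 = 4 ** np.arange(l - 1, -1, -1, dtype=np.int64)
    return win @ pow4
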