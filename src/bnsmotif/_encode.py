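"""Integer encoding of DNA and fast PWM window scoring.

Bases are encoded A=0, C=1, G=2, T=3; N (and padding) is -1.  With this
encoding the Watson-Crick complement of base b is 3-b, so the
reverse-complement of an encoded array is ``3 - a[::-1]`` and the
reverse-complement of a (width x 4) matrix is ``M[::-1, ::-1]``.

k-mers with k <= _MAX_PACK_K are packed into base-4 integers, which turns
both k-mer counting and window scoring into table lookups.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_MAX_PACK_K = 13  # 4**13 < 2**26; lookup tables stay small

_ENC = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = -1
_ENC[ord("n")] = -1


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 (A=0,C=1,G=2,T=3, N=-1)."""
    a = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (a == -2).any():
        bad = seq[int(np.argmax(a == -2))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return a


def decode(arr: np.ndarray) -> str:
    out = np.full(arr.shape, ord("N"), dtype=np.uint8)
    valid = arr >= 0
    out[valid] = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)[arr[valid]]
    return out.tobytes().decode("ascii")


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-or-variable-length sequences into a -1 padded (n, Lmax) matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    lmax = max(len(s) for s in seqs)
    out = np.full((len(seqs), lmax), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = encode(s)
    return out


def revcomp_enc(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded array (N stays N)."""
    out = 3 - arr[..., ::-1]
    out[out == 4] = -1
    return out


def pack_windows(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window of each row into a base-4 integer.

    Returns ``(packed, valid)`` each of shape (n, L-k+1); windows containing
    N/padding are invalid.  Requires k <= 13.
    """
    if k > _MAX_PACK_K:
        raise ValueError(f"k={k} too large to pack (max {_MAX_PACK_K})")
    n, L = mat.shape
    m = L - k + 1
    if m <= 0:
        return (np.empty((n, 0), dtype=np.int64), np.empty((n, 0), dtype=bool))
    # transpose once so per-position access is contiguous
    matc = np.ascontiguousarray(np.where(mat >= 0, mat, 0).T).astype(np.int64)
    packed_t = np.empty((m, n), dtype=np.int64)  # transposed for contiguous stores
    cur = np.zeros(n, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    for i in range(k):
        np.multiply(cur, 4, out=cur)
        np.add(cur, matc[i], out=cur)
    packed_t[0] = cur
    high = np.int64(4 ** (k - 1))
    for j in range(1, m):  # rolling update: drop the leading base, append one
        np.multiply(matc[j - 1], high, out=tmp)
        np.subtract(cur, tmp, out=cur)
        np.multiply(cur, 4, out=cur)
        np.add(cur, matc[j + k - 1], out=cur)
        packed_t[j] = cur
    packed = packed_t.T
    bad = mat < 0
    if bad.any():
        c = np.cumsum(bad, axis=1)
        winbad = c[:, k - 1 :].copy()
        winbad[:, 1:] -= c[:, : m - 1]
        valid = winbad == 0
    else:
        valid = np.ones((n, m), dtype=bool)
    return packed, valid


def pack_kmer(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = v * 4 + ALPHABET.index(c)
    return v


def unpack_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(out))


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement of a packed k-mer code."""
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - code % 4)
        code //= 4
    return out


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse-complement of packed k-mer codes."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - tmp % 4)
        tmp //= 4
    return out


_LETTER_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def unpack_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Vectorized decoding of packed k-mer codes to strings."""
    n = len(codes)
    if n == 0:
        return []
    out = np.empty((n, k), dtype=np.uint8)
    tmp = codes.astype(np.int64).copy()
    for i in range(k - 1, -1, -1):
        out[:, i] = _LETTER_BYTES[tmp % 4]
        tmp //= 4
    flat = out.tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(n)]


def score_table(matrix: np.ndarray) -> np.ndarray:
    """Total score of every k-mer (packed order) under a (k x 4) score matrix.

    Built by iterated outer addition; float64, length 4**k.
    """
    k = matrix.shape[0]
    if k > _MAX_PACK_K:
        raise ValueError(f"width {k} too large for a score table")
    t = np.zeros(1, dtype=np.float64)
    for row in matrix:
        t = (t[:, None] + row[None, :].astype(np.float64)).ravel()
    return t


def window_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of all windows of a single encoded sequence against (w x 4) matrix.

    Windows containing N get -inf.  Works for any width.
    """
    w = matrix.shape[0]
    m = enc.shape[0] - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.float64)
    scores = np.zeros(m, dtype=np.float64)
    valid = np.ones(m, dtype=bool)
    for i in range(w):
        col = enc[i : i + m]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, matrix[i, np.where(ok, col, 0)], 0.0)
    scores[~valid] = -np.inf
    return scores
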