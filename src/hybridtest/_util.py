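"""Small sequence helpers shared across modules.

Sequences are plain upper-case ACGT strings at module boundaries; hot loops
work on uint8 arrays of ASCII codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII codes of *seq* as a uint8 array (no copy of semantics, just bytes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def base_index_array(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character maps to 4."""
    arr = seq_to_array(seq)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, code in enumerate(_BASE_CODES):
        out[arr == code] = i
    return out


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical (lexicographic min of kmer / its revcomp) k-mers."""
    rc = revcomp(seq)
    n = len(seq)
    out: set[str] = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        bwd = rc[n - k - i : n - i]
        out.add(fwd if fwd <= bwd else bwd)
    return out


def phred_char(error_prob: float) -> str:
    """Sanger (phred+33) quality character for a per-base error probability."""
    if error_prob <= 0:
        q = 40
    else:
        q = min(40, int(round(-10.0 * np.log10(error_prob))))
    return chr(q + 33)


def phred_error_probs(quality: str) -> np.ndarray:
    """Per-base error probabilities from a phred+33 quality string."""
    arr = seq_to_array(quality).astype(np.float64) - 33.0
    if np.any(arr < 0) or np.any(arr > 60):
        raise ValueError("malformed phred+33 quality string")
    return np.power(10.0, -arr / 10.0)
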