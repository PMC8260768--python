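"""Small shared DNA-sequence helpers (substitution-only comparisons)."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def sliding_mismatches(window: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Hamming distance of ``probe`` against every offset of ``window``.

    Both arguments are uint8 byte arrays; non-ACGT bytes simply never match.
    Returns an array of length ``len(window) - len(probe) + 1``.
    """
    if len(window) < len(probe):
        return np.empty(0, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(window, len(probe))
    return (view != probe).sum(axis=1)
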