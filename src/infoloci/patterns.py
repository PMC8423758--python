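"""Dominant patterns of genotype changes between populations.

At each locus, every population's genotype-class frequencies (f0, f1, f2)
are quantized into a 3-component binary vector marking the maximal class and
any class within a margin delta of it.  The pattern of genotype changes at a
locus is the partition of the populations induced by equality of their
quantized vectors; pattern occurrences are counted genome-wide and ranked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quantize_profile", "count_patterns", "pattern_signature"]


def quantize_profile(f: np.ndarray, delta: float = 0.2) -> np.ndarray:
    """Quantize genotype-class frequencies into binary vectors.

    Component g is set iff f_g >= max_g' f_g' - delta, so the maximal class is
    always set and classes within ``delta`` of it are co-marked; e.g.
    (0.9, 0.1, 0.0) -> (1, 0, 0) at delta = 0.2.
    """
    f = np.asarray(f, dtype=np.float64)
    return f >= f.max(axis=-1, keepdims=True) - delta


def _vector_codes(quantized: np.ndarray) -> np.ndarray:
    """Encode each 3-bit vector as an integer 1..7 (at least one bit set)."""
    q = quantized.astype(np.int64)
    return q[..., 0] * 4 + q[..., 1] * 2 + q[..., 2]


def pattern_signature(codes: np.ndarray, populations: list[str]) -> str:
    """Canonical string for one pattern: per-population bit-vectors, e.g.
    ``AFR:110|EUR:100``; populations listed in the given (fixed) order."""
    return "|".join(f"{p}:{c >> 2 & 1}{c >> 1 & 1}{c & 1}"
                    for p, c in zip(populations, codes))


def count_patterns(quantized: np.ndarray, populations: list[str]) -> pd.DataFrame:
    """Count occurrences of genotype-change patterns over loci.

    ``quantized`` has shape (n_loci, n_pops, 3).  Each locus maps to exactly
    one pattern: the assignment of populations to quantized vectors (which
    encodes the induced partition).  Returns patterns sorted by descending
    count with columns signature, n_groups, invariant, count, rank; counts
    sum to the number of loci.
    """
    quantized = np.asarray(quantized, dtype=bool)
    if quantized.ndim != 3 or quantized.shape[1] != len(populations):
        raise ValueError("quantized profile must be (n_loci, n_pops, 3)")
    codes = _vector_codes(quantized)  # (n_loci, n_pops)
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    rows = []
    for pattern, count in zip(uniq, counts):
        rows.append((
            pattern_signature(pattern, populations),
            len(set(pattern.tolist())),
            bool(len(set(pattern.tolist())) == 1),
            int(count),
        ))
    df = pd.DataFrame(rows, columns=["signature", "n_groups", "invariant", "count"])
    df = df.sort_values(["count", "signature"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
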