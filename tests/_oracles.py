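"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different algorithms
than the package implementation, so agreement is evidence rather than
tautology.
"""

import numpy as np


def sp_oracle(locus, table):
    """Spectral purity by exact ray-segment intersection via cross
    products, scanning every spectral-locus polyline segment.

    Solves A + s (B - A) = t P for each segment (A, B) and stimulus
    locus P; the outermost intersection (largest t) is the dominant-
    wavelength locus, and SP = 1/t.
    """
    P = np.array([locus.x, locus.y])
    best_t = None
    for A, B in zip(table.xy[:-1], table.xy[1:]):
        d = B - A
        denom = float(P[0] * d[1] - P[1] * d[0])
        if abs(denom) < 1e-300:
            continue
        s = float(A[0] * P[1] - A[1] * P[0]) / denom
        t = float(A[0] * d[1] - A[1] * d[0]) / denom
        if t > 0 and -1e-12 <= s <= 1 + 1e-12:
            if best_t is None or t > best_t:
                best_t = t
    if best_t is None:
        raise ValueError("oracle: stimulus ray misses the spectral locus")
    return 1.0 / best_t


def multinomial_mle_log_odds(counts):
    """Closed-form single-stratum multinomial MLE: log(n_k / n_1)."""
    counts = np.asarray(counts, dtype=float)
    return np.log(counts[1:] / counts[0])
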