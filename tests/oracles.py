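"""Independent brute-force oracles for the algorithmic operations.

Each oracle is written from the operation's mathematical definition, not its
implementation: the cutoff oracle scans the scaled curve explicitly, the
stitching oracle takes connected components of the pairwise gap graph, the
BH oracle evaluates the step-up minimum directly, and the signal oracle
integrates base by base.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def cutoff_oracle(signals) -> tuple[float, int]:
    """Explicit argmin of y_i - x_i over the unit-scaled curve, ties to largest i."""
    s = [max(0.0, float(v)) for v in signals]
    n = len(s)
    assert n >= 2
    smax = max(s)
    if smax == 0:
        return 0.0, n - 1
    best_i, best_d = None, None
    for i in range(n):
        x = i / (n - 1)
        y = s[i] / smax
        d = y - x
        if best_d is None or d < best_d or d == best_d:
            # <= keeps updating, so equal minima land on the largest index
            if best_d is None or d <= best_d:
                best_i, best_d = i, d
    return s[best_i], best_i


def stitch_oracle(starts, ends, stitch_distance):
    """Connected components of the 'gap <= d' graph over peaks of one chromosome.

    Returns a component label per peak; two peaks are joined directly when
    max(start_i, start_j) - min(end_i, end_j) <= d (overlap counts as a
    negative gap), and transitively through chains.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    n = starts.size
    if n == 0:
        return np.zeros(0, dtype=int)
    gap = np.maximum.outer(starts, starts) - np.minimum.outer(ends, ends)
    adj = csr_matrix(gap <= stitch_distance)
    _, labels = connected_components(adj, directed=False)
    return labels


def bh_oracle(pvalues):
    """Step-up q-values: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)  # p_(j) * n / j
    q_sorted = np.array(
        [min(1.0, scaled[rank_pos:].min()) for rank_pos in range(n)]
    )
    out = np.empty(n)
    out[order] = q_sorted
    return out


def region_mass_oracle(arr, bin_width, start, end) -> float:
    """Per-base integration of a binned track over [start, end)."""
    total = 0.0
    for b in range(max(0, start), min(end, len(arr) * bin_width)):
        total += arr[b // bin_width]
    return total


def classify_oracle(control, treated, frac):
    """All-pairs presence/absence classification.

    control/treated are lists of (chrom, start, end); returns (gain, lost)
    as index lists under the >= max(1, frac * shorter length) overlap rule.
    """

    def ov(a, b):
        if a[0] != b[0]:
            return 0
        return max(0, min(a[2], b[2]) - max(a[1], b[1]))

    def matches(a, b):
        need = max(1.0, frac * min(a[2] - a[1], b[2] - b[1]))
        return ov(a, b) >= need

    gain = [
        j for j, t in enumerate(treated)
        if not any(matches(t, c) for c in control)
    ]
    lost = [
        i for i, c in enumerate(control)
        if not any(matches(c, t) for t in treated)
    ]
    return gain, lost
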