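"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive loops and textbook definitions, not the package's
vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np


def fd_bruteforce(params: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Framewise displacement by an explicit per-frame, per-column loop."""
    n = params.shape[0]
    fd = [0.0]
    for t in range(1, n):
        s = 0.0
        for j in range(3):
            s += abs(params[t, j] - params[t - 1, j])
        for j in range(3, 6):
            s += radius * abs(params[t, j] - params[t - 1, j])
        fd.append(s)
    return np.array(fd)


def pac_bruteforce(
    consensus: np.ndarray,
    bounds: tuple[float, float] = (0.1, 0.9),
    valid: np.ndarray | None = None,
) -> float:
    """PAC by a double loop over upper-triangle entries."""
    n = consensus.shape[0]
    lo, hi = bounds
    amb = tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            if valid is not None and not valid[i, j]:
                continue
            tot += 1
            if lo < consensus[i, j] < hi:
                amb += 1
    return amb / tot


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition.

    adj[(i)] = min_{j >= i} min(1, p[(j)] * m / j) on the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def percentile_bruteforce(x: np.ndarray, q: float) -> float:
    """q-th percentile with linear interpolation, from the textbook formula."""
    xs = sorted(x)
    h = (len(xs) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return float(xs[lo])
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def runlength_bruteforce(labels, k: int, tr: float):
    """Entries / duration / occupancy by an explicit run scanner.

    Returns (entries, duration_s, occupancy) arrays of length k.  Any code
    outside 1..k breaks runs and is not counted as assigned.
    """
    runs: list[tuple[int, int]] = []  # (cap, length)
    cur = None
    cur_len = 0
    for lab in list(labels) + [None]:
        cap = lab if (lab is not None and 1 <= lab <= k) else None
        if cap == cur and cap is not None:
            cur_len += 1
        else:
            if cur is not None:
                runs.append((cur, cur_len))
            cur = cap
            cur_len = 1 if cap is not None else 0
    entries = np.zeros(k, dtype=int)
    total = np.zeros(k, dtype=int)
    for cap, length in runs:
        entries[cap - 1] += 1
        total[cap - 1] += length
    duration = np.array(
        [tr * total[c] / entries[c] if entries[c] else 0.0 for c in range(k)]
    )
    assigned = total.sum()
    occupancy = total / assigned if assigned else np.zeros(k)
    return entries, duration, occupancy
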