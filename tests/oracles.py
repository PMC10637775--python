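"""Independent brute-force oracles used to validate the optimized paths.

These deliberately re-derive each quantity from first principles (vertex
enumeration, exhaustive frame scans) and share no code with the package
implementations they check.
"""

from itertools import combinations

import numpy as np


def support_line_bruteforce(y: np.ndarray):
    """Exact cubic lower-envelope fit by vertex enumeration.

    The LP optimum (minimize sum of gaps s.t. cubic <= y) lies at a vertex
    where 4 constraints are active: enumerate all 4-subsets of frames, solve
    for the interpolating cubic, keep feasible ones, return the minimizer.
    Works in the normalized basis x = t/(n-1).  Returns (objective, coeffs).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(n) / (n - 1)
    vand = np.vander(x, 4, increasing=True)
    idx = np.array(list(combinations(range(n), 4)))
    mats = vand[idx]  # (m, 4, 4)
    rhs = y[idx]  # (m, 4)
    dets = np.abs(np.linalg.det(mats))
    ok = dets > 1e-9
    coefs = np.linalg.solve(mats[ok], rhs[ok][..., None])[..., 0]
    vals = coefs @ vand.T  # (m', n)
    feas = np.all(vals <= y + 1e-9, axis=1)
    coefs, vals = coefs[feas], vals[feas]
    objs = y.sum() - vals.sum(axis=1)
    best = int(np.argmin(objs))
    return float(objs[best]), coefs[best]


def participation_bruteforce(raster: np.ndarray, se_peak: int, w: int):
    """Exhaustive frame-by-frame scan for participating cells."""
    n_cells, n_frames = raster.shape
    out = []
    for c in range(n_cells):
        for f in range(n_frames):
            if raster[c, f] and abs(f - se_peak) <= w:
                out.append(c)
                break
    return np.array(out, dtype=int)


def sync_async_bruteforce(peaks, se_peaks, w):
    """Exhaustive window-membership partition of event peaks."""
    n_sync = 0
    for p in peaks:
        if any(abs(int(p) - int(s)) <= w for s in se_peaks):
            n_sync += 1
    return n_sync, len(peaks) - n_sync
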