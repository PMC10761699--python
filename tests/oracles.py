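"""Independent reference implementations used as test oracles."""
from __future__ import annotations

import numpy as np

SLOPE_TIE_RTOL = 1e-9  # same tie rule as the implementation under test


def brute_force_window(times, ln_values, min_points=4, r2_min=0.90):
    """Exhaustive window search with per-window np.polyfit fits.

    Returns (i_start, i_end, slope) over the finite points, or None when
    no window qualifies. Selection: maximal slope; ties (within a small
    relative tolerance) broken by longer window, then earlier start.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ln_values, dtype=float)
    mask = np.isfinite(y) & np.isfinite(t)
    t, y = t[mask], y[mask]
    n = t.size
    best = None  # (i, j, slope)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            x, z = t[i : j + 1], y[i : j + 1]
            if np.ptp(x) == 0:
                continue
            slope, intercept = np.polyfit(x, z, 1)
            pred = slope * x + intercept
            ss_tot = float(np.sum((z - z.mean()) ** 2))
            if ss_tot == 0:
                r2 = 1.0
            else:
                r2 = 1.0 - float(np.sum((z - pred) ** 2)) / ss_tot
            if r2 < r2_min:
                continue
            if best is None:
                best = (i, j, float(slope))
                continue
            tol = SLOPE_TIE_RTOL * max(1.0, abs(best[2]))
            if slope > best[2] + tol:
                best = (i, j, float(slope))
            elif slope >= best[2] - tol:
                if (j - i) > (best[1] - best[0]):
                    best = (i, j, float(slope))
                # earlier start at equal length is already in `best`
                # because of the iteration order
    return best


def exclusion_rule_violations(times, gi, gi0, restart_times):
    """Straight-line re-evaluation of the point-level exclusion rules.

    Returns the set of times that any rule removes: GI below the gi0
    reference, plus the first reading strictly after each restart
    (evaluated left to right, skipping already-removed readings).
    """
    times = np.asarray(times, dtype=float)
    gi = np.asarray(gi, dtype=float)
    removed = set()
    # restart removals, consuming left to right
    alive = list(range(times.size))
    for t_r in restart_times:
        for idx in alive:
            if times[idx] > t_r:
                removed.add(float(times[idx]))
                alive.remove(idx)
                break
    for idx in list(alive):
        if gi[idx] < gi0:
            removed.add(float(times[idx]))
    return removed
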