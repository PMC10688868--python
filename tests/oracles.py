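"""Independent brute-force oracles used by the test suite.

Every function here re-derives a statistic from its definition with plain
Python loops, deliberately sharing no code path with the package
implementation it checks.
"""

import math


def mage_oracle(values):
    """Exhaustive turning-point MAGE on a raw value list.

    Definition: smooth with a centered 3-point moving average (endpoints
    passed through), compress equal-value runs to their midpoint index,
    mark every interior sign change of successive differences as a turning
    point, take amplitudes between raw values at successive turning points,
    keep those exceeding one sample standard deviation of the raw series,
    and average them.  Returns (mage, qualifying_set).
    """
    v = [float(x) for x in values]
    n = len(v)
    if n < 3:
        return 0.0, set()
    mean = sum(v) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))

    smooth = list(v)
    for i in range(1, n - 1):
        smooth[i] = (v[i - 1] + v[i] + v[i + 1]) / 3.0

    # compress equal runs, representative index = run midpoint
    reps = []  # (index, value)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        reps.append(((i + j) // 2, smooth[i]))
        i = j + 1

    turns = []
    for k in range(1, len(reps) - 1):
        d1 = reps[k][1] - reps[k - 1][1]
        d2 = reps[k + 1][1] - reps[k][1]
        if (d1 > 0 > d2) or (d1 < 0 < d2):
            turns.append(reps[k][0])

    qualifying = set()
    amps = []
    for a, b in zip(turns, turns[1:]):
        amp = abs(v[b] - v[a])
        if amp > sd:
            qualifying.add((a, b))
            amps.append(amp)
    if not amps:
        return 0.0, set()
    return sum(amps) / len(amps), qualifying


def weighted_mean_oracle(days):
    """Mean-of-cell-means oracle for inverse-frequency weighting.

    ``days`` is a list of ((weekday, season), value) pairs for one
    participant; the weighted mean equals the unweighted average of the
    per-cell averages.
    """
    cells = {}
    for cell, value in days:
        cells.setdefault(cell, []).append(value)
    cell_means = [sum(vs) / len(vs) for vs in cells.values()]
    return sum(cell_means) / len(cell_means)


def bray_curtis_oracle(x, y):
    """Naive elementwise Bray-Curtis between two abundance vectors."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def completion_rate_oracle(rows, stratum_key):
    """Group-by-dict completion rates per (cohort, stratum level).

    ``rows``: list of dicts with keys cohort, phase, and the stratum key.
    Returns {(cohort, level): (n_enrolled, n_completed)}.
    """
    out = {}
    for r in rows:
        key = (r["cohort"], r[stratum_key])
        n_enr, n_comp = out.get(key, (0, 0))
        out[key] = (n_enr + 1, n_comp + (1 if r["phase"] == "completed" else 0))
    return out


def censoring_retention_oracle(n_days, scan_mean_h, memory_h, rng, n_reps):
    """Monte-Carlo retained fraction of a 15-min grid under renewal scanning.

    Scans arrive with exponential gaps of mean ``scan_mean_h`` hours from
    the window start; a grid point survives iff a scan lands within
    ``memory_h`` hours after it.
    """
    total_kept = 0
    total = 0
    grid = [i * 0.25 for i in range(n_days * 96)]
    horizon = grid[-1]  # scans stop at the last reading, as the sensor does
    for _ in range(n_reps):
        scans = []
        t = 0.0
        while True:
            t += rng.exponential(scan_mean_h)
            if t > horizon:
                break
            scans.append(t)
        kept = 0
        si = 0
        for g in grid:
            while si < len(scans) and scans[si] < g:
                si += 1
            if si < len(scans) and scans[si] - g <= memory_h:
                kept += 1
        total_kept += kept
        total += len(grid)
    return total_kept / total
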