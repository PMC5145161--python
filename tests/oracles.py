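"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for transparency, not speed: plain loops over
bins, pairs and label grids, no shared code with the package internals.
"""

from __future__ import annotations

import numpy as np

# mirror of the documented selection constants (kept literal on purpose)
SIZE_TOL = 0.95
SKIP_FRAC = 0.8


def brute_rate_mask(times, bin_ms=500.0, hop_ms=250.0, max_events=100):
    """Remove events covered by any over-full overlapping bin."""
    times = np.asarray(times, float)
    keep = np.ones(times.size, bool)
    if times.size == 0:
        return keep
    t_end = times.max()
    start = 0.0
    while start <= t_end:
        inside = (times >= start) & (times < start + bin_ms)
        if inside.sum() > max_events:
            keep[inside] = False
        start += hop_ms
    return keep


def brute_concurrent_masks(times_by_channel, bin_ms=3.0, hop_ms=1.5,
                           frac=0.5, min_channels=10):
    channels = list(times_by_channel)
    keep = {c: np.ones(len(times_by_channel[c]), bool) for c in channels}
    if len(channels) < min_channels:
        return keep
    arrays = {c: np.asarray(times_by_channel[c], float) for c in channels}
    t_end = max((a.max() for a in arrays.values() if a.size), default=-1.0)
    start = 0.0
    while start <= t_end:
        occupied = sum(
            1 for a in arrays.values()
            if np.any((a >= start) & (a < start + bin_ms))
        )
        if occupied >= frac * len(channels):
            for c, a in arrays.items():
                keep[c][(a >= start) & (a < start + bin_ms)] = False
        start += hop_ms
    return keep


def brute_double_mask(times, maxima, window=1.5):
    """Left-to-right sweep keeping the larger maximum of close pairs."""
    times = np.asarray(times, float)
    keep = np.ones(times.size, bool)
    if times.size < 2:
        return keep
    survivor = 0
    for j in range(1, times.size):
        if times[j] - times[survivor] < window:
            if maxima[j] > maxima[survivor]:
                keep[survivor] = False
                survivor = j
            else:
                keep[j] = False
        else:
            survivor = j
    return keep


def brute_select_from_table(size_table, c_max, s_min, n_total,
                            skip_frac=SKIP_FRAC, skip_all_temps=False,
                            trivial_first=True):
    """Selection decisions from a per-temperature size table.

    ``size_table`` is a list (per temperature) of descending size lists.
    Returns the set of (temperature, rank) pairs that qualify and survive
    the c_max cap; membership/claiming is not modelled here (tables only).
    ``trivial_first`` zeroes the first row when it is the single all-points
    cluster.
    """
    table = [list(row) for row in size_table]
    if trivial_first and len(table[0]) == 1 and table[0][0] == n_total:
        table[0] = []

    def at(j, i):
        return table[j][i] if i < len(table[j]) else 0

    chosen = []
    for j in range(1, len(table) - 1):
        n_sel = 0
        for i in range(len(table[j])):
            size = at(j, i)
            if size < s_min:
                break
            if size >= skip_frac * n_total and (skip_all_temps or j == 1):
                continue
            if not (size >= SIZE_TOL * at(j - 1, i)
                    and size >= SIZE_TOL * at(j + 1, i)):
                continue
            if n_sel >= c_max:
                break
            chosen.append((j, i))
            n_sel += 1
    return chosen


def brute_nearest_admissible(spike, means, radii):
    """Index of the nearest cluster whose radius admits the spike, or -1."""
    best, best_d = -1, np.inf
    for c, (m, r) in enumerate(zip(means, radii)):
        d = float(np.linalg.norm(spike - m))
        if d < r and d < best_d:
            best, best_d = c, d
    return best


def brute_merge(stats, c_stop, metric="normalized"):
    """Exhaustive min-pair agglomeration over (mean, var, size) triples.

    ``stats`` maps cluster id -> (mean_wave, var_wave, size). Returns the
    final grouping as a set of frozensets of cluster ids.
    """
    groups = {cid: ([cid], np.asarray(m, float), np.asarray(v, float), n)
              for cid, (m, v, n) in stats.items()}

    def dist(a, b):
        d = float(np.linalg.norm(a[1] - b[1]))
        if metric == "raw":
            return d
        s = min(np.sqrt(a[2].sum()), np.sqrt(b[2].sum()))
        if s == 0:
            return 0.0 if d == 0 else np.inf
        return d / s

    while len(groups) > 1:
        keys = sorted(groups)
        pairs = [(dist(groups[a], groups[b]), a, b)
                 for i, a in enumerate(keys) for b in keys[i + 1:]]
        d, a, b = min(pairs)
        if d > c_stop:
            break
        ga, gb = groups.pop(a), groups.pop(b)
        n = ga[3] + gb[3]
        mean = (ga[3] * ga[1] + gb[3] * gb[1]) / n
        var = (ga[3] * (ga[2] + (ga[1] - mean) ** 2)
               + gb[3] * (gb[2] + (gb[1] - mean) ** 2)) / n
        groups[a] = (ga[0] + gb[0], mean, var, n)
    return {frozenset(g[0]) for g in groups.values()}


def brute_hits(unit_labels, true_labels, neuron_totals):
    """Contingency-table hit scoring.

    ``unit_labels``: per sorted spike, its unit id; ``true_labels``: per
    sorted spike, the matched true neuron (0 = unmatched);
    ``neuron_totals``: total true spikes per neuron. Returns
    ``{unit: (neuron, purity, completeness, hit)}``.
    """
    out = {}
    for unit in sorted(set(unit_labels)):
        members = [t for u, t in zip(unit_labels, true_labels) if u == unit]
        counts = {}
        for t in members:
            if t != 0:
                counts[t] = counts.get(t, 0) + 1
        if not counts:
            out[unit] = (0, 0.0, 0.0, False)
            continue
        # plurality neuron, lowest id on ties (matches argmax convention)
        neuron = max(sorted(counts), key=lambda k: counts[k])
        purity = counts[neuron] / len(members)
        completeness = counts[neuron] / neuron_totals[neuron]
        out[unit] = (neuron, purity, completeness,
                     purity >= 0.5 and completeness >= 0.5)
    return out


def brute_bh(pvals):
    """Textbook step-up adjustment: adj_i = min_{p_(j) >= p_(i)} m p_(j)/j."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
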