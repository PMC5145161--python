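"""Static diagnostic plots: temperature sweeps and per-unit panels."""

from __future__ import annotations

import numpy as np

from .containers import SortingResult, SpikeSet
from .sorter import BlockResult
from .spc import SPCResult


def plot_temperatures(spc: SPCResult, trace=None, ax=None, max_rank: int = 8):
    """Cluster sizes over the temperature sweep, selected clusters marked.

    Each line follows one size rank across temperatures (log scale);
    selected clusters from the selection trace are marked black, skipped
    ones red.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    table = np.zeros((spc.n_t, max_rank))
    for j in range(spc.n_t):
        sizes = spc.sizes(j)[:max_rank]
        table[j, :sizes.size] = sizes
    for i in range(max_rank):
        ax.plot(spc.temperatures, np.maximum(table[:, i], 1), "-",
                color="0.6", lw=0.8)
    if trace:
        for ev in trace:
            if ev.temp_index >= spc.n_t:
                continue
            ax.plot(spc.temperatures[ev.temp_index], max(ev.size, 1),
                    "o", ms=5, color="k" if ev.selected else "r")
    ax.set_yscale("log")
    ax.set_xlabel("temperature")
    ax.set_ylabel("cluster size (spikes)")
    return ax


def plot_unit(spikes: SpikeSet, sorting: SortingResult, group: int,
              thresholds: list[float] | None = None):
    """Panel set for one unit group: densities, means, ISI, counts, maxima.

    Produces the standard quality panels: waveform density (linear and
    log), overlay of member-cluster means, inter-spike-interval histogram,
    cumulative spike count over time, distribution of spike maxima against
    the detection threshold(s), and maxima over time.
    """
    import matplotlib.pyplot as plt

    idx = sorting.spikes_of_group(group)
    waves = spikes.waveforms[idx]
    times = sorting.times[idx]
    fig, axes = plt.subplots(2, 4, figsize=(14, 6))
    (ax_d, ax_dl, ax_m, ax_isi), (ax_cum, ax_max, ax_maxt, ax_off) = axes

    k = waves.shape[1]
    t_axis = np.arange(k) / spikes.rate_eff * 1000.0
    for ax, log in ((ax_d, False), (ax_dl, True)):
        amp_edges = np.linspace(waves.min(), waves.max(), 80)
        dens = np.stack([np.histogram(waves[:, i], bins=amp_edges)[0]
                         for i in range(k)]).T
        if log:
            dens = np.log1p(dens)
        ax.imshow(dens, origin="lower", aspect="auto",
                  extent=[t_axis[0], t_axis[-1], amp_edges[0], amp_edges[-1]])
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("amplitude (uV)")
        ax.set_title("density" + (" (log)" if log else ""))

    members = [c for c, g in sorting.group_id.items() if g == group]
    for cid in members:
        midx = sorting.spikes_of(cid)
        if midx.size:
            ax_m.plot(t_axis, spikes.waveforms[midx].mean(axis=0), lw=1)
    ax_m.set_title(f"member means (n={len(members)})")
    ax_m.set_xlabel("time (ms)")

    isi = np.diff(np.sort(times))
    ax_isi.hist(isi[isi < 100], bins=50)
    ax_isi.set_xlabel("ISI (ms)")
    ax_isi.set_title("inter-spike intervals")

    ax_cum.plot(np.sort(times) / 60000.0, np.arange(1, idx.size + 1))
    ax_cum.set_xlabel("time (min)")
    ax_cum.set_title("cumulative count")

    maxima = waves.max(axis=1)
    ax_max.hist(maxima, bins=60)
    for thr in thresholds or []:
        ax_max.axvline(thr, color="m", lw=1)
    ax_max.set_xlabel("spike maximum (uV)")
    ax_max.set_title("maxima distribution")

    ax_maxt.plot(times / 60000.0, maxima, ".", ms=1)
    for thr in thresholds or []:
        ax_maxt.axhline(thr, color="m", lw=1)
    ax_maxt.set_xlabel("time (min)")
    ax_maxt.set_title("maxima over time")

    ax_off.axis("off")
    fig.suptitle(f"group {group}: {idx.size} spikes")
    fig.tight_layout()
    return fig
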