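"""Event-level (pre-sorting) and cluster-level (post-sorting) artifact rules.

Pre-sorting criteria operate on detected events before any clustering:

1. firing-rate — overlapping time bins containing more events than a
   physiological ceiling are excised wholesale;
2. amplitude — events whose absolute extremum exceeds 1 mV are discarded;
3. double detection — of two detections closer than the extraction window
   allows, the one with the smaller maximum is discarded;
4. concurrency — time bins in which a large fraction of all recorded
   channels carry an event are excised on every channel (movement and mains
   artifacts hit many channels, action potentials do not).

Criteria 1–3 look at a single channel only; criterion 4 is the only
cross-channel rule. All bin grids are anchored at recording start (t = 0)
and an event is removed if *any* covering bin violates its rule. Thresholds
are strict inequalities ("more than", "exceeding").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ARTIFACT_BITS
from .params import ArtifactParams

__all__ = [
    "mask_high_rate",
    "mask_high_amplitude",
    "resolve_double_detections",
    "mask_concurrent",
    "reject_events",
    "flag_artifact_cluster",
    "RejectionReport",
]


def _bin_starts(t_end: float, width: float, hop: float) -> np.ndarray:
    """Left edges of overlapping bins [start, start+width) covering [0, t_end]."""
    if t_end < 0:
        return np.empty(0)
    n = int(np.floor(t_end / hop)) + 1
    return np.arange(n) * hop


def _events_in_violating_bins(times: np.ndarray, width: float, hop: float,
                              violates) -> np.ndarray:
    """Keep-mask; an event is dropped if any covering bin satisfies ``violates``.

    ``violates`` maps an array of per-bin event counts (or the bin index
    grid) to a boolean array. Bins are [start, start+width), starts on a
    ``hop`` grid from time 0.
    """
    times = np.asarray(times, dtype=np.float64)
    keep = np.ones(times.size, dtype=bool)
    if times.size == 0:
        return keep
    times_sorted = np.sort(times) if np.any(np.diff(times) < 0) else times
    starts = _bin_starts(times.max(), width, hop)
    lo = np.searchsorted(times_sorted, starts, side="left")
    hi = np.searchsorted(times_sorted, starts + width, side="left")
    bad = violates(hi - lo)
    drop = np.zeros(times.size + 1, dtype=np.int64)
    np.add.at(drop, lo[bad], 1)
    np.add.at(drop, hi[bad], -1)
    covered = np.cumsum(drop[:-1]) > 0
    if times_sorted is times:
        keep = ~covered
    else:  # map back to original order
        order = np.argsort(times, kind="stable")
        keep[order] = ~covered
    return keep


def mask_high_rate(times: np.ndarray, p: ArtifactParams | None = None) -> np.ndarray:
    """Criterion 1: excise overlapping bins with implausibly many events.

    Default geometry is 500 ms bins with a 250 ms hop; a bin holding
    strictly more than ``rate_max_events`` (100, i.e. a 200 Hz rate) events
    is removed together with every event it covers.
    """
    p = p or ArtifactParams()
    return _events_in_violating_bins(
        times, p.rate_bin, p.rate_bin - p.rate_overlap,
        lambda counts: counts > p.rate_max_events,
    )


def mask_high_amplitude(waveforms: np.ndarray,
                        p: ArtifactParams | None = None) -> np.ndarray:
    """Criterion 2: drop events whose absolute extremum exceeds 1 mV."""
    p = p or ArtifactParams()
    waveforms = np.atleast_2d(waveforms)
    if waveforms.shape[0] == 0:
        return np.empty(0, dtype=bool)
    return np.abs(waveforms).max(axis=1) <= p.amp_limit


def resolve_double_detections(times: np.ndarray, waveforms: np.ndarray,
                              p: ArtifactParams | None = None) -> np.ndarray:
    """Criterion 3: of two detections < 1.5 ms apart keep the larger maximum.

    Chains are resolved by a single deterministic left-to-right sweep: the
    current survivor is compared with the next event in time; the smaller
    maximum is dropped and the larger one carries the comparison forward.

    The compared maximum is each waveform's value at the common alignment
    index (inferred as the median peak position), not the window-wide
    maximum: when two detections are close, both extraction windows contain
    the same physical peak, and the window-wide maximum would make the
    comparison a coin flip instead of preferring the detection aligned on
    that peak.
    """
    p = p or ArtifactParams()
    times = np.asarray(times, dtype=np.float64)
    keep = np.ones(times.size, dtype=bool)
    if times.size < 2:
        return keep
    waves = np.atleast_2d(waveforms)
    align = int(np.median(waves.argmax(axis=1)))
    maxima = waves[:, align]
    survivor = 0
    for j in range(1, times.size):
        if times[j] - times[survivor] < p.double_window:
            if maxima[j] > maxima[survivor]:
                keep[survivor] = False
                survivor = j
            else:
                keep[j] = False
        else:
            survivor = j
    return keep


def mask_concurrent(times_by_channel: dict[str, np.ndarray],
                    p: ArtifactParams | None = None) -> dict[str, np.ndarray]:
    """Criterion 4: excise bins carrying events on >= 50% of all channels.

    Uses 3 ms bins with a 1.5 ms hop over all channels at once; every event
    of a violating bin is removed on every channel. With fewer than
    ``conc_min_channels`` channels the rule is disabled (it would delete
    genuine coincident firing on small setups) and all-keep masks return.
    """
    p = p or ArtifactParams()
    channels = list(times_by_channel)
    keep = {c: np.ones(np.asarray(times_by_channel[c]).size, dtype=bool)
            for c in channels}
    n_ch = len(channels)
    if n_ch < p.conc_min_channels:
        return keep
    all_times = [np.asarray(times_by_channel[c], dtype=np.float64) for c in channels]
    t_max = max((t.max() for t in all_times if t.size), default=-1.0)
    if t_max < 0:
        return keep
    hop = p.conc_bin - p.conc_overlap
    starts = _bin_starts(t_max, p.conc_bin, hop)
    occupancy = np.zeros(starts.size, dtype=np.int64)
    bounds = {}
    for c, t in zip(channels, all_times):
        ts = np.sort(t) if t.size and np.any(np.diff(t) < 0) else t
        lo = np.searchsorted(ts, starts, side="left")
        hi = np.searchsorted(ts, starts + p.conc_bin, side="left")
        bounds[c] = (ts, lo, hi)
        occupancy += hi > lo
    bad = occupancy >= p.conc_frac * n_ch
    for c, t in zip(channels, all_times):
        ts, lo, hi = bounds[c]
        drop = np.zeros(t.size + 1, dtype=np.int64)
        np.add.at(drop, lo[bad], 1)
        np.add.at(drop, hi[bad], -1)
        covered = np.cumsum(drop[:-1]) > 0
        if ts is t:
            keep[c] = ~covered
        else:
            order = np.argsort(t, kind="stable")
            keep[c][order] = ~covered
    return keep


@dataclass
class RejectionReport:
    """Per-criterion keep-masks and removal counts for one channel set."""

    masks: dict[str, dict[str, np.ndarray]]   # channel -> criterion -> keep
    params: ArtifactParams = field(default_factory=ArtifactParams)

    CRITERIA = ("rate", "amplitude", "double", "concurrent")

    def keep(self, channel: str) -> np.ndarray:
        """Final keep-mask: AND over all criterion masks."""
        masks = self.masks[channel]
        out = np.ones_like(next(iter(masks.values())), dtype=bool)
        for m in masks.values():
            out &= m
        return out

    def removed_counts(self, channel: str) -> dict[str, int]:
        return {crit: int((~m).sum()) for crit, m in self.masks[channel].items()}

    def summary(self):
        """Tabular per-criterion summary (fractions removed per channel)."""
        import pandas as pd

        rows = []
        for crit in self.CRITERIA:
            fracs = []
            removed = total = 0
            for ch, masks in self.masks.items():
                n = masks[crit].size
                r = int((~masks[crit]).sum())
                total += n
                removed += r
                if n:
                    fracs.append(r / n)
            fracs = np.asarray(fracs)
            affected = fracs > 0
            rows.append({
                "criterion": crit,
                "pct_channels_affected": 100 * affected.mean() if fracs.size else 0.0,
                "mean_pct_removed_affected":
                    100 * fracs[affected].mean() if affected.any() else 0.0,
                "max_pct_removed": 100 * fracs.max() if fracs.size else 0.0,
                "pct_of_all_spikes": 100 * removed / total if total else 0.0,
            })
        # combined row: any criterion
        fracs = []
        removed = total = 0
        for ch in self.masks:
            keep = self.keep(ch)
            total += keep.size
            removed += int((~keep).sum())
            if keep.size:
                fracs.append((~keep).mean())
        fracs = np.asarray(fracs)
        affected = fracs > 0
        rows.append({
            "criterion": "any",
            "pct_channels_affected": 100 * affected.mean() if fracs.size else 0.0,
            "mean_pct_removed_affected":
                100 * fracs[affected].mean() if affected.any() else 0.0,
            "max_pct_removed": 100 * fracs.max() if fracs.size else 0.0,
            "pct_of_all_spikes": 100 * removed / total if total else 0.0,
        })
        return pd.DataFrame(rows).set_index("criterion")


def reject_events(spike_sets: dict[str, "SpikeSet"],
                  p: ArtifactParams | None = None) -> RejectionReport:
    """Run all four pre-sorting criteria over a set of channels.

    ``spike_sets`` maps channel id to its SpikeSet. Surviving spikes keep
    their original order (masks never reorder).
    """
    p = p or ArtifactParams()
    masks: dict[str, dict[str, np.ndarray]] = {}
    for ch, ss in spike_sets.items():
        masks[ch] = {
            "rate": mask_high_rate(ss.times, p),
            "amplitude": mask_high_amplitude(ss.waveforms, p),
            "double": resolve_double_detections(ss.times, ss.waveforms, p),
        }
    conc = mask_concurrent({ch: ss.times for ch, ss in spike_sets.items()}, p)
    for ch in spike_sets:
        masks[ch]["concurrent"] = conc[ch]
    return RejectionReport(masks=masks, params=p)


def _local_maxima(wave: np.ndarray, smooth: int = 0) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D waveform."""
    w = np.asarray(wave, dtype=np.float64)
    if smooth > 0:
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        w = np.convolve(w, kernel, mode="same")
    d = np.diff(w)
    # strict sign change + -> - of the first difference
    return np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1


def flag_artifact_cluster(cluster_waveforms: np.ndarray, rate_eff: float,
                          p: ArtifactParams | None = None
                          ) -> tuple[bool, frozenset]:
    """Post-sorting artifact decision for one cluster.

    A cluster is an artifact if any of the following holds for its mean
    waveform: (a) more than 5 local maxima; (b) the ratio of the largest to
    the second-largest local maximum is below 2, counting only maxima at
    least 0.3 ms apart; (c) the amplitude range spanned by the second half
    exceeds the global maximum; or (d) the mean over sampling points of the
    per-point standard error of the mean exceeds 2 uV. Criterion (d) is
    undefined for single-spike clusters and skipped with a warning.

    Returns ``(is_artifact, criteria_fired)`` with criteria named by the
    keys of :data:`spikeblocks.containers.ARTIFACT_BITS`.
    """
    import warnings

    p = p or ArtifactParams()
    waves = np.atleast_2d(np.asarray(cluster_waveforms, dtype=np.float64))
    if waves.shape[0] < 1:
        raise ValueError("cluster must contain at least one waveform")
    mean = waves.mean(axis=0)
    fired = set()

    maxima = _local_maxima(mean, p.maxima_smooth)
    if maxima.size > p.max_local_maxima:
        fired.add("maxima")

    # (b): ratio of the two largest maxima, only maxima >= peak_sep apart
    if maxima.size >= 2:
        sep = p.peak_sep * rate_eff / 1000.0
        order = maxima[np.argsort(mean[maxima])[::-1]]
        kept = [order[0]]
        for idx in order[1:]:
            if all(abs(idx - kj) >= sep for kj in kept):
                kept.append(idx)
        if len(kept) >= 2:
            largest, second = mean[kept[0]], mean[kept[1]]
            if second > 0 and largest / second < p.peak_ratio_min:
                fired.add("peak_ratio")

    half = mean[mean.size // 2:]
    if half.size and (half.max() - half.min()) > mean.max():
        fired.add("tail_range")

    if waves.shape[0] >= 2:
        sem = waves.std(axis=0, ddof=1) / np.sqrt(waves.shape[0])
        if sem.mean() > p.sem_limit:
            fired.add("sem")
    else:
        warnings.warn("single-spike cluster: SEM criterion skipped", stacklevel=2)

    assert fired <= set(ARTIFACT_BITS)
    return bool(fired), frozenset(fired)
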