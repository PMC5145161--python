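"""Ground-truth scoring and stimulus-response detection.

Hit scoring compares a sorting against simulated ground truth: sorted
spikes are matched to true spikes by time (nearest neighbor within a
tolerance, one-to-one), each sorted unit is paired with its plurality
neuron, and a unit counts as a *hit* when at least 50% of its spikes come
from that neuron (purity) and at least 50% of that neuron's spikes are in
the unit (completeness).

Response scoring detects stimulus-locked firing: spike counts in 19
overlapping 100 ms bins over the 1 s stimulus window are tested per bin
against baseline counts (Mann-Whitney U), the 19 p-values are adjusted by
the Benjamini-Hochberg step-up procedure, and the unit-stimulus pair is a
response when the minimum adjusted p-value falls below 0.001 and spikes
occur during at least four presentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GroundTruth, SortingResult
from .params import ResponseParams

__all__ = [
    "match_spike_times",
    "score_hits",
    "HitReport",
    "bh_adjust",
    "response_score",
]


def match_spike_times(sorted_times: np.ndarray, true_times: np.ndarray,
                      tol_ms: float = 0.5) -> np.ndarray:
    """One-to-one nearest-neighbor matching of event times.

    Returns, per sorted spike, the index of its matched true spike or -1.
    Each true spike is used at most once; when two sorted spikes are
    nearest to the same true spike, the earlier sorted spike wins.
    """
    sorted_times = np.asarray(sorted_times, dtype=np.float64)
    true_times = np.asarray(true_times, dtype=np.float64)
    match = np.full(sorted_times.size, -1, dtype=np.int64)
    if sorted_times.size == 0 or true_times.size == 0:
        return match
    # ground-truth times are only guaranteed sorted per neuron
    true_order = np.argsort(true_times, kind="stable")
    true_sorted = true_times[true_order]
    taken = np.zeros(true_sorted.size, dtype=bool)
    pos = np.searchsorted(true_sorted, sorted_times)
    for i in np.argsort(sorted_times, kind="stable"):
        best, best_d = -1, tol_ms
        for j in (pos[i] - 1, pos[i]):
            if 0 <= j < true_sorted.size and not taken[j]:
                d = abs(sorted_times[i] - true_sorted[j])
                if d <= best_d:
                    best, best_d = j, d
        if best >= 0:
            match[i] = int(true_order[best])
            taken[best] = True
    return match


@dataclass
class HitReport:
    """Per-unit purity/completeness against ground truth, plus the summary."""

    units: pd.DataFrame      # unit, matched_neuron, purity, completeness, hit
    n_neurons: int
    n_hits: int

    @property
    def hit_fraction(self) -> float:
        return self.n_hits / self.n_neurons if self.n_neurons else 0.0


def score_hits(sorting: SortingResult, truth: GroundTruth,
               tol_ms: float = 0.5, by_group: bool = True) -> HitReport:
    """Score sorted units against simulated neurons by the 50%/50% rule.

    Units are merged groups when ``by_group`` (falling back to clusters
    that are in no group), otherwise raw clusters. The residual cluster is
    never a unit. The summary counts distinct neurons hit, as a fraction of
    all simulated neurons.
    """
    match = match_spike_times(sorting.times, truth.times, tol_ms)
    spike_neuron = np.where(match >= 0, truth.neuron_id[match.clip(min=0)], 0)
    neuron_totals = {int(nid): int((truth.neuron_id == nid).sum())
                     for nid in np.unique(truth.neuron_id)}

    if by_group:
        units = {f"g{g}": sorting.spikes_of_group(g) for g in sorting.groups()}
        grouped = set(sorting.group_id)
        for cid in sorting.cluster_ids():
            if cid not in grouped and not sorting.is_artifact(cid):
                units[f"c{cid}"] = sorting.spikes_of(cid)
    else:
        units = {f"c{cid}": sorting.spikes_of(cid)
                 for cid in sorting.cluster_ids()}

    rows = []
    hit_neurons = set()
    for name, idx in sorted(units.items()):
        if idx.size == 0:
            continue
        labels = spike_neuron[idx]
        counted = np.bincount(labels[labels > 0])
        if counted.size <= 1 or counted[1:].max() == 0:
            rows.append({"unit": name, "n_spikes": int(idx.size),
                         "matched_neuron": 0, "purity": 0.0,
                         "completeness": 0.0, "hit": False})
            continue
        neuron = int(np.argmax(counted[1:]) + 1)
        overlap = int(counted[neuron])
        purity = overlap / idx.size
        completeness = overlap / neuron_totals[neuron]
        hit = purity >= 0.5 and completeness >= 0.5
        if hit:
            hit_neurons.add(neuron)
        rows.append({"unit": name, "n_spikes": int(idx.size),
                     "matched_neuron": neuron, "purity": purity,
                     "completeness": completeness, "hit": hit})
    units_df = pd.DataFrame(
        rows, columns=["unit", "n_spikes", "matched_neuron", "purity",
                       "completeness", "hit"])
    return HitReport(units=units_df, n_neurons=truth.n_neurons,
                     n_hits=len(hit_neurons))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bin_counts(spike_times: np.ndarray, start_ms: float, rp: ResponseParams
                ) -> np.ndarray:
    """Counts in the overlapping peristimulus bins after one onset."""
    edges_lo = start_ms + np.arange(rp.n_bins) * rp.hop_ms
    edges_hi = edges_lo + rp.bin_ms
    lo = np.searchsorted(spike_times, edges_lo)
    hi = np.searchsorted(spike_times, edges_hi)
    return hi - lo


def response_score(spike_times: np.ndarray, stim_onsets: np.ndarray,
                   rp: ResponseParams | None = None,
                   baseline_onsets: np.ndarray | None = None
                   ) -> tuple[float, bool]:
    """Score one unit-stimulus pair; returns ``(score, is_response)``.

    ``stim_onsets`` are the onsets (ms) of the presentations of one
    stimulus; ``baseline_onsets`` the onsets pooled for the baseline
    distribution (all pictures' onsets in a session; defaults to
    ``stim_onsets``). Per presentation, counts in ``n_bins`` overlapping
    bins after onset form the test samples; the baseline sample holds
    100 ms sub-bin counts tiling the 500 ms before every baseline onset, so
    both sides of the Mann-Whitney U test are 100 ms counts. The score is
    the minimum Benjamini-Hochberg-adjusted p-value over the bins; a
    response needs score < alpha and spikes during at least
    ``min_presentations`` stimulus-on windows.
    """
    from scipy.stats import mannwhitneyu

    rp = rp or ResponseParams()
    spike_times = np.sort(np.asarray(spike_times, dtype=np.float64))
    stim_onsets = np.asarray(stim_onsets, dtype=np.float64)
    if baseline_onsets is None:
        baseline_onsets = stim_onsets

    n_sub = int(round(rp.baseline_ms / rp.bin_ms))
    baseline = []
    for onset in baseline_onsets:
        starts = onset - rp.baseline_ms + np.arange(n_sub) * rp.bin_ms
        lo = np.searchsorted(spike_times, starts)
        hi = np.searchsorted(spike_times, starts + rp.bin_ms)
        baseline.extend(hi - lo)
    baseline = np.asarray(baseline)

    counts = np.stack([_bin_counts(spike_times, o, rp) for o in stim_onsets])
    pvals = np.ones(rp.n_bins)
    for b in range(rp.n_bins):
        sample = counts[:, b]
        if baseline.size and (sample.var() > 0 or baseline.var() > 0
                              or sample.mean() != baseline.mean()):
            pvals[b] = mannwhitneyu(sample, baseline,
                                    alternative="two-sided").pvalue
    score = float(bh_adjust(pvals).min())

    window_ms = rp.n_bins * rp.hop_ms + (rp.bin_ms - rp.hop_ms)
    lo = np.searchsorted(spike_times, stim_onsets)
    hi = np.searchsorted(spike_times, stim_onsets + window_ms)
    active = int(np.count_nonzero(hi > lo))
    is_response = score < rp.alpha and active >= rp.min_presentations
    return score, is_response
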