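"""Band-pass filtering, threshold spike detection and waveform extraction.

Detection follows the standard robust-threshold recipe: the per-channel
noise scale is estimated as ``median(|x|) / 0.6745`` (the median absolute
deviation of a zero-mean Gaussian equals 0.6745 sigma) and the threshold is
``thr_mult`` times that. No artificial refractory period is imposed —
overlapping detections are dealt with downstream by the artifact stage.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .containers import Recording, SpikeSet
from .io import log_stage
from .params import DetectParams

__all__ = [
    "bandpass_filter",
    "noise_scale",
    "detect_spikes",
    "extract_align",
    "extract_channel",
]


def bandpass_filter(rec: Recording, band: tuple[float, float] = (300.0, 1000.0),
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), so spike
    shapes are not skewed by phase delay. Output has identical length/rate.
    """
    lo, hi = band
    nyq = rec.rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:g})")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return Recording(filtered, rec.rate, channel_ids=list(rec.channel_ids),
                     start_time=rec.start_time)


def noise_scale(x: np.ndarray) -> float:
    """Robust noise sigma estimate: median(|x|) / 0.6745."""
    return float(np.median(np.abs(x)) / 0.6745)


def _detect_one(x: np.ndarray, rate: float, params: DetectParams,
                sign: str) -> np.ndarray:
    """Indices of sign-appropriate extrema following threshold crossings."""
    y = x if sign == "positive" else -x
    thr = params.thr_mult * noise_scale(x)
    above = y > thr
    if not above.any():
        return np.empty(0, dtype=np.int64)
    # upward crossings of the threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    search = max(1, int(round(rate * 1e-3)))  # extremum within 1 ms
    peaks = np.empty(crossings.size, dtype=np.int64)
    for i, c in enumerate(crossings):
        stop = min(c + search, y.size)
        peaks[i] = c + int(np.argmax(y[c:stop]))
    return peaks


def detect_spikes(filtered: Recording, params: DetectParams | None = None
                  ) -> dict[str, dict[str, np.ndarray]]:
    """Detect threshold-crossing events on every channel.

    Returns ``{channel_id: {"positive": sample_indices, ...}}`` containing
    one entry per requested polarity. An empty channel yields empty arrays.
    """
    params = params or DetectParams()
    signs = ("positive", "negative") if params.sign == "both" else (params.sign,)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cid, x in zip(filtered.channel_ids, filtered.data):
        out[cid] = {s: _detect_one(x, filtered.rate, params, s) for s in signs}
    return out


def extract_align(filtered: Recording, peak_indices: np.ndarray,
                  params: DetectParams | None = None, channel_id: str | None = None,
                  sign: str = "positive") -> SpikeSet:
    """Cut and peak-align waveforms around detected events.

    Each waveform has ``k = round(window_ms * rate / 1000)`` samples with the
    peak at index ``round(pre_frac * k)``. Alignment upsamples by cubic
    spline (factor ``upsample``), shifts the window so the extremum lands on
    the alignment index, and decimates back to the original rate. Events too
    close to the recording edge are dropped and the count logged. Negative
    streams are sign-flipped so downstream stages always see positive peaks.
    """
    params = params or DetectParams()
    if channel_id is None:
        channel_id = filtered.channel_ids[0]
    x = filtered.channel(channel_id)
    if sign == "negative":
        x = -x
    rate = filtered.rate
    up = params.upsample
    k = int(round(params.window_ms * rate / 1000.0))
    pre = int(round(params.pre_frac * k))
    margin = max(2, up)  # coarse samples of slack for realignment
    peak_indices = np.asarray(peak_indices, dtype=np.int64)

    lo = peak_indices - pre - margin
    hi = peak_indices + (k - pre) + margin
    valid = (lo >= 0) & (hi < x.size)
    dropped = int((~valid).sum())
    if dropped:
        log_stage("extract", channel_id, dropped_edge=dropped)
    idx = peak_indices[valid]
    n = idx.size
    width = k + 2 * margin
    if n == 0:
        return SpikeSet(np.empty((0, k)), np.empty(0), channel_id=channel_id,
                        rate_eff=rate, sign=sign)

    segs = x[(idx - pre - margin)[:, None] + np.arange(width)[None, :]]
    if up > 1:
        coarse = np.arange(width)
        spline = CubicSpline(coarse, segs, axis=1)
        fine = np.arange((width - 1) * up + 1) / up
        fine_segs = spline(fine)
    else:
        fine_segs = segs
    # nominal peak sits at fine index (pre + margin) * up; realign within
    # +/- margin coarse samples
    center = (pre + margin) * up
    span = margin * up
    window = fine_segs[:, center - span:center + span + 1]
    shift = window.argmax(axis=1) - span
    starts = center + shift - pre * up
    take = starts[:, None] + (np.arange(k) * up)[None, :]
    waves = np.take_along_axis(fine_segs, take, axis=1)

    # event time = aligned peak position, ms from recording start
    times = (idx + shift / up) / rate * 1000.0
    order = np.argsort(times, kind="stable")
    return SpikeSet(waves[order], times[order], channel_id=channel_id,
                    rate_eff=rate, sign=sign)


def extract_channel(rec: Recording, channel_id: str | None = None,
                    params: DetectParams | None = None,
                    prefiltered: bool = False) -> list[SpikeSet]:
    """Filter, detect and extract one channel; one SpikeSet per polarity."""
    params = params or DetectParams()
    filtered = rec if prefiltered else bandpass_filter(rec, params.band, params.order)
    if channel_id is None:
        channel_id = filtered.channel_ids[0]
    events = detect_spikes(filtered, params)[channel_id]
    return [
        extract_align(filtered, idx, params, channel_id=channel_id, sign=sign)
        for sign, idx in events.items()
    ]
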