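"""Ground-truth synthetic recordings for validating the sorting pipeline.

The generator emulates single-wire extracellular recordings: a small set of
template neurons firing as Poisson processes with an absolute refractory
period, superimposed on broadband Gaussian background noise and a
low-amplitude multi-unit "hash", with optional injected artifacts —
sparse high-frequency sinusoidal chirps (electrical noise), high-amplitude
transients, and transients hitting many channels at once. Templates are
parametric bi-/tri-phasic difference-of-Gaussians shapes, so datasets are
fully reproducible from a seed without shipping any data.

A separate operation turns a short base spike set into a multi-hour one by
concatenation, with linear amplitude drift and added waveform noise, for
long-term tracking experiments.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import GroundTruth, Recording, SpikeSet
from .params import SimConfig

__all__ = ["make_template", "make_dataset", "make_multihour"]


def make_template(rate: float, width_ms: float = 0.3, peak_uv: float = 100.0,
                  trough_frac: float = 0.45, trough_lag_ms: float = 0.35,
                  second_peak_frac: float = 0.0, k_ms: float = 4.0,
                  pre_trough_frac: float = 0.0,
                  pre_lag_ms: float = 0.3) -> np.ndarray:
    """Parametric spike template: sum of Gaussian phases, unit-free shape.

    A positive Gaussian peak of width ``width_ms``, an optional preceding
    trough (``pre_trough_frac`` of the peak, ``pre_lag_ms`` before it —
    extracellular waveforms can lead with the negative phase), a trough
    ``trough_lag_ms`` after the peak (depth ``trough_frac``) and an
    optional late second positive phase. Scaled so the maximum equals
    ``peak_uv``. Length is ``k_ms`` milliseconds at sampling rate ``rate``.
    """
    k = int(round(k_ms * rate / 1000.0))
    t = (np.arange(k) - k // 3) / rate * 1000.0  # ms, peak near k/3
    wave = np.exp(-0.5 * (t / width_ms) ** 2)
    wave -= trough_frac * np.exp(
        -0.5 * ((t - trough_lag_ms) / (1.6 * width_ms)) ** 2)
    if pre_trough_frac:
        wave -= pre_trough_frac * np.exp(
            -0.5 * ((t + pre_lag_ms) / (1.4 * width_ms)) ** 2)
    if second_peak_frac:
        wave += second_peak_frac * np.exp(
            -0.5 * ((t - 1.8 * trough_lag_ms) / (1.5 * width_ms)) ** 2)
    return wave / wave.max() * peak_uv


def _default_templates(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """A spread of distinct shapes: widths, trough depths and amplitudes."""
    n = cfg.n_neurons
    if n == 0:
        return np.empty((0, int(round(4.0 * cfg.sampling_rate / 1000.0))))
    # bank of fast (~1 ms) physiological shapes chosen for mutual waveform
    # distance after band-pass filtering: polarity sequence (pre-trough
    # leading vs trailing), peak width and rebound phases all differ, so
    # neighboring amplitudes never share a shape; cycled with perturbation
    # beyond five neurons
    bank = [  # amp, width, trough, lag, second, pre-trough, pre-lag
        (110.0, 0.12, 0.75, 0.25, 0.0, 0.0, 0.30),
        (100.0, 0.35, 0.15, 0.55, 0.45, 0.0, 0.30),
        (105.0, 0.16, 0.10, 0.30, 0.0, 0.95, 0.35),
        (115.0, 0.22, 0.65, 0.30, 0.25, 0.0, 0.30),
        (95.0, 0.15, 0.55, 0.28, 0.0, 0.75, 0.55),
    ]
    rows = []
    for i in range(n):
        a, w, t, l, s, pt, pl = bank[i % 5]
        f = 1 + 0.12 * (i // 5)
        if cfg.amplitudes is not None:
            a = cfg.amplitudes[i]
        rows.append(make_template(cfg.sampling_rate, w * f, a, t / f, l * f,
                                  s, pre_trough_frac=pt, pre_lag_ms=pl * f))
    return np.stack(rows)


def _poisson_train(rate_hz: float, duration_s: float, refractory_ms: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Event times (ms) of a Poisson process with absolute refractory period."""
    if rate_hz <= 0:
        return np.empty(0)
    # thinning-free construction: exponential gaps shifted by the refractory
    n_guess = int(rate_hz * duration_s * 1.5) + 20
    eff_rate = rate_hz / max(1e-9, 1 - rate_hz * refractory_ms / 1000.0)
    gaps = rng.exponential(1000.0 / eff_rate, size=n_guess) + refractory_ms
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration_s * 1000.0:
        extra = rng.exponential(1000.0 / eff_rate, size=n_guess) + refractory_ms
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < duration_s * 1000.0]


def _add_at(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    """Add ``wave`` into ``trace`` starting at sample ``start``, clipped."""
    lo = max(start, 0)
    hi = min(start + wave.size, trace.size)
    if hi > lo:
        trace[lo:hi] += wave[lo - start:hi - start]


def make_dataset(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Render a continuous recording plus its ground truth.

    The trace is the sum of template spike trains (linear superposition:
    near-coincident spikes of different neurons overlap and keep their
    labels), Gaussian background noise, multi-unit hash, and any artifacts
    requested in the config. Ground-truth times are the template-peak times
    in milliseconds. The same config and seed always produce the identical
    recording.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.duration * cfg.sampling_rate))
    templates = _default_templates(cfg, rng)
    k = templates.shape[1] if templates.size else 0
    # sparse firing typical of human MTL single units
    rates = (np.asarray(cfg.rates) if cfg.rates is not None
             else np.linspace(0.5, 2.5, cfg.n_neurons))
    if k and cfg.n_neurons:
        min_gap_ms = k / cfg.sampling_rate * 1000.0
        if np.any(1000.0 / rates < min_gap_ms):
            warnings.warn("template longer than mean ISI: overlaps intended",
                          stacklevel=2)

    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, n_samp))
    truth_times, truth_ids = [], []
    peak_offset = int(np.argmax(templates[0])) if cfg.n_neurons else 0

    for nid in range(cfg.n_neurons):
        tpl = templates[nid]
        peak = int(np.argmax(tpl))
        times = _poisson_train(rates[nid], cfg.duration, cfg.refractory_ms, rng)
        for t in times:
            start = int(round(t * cfg.sampling_rate / 1000.0)) - peak
            _add_at(data[0], start, tpl)
        truth_times.append(times)
        truth_ids.append(np.full(times.size, nid + 1, dtype=np.int64))

    # multi-unit hash: many faint, jittered shapes
    if cfg.mua_rate > 0:
        mua_times = _poisson_train(cfg.mua_rate, cfg.duration, 0.5, rng)
        for t in mua_times:
            amp = cfg.mua_amplitude * rng.uniform(0.5, 1.2)
            width = rng.uniform(0.2, 0.5)
            tpl = make_template(cfg.sampling_rate, width, amp,
                                rng.uniform(0.3, 0.6), rng.uniform(0.3, 0.5))
            start = int(round(t * cfg.sampling_rate / 1000.0)) - int(np.argmax(tpl))
            _add_at(data[0], start, tpl)

    art_times, art_kinds = [], []
    if cfg.artifact_sine_rate > 0:
        # short in-band sinusoidal chirps: stereotyped non-neural waveforms
        chirp_ms = 5.0
        m = int(round(chirp_ms * cfg.sampling_rate / 1000.0))
        tt = np.arange(m) / cfg.sampling_rate
        envelope = np.hanning(m)
        chirp = (cfg.artifact_sine_amplitude * envelope
                 * np.sin(2 * np.pi * cfg.artifact_sine_freq * tt))
        times = _poisson_train(cfg.artifact_sine_rate, cfg.duration, 5.0, rng)
        for t in times:
            start = int(round(t * cfg.sampling_rate / 1000.0)) - m // 2
            _add_at(data[0], start, chirp)
        art_times.append(times)
        art_kinds.append(np.full(times.size, "sine", dtype="U16"))

    if cfg.artifact_transient_rate > 0:
        times = _poisson_train(cfg.artifact_transient_rate, cfg.duration, 5.0, rng)
        for t in times:
            tpl = make_template(cfg.sampling_rate, 0.25,
                                cfg.artifact_transient_amplitude, 0.5, 0.4)
            start = int(round(t * cfg.sampling_rate / 1000.0)) - int(np.argmax(tpl))
            _add_at(data[0], start, tpl)
        art_times.append(times)
        art_kinds.append(np.full(times.size, "transient", dtype="U16"))

    if cfg.artifact_concurrent_rate > 0 and cfg.n_channels > 1:
        times = _poisson_train(cfg.artifact_concurrent_rate, cfg.duration, 5.0, rng)
        tpl = make_template(cfg.sampling_rate, 0.3, 80.0, 0.5, 0.4)
        for t in times:
            start = int(round(t * cfg.sampling_rate / 1000.0)) - int(np.argmax(tpl))
            for ch in range(cfg.n_channels):
                _add_at(data[ch], start, tpl)
        art_times.append(times)
        art_kinds.append(np.full(times.size, "concurrent", dtype="U16"))

    if truth_times:
        times = np.concatenate(truth_times)
        ids = np.concatenate(truth_ids)
        order = np.argsort(times, kind="stable")
        # GroundTruth requires per-neuron sorted times; global sort suffices
        times, ids = times[order], ids[order]
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)

    rec = Recording(data, cfg.sampling_rate,
                    channel_ids=[f"ch{i}" for i in range(cfg.n_channels)])
    truth = GroundTruth(
        times=times, neuron_id=ids, templates=templates,
        artifact_times=np.concatenate(art_times) if art_times else np.empty(0),
        artifact_kind=np.concatenate(art_kinds) if art_kinds else
        np.empty(0, dtype="U16"),
    )
    return rec, truth


def make_multihour(spikes: SpikeSet, truth: GroundTruth, n_cat: int = 60,
                   drift_to: float = 1.5, noise_frac: float = 0.2,
                   base_duration_ms: float | None = None,
                   seed: int = 0) -> tuple[SpikeSet, GroundTruth]:
    """Tile a base spike set into a long recording with drift and noise.

    The base set is concatenated ``n_cat`` times with times shifted by the
    base duration; every waveform is multiplied by a factor linear in time
    from 1 at the start to ``drift_to`` at the end (electrode drift), and
    i.i.d. Gaussian noise with standard deviation ``noise_frac`` times the
    global maximum over all base waveform samples is added to every sample.
    Ground-truth labels are propagated, so spike count and duration scale
    exactly by ``n_cat``.
    """
    if base_duration_ms is None:
        base_duration_ms = float(spikes.times.max()) + 1.0 if spikes.n_spikes else 0.0
    rng = np.random.default_rng(seed)
    n = spikes.n_spikes
    total_ms = n_cat * base_duration_ms
    times = np.concatenate(
        [spikes.times + i * base_duration_ms for i in range(n_cat)])
    waves = np.tile(spikes.waveforms, (n_cat, 1))
    scale = 1.0 + (drift_to - 1.0) * (times / total_ms if total_ms else times)
    waves = waves * scale[:, None]
    if noise_frac > 0:
        sd = noise_frac * float(spikes.waveforms.max())
        waves = waves + rng.normal(0.0, sd, size=waves.shape)
    out_spikes = SpikeSet(waves, times, channel_id=spikes.channel_id,
                          rate_eff=spikes.rate_eff, sign=spikes.sign)

    t_times = np.concatenate(
        [truth.times + i * base_duration_ms for i in range(n_cat)])
    t_ids = np.tile(truth.neuron_id, n_cat)
    a_times = np.concatenate(
        [truth.artifact_times + i * base_duration_ms for i in range(n_cat)]) \
        if truth.artifact_times.size else np.empty(0)
    out_truth = GroundTruth(
        times=t_times, neuron_id=t_ids, templates=truth.templates,
        artifact_times=a_times,
        artifact_kind=np.tile(truth.artifact_kind, n_cat),
    )
    return out_spikes, out_truth
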