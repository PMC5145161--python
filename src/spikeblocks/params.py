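"""Parameter sets for every stage of the sorting pipeline.

Each parameter block is a frozen-by-convention dataclass whose defaults are
the framework's reference operating point. A single YAML/JSON config file can
override any field by name; unknown keys raise immediately rather than being
silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SortParams",
    "ArtifactParams",
    "DetectParams",
    "SPCHyper",
    "SimConfig",
    "ResponseParams",
    "load_config",
]


@dataclass
class SortParams:
    """Parameters of the block-wise sorting core.

    ``n_block``
        Number of consecutive spikes per independently sorted block.
    ``c_max``
        Maximum number of clusters selected at any one temperature.
    ``s_min``
        Minimum cluster size at selection time. Interpreted as an absolute
        spike count when >= 1, or as a fraction of the block size when < 1.
    ``r_min``
        Minimum cluster size that triggers iterative re-clustering.
    ``n_rep``
        Number of clustering iterations per block (1 = single pass).
    ``f1`` / ``f2``
        Template-matching radii (within-block / across-blocks), in units of
        a cluster's variability measure ``s``.
    ``c_stop``
        Normalized mean-waveform distance at which hierarchical merging of
        clusters stops.
    ``n_t`` / ``t_min`` / ``t_max``
        Number of clustering temperatures and the interval they tile.
    """

    n_block: int = 20_000
    c_max: int = 5
    s_min: float = 15
    r_min: int = 2000
    n_rep: int = 1
    f1: float = 0.75
    f2: float = 3.0
    c_stop: float = 1.8
    n_t: int = 21
    t_min: float = 0.0
    t_max: float = 0.2
    merge_metric: str = "normalized"  # "normalized" | "raw"

    def __post_init__(self) -> None:
        if self.n_block <= 0 or self.c_max <= 0 or self.s_min <= 0:
            raise ValueError("n_block, c_max and s_min must be positive")
        if self.r_min <= 0 or self.n_rep <= 0:
            raise ValueError("r_min and n_rep must be positive")
        if self.f1 <= 0 or self.f2 <= 0 or self.c_stop <= 0:
            raise ValueError("f1, f2 and c_stop must be positive")
        if self.n_t < 3:
            raise ValueError("need at least 3 temperatures")
        if not 0 <= self.t_min < self.t_max:
            raise ValueError("require 0 <= t_min < t_max")
        if self.merge_metric not in ("normalized", "raw"):
            raise ValueError("merge_metric must be 'normalized' or 'raw'")

    def s_min_count(self, block_size: int) -> int:
        """Resolve ``s_min`` to an absolute spike count for a block."""
        if self.s_min >= 1:
            return int(self.s_min)
        return max(1, int(round(self.s_min * block_size)))


@dataclass
class ArtifactParams:
    """Thresholds of the pre- and post-sorting artifact criteria.

    Pre-sorting: ``rate_*`` govern the firing-rate criterion (events per
    overlapping time bin), ``amp_limit`` the absolute-amplitude criterion,
    ``double_window`` the overlapping-detection criterion and ``conc_*`` the
    cross-channel concurrency criterion. Post-sorting: ``max_local_maxima``,
    ``peak_ratio_min``/``peak_sep`` and ``sem_limit`` flag non-neural
    clusters by the shape and stability of their mean waveform.
    """

    rate_bin: float = 500.0          # ms
    rate_overlap: float = 250.0      # ms
    rate_max_events: int = 100       # strictly-more-than removes the bin
    amp_limit: float = 1000.0        # uV
    double_window: float = 1.5       # ms
    conc_bin: float = 3.0            # ms
    conc_overlap: float = 1.5        # ms
    conc_frac: float = 0.5           # fraction of channels
    conc_min_channels: int = 10      # criterion disabled below this count
    max_local_maxima: int = 5
    peak_ratio_min: float = 2.0
    peak_sep: float = 0.3            # ms
    sem_limit: float = 2.0           # uV
    maxima_smooth: int = 0           # boxcar half-width (samples), 0 = none

    def __post_init__(self) -> None:
        if self.rate_bin <= 0 or self.conc_bin <= 0:
            raise ValueError("bin widths must be positive")
        if not 0 <= self.rate_overlap < self.rate_bin:
            raise ValueError("rate_overlap must lie in [0, rate_bin)")
        if not 0 <= self.conc_overlap < self.conc_bin:
            raise ValueError("conc_overlap must lie in [0, conc_bin)")
        if not 0 < self.conc_frac <= 1:
            raise ValueError("conc_frac must lie in (0, 1]")
        if self.amp_limit <= 0 or self.double_window <= 0:
            raise ValueError("amp_limit and double_window must be positive")
        if self.sem_limit <= 0 or self.peak_sep <= 0:
            raise ValueError("sem_limit and peak_sep must be positive")


@dataclass
class DetectParams:
    """Band-pass, threshold-detection and extraction settings."""

    band: tuple[float, float] = (300.0, 3000.0)  # Hz
    thr_mult: float = 5.0
    window_ms: float = 2.0
    pre_frac: float = 0.25
    upsample: int = 3
    sign: str = "both"  # "positive" | "negative" | "both"
    order: int = 4      # Butterworth order (applied forward-backward)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.thr_mult <= 0 or self.window_ms <= 0:
            raise ValueError("thr_mult and window_ms must be positive")
        if not 0 < self.pre_frac < 1:
            raise ValueError("pre_frac must lie in (0, 1)")
        if self.upsample < 1:
            raise ValueError("upsample must be >= 1")
        if self.sign not in ("positive", "negative", "both"):
            raise ValueError("sign must be positive/negative/both")


@dataclass
class SPCHyper:
    """Internals of the superparamagnetic clustering engine.

    ``q``
        Number of Potts spin states.
    ``k_nn``
        Neighbors per point in the mutual-nearest-neighbor interaction graph.
    ``sweeps`` / ``burn_in``
        Swendsen-Wang Monte Carlo sweeps used for the correlation estimate,
        and discarded equilibration sweeps before them.
    ``corr_thresh``
        Spin-spin correlation above which two neighbors are linked when
        clusters are read out.
    """

    q: int = 20
    k_nn: int = 11
    sweeps: int = 300
    burn_in: int = 100
    corr_thresh: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.k_nn < 1:
            raise ValueError("k_nn must be >= 1")
        if self.sweeps < 1 or self.burn_in < 0:
            raise ValueError("sweeps must be >= 1 and burn_in >= 0")
        if not 0 < self.corr_thresh < 1:
            raise ValueError("corr_thresh must lie in (0, 1)")


@dataclass
class SimConfig:
    """Configuration of the ground-truth recording simulator.

    The defaults emulate a ten-minute single-wire recording sampled at
    24 kHz: a handful of template neurons with Poisson firing (absolute 2 ms
    refractory period), Gaussian background noise, low-amplitude multi-unit
    hash, and optional injected artifacts (sparse sinusoidal noise chirps,
    high-amplitude transients and cross-channel transients).
    """

    n_neurons: int = 5
    rates: tuple[float, ...] | None = None        # Hz; default spreads 1.5-4
    amplitudes: tuple[float, ...] | None = None   # uV peak; default 60-120
    duration: float = 600.0                       # s
    sampling_rate: float = 24_000.0               # Hz
    noise_sd: float = 10.0                        # uV, broadband background
    mua_rate: float = 25.0                        # Hz, multi-unit hash
    mua_amplitude: float = 15.0                   # uV peak
    n_channels: int = 1
    artifact_sine_rate: float = 0.0               # Hz, sinusoidal chirps
    artifact_sine_amplitude: float = 100.0        # uV (in-band, post-filter ~70)
    artifact_sine_freq: float = 900.0             # Hz
    artifact_transient_rate: float = 0.0          # Hz, >1 mV transients
    artifact_transient_amplitude: float = 3000.0  # uV
    artifact_concurrent_rate: float = 0.0         # Hz, cross-channel bursts
    refractory_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.rates is not None:
            if len(self.rates) != self.n_neurons:
                raise ValueError("rates must have one entry per neuron")
            if any(r <= 0 for r in self.rates):
                raise ValueError("rates must be positive")
        if self.amplitudes is not None and len(self.amplitudes) != self.n_neurons:
            raise ValueError("amplitudes must have one entry per neuron")


@dataclass
class ResponseParams:
    """Stimulus-response scoring settings (peristimulus bin test)."""

    n_bins: int = 19
    bin_ms: float = 100.0
    hop_ms: float = 50.0
    baseline_ms: float = 500.0
    alpha: float = 0.001
    min_presentations: int = 4
    n_reps: int = 6

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.bin_ms <= 0 or self.hop_ms <= 0:
            raise ValueError("n_bins, bin_ms and hop_ms must be positive")
        if self.baseline_ms <= 0:
            raise ValueError("baseline_ms must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_presentations < 1 or self.n_reps < 1:
            raise ValueError("min_presentations and n_reps must be >= 1")


_SECTIONS = {
    "sort": SortParams,
    "artifact": ArtifactParams,
    "detect": DetectParams,
    "spc": SPCHyper,
    "simulate": SimConfig,
    "response": ResponseParams,
}


def _build(cls, overrides: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    coerced = {}
    for key, value in overrides.items():
        coerced[key] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)


def load_config(path: str | Path) -> dict:
    """Load a declarative YAML/JSON config into parameter objects.

    The file holds one mapping per pipeline stage (``sort``, ``artifact``,
    ``detect``, ``spc``, ``simulate``, ``response``); every key must name a
    dataclass field of that stage. Missing sections fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise KeyError(
            f"unknown config sections: {sorted(unknown)}; "
            f"known sections: {sorted(_SECTIONS)}"
        )
    return {name: _build(cls, raw.get(name, {})) for name, cls in _SECTIONS.items()}
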