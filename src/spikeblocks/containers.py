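"""In-memory data model shared by all pipeline stages.

The single internal voltage unit is the microvolt and all event times are
milliseconds from recording start (64-bit floats). Loaders are responsible
for coercing into these units; nothing downstream rescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Recording",
    "SpikeSet",
    "AssignStage",
    "ClusterStats",
    "SortingResult",
    "GroundTruth",
]


class AssignStage(IntEnum):
    """How a spike obtained its cluster id."""

    SPC = 0          # selected directly from a clustering temperature
    TM_WITHIN = 1    # within-block template matching
    TM_ACROSS = 2    # across-block template matching
    RESIDUAL = 3     # never assigned


@dataclass
class Recording:
    """Continuous multi-channel voltage trace.

    ``data`` is an (n_channels, n_samples) float array in microvolts;
    ``rate`` the sampling frequency in Hz; ``start_time`` an offset in
    seconds carried through for provenance only.
    """

    data: np.ndarray
    rate: float
    channel_ids: list[str] | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("one channel id per data row required")
        for cid, row in zip(self.channel_ids, self.data):
            if not np.all(np.isfinite(row)):
                raise ValueError(f"non-finite samples in channel {cid!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]


@dataclass
class SpikeSet:
    """Extracted spike waveforms with event times for one channel.

    ``waveforms`` is (n_spikes, k_samples) in microvolts; ``times`` are
    milliseconds from recording start and must be non-decreasing. ``sign``
    records the detection polarity of the stream; negative streams are
    sign-flipped at extraction so every consumer sees positive peaks.
    """

    waveforms: np.ndarray
    times: np.ndarray
    channel_id: str = "ch0"
    rate_eff: float = 24_000.0
    sign: str = "positive"

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=np.float64))
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size == 0:
            self.waveforms = self.waveforms.reshape(0, self.waveforms.shape[-1])
        if self.waveforms.shape[0] != self.times.size:
            raise ValueError("waveform row count must equal number of times")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.rate_eff <= 0:
            raise ValueError("rate_eff must be positive")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def subset(self, index: np.ndarray) -> "SpikeSet":
        return SpikeSet(
            self.waveforms[index],
            self.times[index],
            channel_id=self.channel_id,
            rate_eff=self.rate_eff,
            sign=self.sign,
        )


@dataclass
class ClusterStats:
    """Summary statistics of one cluster used by matching and merging.

    ``s = sqrt(sum_i var(x_i))`` is the cluster's variability measure: the
    root of the per-sample variances summed over the waveform, so that a
    template-matching radius ``f * s`` is commensurable with a Euclidean
    distance in waveform space (microvolts).
    """

    mean_wave: np.ndarray
    var_wave: np.ndarray      # per-sample variance, ddof=0
    size: int

    def __post_init__(self) -> None:
        self.mean_wave = np.asarray(self.mean_wave, dtype=np.float64)
        self.var_wave = np.asarray(self.var_wave, dtype=np.float64)
        if self.mean_wave.shape != self.var_wave.shape:
            raise ValueError("mean_wave and var_wave must have equal length")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")

    @property
    def s(self) -> float:
        return float(np.sqrt(self.var_wave.sum()))

    @property
    def sem_mean(self) -> float:
        """Mean over sampling points of the per-point standard error."""
        if self.size < 2:
            return float("nan")
        sd = np.sqrt(self.var_wave * self.size / (self.size - 1))
        return float(np.mean(sd / np.sqrt(self.size)))

    @classmethod
    def from_waveforms(cls, waveforms: np.ndarray) -> "ClusterStats":
        waveforms = np.atleast_2d(waveforms)
        return cls(
            mean_wave=waveforms.mean(axis=0),
            var_wave=waveforms.var(axis=0),
            size=waveforms.shape[0],
        )


# Bits identifying which post-sorting artifact criterion fired.
ARTIFACT_BITS = {"maxima": 1, "peak_ratio": 2, "tail_range": 4, "sem": 8}


@dataclass
class SortingResult:
    """Final per-spike assignment plus per-cluster annotations.

    Cluster id 0 is the residual (never-assigned) cluster. Merging assigns a
    ``group_id`` per cluster but never touches ``original_cluster_id``, so a
    grouping can be undone exactly.
    """

    times: np.ndarray
    cluster_id: np.ndarray
    original_cluster_id: np.ndarray
    block_index: np.ndarray
    assign_stage: np.ndarray
    artifact: dict[int, frozenset] = field(default_factory=dict)
    group_id: dict[int, int] = field(default_factory=dict)
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.cluster_id = np.asarray(self.cluster_id, dtype=np.int64)
        self.original_cluster_id = np.asarray(self.original_cluster_id, dtype=np.int64)
        self.block_index = np.asarray(self.block_index, dtype=np.int64)
        self.assign_stage = np.asarray(self.assign_stage, dtype=np.int64)
        n = self.times.size
        for name in ("cluster_id", "original_cluster_id", "block_index", "assign_stage"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have one entry per spike")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def cluster_ids(self, include_residual: bool = False) -> list[int]:
        ids = sorted(int(c) for c in np.unique(self.cluster_id))
        if not include_residual:
            ids = [c for c in ids if c != 0]
        return ids

    def is_artifact(self, cluster: int) -> bool:
        return bool(self.artifact.get(cluster))

    def spikes_of(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == cluster)

    def spikes_of_group(self, group: int) -> np.ndarray:
        members = [c for c, g in self.group_id.items() if g == group]
        return np.flatnonzero(np.isin(self.cluster_id, members))

    def groups(self) -> list[int]:
        return sorted(set(self.group_id.values()))

    def ungroup(self) -> "SortingResult":
        """Undo merging: one group per non-artifact cluster, ids restored."""
        out = SortingResult(
            times=self.times.copy(),
            cluster_id=self.original_cluster_id.copy(),
            original_cluster_id=self.original_cluster_id.copy(),
            block_index=self.block_index.copy(),
            assign_stage=self.assign_stage.copy(),
            artifact=dict(self.artifact),
            group_id={},
            channel_id=self.channel_id,
        )
        return out


@dataclass
class GroundTruth:
    """Known spike provenance of a simulated recording.

    ``neuron_id`` uses dense ids 1..n_neurons; ``times`` are ms of the
    template peak. Injected artifact events carry their own labels so that
    rejection stages can be scored against them.
    """

    times: np.ndarray
    neuron_id: np.ndarray
    templates: np.ndarray          # (n_neurons, k) uV
    artifact_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_kind: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U16"))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.neuron_id = np.asarray(self.neuron_id, dtype=np.int64)
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=np.float64))
        self.artifact_times = np.asarray(self.artifact_times, dtype=np.float64)
        self.artifact_kind = np.asarray(self.artifact_kind)
        if self.times.size != self.neuron_id.size:
            raise ValueError("times and neuron_id must have equal length")
        for nid in np.unique(self.neuron_id):
            t = self.times[self.neuron_id == nid]
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times of neuron {nid} must be sorted")

    @property
    def n_neurons(self) -> int:
        return self.templates.shape[0] if self.templates.size else 0

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_id == neuron]
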