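"""Container I/O: continuous recordings, spike sets and sorting results.

Continuous data travel either as an HDF5 file (one dataset per channel under
``/channels``, with a ``rate`` attribute) or as flat interleaved int16 binary
with a JSON sidecar carrying ``rate``, ``gain_uv`` (microvolts per LSB),
``n_channels`` and optional ``channel_ids``. Spike and sorting containers are
HDF5 with one group per channel. Every writer/reader pair is a lossless
round trip; units are coerced to microvolts on load and never touched again.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np

from .containers import GroundTruth, Recording, SortingResult, SpikeSet

__all__ = [
    "read_recording",
    "write_recording",
    "write_spikes",
    "read_spikes",
    "write_sorting",
    "read_sorting",
    "write_ground_truth",
    "read_ground_truth",
]

log = logging.getLogger("spikeblocks")


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, path: str | Path) -> None:
    """Persist a Recording as an HDF5 container (microvolt float data)."""
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = rec.rate
        f.attrs["start_time"] = rec.start_time
        grp = f.create_group("channels")
        for cid, row in zip(rec.channel_ids, rec.data):
            grp.create_dataset(cid, data=row)
        f.attrs["channel_order"] = [str(c) for c in rec.channel_ids]


def _read_recording_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate"])
        start = float(f.attrs.get("start_time", 0.0))
        order = [str(c) for c in f.attrs["channel_order"]]
        grp = f["channels"]
        data = [np.asarray(grp[c]) for c in order]
    lengths = {len(row) for row in data}
    if len(lengths) > 1:
        raise ValueError(f"channel length mismatch in {path}: {sorted(lengths)}")
    return Recording(np.vstack(data), rate, channel_ids=order, start_time=start)


def _read_recording_flat(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"flat binary {path} requires sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    n_ch = int(meta["n_channels"])
    gain = float(meta["gain_uv"])
    raw = np.fromfile(path, dtype=np.int16)
    if raw.size % n_ch:
        raise ValueError(
            f"{path}: {raw.size} samples not divisible by {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64) * gain
    return Recording(
        data,
        float(meta["rate"]),
        channel_ids=meta.get("channel_ids"),
        start_time=float(meta.get("start_time", 0.0)),
    )


def read_recording(path: str | Path, format_spec: str = "hdf5") -> Recording:
    """Load a continuous recording, validating units and invariants.

    ``format_spec`` is ``"hdf5"`` or ``"flat_binary"``. Flat binary data are
    scaled to microvolts by the sidecar's ``gain_uv``; non-finite samples or
    mismatched channel lengths raise with the offending channel named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_spec == "hdf5":
        return _read_recording_hdf5(path)
    if format_spec == "flat_binary":
        return _read_recording_flat(path)
    raise ValueError(f"unknown recording format {format_spec!r}")


def write_flat_binary(rec: Recording, path: str | Path, gain_uv: float = 0.1) -> None:
    """Write interleaved int16 + JSON sidecar (mainly for tests/examples)."""
    path = Path(path)
    scaled = np.round(rec.data / gain_uv)
    if np.abs(scaled).max(initial=0) > np.iinfo(np.int16).max:
        raise ValueError("gain_uv too small: samples overflow int16")
    scaled.T.astype(np.int16).tofile(path)
    meta = {
        "rate": rec.rate,
        "gain_uv": gain_uv,
        "n_channels": rec.n_channels,
        "channel_ids": list(rec.channel_ids),
        "start_time": rec.start_time,
        "order": "interleaved",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------- spike sets

def write_spikes(spikes: SpikeSet | list[SpikeSet], path: str | Path) -> None:
    """Write one or more per-channel SpikeSets into one HDF5 container."""
    sets = spikes if isinstance(spikes, list) else [spikes]
    with h5py.File(path, "w") as f:
        for ss in sets:
            grp = f.create_group(ss.channel_id)
            grp.create_dataset("waveforms", data=ss.waveforms)
            grp.create_dataset("times", data=ss.times)
            grp.attrs["rate_eff"] = ss.rate_eff
            grp.attrs["sign"] = ss.sign


def read_spikes(path: str | Path, channel_id: str | None = None):
    """Read SpikeSets back; returns one set if ``channel_id`` given."""
    out = []
    with h5py.File(path, "r") as f:
        for cid in sorted(f.keys()):
            if channel_id is not None and cid != channel_id:
                continue
            grp = f[cid]
            out.append(
                SpikeSet(
                    np.asarray(grp["waveforms"]),
                    np.asarray(grp["times"]),
                    channel_id=cid,
                    rate_eff=float(grp.attrs["rate_eff"]),
                    sign=str(grp.attrs["sign"]),
                )
            )
    if channel_id is not None:
        if not out:
            raise KeyError(f"channel {channel_id!r} not in {path}")
        return out[0]
    return out


# ------------------------------------------------------------ sorting results

_SPIKE_FIELDS = ("times", "cluster_id", "original_cluster_id", "block_index",
                 "assign_stage")


def write_sorting(result: SortingResult, path: str | Path) -> None:
    """Persist a SortingResult losslessly (round trip is field-identical)."""
    from .containers import ARTIFACT_BITS

    with h5py.File(path, "w") as f:
        grp = f.create_group(result.channel_id)
        for name in _SPIKE_FIELDS:
            grp.create_dataset(name, data=getattr(result, name))
        cids = sorted(set(result.artifact) | set(result.group_id))
        mask = [
            sum(ARTIFACT_BITS[c] for c in result.artifact.get(cid, frozenset()))
            for cid in cids
        ]
        gids = [result.group_id.get(cid, -1) for cid in cids]
        defined = [cid in result.artifact for cid in cids]
        cl = grp.create_group("clusters")
        cl.create_dataset("ids", data=np.asarray(cids, dtype=np.int64))
        cl.create_dataset("artifact_mask", data=np.asarray(mask, dtype=np.int64))
        cl.create_dataset("artifact_defined", data=np.asarray(defined, dtype=bool))
        cl.create_dataset("group_id", data=np.asarray(gids, dtype=np.int64))


def read_sorting(path: str | Path, channel_id: str | None = None) -> SortingResult:
    """Read a SortingResult; a container missing any field is an error."""
    from .containers import ARTIFACT_BITS

    bit_names = {v: k for k, v in ARTIFACT_BITS.items()}
    with h5py.File(path, "r") as f:
        keys = sorted(f.keys())
        cid = channel_id if channel_id is not None else keys[0]
        if cid not in f:
            raise KeyError(f"channel {cid!r} not in {path}")
        grp = f[cid]
        missing = [n for n in _SPIKE_FIELDS if n not in grp]
        if missing or "clusters" not in grp:
            raise ValueError(f"corrupted sorting container {path}: missing {missing or ['clusters']}")
        fields = {name: np.asarray(grp[name]) for name in _SPIKE_FIELDS}
        cl = grp["clusters"]
        ids = np.asarray(cl["ids"])
        masks = np.asarray(cl["artifact_mask"])
        defined = np.asarray(cl["artifact_defined"])
        gids = np.asarray(cl["group_id"])
    artifact = {}
    group_id = {}
    for cid_, mask, has_entry, gid in zip(ids, masks, defined, gids):
        if has_entry:
            artifact[int(cid_)] = frozenset(
                n for b, n in bit_names.items() if mask & b
            )
        if gid >= 0:
            group_id[int(cid_)] = int(gid)
    return SortingResult(channel_id=cid, artifact=artifact, group_id=group_id, **fields)


# -------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=truth.times)
        f.create_dataset("neuron_id", data=truth.neuron_id)
        f.create_dataset("templates", data=truth.templates)
        f.create_dataset("artifact_times", data=truth.artifact_times)
        f.create_dataset(
            "artifact_kind",
            data=np.asarray(truth.artifact_kind, dtype="S16"),
        )


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        return GroundTruth(
            times=np.asarray(f["times"]),
            neuron_id=np.asarray(f["neuron_id"]),
            templates=np.asarray(f["templates"]),
            artifact_times=np.asarray(f["artifact_times"]),
            artifact_kind=np.asarray(f["artifact_kind"]).astype("U16"),
        )


def log_stage(stage: str, channel: str, **counts) -> None:
    """Structured per-stage logging of rejection/assignment counts."""
    payload = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s channel=%s %s", stage, channel, payload)
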