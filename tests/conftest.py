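"""Shared fixtures: small simulated datasets and fully sorted pipelines.

The heavy end-to-end fixtures are session-scoped so the recovery, artifact
and tracking checks all reuse one pipeline run.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikeblocks import (extract_channel, make_dataset, make_multihour,
                         reject_events, sort_channel)
from spikeblocks.params import SimConfig, SortParams, SPCHyper


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_small():
    """Two-minute artifact-free recording with 3 neurons, extracted."""
    cfg = SimConfig(n_neurons=3, duration=120.0, seed=5)
    rec, truth = make_dataset(cfg)
    pos = [s for s in extract_channel(rec) if s.sign == "positive"][0]
    return rec, truth, pos


@pytest.fixture(scope="session")
def short_run():
    """Ten-minute 5-neuron recording with injected artifacts, fully sorted.

    Simulation and sorting parameters follow the reference operating point
    for short ground-truth recordings (c_max=7, c_stop=1.6, n_rep=2,
    r_min=1000).
    """
    cfg = SimConfig(n_neurons=5, duration=600.0, seed=7,
                    artifact_sine_rate=2.0, artifact_transient_rate=0.5)
    rec, truth = make_dataset(cfg)
    pos = [s for s in extract_channel(rec) if s.sign == "positive"][0]
    report = reject_events({"ch0": pos})
    keep = report.keep("ch0")
    clean = pos.subset(keep)
    params = SortParams(c_max=7, c_stop=1.6, n_rep=2, r_min=1000)
    result = sort_channel(clean, params, SPCHyper(seed=3))
    return {
        "truth": truth,
        "detected": pos,
        "keep": keep,
        "report": report,
        "clean": clean,
        "result": result,
    }


@pytest.fixture(scope="session")
def multihour_run():
    """Scaled-down long-recording protocol: 12x concatenation with drift.

    A 5-minute 3-neuron base is tiled 12 times (one-hour equivalent),
    waveforms drift linearly from 1 to 1.5 and carry added Gaussian noise
    of 20% of the base maximum. Blocks are scaled (1000 spikes) so the
    drift per block matches the full-scale regime; artifact flagging is
    off, as in ground-truth evaluations of artifact-free simulations.
    """
    cfg = SimConfig(n_neurons=3, duration=300.0, seed=7)
    rec, truth = make_dataset(cfg)
    pos = [s for s in extract_channel(rec) if s.sign == "positive"][0]
    clean = pos.subset(reject_events({"ch0": pos}).keep("ch0"))
    spikes, mh_truth = make_multihour(clean, truth, n_cat=12, drift_to=1.5,
                                      noise_frac=0.2,
                                      base_duration_ms=cfg.duration * 1000.0,
                                      seed=1)
    params = SortParams(n_block=1000, c_max=7, c_stop=1.2, n_rep=2, r_min=500)
    result = sort_channel(spikes, params, SPCHyper(seed=3),
                          flag_artifacts=False)
    return {"base": clean, "base_truth": truth, "spikes": spikes,
            "truth": mh_truth, "result": result}
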