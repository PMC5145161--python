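# spikeblocks

Block-wise superparamagnetic spike sorting for long, noisy extracellular
recordings.

Extracellular micro-electrodes record the action potentials of several
nearby neurons superimposed on noise; *spike sorting* attributes each
recorded spike to the neuron that fired it. Recordings from clinical
settings — e.g. whole-night sessions from the human medial temporal lobe —
add two hard problems: hundreds of thousands of spikes per channel, and
periods of heavy non-neural contamination and electrode drift. This package
implements a complete, fully automatic pipeline built for exactly that
regime, for electrophysiologists who need single units tracked across
hours:

- band-pass filtering, robust threshold detection
  (`5 × median(|x|)/0.6745`) and sub-sample waveform alignment;
- rule-based artifact rejection before sorting (firing-rate, amplitude,
  double-detection and cross-channel concurrency rules) and after sorting
  (mean-waveform shape and stability rules);
- clustering of blocks of 20 000 consecutive spikes, each block sorted
  independently (and in parallel) by **superparamagnetic clustering**: a
  q-state Potts model on the mutual k-nearest-neighbor graph of 10
  KS-selected Haar wavelet coefficients, simulated by Swendsen–Wang over 21
  temperatures in [0, 0.2], with clusters read out from spin–spin
  correlations and selected across temperatures at local maxima of cluster
  size;
- iterative re-clustering of large clusters, two-stage template matching
  (within block, radius `f₁·s = 0.75·s`; across blocks, `f₂·s = 3·s`,
  where `s = √Σᵢ var(xᵢ)` is a cluster's variability), and hierarchical
  merging of similar clusters within and across blocks (stop threshold
  `C_stop`) — which is what turns per-block clusters into units tracked
  over the whole recording;
- a ground-truth recording simulator (template neurons, noise, multi-unit
  hash, injectable artifacts, concatenation with drift for multi-hour
  protocols) and evaluation tools: the 50%/50% purity/completeness *hit*
  criterion and the peristimulus response score (19 overlapping 100 ms
  bins, Mann–Whitney U against baseline, Benjamini–Hochberg, α = 0.001,
  ≥ 4 active presentations).

See `docs/methods.md` for the full model description and design rationale.

## Worked example

`examples/simulate_and_sort.py` simulates two minutes of a three-neuron
channel, runs the full pipeline and scores it against ground truth:

```
simulated 120 s at 24000 Hz, 549 true spikes from 3 neurons
detected 701 events, 123 rejected pre-sorting
3 clusters (0 flagged as artifacts), 3 merged unit groups, 9 residual spikes
unit  n_spikes  matched_neuron   purity  completeness  hit
  g1       308               3 1.000000      0.990354 True
  g2       207               2 0.879227      0.989130 True
  g3        54               1 1.000000      1.000000 True
hits: 3/3 (100% of simulated neurons recovered)
```

Each recovered unit group is listed with the simulated neuron it matches,
its *purity* (fraction of the unit's spikes that belong to that neuron) and
*completeness* (fraction of that neuron's spikes captured by the unit); a
unit with both at least 0.5 is a *hit*. The 123 pre-sorting rejections here
are mostly overlapping double detections; the residual cluster holds spikes
(largely multi-unit hash) that no cluster or matching stage claimed.

Other examples: `artifact_rejection.py` (per-criterion rejection summary on
a contaminated recording), `multihour_tracking.py` (drift + noise tracking
protocol), `response_scoring.py` (stimulus-response detection). A thin CLI
mirrors the pipeline stages (`spikeblocks simulate | extract | reject |
sort | evaluate | respscore | plot-temps | plot-unit`).

## Library layout

| module | contents |
|---|---|
| `spikeblocks.containers` | `Recording`, `SpikeSet`, `SortingResult`, `ClusterStats`, `GroundTruth` |
| `spikeblocks.params` | all parameter sets + declarative YAML/JSON config |
| `spikeblocks.io` | HDF5 / flat-binary containers, lossless round trips |
| `spikeblocks.detect` | filtering, detection, extraction/alignment |
| `spikeblocks.artifacts` | pre-sorting event rules, post-sorting cluster rules |
| `spikeblocks.features` | Haar wavelet features, KS feature selection |
| `spikeblocks.spc` | the Potts/Swendsen–Wang temperature sweep |
| `spikeblocks.sorter` | blocks, selection, splitting, matching, merging |
| `spikeblocks.simulate` | ground-truth simulator, multi-hour protocol |
| `spikeblocks.evaluate` | hit scoring, BH adjustment, response score |

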