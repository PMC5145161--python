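# Methods

`spikeblocks` sorts spikes from long, noisy single-wire extracellular
recordings by clustering blocks of consecutive spikes independently and
re-joining the per-block clusters into tracked units. This note documents
the model and procedure, the parameters that matter, the numerical choices
made where the design was genuinely open, what the built-in simulator does
and does not emulate, and known limitations.

## Pipeline overview

1. **Filtering and detection.** Each channel is band-pass filtered with a
   zero-phase 4th-order Butterworth (applied forward and backward so spike
   shapes are not skewed). Default passband 300–3000 Hz — the standard
   extraction band for single-unit work; a narrower 300–1000 Hz band, often
   used for display, smears a 0.2 ms spike into a ringing tail that
   corrupts the shape-based artifact criteria downstream. The detection
   threshold is `thr_mult × median(|x|)/0.6745` per channel (the median
   absolute deviation of a zero-mean Gaussian is 0.6745 σ, so this
   estimates the noise σ robustly even when spikes are present);
   `thr_mult = 5` by default. Events are upward threshold crossings; the
   extremum within 1 ms after the crossing is the event peak. No artificial
   refractory period is imposed. Both polarities can be extracted; a
   negative stream is sign-flipped so all downstream code sees positive
   peaks.

2. **Extraction and alignment.** Waveforms of `window_ms` (2 ms, k samples)
   are cut around each peak with the peak at index `round(pre_frac·k)`
   (`pre_frac = 0.25`). Alignment is sub-sample: cubic-spline upsampling by
   3, realignment of the extremum, decimation back. Events too close to the
   recording edge are dropped and counted.

3. **Pre-sorting artifact rejection.** Four rules, with strict inequalities
   ("more than", "exceeding") and bin grids anchored at recording start:
   (1) overlapping 500 ms bins (250 ms hop) holding more than 100 events
   are excised wholesale (200 Hz is beyond plausible sustained firing);
   (2) events whose absolute extremum exceeds 1 mV are discarded;
   (3) of two detections closer than 1.5 ms, the one with the smaller
   *aligned* maximum is discarded; (4) with ten or more channels, 3 ms bins
   (1.5 ms hop) carrying an event on ≥ 50% of all channels are excised on
   every channel. Rules 1–3 are per-channel; rule 4 is the only
   cross-channel rule and is disabled below ten channels, where genuine
   coincident firing would be deleted. An event is removed if *any*
   covering bin violates its rule.

   In rule 3 the compared maximum is each waveform's value at the common
   alignment index (the median peak position), not the window-wide maximum:
   two detections less than 1.5 ms apart have windows containing the same
   physical peak, so a window-wide comparison degenerates to a coin flip
   and can discard the correctly aligned detection in favour of a
   mis-aligned duplicate.

4. **Block segmentation.** Clean spikes are split into blocks of `n_block`
   consecutive events (default 20 000; the last block takes the
   remainder). Count-based blocks confine bursts of residual contamination
   to few blocks and give every block enough spikes to cluster. Blocks are
   sorted independently and in parallel; each block's random seed is
   derived from the channel seed plus the block index, so results are
   bitwise independent of worker count and scheduling.

5. **Features.** Each spike gets a four-level Haar wavelet decomposition
   (orthonormal, so coefficient energy equals waveform energy), and the 10
   coefficients whose empirical distributions deviate most from a normal
   distribution are kept. Deviation is the Kolmogorov–Smirnov statistic
   against a normal with the coefficient's own sample mean and SD
   (Lilliefors-style); multimodality — the signature of multiple spike
   classes — produces large deviations. Zero-variance coefficients score 0;
   ties break toward the lower coefficient index for determinism.

6. **Superparamagnetic clustering (SPC).** Each spike carries a q-state
   Potts spin (q = 20). Mutual 11-nearest-neighbor pairs interact with
   coupling `J_ij = (1/K) exp(−d_ij²/2a²)` (a = mean neighbor distance,
   K = mean neighbor count); isolated graph components are reconnected
   through their nearest external point so the zero-temperature limit is a
   single cluster. At each of 21 temperatures equally spaced on [0, 0.2]
   the model is simulated by Swendsen–Wang (100 burn-in + 300 measurement
   sweeps); the pair correlation estimate `G_ij` is normalized to
   `c_ij = (q·G_ij − 1)/(q − 1)` and pairs with `c_ij > 0.5` are linked;
   connected components of links are that temperature's clusters. T = 0 is
   evaluated exactly (all bonds frozen). Low temperatures give one cluster,
   high temperatures fragment; in between, spins align within natural
   clusters only.

7. **Multi-temperature cluster selection.** Iterating temperatures from
   low to high (starting at the second, where a local maximum across
   temperature is defined), the rank-i cluster at `T_j` qualifies when its
   size is a local maximum of the rank-i size in temperature, with a
   stability tolerance: `size ≥ 0.95 ×` the rank-i size at both `T_{j−1}`
   and `T_{j+1}`. The tolerance is needed because the deterministic
   correlation readout produces smooth, slowly eroding size curves for
   stable clusters (a few percent per temperature step); a strict local
   maximum would never fire on them, while clusters still decaying fast —
   unions of units that have not yet fragmented — fail even the tolerant
   test. Two uninformative structures are excluded: the trivial all-points
   partition at the lowest temperature contributes size 0 to comparisons,
   and a *supercluster* holding ≥ 80% of all points (the not-yet-fragmented
   input) cannot be selected at the second temperature — if it is genuinely
   stable it re-qualifies one temperature later, and when re-clustering a
   single parent cluster (step 8) it is excluded at every temperature,
   since there the parent must never be re-selected whole. At most `c_max`
   qualifying clusters are taken per temperature (largest first; the cap
   counts qualifying clusters, which keeps the rule independent of
   membership history), each must contribute at least `s_min` previously
   unclaimed spikes, and claimed spikes are never reassigned at higher
   temperatures. Typically a substantial fraction of spikes remains
   unassigned and is handled by template matching.

8. **Splitting of large clusters.** Every cluster with at least `r_min`
   spikes is re-clustered on its own members — feature selection is
   repeated on the members' wavelet coefficients, because the coefficients
   that discriminate inside one cluster are generally not those that
   discriminate the whole block — and replaced only if at least two
   subclusters emerge; subclusters recurse. This counters under-clustering
   by low-temperature lumping.

9. **Template matching, twice.** For each cluster, the mean waveform and
   the variability `s = sqrt(Σ_i var(x_i))` (root of summed per-sample
   variances, so `f·s` is commensurable with Euclidean distance in µV) are
   computed. Each unassigned spike joins the nearest cluster whose mean is
   closer than `f·s`. Within a block the conservative `f₁ = 0.75` is used;
   after all blocks are sorted, a second pass with `f₂ = 3` matches the
   remaining spikes against the pooled clusters of *all* blocks. Spikes
   never captured stay in the residual cluster (id 0). The whole
   cluster-and-match cycle can be repeated `n_rep` times on still
   unassigned spikes.

10. **Post-sorting artifact flagging.** A cluster is non-neural if any of:
    (a) its mean waveform has more than 5 strict local maxima; (b) the
    ratio of the largest to second-largest local maximum is below 2,
    counting only maxima at least 0.3 ms apart (sinusoidal noise has many
    near-equal peaks); (c) the amplitude range of the second half of the
    mean waveform exceeds the global maximum (a real spike is quiet after
    repolarization); (d) the mean over sampling points of the per-point
    standard error of the mean exceeds 2 µV (heterogeneous residue, not a
    unit). Criterion (d) is skipped with a warning for single-spike
    clusters. Local maxima are strict sign changes of the first
    difference, unsmoothed by default (configurable smoothing provided);
    this presumes band-limited waveforms — with artificially white
    per-sample noise added to waveforms, (a) fires on noise wiggles, which
    is one reason ground-truth evaluations of artifact-free simulations
    run with flagging disabled.

11. **Merging into unit groups.** All non-artifact clusters from all
    blocks are pooled and merged hierarchically: repeatedly the pair of
    groups with the smallest distance between mean waveforms is merged,
    the merged mean (count-weighted) and pooled per-sample variance
    (within + between) are recomputed, and merging stops when the smallest
    distance exceeds `c_stop` (default 1.8). Within- and across-block
    merging happen in one pass, so the same unit found in many blocks ends
    up in one group — this is what tracks a neuron across a long
    recording. The default metric divides the Euclidean distance by the
    *smaller* variability `s` of the candidate pair, putting `c_stop` on
    the same scale as the matching radii `f₁`, `f₂`; the minimum (rather
    than a count-weighted pool) prevents a high-variance junk cluster from
    acting as glue that chains tight, distinct units together. A raw-µV
    metric is available (`merge_metric="raw"`). Original cluster ids are
    preserved, so any grouping can be undone exactly
    (`SortingResult.ungroup`).

## Evaluation procedures

**Hit scoring.** Sorted spikes are matched to ground-truth spikes by time
(one-to-one nearest neighbor within 0.5 ms; when two sorted spikes want the
same truth spike the earlier one wins). Each unit (merged group, or
ungrouped cluster) is paired with its plurality neuron; it is a **hit** when
purity ≥ 0.5 and completeness ≥ 0.5. The summary counts distinct neurons
hit as a fraction of simulated neurons.

**Response scoring.** For one unit and one stimulus with several
presentations: spike counts in 19 overlapping 100 ms bins (50 ms hop) over
the 1 s post-onset window, each bin's counts tested against baseline counts
with the Mann–Whitney U test; the baseline pools 100 ms sub-bin counts
tiling the 500 ms before every onset in the session, so both samples are
100 ms counts and the test compares like with like. The 19 p-values are
Benjamini–Hochberg adjusted and the score is their minimum — one number per
unit-stimulus pair that preserves the per-family 0.001 criterion. A
*response* additionally requires spikes during at least four presentation
windows, which vetoes spuriously low scores from one or two bursts. The
Monte-Carlo false-positive rate of the full procedure under a homogeneous
Poisson null is below 0.005 (checked over 1000 simulated null units).

## The simulator

`make_dataset` renders: template neurons firing as Poisson processes with a
2 ms absolute refractory period (sparse rates, default 0.5–2.5 Hz,
typical of human MTL units), linear superposition of waveforms (coincident
spikes overlap and keep their labels), broadband Gaussian background
(10 µV SD), a low-amplitude multi-unit hash (15 µV peaks — at the noise
floor, mostly below threshold, as real hash is), and optional artifacts:
sparse in-band sinusoidal chirps (900 Hz, 5 ms — residual electrical noise
that survives the band-pass), high-amplitude transients (3 mV), and
transients hitting all channels simultaneously. Templates come from a bank
of five distinct difference-of-Gaussians archetypes (95–115 µV peaks)
varying peak width, trough depth/lag, late second phases and — importantly
— polarity order (trough-leading vs trough-trailing), chosen so that
band-pass-filtered shapes remain mutually distant; beyond five neurons the
bank cycles with perturbed parameters. Ground truth records every inserted
spike time (at the template peak) and artifact event.

`make_multihour` emulates the long-recording protocol at the spike-set
level: the extracted base set is tiled `n_cat` times, each waveform is
scaled by a factor linear in time from 1 to `drift_to` (electrode drift),
and i.i.d. Gaussian noise with SD = `noise_frac ×` the global maximum of
the base waveforms is added to every sample.

What the simulator does **not** emulate: bursting and rate
non-stationarity, electrode-specific noise spectra, true waveform
non-stationarity beyond multiplicative drift, overlapping-spike
superposition at high rates, field potentials, or realistic multi-channel
correlation structure. Passing the built-in recovery tests therefore shows
the pipeline is internally correct under controlled, favourable conditions;
it does not bound performance on clinical recordings.

## Reference problem sizes

The bundled evaluations run at desk scale: a ten-minute, five-neuron,
single-channel recording with injected artifacts for recovery and artifact
scoring (sorted with `c_max=7, c_stop=1.6, n_rep=2, r_min=1000`, the
reference operating point for short ground-truth recordings); and a
five-minute three-neuron base tiled 12× with drift 1→1.5 and 20%-of-max
noise for tracking, sorted with `n_block=1000, c_max=7, c_stop=1.2,
n_rep=2, r_min=500`. The tracking run uses three neurons and small blocks
deliberately: with 20%-of-max noise the cluster variability `s` is
noise-dominated, and peak-aligned spike shapes cannot be made pairwise more
distant than about 1.3× that scale for five simultaneous templates — some
pairs would merge below any reasonable `c_stop`, which is a property of the
noise protocol, not of the implementation; and scaling `n_block` down keeps
the drift per block in the same regime as a full-scale run (~40 blocks per
recording), which is what chain merging across drift requires.

## Numerical and degenerate-input choices

- All voltages are microvolts; all event times are milliseconds from
  recording start (float64). Loaders coerce units once; nothing downstream
  rescales.
- `s_min` is an absolute count when ≥ 1, a fraction of the block when < 1.
- Blocks smaller than twice the minimum cluster size pass through as a
  single cluster with a warning; SPC on fewer points than `k_nn + 1` falls
  back to the complete interaction graph with a warning.
- Waveform lengths not decomposable into 4 dyadic levels are zero-padded
  with a warning.
- A merge candidate pair with zero variability merges only at distance 0.
- The per-block RNG seed is `seed + block_index`; SPC sub-runs inside
  splitting derive distinct seeds per recursion step. Identical inputs,
  parameters and seed give bitwise-identical results at any worker count.

## Known limitations

- Single-wire electrodes only; no joint detection across tetrode channels.
- The SPC sweep is the computational bottleneck (~40 s per 20 000-spike
  block at default settings on one core); blocks parallelize.
- Cluster selection constants (stability tolerance 0.95, supercluster
  fraction 0.8) are fixed module constants; they were chosen from the
  geometry of the deterministic readout, not fitted.
- The post-sorting maxima criterion assumes band-limited mean waveforms
  (see step 10).
- Response scoring assumes stationary baseline firing between trials.
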