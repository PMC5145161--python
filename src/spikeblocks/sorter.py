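"""The sorting core: blocks, multi-temperature selection, matching, merging.

A channel's spikes are segmented into blocks of ``n_block`` consecutive
events, each block is clustered independently (parallelizable, per-block
derived seeds keep results scheduling-independent), remaining spikes are
captured by template matching first within and then across blocks, clusters
are screened by the post-sorting artifact criteria, and finally all
non-artifact clusters are merged hierarchically into unit groups — within
and across blocks in one pass — so that a unit can be tracked over the
whole recording. Original cluster identities are preserved through merging,
so any grouping can be undone exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .artifacts import flag_artifact_cluster
from .containers import AssignStage, ClusterStats, SortingResult, SpikeSet
from .features import select_features_ks, wavelet_features
from .params import ArtifactParams, SortParams, SPCHyper
from .spc import SPCResult, spc_run

__all__ = [
    "segment_blocks",
    "select_clusters",
    "split_large",
    "template_match",
    "sort_block",
    "sort_channel",
    "merge_groups",
    "BlockResult",
    "SelectionEvent",
]


def segment_blocks(spikes: SpikeSet, n_block: int) -> list[SpikeSet]:
    """Split time-sorted spikes into consecutive blocks of ``n_block``.

    The final block holds the remainder; 350 000 spikes at the default
    block size of 20 000 give 18 blocks.
    """
    n = spikes.n_spikes
    if n == 0:
        return []
    edges = list(range(0, n, n_block)) + [n]
    return [spikes.subset(np.arange(a, b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SelectionEvent:
    """One row of the selection trace (for temperature diagnostics plots)."""

    temp_index: int
    rank: int              # 0-based rank by size at this temperature
    size: int              # raw cluster size in the partition
    n_new: int             # previously unclaimed spikes contributed
    cluster_id: int        # assigned id, or -1 if skipped
    selected: bool


SIZE_TOL = 0.95       # stability tolerance of the size-bump comparisons
SKIP_FRAC = 0.8       # clusters spanning this fraction of all points are
                      # "superclusters" (the not-yet-fragmented input)


def select_clusters(spc: SPCResult, c_max: int = 5, s_min: int = 15,
                    skip_frac: float = SKIP_FRAC, skip_all_temps: bool = False
                    ) -> tuple[np.ndarray, list[SelectionEvent]]:
    """Pick clusters from the temperature sweep by the size-bump rule.

    Iterating temperatures from low to high (starting at the second one,
    where a local maximum in temperature is defined), the rank-i cluster at
    temperature ``T_j`` qualifies when its size is a local maximum of the
    rank-i size across neighboring temperatures, up to a stability
    tolerance: ``size >= SIZE_TOL * size`` at both ``T_(j-1)`` and
    ``T_(j+1)``. The tolerance makes the rule robust to the slow boundary
    erosion of a stable cluster while still rejecting clusters that are
    decaying quickly (unions of units that have not yet fragmented).

    Two partitions carry no information and are excluded: the trivial
    all-points partition at the lowest temperature contributes size 0 to
    the comparisons, and a *supercluster* — a cluster spanning at least
    ``skip_frac`` of all points, i.e. essentially the unsplit input — is
    never selected at the second temperature (``skip_all_temps=False``, the
    default; if such a mass is genuinely stable it re-qualifies one
    temperature later) or at any temperature (``skip_all_temps=True``, used
    when re-clustering a single parent cluster, which must never be
    re-selected whole).

    Among qualifying clusters at one temperature, at most ``c_max``
    (largest first) are selected, and a cluster is selected only if it
    contributes at least ``s_min`` previously unclaimed spikes. Spikes join
    the first cluster that claims them and are never reassigned at higher
    temperatures; qualifying clusters whose members were already claimed
    are recorded as skipped.

    Returns ``(labels, trace)`` where ``labels`` holds 0 for unassigned
    spikes and dense ids from 1 for selected clusters.
    """
    n = spc.n
    labels = np.zeros(n, dtype=np.int64)
    trace: list[SelectionEvent] = []
    size_table = []
    member_table = []
    for j in range(spc.n_t):
        members = spc.clusters_at(j)
        sizes = np.array([m.size for m in members], dtype=np.int64)
        if j == 0 and len(members) == 1 and members[0].size == n:
            sizes = np.empty(0, dtype=np.int64)  # trivial partition
            members = []
        size_table.append(sizes)
        member_table.append(members)

    def rank_size(j: int, i: int) -> int:
        s = size_table[j]
        return int(s[i]) if i < len(s) else 0

    next_id = 1
    for j in range(1, spc.n_t - 1):
        n_qualified = 0
        for i, members in enumerate(member_table[j]):
            size = rank_size(j, i)
            if size < s_min:
                break  # sizes are descending; nothing below qualifies
            if size >= skip_frac * n and (skip_all_temps or j == 1):
                continue  # uninformative supercluster
            if not (size >= SIZE_TOL * rank_size(j - 1, i)
                    and size >= SIZE_TOL * rank_size(j + 1, i)):
                continue
            if n_qualified >= c_max:
                break
            n_qualified += 1
            new = members[labels[members] == 0]
            if new.size >= s_min:
                labels[new] = next_id
                trace.append(SelectionEvent(j, i, size, new.size, next_id, True))
                next_id += 1
            else:
                trace.append(SelectionEvent(j, i, size, new.size, -1, False))
    return labels, trace


def split_large(labels: np.ndarray, coefficients: np.ndarray, r_min: int,
                params: SortParams | None = None, hyper: SPCHyper | None = None,
                seed: int | None = None) -> np.ndarray:
    """Re-cluster every cluster holding at least ``r_min`` spikes.

    Each sufficiently large cluster is clustered again — feature selection
    is repeated on the cluster's own wavelet ``coefficients`` (the
    coefficients that discriminate inside one cluster are generally not the
    ones that discriminate the whole block), then temperature sweep and
    selection run on its members. The split replaces the cluster only when
    at least two subclusters emerge; members claimed by no subcluster fall
    back to unassigned. Subclusters are split recursively until none
    qualifies or no further split occurs. Counters under-clustering: a
    low-temperature cluster may lump several units that separate once
    clustered in isolation.
    """
    params = params or SortParams()
    hyper = hyper or SPCHyper()
    seed = hyper.seed if seed is None else seed
    coefficients = getattr(coefficients, "values", coefficients)
    labels = labels.copy()
    queue = [c for c in np.unique(labels) if c != 0]
    round_ = 0
    while queue:
        cid = queue.pop(0)
        members = np.flatnonzero(labels == cid)
        if members.size < r_min:
            continue
        round_ += 1
        feats = select_features_ks(coefficients[members], d=10)
        sub_spc = spc_run(feats, params, hyper, seed=seed + 7919 * round_)
        s_min = params.s_min_count(members.size)
        sub_labels, _ = select_clusters(sub_spc, params.c_max, s_min,
                                        skip_frac=0.9, skip_all_temps=True)
        sub_ids = [c for c in np.unique(sub_labels) if c != 0]
        if len(sub_ids) < 2:
            continue  # no effective split
        base = labels.max()
        labels[members] = 0
        for offset, sub in enumerate(sub_ids, start=1):
            sel = members[sub_labels == sub]
            labels[sel] = base + offset
            queue.append(base + offset)
    return labels


def cluster_stats(waveforms: np.ndarray, labels: np.ndarray
                  ) -> dict[int, ClusterStats]:
    """Per-cluster mean waveform, per-sample variance and size."""
    out = {}
    for cid in np.unique(labels):
        if cid == 0:
            continue
        out[int(cid)] = ClusterStats.from_waveforms(waveforms[labels == cid])
    return out


def template_match(waveforms: np.ndarray, unassigned: np.ndarray,
                   clusters: dict[int, ClusterStats], f: float
                   ) -> dict[int, int]:
    """Assign unassigned spikes to the nearest admissible cluster.

    For each unassigned spike the Euclidean distance in waveform space to
    every cluster mean is computed; the spike joins the nearest cluster
    whose distance is below ``f * s`` (``s`` the cluster's variability
    measure). Spikes admissible to no cluster stay unassigned. Returns
    ``{spike_index: cluster_id}`` for the newly assigned spikes.
    """
    if not clusters or unassigned.size == 0:
        return {}
    cids = list(clusters)
    means = np.stack([clusters[c].mean_wave for c in cids])
    radii = np.array([f * clusters[c].s for c in cids])
    out: dict[int, int] = {}
    # chunk to bound the (n_unassigned, n_clusters, k) intermediate
    chunk = max(1, int(4e6 // max(means.size, 1)))
    for start in range(0, unassigned.size, chunk):
        idx = unassigned[start:start + chunk]
        d = np.linalg.norm(waveforms[idx][:, None, :] - means[None], axis=2)
        admissible = d < radii[None, :]
        d_masked = np.where(admissible, d, np.inf)
        best = d_masked.argmin(axis=1)
        ok = np.isfinite(d_masked[np.arange(idx.size), best])
        for spike, b in zip(idx[ok], best[ok]):
            out[int(spike)] = cids[b]
    return out


@dataclass
class BlockResult:
    """Outcome of sorting one block of spikes."""

    labels: np.ndarray                 # per-spike cluster id, 0 = unassigned
    stages: np.ndarray                 # AssignStage per spike
    trace: list[SelectionEvent] = field(default_factory=list)
    spc: SPCResult | None = None       # first-pass sweep, for diagnostics

    @property
    def n_clusters(self) -> int:
        return np.unique(self.labels[self.labels != 0]).size


def sort_block(block: SpikeSet, params: SortParams | None = None,
               hyper: SPCHyper | None = None, seed: int | None = None
               ) -> BlockResult:
    """Cluster one block: features -> sweep -> selection -> split -> match.

    The whole pipeline is re-applied to still-unassigned spikes
    ``n_rep - 1`` further times. Blocks too small to cluster (fewer than
    twice the minimum cluster size, or fewer than 10 spikes) pass through
    as a single cluster with a warning.
    """
    params = params or SortParams()
    hyper = hyper or SPCHyper()
    seed = hyper.seed if seed is None else seed
    n = block.n_spikes
    s_min = params.s_min_count(n)
    stages = np.full(n, AssignStage.RESIDUAL, dtype=np.int64)
    if n < max(2 * s_min, 10):
        warnings.warn(f"block of {n} spikes below clusterable size: "
                      "pass-through cluster", stacklevel=2)
        return BlockResult(labels=np.ones(n, dtype=np.int64),
                           stages=np.full(n, AssignStage.SPC, dtype=np.int64))

    labels = np.zeros(n, dtype=np.int64)
    trace: list[SelectionEvent] = []
    first_spc = None
    coeffs_all = wavelet_features(block)
    for rep in range(params.n_rep):
        todo = np.flatnonzero(labels == 0)
        if todo.size < max(2 * s_min, hyper.k_nn + 2, 10):
            break
        feats = select_features_ks(coeffs_all[todo], d=10)
        spc = spc_run(feats, params, hyper, seed=seed + 131 * rep)
        if rep == 0:
            first_spc = spc
        sub_labels, sub_trace = select_clusters(spc, params.c_max, s_min)
        sub_labels = split_large(sub_labels, coeffs_all[todo], params.r_min,
                                 params, hyper, seed=seed + 131 * rep + 1)
        base = labels.max()
        newly = sub_labels != 0
        labels[todo[newly]] = sub_labels[newly] + base
        stages[todo[newly]] = AssignStage.SPC
        trace.extend(sub_trace)

        stats = cluster_stats(block.waveforms, labels)
        assigned = template_match(block.waveforms, np.flatnonzero(labels == 0),
                                  stats, params.f1)
        for spike, cid in assigned.items():
            labels[spike] = cid
            stages[spike] = AssignStage.TM_WITHIN

    # densify cluster ids to 1..m in first-appearance order
    ids = [c for c in np.unique(labels) if c != 0]
    remap = {c: i + 1 for i, c in enumerate(ids)}
    labels = np.array([remap.get(c, 0) for c in labels], dtype=np.int64)
    return BlockResult(labels=labels, stages=stages, trace=trace, spc=first_spc)


def merge_groups(clusters: dict[int, ClusterStats], c_stop: float = 1.8,
                 metric: str = "normalized") -> dict[int, int]:
    """Agglomerate similar clusters into unit groups.

    Within- and across-block clusters are pooled and merged in one pass:
    repeatedly the pair of groups at minimal distance between mean
    waveforms is merged, the merged group's spike-count-weighted mean and
    pooled variability are recomputed, and distances refreshed; merging
    stops once the minimal distance exceeds ``c_stop``. With the default
    ``normalized`` metric the distance is Euclidean distance divided by
    the smaller variability measure ``s`` of the candidate pair, putting
    ``c_stop`` on the same scale as the template-matching radii while
    keeping a tight cluster from being absorbed by a high-variance one;
    ``raw`` uses plain microvolt distance. Returns ``{cluster_id:
    group_id}`` with dense group ids from 1.
    """
    if metric not in ("normalized", "raw"):
        raise ValueError("metric must be 'normalized' or 'raw'")
    cids = sorted(clusters)
    if not cids:
        return {}
    groups = {g: [cid] for g, cid in enumerate(cids)}
    stats = {g: clusters[cid] for g, cid in enumerate(cids)}

    def distance(a: ClusterStats, b: ClusterStats) -> float:
        d = float(np.linalg.norm(a.mean_wave - b.mean_wave))
        if metric == "raw":
            return d
        s = min(a.s, b.s)
        if s == 0:
            return 0.0 if d == 0 else np.inf
        return d / s

    def pooled(a: ClusterStats, b: ClusterStats) -> ClusterStats:
        n = a.size + b.size
        mean = (a.size * a.mean_wave + b.size * b.mean_wave) / n
        var = (a.size * (a.var_wave + (a.mean_wave - mean) ** 2)
               + b.size * (b.var_wave + (b.mean_wave - mean) ** 2)) / n
        return ClusterStats(mean_wave=mean, var_wave=var, size=n)

    while len(groups) > 1:
        keys = sorted(groups)
        best = None
        for i, ga in enumerate(keys):
            for gb in keys[i + 1:]:
                d = distance(stats[ga], stats[gb])
                if best is None or d < best[0]:
                    best = (d, ga, gb)
        d_min, ga, gb = best
        if d_min > c_stop:
            break
        groups[ga] = groups[ga] + groups[gb]
        stats[ga] = pooled(stats[ga], stats[gb])
        del groups[gb], stats[gb]

    out = {}
    for new_gid, g in enumerate(sorted(groups), start=1):
        for cid in groups[g]:
            out[cid] = new_gid
    return out


def sort_channel(spikes: SpikeSet, params: SortParams | None = None,
                 hyper: SPCHyper | None = None,
                 artifact_params: ArtifactParams | None = None,
                 seed: int | None = None, n_jobs: int = 1,
                 flag_artifacts: bool = True) -> SortingResult:
    """Sort one channel end to end.

    Blocks are sorted independently (``n_jobs`` workers; per-block seeds
    derived from the channel seed keep the result identical regardless of
    scheduling), across-block template matching with radius ``f2`` assigns
    remaining spikes to any block's cluster, every cluster is screened by
    the post-sorting artifact criteria, and non-artifact clusters are
    merged into groups. Spikes never captured stay in the residual cluster
    (id 0).
    """
    params = params or SortParams()
    hyper = hyper or SPCHyper()
    artifact_params = artifact_params or ArtifactParams()
    seed = hyper.seed if seed is None else seed

    n = spikes.n_spikes
    blocks = segment_blocks(spikes, params.n_block)
    if n_jobs != 1 and len(blocks) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(sort_block)(b, params, hyper, seed=seed + i)
            for i, b in enumerate(blocks)
        )
    else:
        results = [sort_block(b, params, hyper, seed=seed + i)
                   for i, b in enumerate(blocks)]

    cluster_id = np.zeros(n, dtype=np.int64)
    block_index = np.zeros(n, dtype=np.int64)
    stages = np.full(n, AssignStage.RESIDUAL, dtype=np.int64)
    next_id = 1
    offset = 0
    for bi, (blk, res) in enumerate(zip(blocks, results)):
        m = blk.n_spikes
        sl = slice(offset, offset + m)
        block_index[sl] = bi
        local = res.labels
        ids = [c for c in np.unique(local) if c != 0]
        remap = {c: next_id + i for i, c in enumerate(ids)}
        next_id += len(ids)
        cluster_id[sl] = [remap.get(c, 0) for c in local]
        stages[sl] = res.stages
        offset += m

    # across-block template matching over the pooled clusters of all blocks
    stats = cluster_stats(spikes.waveforms, cluster_id)
    assigned = template_match(spikes.waveforms, np.flatnonzero(cluster_id == 0),
                              stats, params.f2)
    for spike, cid in assigned.items():
        cluster_id[spike] = cid
        stages[spike] = AssignStage.TM_ACROSS
    stats = cluster_stats(spikes.waveforms, cluster_id)

    artifact: dict[int, frozenset] = {}
    if flag_artifacts:
        for cid in stats:
            _, fired = flag_artifact_cluster(
                spikes.waveforms[cluster_id == cid], spikes.rate_eff,
                artifact_params)
            artifact[cid] = fired
    else:
        artifact = {cid: frozenset() for cid in stats}

    clean = {cid: st for cid, st in stats.items() if not artifact[cid]}
    group_id = merge_groups(clean, params.c_stop, params.merge_metric)

    return SortingResult(
        times=spikes.times.copy(),
        cluster_id=cluster_id,
        original_cluster_id=cluster_id.copy(),
        block_index=block_index,
        assign_stage=stages,
        artifact=artifact,
        group_id=group_id,
        channel_id=spikes.channel_id,
    )
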