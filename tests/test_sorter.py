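"""Block segmentation, cluster selection, matching, splitting and merging."""

import numpy as np
import pytest

from oracles import brute_merge, brute_nearest_admissible, brute_select_from_table
from spikeblocks.containers import AssignStage, ClusterStats, SpikeSet
from spikeblocks.params import SortParams, SPCHyper
from spikeblocks.sorter import (merge_groups, segment_blocks, select_clusters,
                                sort_block, sort_channel, split_large,
                                template_match)
from spikeblocks.spc import SPCResult


def toy_spikes(n, k=48, seed=0):
    rng = np.random.default_rng(seed)
    return SpikeSet(rng.normal(size=(n, k)), np.arange(n, dtype=float))


class TestSegmentation:
    @pytest.mark.parametrize("n,n_block,expected", [
        (350_000, 20_000, 18),
        (60_000, 20_000, 3),
        (5_000, 20_000, 1),
    ])
    def test_block_counts(self, n, n_block, expected):
        ss = SpikeSet(np.zeros((n, 1)), np.arange(n, dtype=float))
        blocks = segment_blocks(ss, n_block)
        assert len(blocks) == expected
        assert sum(b.n_spikes for b in blocks) == n
        assert all(b.n_spikes == n_block for b in blocks[:-1])


def spc_from_labels(labels, temperatures=None):
    labels = np.asarray(labels)
    if temperatures is None:
        temperatures = np.linspace(0, 0.2, labels.shape[0])
    return SPCResult(temperatures=np.asarray(temperatures), labels=labels)


def size_table_of(spc):
    return [list(spc.sizes(j)) for j in range(spc.n_t)]


def random_spc(rng, n=80, n_t=6):
    """Random label matrix with a trivial first row, like a real sweep."""
    labels = np.zeros((n_t, n), dtype=np.int64)
    for j in range(1, n_t):
        n_clusters = int(rng.integers(1, 6))
        labels[j] = rng.integers(0, n_clusters, n)
    return spc_from_labels(labels)


class TestSelectClusters:
    def test_matches_table_oracle_on_random_sweeps(self, rng):
        """Selection decisions equal the brute-force size-table rule."""
        for case in range(300):
            spc = random_spc(rng)
            c_max = int(rng.integers(1, 4))
            s_min = int(rng.integers(2, 10))
            _, trace = select_clusters(spc, c_max, s_min)
            got = [(ev.temp_index, ev.rank) for ev in trace]
            expect = brute_select_from_table(size_table_of(spc), c_max,
                                             s_min, spc.n)
            assert got == expect, f"case {case}"

    def test_constructed_bump_is_selected(self):
        """One clear size bump at an intermediate temperature is picked."""
        n = 60
        labels = np.zeros((5, n), dtype=np.int64)
        labels[1, 40:] = 1                       # sizes 40 / 20
        labels[2, 40:] = 1
        labels[2, 20:40] = 2                     # sizes 20/20/20: rank-2 bump
        labels[3] = np.arange(n) % 10            # fragmented
        labels[4] = np.arange(n)
        spc = spc_from_labels(labels)
        assigned, trace = select_clusters(spc, c_max=5, s_min=5)
        selected = {(ev.temp_index, ev.rank) for ev in trace if ev.selected}
        expect = set(brute_select_from_table(size_table_of(spc), 5, 5, n))
        assert {(t, r) for t, r in expect} >= selected
        assert (1, 0) in selected and (1, 1) in selected

    def test_nothing_below_s_min(self):
        labels = np.zeros((4, 30), dtype=np.int64)
        labels[1] = np.arange(30) % 10           # all clusters of size 3
        labels[2] = np.arange(30) % 10
        labels[3] = np.arange(30)
        spc = spc_from_labels(labels)
        assigned, trace = select_clusters(spc, c_max=5, s_min=15)
        assert not assigned.any()
        assert all(not ev.selected for ev in trace)

    def test_c_max_caps_selections_per_temperature(self, rng):
        n = 200
        labels = np.zeros((4, n), dtype=np.int64)
        labels[1] = np.arange(n) % 10            # ten clusters of 20 each
        labels[2] = np.arange(n) % 10
        labels[3] = np.arange(n)
        spc = spc_from_labels(labels)
        _, trace = select_clusters(spc, c_max=5, s_min=5)
        per_temp = {}
        for ev in trace:
            if ev.selected:
                per_temp[ev.temp_index] = per_temp.get(ev.temp_index, 0) + 1
        assert all(v <= 5 for v in per_temp.values())
        assert per_temp.get(1, 0) == 5

    def test_claimed_spikes_never_reassigned(self):
        """Irreversibility: later temperatures cannot steal marked spikes."""
        n = 40
        labels = np.zeros((5, n), dtype=np.int64)
        labels[1, :20] = 1                       # cluster A claims 0..19
        labels[2, :20] = 1
        labels[2, 20:] = 2                       # cluster B claims the rest
        labels[3, :30] = 1                       # would overlap A's spikes
        labels[4] = np.arange(n)
        spc = spc_from_labels(labels)
        assigned, trace = select_clusters(spc, c_max=5, s_min=5)
        first = assigned.copy()
        # every selected event contributes only previously unclaimed spikes
        claimed = np.zeros(n, bool)
        for ev in sorted([e for e in trace if e.selected],
                         key=lambda e: e.temp_index):
            members = np.flatnonzero(assigned == ev.cluster_id)
            assert not claimed[members].any()
            claimed[members] = True
        np.testing.assert_array_equal(first, assigned)


class TestTemplateMatch:
    def stats(self, mean, s_scalar, k=8, size=50):
        var = np.full(k, (s_scalar ** 2) / k)
        m = np.zeros(k)
        m[:len(np.atleast_1d(mean))] = mean
        return ClusterStats(mean_wave=m, var_wave=var, size=size)

    def test_exact_match_assigned(self):
        cl = {1: self.stats([10.0, 5.0], 4.0)}
        waves = np.zeros((1, 8))
        waves[0, 0], waves[0, 1] = 10.0, 5.0
        out = template_match(waves, np.array([0]), cl, f=0.75)
        assert out == {0: 1}

    def test_outside_radius_unassigned(self):
        """Distance 0.8 s with f = 0.75 stays unassigned."""
        s = 10.0
        cl = {1: self.stats([0.0], s)}
        waves = np.zeros((1, 8))
        waves[0, 0] = 0.8 * s
        assert template_match(waves, np.array([0]), cl, f=0.75) == {}
        assert template_match(waves, np.array([0]), cl, f=0.9) == {0: 1}

    def test_nearest_admissible_oracle(self, rng):
        k = 8
        for _ in range(100):
            n_cl = int(rng.integers(1, 5))
            clusters = {}
            means, radii = [], []
            f = 1.5
            for c in range(n_cl):
                mean = rng.normal(0, 20, k)
                s = rng.uniform(1, 30)
                clusters[c + 1] = ClusterStats(
                    mean_wave=mean, var_wave=np.full(k, s ** 2 / k), size=10)
                means.append(mean)
                radii.append(f * clusters[c + 1].s)
            waves = rng.normal(0, 25, (12, k))
            got = template_match(waves, np.arange(12), clusters, f=f)
            for i in range(12):
                expect = brute_nearest_admissible(waves[i], means, radii)
                assert got.get(i, -1) == (expect + 1 if expect >= 0 else -1)

    def test_no_clusters_identity(self):
        assert template_match(np.zeros((3, 8)), np.arange(3), {}, 0.75) == {}


class TestSplitLarge:
    def two_template_features(self, rng, n=3000):
        half = n // 2
        x = np.vstack([rng.normal(0, 1, (half, 48)),
                       rng.normal(0, 1, (n - half, 48)) + 8.0])
        return x, np.repeat([0, 1], [half, n - half])

    def test_below_threshold_untouched(self, rng):
        feats = rng.normal(size=(100, 48))
        labels = np.ones(100, dtype=np.int64)
        out = split_large(labels, feats, r_min=2000)
        np.testing.assert_array_equal(out, labels)

    def test_merged_blob_splits_into_pure_subclusters(self, rng):
        coeffs, truth = self.two_template_features(rng)
        labels = np.ones(3000, dtype=np.int64)
        out = split_large(labels, coeffs, r_min=2000,
                         params=SortParams(), hyper=SPCHyper(seed=5))
        ids = [c for c in np.unique(out) if c != 0]
        assert len(ids) >= 2
        big = sorted(ids, key=lambda c: -(out == c).sum())[:2]
        for cid in big:
            members = np.flatnonzero(out == cid)
            purity = np.bincount(truth[members]).max() / members.size
            assert purity > 0.9

    def test_homogeneous_cluster_not_split(self, rng):
        coeffs = rng.normal(0, 1, (3000, 48))
        labels = np.ones(3000, dtype=np.int64)
        out = split_large(labels, coeffs, r_min=2000,
                         params=SortParams(), hyper=SPCHyper(seed=5))
        # either untouched, or split attempt found nothing to replace
        assert np.array_equal(out, labels)


class TestMergeGroups:
    def mkstats(self, mean, var_scalar, size, k=6):
        return ClusterStats(mean_wave=np.asarray(mean, float),
                            var_wave=np.full(k, var_scalar), size=size)

    def test_identical_means_merge(self):
        m = np.arange(6.0)
        groups = merge_groups({1: self.mkstats(m, 4.0, 10),
                               2: self.mkstats(m, 9.0, 20)}, c_stop=0.1)
        assert groups[1] == groups[2]

    def test_distance_beyond_c_stop_not_merged(self):
        """Normalized distance 2.0 with C_stop = 1.8 keeps two groups."""
        k = 6
        s = 5.0
        a = np.zeros(k)
        b = np.zeros(k)
        b[0] = 2.0 * s
        groups = merge_groups(
            {1: self.mkstats(a, s ** 2 / k, 10),
             2: self.mkstats(b, s ** 2 / k, 10)}, c_stop=1.8)
        assert groups[1] != groups[2]

    def test_single_cluster_single_group(self):
        groups = merge_groups({5: self.mkstats(np.ones(6), 1.0, 4)}, 1.8)
        assert groups == {5: 1}

    def test_four_cluster_oracle_equality(self, rng):
        k = 6
        for _ in range(100):
            stats = {}
            raw = {}
            for cid in range(1, 5):
                mean = rng.normal(0, 10, k)
                var = np.abs(rng.normal(1, 0.5, k)) + 0.1
                size = int(rng.integers(5, 50))
                stats[cid] = ClusterStats(mean_wave=mean, var_wave=var,
                                          size=size)
                raw[cid] = (mean, var, size)
            c_stop = float(rng.uniform(0.5, 3.0))
            groups = merge_groups(stats, c_stop)
            got = {}
            for cid, g in groups.items():
                got.setdefault(g, set()).add(cid)
            expect = brute_merge(raw, c_stop)
            assert {frozenset(v) for v in got.values()} == expect

    def test_group_count_monotone_in_c_stop(self, rng):
        k = 6
        stats = {cid: ClusterStats(mean_wave=rng.normal(0, 8, k),
                                   var_wave=np.abs(rng.normal(1, 0.3, k)),
                                   size=int(rng.integers(5, 50)))
                 for cid in range(1, 9)}
        counts = [len(set(merge_groups(stats, c).values()))
                  for c in (1.2, 1.4, 1.6, 1.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSortBlock:
    def synthetic_block(self, rng, n=1200, n_units=3, sep=10.0, probs=None):
        k = 48
        from scipy.ndimage import gaussian_filter1d

        i = np.arange(k)
        waves = np.empty((n, k))
        truth = rng.choice(n_units, size=n, p=probs)
        for u in range(n_units):
            tpl = (sep * (u + 2) * np.exp(-0.5 * ((i - 6 - 4 * u) / 2.0) ** 2)
                   - sep * (u + 1) * np.exp(-0.5 * ((i - 20 - 3 * u) / 3.0) ** 2))
            members = truth == u
            # band-limited noise, like real extracted waveforms
            noise = gaussian_filter1d(
                rng.normal(0, 1.8, (members.sum(), k)), 1.5, axis=1)
            waves[members] = tpl + noise
        return SpikeSet(waves, np.arange(n, dtype=float)), truth

    def test_conservation_and_purity(self, rng):
        block, truth = self.synthetic_block(rng)
        res = sort_block(block, SortParams(r_min=2000), SPCHyper(seed=2))
        assert res.labels.size == block.n_spikes
        assert ((res.labels == 0) == (res.stages == AssignStage.RESIDUAL)).all()
        ids = [c for c in np.unique(res.labels) if c]
        assert len(ids) >= 3
        big = sorted(ids, key=lambda c: -(res.labels == c).sum())[:3]
        for cid in big:
            members = np.flatnonzero(res.labels == cid)
            assert np.bincount(truth[members]).max() / members.size > 0.9

    def test_tiny_block_passes_through_with_warning(self):
        ss = toy_spikes(8)
        with pytest.warns(UserWarning, match="pass-through"):
            res = sort_block(ss, SortParams(), SPCHyper(seed=0))
        assert (res.labels == 1).all()

    def test_second_iteration_rescues_capped_population(self, rng):
        """With c_max=1 pass one takes one unit; pass two takes the other."""
        block, truth = self.synthetic_block(rng, n=1000, n_units=2, sep=30.0,
                                            probs=[0.75, 0.25])
        one = sort_block(block, SortParams(c_max=1, n_rep=1, r_min=5000),
                         SPCHyper(seed=2))
        two = sort_block(block, SortParams(c_max=1, n_rep=2, r_min=5000),
                         SPCHyper(seed=2))
        assigned_one = (one.labels != 0).sum()
        assigned_two = (two.labels != 0).sum()
        assert assigned_two > assigned_one
        # both units recovered in the two-pass run
        ids = [c for c in np.unique(two.labels) if c]
        majors = set()
        for cid in ids:
            members = np.flatnonzero(two.labels == cid)
            if members.size > 100:
                majors.add(int(np.bincount(truth[members]).argmax()))
        assert majors == {0, 1}


class TestSortChannel:
    def test_single_block_degenerate(self, rng):
        helper = TestSortBlock()
        block, _ = helper.synthetic_block(rng, n=800)
        res = sort_channel(block, SortParams(r_min=5000), SPCHyper(seed=2))
        assert res.n_spikes == 800
        assert (res.block_index == 0).all()
        np.testing.assert_array_equal(res.cluster_id, res.original_cluster_id)
        assert set(res.artifact) == set(res.cluster_ids())

    def test_conservation_and_ungroup(self, rng):
        helper = TestSortBlock()
        block, _ = helper.synthetic_block(rng, n=900)
        res = sort_channel(block, SortParams(n_block=300, r_min=5000),
                           SPCHyper(seed=2))
        # every spike in exactly one cluster or residual
        assert res.cluster_id.size == 900
        assert res.cluster_id.min() >= 0
        undone = res.ungroup()
        assert undone.group_id == {}
        np.testing.assert_array_equal(undone.cluster_id,
                                      res.original_cluster_id)

    def test_two_units_tracked_across_blocks(self, rng):
        """Stable waveforms over 3 blocks give groups spanning all blocks."""
        helper = TestSortBlock()
        block, truth = helper.synthetic_block(rng, n=1800, n_units=2)
        res = sort_channel(block, SortParams(n_block=600, r_min=5000,
                                             c_max=7),
                           SPCHyper(seed=2))
        spanning = 0
        for g in res.groups():
            idx = res.spikes_of_group(g)
            if idx.size < 200:
                continue
            if np.unique(res.block_index[idx]).size == 3:
                spanning += 1
        assert spanning >= 2
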