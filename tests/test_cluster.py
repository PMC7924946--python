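"""Cluster formation and the Monte-Carlo permutation test."""

import numpy as np
import pytest

from cuedpain.design import heat_cells
from cuedpain.montage import ChannelNeighborhood
from cuedpain.rm_stats import ConditionAverage, FStatMap
from cuedpain.cluster import find_clusters, permutation_test


def ring_neighborhood(n: int) -> ChannelNeighborhood:
    chs = [f"ch{i}" for i in range(n)]
    if n == 1:
        return ChannelNeighborhood({chs[0]: set()})
    nb = {chs[i]: {chs[(i - 1) % n], chs[(i + 1) % n]} for i in range(n)}
    return ChannelNeighborhood(nb)


def random_neighborhood(rng, n: int, p: float = 0.3) -> ChannelNeighborhood:
    chs = [f"ch{i}" for i in range(n)]
    nb = {ch: set() for ch in chs}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                nb[chs[i]].add(chs[j])
                nb[chs[j]].add(chs[i])
    return ChannelNeighborhood(nb)


def fmap(F, slope=None, df=(1, 7)):
    F = np.asarray(F, float)
    slope = np.sign(F) if slope is None else np.asarray(slope)
    return FStatMap(F=np.abs(F), slope=slope, df=df)


def brute_force_clusters(F, slope, threshold, neighbor_sets, min_nb=1):
    """Independent oracle: explicit pairwise adjacency + networkx components.

    Implements the stated rule from scratch: supra-threshold samples,
    one-pass removal of samples without a supra-threshold channel
    neighbor (skipped for single-channel maps), sign splitting, then
    connectivity over (+/-1 time, +/-1 freq bin, neighboring channel).
    """
    import networkx as nx

    n_ch, n_f, n_t = F.shape
    supra = {(c, f, t) for c in range(n_ch) for f in range(n_f) for t in range(n_t)
             if F[c, f, t] > threshold}
    if n_ch > 1 and min_nb > 0:
        kept = {s for s in supra
                if sum((c2, s[1], s[2]) in supra for c2 in neighbor_sets[s[0]]) >= min_nb}
    else:
        kept = supra
    out = []
    for sign in (1, -1):
        nodes = [s for s in kept if slope[s] == sign]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a in nodes:
            for b in nodes:
                if a >= b:
                    continue
                c1, f1, t1 = a
                c2, f2, t2 = b
                if (c1 == c2 and f1 == f2 and abs(t1 - t2) == 1) or \
                   (c1 == c2 and t1 == t2 and abs(f1 - f2) == 1) or \
                   (f1 == f2 and t1 == t2 and c2 in neighbor_sets[c1]):
                    g.add_edge(a, b)
        for comp in nx.connected_components(g):
            out.append((sign, frozenset(comp), sum(F[s] for s in comp)))
    return out


class TestFindClusters:
    def test_isolated_sample_without_channel_support_excluded(self):
        F = np.zeros((3, 2, 2))
        F[1, 0, 0] = 6.0  # lone supra-threshold sample
        nb = ring_neighborhood(3)
        assert find_clusters(fmap(F), 4.196, nb, nb.channels, np.arange(2), np.arange(2)) == []

    def test_two_time_adjacent_samples_form_one_cluster(self):
        F = np.zeros((2, 1, 3))
        F[0, 0, 0], F[0, 0, 1] = 5.0, 6.0
        F[1, 0, 0], F[1, 0, 1] = 5.5, 5.5  # channel support
        nb = ring_neighborhood(2)
        clusters = find_clusters(fmap(F), 4.196, nb, nb.channels, np.arange(1), np.arange(3))
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(5.0 + 6.0 + 5.5 + 5.5)
        assert clusters[0].n_members == 4

    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_ch = 10
            nb = random_neighborhood(rng, n_ch)
            sets = [set(int(x[2:]) for x in nb[f"ch{i}"]) for i in range(n_ch)]
            F = rng.chisquare(2, size=(n_ch, 10, 10)) * 2
            slope = rng.choice([-1, 1], size=F.shape)
            ours = find_clusters(fmap(F, slope), 4.196, nb, nb.channels,
                                 np.arange(10), np.arange(10))
            ours_set = {(c.sign, frozenset(map(tuple, c.members)), round(c.mass, 6))
                        for c in ours}
            oracle = {(s, m, round(mass, 6))
                      for s, m, mass in brute_force_clusters(F, slope, 4.196, sets)}
            assert ours_set == oracle

    def test_single_channel_reduces_to_2d_time_frequency_clustering(self):
        from scipy import ndimage

        rng = np.random.default_rng(8)
        F = rng.chisquare(2, size=(1, 20, 20)) * 2.5
        nb = ring_neighborhood(1)
        ours = find_clusters(fmap(F, np.ones_like(F)), 4.196, nb, nb.channels,
                             np.arange(20), np.arange(20))
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labels, n = ndimage.label(F[0] > 4.196, structure=structure)
        oracle = {frozenset((0, f, t) for f, t in zip(*np.nonzero(labels == k)))
                  for k in range(1, n + 1)}
        assert {frozenset(map(tuple, c.members)) for c in ours} == oracle

    def test_partition_invariant_to_channel_enumeration_order(self):
        rng = np.random.default_rng(9)
        nb = random_neighborhood(rng, 6)
        F = rng.chisquare(2, size=(6, 8, 8)) * 2
        slope = rng.choice([-1, 1], size=F.shape)
        chs = nb.channels
        base = find_clusters(fmap(F, slope), 4.196, nb, chs, np.arange(8), np.arange(8))
        perm = rng.permutation(6)
        permuted = find_clusters(
            fmap(F[perm], slope[perm]), 4.196, nb, [chs[i] for i in perm],
            np.arange(8), np.arange(8))

        def key(clusters):
            return sorted(
                (c.sign, round(c.mass, 9),
                 frozenset((c.ch_names[m[0]], m[1], m[2]) for m in c.members))
                for c in clusters)

        assert key(base) == key(permuted)

    def test_raising_threshold_never_merges_or_grows_clusters(self):
        rng = np.random.default_rng(10)
        nb = random_neighborhood(rng, 8)
        F = rng.chisquare(2, size=(8, 10, 10)) * 3
        slope = rng.choice([-1, 1], size=F.shape)
        lo = find_clusters(fmap(F, slope), 4.0, nb, nb.channels, np.arange(10), np.arange(10))
        hi = find_clusters(fmap(F, slope), 6.0, nb, nb.channels, np.arange(10), np.arange(10))
        lo_sets = [set(map(tuple, c.members)) for c in lo]
        for c in hi:
            mem = set(map(tuple, c.members))
            parents = [s for s in lo_sets if mem & s]
            assert len(parents) == 1  # no merging across the looser partition
            assert mem <= parents[0]  # no growth

    def test_mass_at_least_threshold_times_members(self):
        rng = np.random.default_rng(11)
        nb = random_neighborhood(rng, 8)
        F = rng.chisquare(2, size=(8, 10, 10)) * 3
        for c in find_clusters(fmap(F, np.ones_like(F)), 4.196, nb, nb.channels,
                               np.arange(10), np.arange(10)):
            assert c.mass >= 4.196 * c.n_members

    def test_peak_is_argmax_of_F_within_cluster(self):
        rng = np.random.default_rng(12)
        nb = random_neighborhood(rng, 6)
        F = rng.chisquare(2, size=(6, 8, 8)) * 3
        slope = rng.choice([-1, 1], size=F.shape)
        for c in find_clusters(fmap(F, slope), 4.196, nb, nb.channels,
                               np.arange(8), np.arange(8)):
            member_F = [F[tuple(m)] for m in c.members]
            assert c.peak["F"] == pytest.approx(max(member_F))
            m = c.members[int(np.argmax(member_F))]
            assert c.peak["channel"] == nb.channels[m[0]]

    def test_empty_supra_set_returns_empty_list(self):
        nb = ring_neighborhood(3)
        F = np.ones((3, 4, 4))
        assert find_clusters(fmap(F), 4.196, nb, nb.channels, np.arange(4), np.arange(4)) == []


def make_condition_average(rng, n_sub=8, n_ch=4, n_f=5, n_t=6, effect=None):
    cells = heat_cells()
    z = rng.standard_normal((n_sub, 9, n_ch, n_f, n_t))
    if effect is not None:
        z += effect
    return ConditionAverage(z=z, cells=cells, ch_names=[f"ch{i}" for i in range(n_ch)],
                            freqs=np.arange(5.0, 5.0 + n_f), times=np.arange(n_t) * 0.05)


class TestPermutationTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        data = make_condition_average(rng)
        nb = ring_neighborhood(4)
        a = permutation_test(data, "INT", nb, n_perm=150, seed=5)
        b = permutation_test(data, "INT", nb, n_perm=150, seed=5)
        np.testing.assert_array_equal(a.null_max_mass, b.null_max_mass)
        assert [(c.mass, c.p) for c in a.clusters] == [(c.mass, c.p) for c in b.clusters]

    def test_strong_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(1)
        from cuedpain.rm_stats import contrast_weights

        cells = heat_cells()
        w = contrast_weights(cells, "INT")
        effect = 30.0 * w[None, :, None, None, None]
        data = make_condition_average(rng, effect=effect)
        nb = ring_neighborhood(4)
        res = permutation_test(data, "INT", nb, n_perm=199, seed=2)
        # observed mass above every permutation's max: p = 1/(n_perm+1)
        assert res.clusters[0].p == pytest.approx(1.0 / 200.0)
        assert res.clusters[0].sign == 1

    def test_default_threshold_is_crit_F(self):
        rng = np.random.default_rng(2)
        data = make_condition_average(rng, n_sub=29)
        nb = ring_neighborhood(4)
        res = permutation_test(data, "EXP", nb, n_perm=100, seed=0)
        assert res.threshold == pytest.approx(4.196, abs=5e-4)
        assert res.df == (1, 28)

    def test_tiny_design_enumerates_exhaustively(self):
        rng = np.random.default_rng(3)
        cells = heat_cells("reduced")[:2]  # two cells -> 2^n_subjects permutations
        data = ConditionAverage(
            z=rng.standard_normal((3, 2, 1, 2, 2)), cells=cells,
            ch_names=["ch0"], freqs=np.arange(2.0), times=np.arange(2) * 0.05,
            model="custom",
        )
        nb = ring_neighborhood(1)
        with pytest.warns(RuntimeWarning, match="exhaustively"):
            res = permutation_test(data, "INT", nb, n_perm=100, seed=0,
                                   threshold=1.0, min_channel_neighbors=0)
        assert res.n_perm == 2**3

    def test_window_and_band_cropping(self):
        rng = np.random.default_rng(4)
        data = make_condition_average(rng, n_f=6, n_t=10)
        nb = ring_neighborhood(4)
        res = permutation_test(data, "PE", nb, n_perm=100, seed=1,
                               window=(0.1, 0.3), band=(6.0, 8.0))
        for c in res.clusters:
            t0, t1 = c.time_range
            f0, f1 = c.freq_range
            assert 0.1 <= t0 <= t1 <= 0.3
            assert 6.0 <= f0 <= f1 <= 8.0
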