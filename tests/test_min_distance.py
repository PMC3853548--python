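"""Minimum-distance trees: encoding, objective, gradients, optimization."""

import numpy as np
import pytest

from treesum.core import TreeSample
from treesum.distances import METRICS, build_clade_index, set_distance
from treesum.min_distance import (
    OptimizerOptions,
    ParamVector,
    Topology,
    decode,
    encode,
    init_tree,
    min_distance_tree,
    objective,
    optimize_fixed_topology,
)

from conftest import make_sample, random_sample, random_tree

OPTS = OptimizerOptions(seed=7)


class TestEncoding:
    def test_example(self, fixture_trees):
        pv = encode(fixture_trees[0])
        assert pv.z[0] == pytest.approx(2.0)
        assert pv.z[1] == pytest.approx(0.5)
        assert decode(pv).equals(fixture_trees[0])

    def test_round_trip_random(self, rng):
        for _ in range(40):
            t = random_tree(rng, n=int(rng.integers(3, 10)))
            assert decode(encode(t)).equals(t, tol=1e-12)

    def test_bounds_enforced(self, fixture_trees):
        topo = Topology.of(fixture_trees[0].taxa, fixture_trees[0])
        with pytest.raises(ValueError):
            ParamVector(topo, np.array([-1.0, 0.5]))
        with pytest.raises(ValueError):
            ParamVector(topo, np.array([1.0, 1.5]))

    def test_decode_never_negative_branches(self, rng):
        topo = Topology.of(None, random_tree(rng, n=6))
        for _ in range(20):
            z = np.concatenate(
                ([rng.uniform(0, 5)], rng.uniform(0, 1, topo.m - 1))
            )
            t = decode(ParamVector(topo, z))
            for c, p in t.parent.items():
                assert t.ages[p] >= t.ages[c]


class TestObjective:
    def test_value_equals_set_distance(self, rng):
        for _ in range(10):
            sample = random_sample(rng, n=5, size=8)
            topo = Topology.of(sample.taxa, sample[0])
            z = np.concatenate(
                ([rng.uniform(0.1, 3)], rng.uniform(0, 1, topo.m - 1))
            )
            pv = ParamVector(topo, z)
            for m in METRICS:
                idx = build_clade_index(sample, m)
                val, _ = objective(pv, idx)
                assert val == pytest.approx(
                    set_distance(decode(pv), idx), abs=1e-9
                )

    @pytest.mark.parametrize("metric", METRICS)
    def test_gradient_matches_finite_differences(self, metric, rng):
        eps, hits = 1e-6, 0
        while hits < 25:
            sample = random_sample(rng, n=5, size=6)
            topo = Topology.of(sample.taxa, sample[0])
            idx = build_clade_index(sample, metric)
            z = np.concatenate(
                ([rng.uniform(0.2, 2.5)], rng.uniform(0.05, 0.95, topo.m - 1))
            )
            _, g = objective(ParamVector(topo, z), idx)
            ok = True
            for i in range(topo.m):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                fd = (
                    objective(ParamVector(topo, zp), idx)[0]
                    - objective(ParamVector(topo, zm), idx)[0]
                ) / (2 * eps)
                # skip points straddling an L1 kink (one-sided slopes differ)
                fp = (objective(ParamVector(topo, zp), idx)[0]
                      - objective(ParamVector(topo, z), idx)[0]) / eps
                if abs(fp - fd) > 1e-3 * max(1, abs(fd)):
                    ok = False
                    break
                assert g[i] == pytest.approx(fd, abs=1e-4 * max(1, abs(fd)))
            hits += ok


class TestInitTree:
    def test_single_tree_sample_recovers_tree(self, rng):
        t = random_tree(rng, n=6)
        for m in METRICS:
            idx = build_clade_index(make_sample(t), m)
            assert init_tree(t, idx).equals(t, tol=1e-12)

    def test_srbs_example(self, tx, fixture_trees):
        TA, TB, _ = fixture_trees
        idx = build_clade_index(make_sample(TA, TB), "srbs")
        t0 = init_tree(TA, idx)
        assert t0.ages[tx.clade("ab")] == pytest.approx(0.75)
        assert t0.ages[tx.clade("abc")] == pytest.approx(2.5)

    def test_rbs_even_median_midpoint(self, tx, fixture_trees):
        TA, TB, _ = fixture_trees
        idx = build_clade_index(make_sample(TA, TB), "rbs")
        from treesum.min_distance import _padded_branch_stat

        assert _padded_branch_stat(idx, tx.clade("a"), "rbs") == pytest.approx(
            0.75
        )


class TestOptimize:
    def test_srbs_closed_form_example(self, tx, fixture_trees):
        TA, TB, _ = fixture_trees
        sample = make_sample(TA, TB)
        t = optimize_fixed_topology(TA, sample, "srbs", OPTS)
        assert t.ages[tx.clade("ab")] == pytest.approx(0.75, abs=1e-6)
        assert t.ages[tx.clade("abc")] == pytest.approx(2.5, abs=1e-6)
        idx = build_clade_index(sample, "srbs")
        assert set_distance(t, idx) == pytest.approx(0.9375, abs=1e-9)

    def test_single_tree_sample_distance_zero(self, rng):
        t = random_tree(rng, n=5)
        for m in METRICS:
            opt = optimize_fixed_topology(t, make_sample(t), m, OPTS)
            assert opt.equals(t, tol=1e-9)

    @pytest.mark.parametrize("metric", METRICS)
    def test_never_worse_than_init(self, metric, rng):
        for _ in range(5):
            sample = random_sample(rng, n=6, size=10)
            idx = build_clade_index(sample, metric)
            topo = Topology.of(sample.taxa, sample[0])
            opt = optimize_fixed_topology(topo, idx, opts=OPTS)
            assert set_distance(opt, idx) <= set_distance(
                init_tree(topo, idx), idx
            ) + 1e-12

    def test_srbs_gradient_small_at_interior_optimum(self, rng):
        sample = random_sample(rng, n=5, size=8)
        idx = build_clade_index(sample, "srbs")
        topo = Topology.of(sample.taxa, sample[0])
        opt = optimize_fixed_topology(topo, idx, opts=OPTS)
        pv = encode(opt)
        _, g = objective(ParamVector(Topology.of(sample.taxa, opt), pv.z), idx)
        scale = max(1.0, abs(set_distance(opt, idx)))
        for i, zi in enumerate(pv.z):
            interior = (zi > 1e-8) and (i == 0 or zi < 1 - 1e-8)
            if interior:
                assert abs(g[i]) < 1e-4 * scale

    def test_deterministic_given_seed(self, rng):
        sample = random_sample(rng, n=5, size=10)
        a = min_distance_tree(sample, "ras", "all_sampled", OPTS)
        b = min_distance_tree(sample, "ras", "all_sampled", OPTS)
        assert a.equals(b, tol=0.0)


class TestMinDistanceTree:
    def test_single_topology_matches_fixed(self, rng):
        sample = random_sample(rng, n=5, size=8, moves=0.0, cv=0.3)
        for m in ("rbs", "srbs"):
            a = min_distance_tree(sample, m, "all_sampled", OPTS)
            idx = build_clade_index(sample, m)
            b = optimize_fixed_topology(sample[0], idx, opts=OPTS)
            assert set_distance(a, idx) <= set_distance(b, idx) + 1e-12

    @pytest.mark.parametrize("metric", METRICS)
    def test_dominates_all_sampled_trees(self, metric, rng):
        for _ in range(5):
            sample = random_sample(rng, n=5, size=8, moves=1.5)
            best = min_distance_tree(sample, metric, "all_sampled", OPTS)
            idx = build_clade_index(sample, metric)
            assert set_distance(best, idx) <= min(
                set_distance(t, idx) for t in sample
            ) + 1e-12

    def test_selected_topology_sources(self, rng):
        sample = random_sample(rng, n=5, size=10, moves=1.0)
        for src in ("mcc", "tcb"):
            t = min_distance_tree(sample, "rbs", src, OPTS)
            assert t.taxa == sample.taxa
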