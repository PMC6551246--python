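import numpy as np
import pytest
from scipy import stats

from scpowerkit import (SimulationParams, allocate_cells, generate_dataset,
                        inject_marker_means, sample_fold_change, select_markers,
                        simulate_counts, simulate_gene_means,
                        simulate_library_sizes)
from scpowerkit.simdata import SimulationError, _substreams


class TestAllocateCells:
    @pytest.mark.parametrize("props,n,expected", [
        ((0.1, 0.2, 0.2, 0.2, 0.3), 1000, (100, 200, 200, 200, 300)),
        # hand apportionment: quotas (19.98, 199.8, 199.8, 199.8, 379.62),
        # floors sum 995, remainders .98 > .8 = .8 = .8 > .62 -> first four +1
        ((0.02, 0.2, 0.2, 0.2, 0.38), 999, (20, 200, 200, 200, 379)),
        ((0.5, 0.5), 5, (3, 2)),  # tie in remainder -> lower index wins
    ])
    def test_largest_remainder(self, props, n, expected):
        got = allocate_cells(props, n)
        assert tuple(got) == expected
        assert got.sum() == n

    def test_single_type_rejected(self):
        with pytest.raises(SimulationError):
            allocate_cells((1.0,), 100)

    def test_zero_cell_type_is_error(self):
        with pytest.raises(SimulationError, match="too small"):
            allocate_cells((0.002, 0.998), 100)

    @pytest.mark.parametrize("n", [50, 73, 999, 1000, 3001])
    def test_conservation(self, n):
        got = allocate_cells((0.02, 0.2, 0.2, 0.2, 0.38), n)
        assert got.sum() == n and got.min() >= 1


class TestGeneMeans:
    def test_moments_and_support(self):
        rng = np.random.default_rng(0)
        x = simulate_gene_means(100_000, 0.6, 0.3, rng)
        assert np.all(x > 0)
        # gamma(0.6, rate 0.3): mean 2, var 0.6/0.09
        se = np.sqrt(0.6 / 0.09 / x.size)
        assert abs(x.mean() - 2.0) < 3 * se
        assert abs(x.var() - 0.6 / 0.09) < 0.3

    def test_bad_params(self):
        with pytest.raises(SimulationError):
            simulate_gene_means(10, 0.0, 0.3, np.random.default_rng(0))


class TestFoldChange:
    def test_untruncated_moments(self):
        rng = np.random.default_rng(1)
        x = sample_fold_change(4.0, rng, truncate_below_one=False, size=100_000)
        assert abs(x.mean() - 4.0) < 3 * np.sqrt(4.0 / x.size)
        y = sample_fold_change(2.0, rng, truncate_below_one=False, size=100_000)
        assert abs(y.var() - 2.0) < 0.1

    def test_truncated_support(self):
        rng = np.random.default_rng(2)
        x = sample_fold_change(2.0, rng, truncate_below_one=True, size=50_000)
        assert x.min() >= 1.0

    def test_fc_below_one_rejected(self):
        with pytest.raises(SimulationError):
            sample_fold_change(0.5, np.random.default_rng(0))


class TestMarkerInjection:
    def test_non_markers_untouched_markers_scaled(self):
        rng = np.random.default_rng(3)
        base = np.full(100, 2.0)
        mmap = {1: np.arange(0, 10), 2: np.arange(10, 20)}
        adj = inject_marker_means(base, mmap, 4.0, rng, truncate_below_one=True)
        assert adj.shape == (2, 100)
        np.testing.assert_array_equal(adj[:, 20:], 2.0)
        # each type leaves the other type's markers at baseline
        np.testing.assert_array_equal(adj[0, 10:20], 2.0)
        np.testing.assert_array_equal(adj[1, :10], 2.0)
        assert np.all(adj[0, :10] >= 2.0) and np.all(adj[1, 10:20] >= 2.0)

    def test_plugin_expectation(self):
        # realized mean ratio over many (marker, sim) pairs -> fC, untruncated
        rng = np.random.default_rng(4)
        base = np.ones(50)
        ratios = []
        for _ in range(1000):
            adj = inject_marker_means(base, {1: np.arange(50)}, 4.0, rng,
                                      truncate_below_one=False)
            ratios.append(adj[0] / base)
        mean = np.mean(ratios)
        assert abs(mean - 4.0) < 3 * np.sqrt(4.0 / (1000 * 50))

    def test_marker_out_of_range(self):
        with pytest.raises(SimulationError, match="out of range"):
            inject_marker_means(np.ones(10), {1: np.array([12])}, 2.0,
                                np.random.default_rng(0))


class TestLibrarySizes:
    def test_median_and_support(self):
        rng = np.random.default_rng(5)
        x = simulate_library_sizes(100_000, np.log(20_000), 0.2, rng)
        assert np.all(x > 0)
        assert abs(np.median(x) / 20_000 - 1) < 0.01

    def test_degenerate_scale(self):
        rng = np.random.default_rng(6)
        x = simulate_library_sizes(100, np.log(500), 0.0, rng)
        np.testing.assert_allclose(x, 500.0)


class TestSimulateCounts:
    def _setup(self, bcv, n_cells=400, libscale=0.0):
        rng = np.random.default_rng(8)
        means = np.tile(np.linspace(1, 20, 200), (2, 1))
        lib = simulate_library_sizes(n_cells, np.log(5000), libscale,
                                     np.random.default_rng(9))
        types = np.array([1] * (n_cells // 2) + [2] * (n_cells // 2))
        counts = simulate_counts(means, lib, types, bcv, rng)
        return counts.toarray(), lib, types

    def test_poisson_dispersion_when_bcv_zero(self):
        x, _, types = self._setup(bcv=0.0)
        block = x[:, types == 1]
        mu = block.mean(axis=1)
        ratio = block.var(axis=1, ddof=1)[mu > 1] / mu[mu > 1]
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_column_sums_match_library_size(self):
        x, lib, _ = self._setup(bcv=0.0, libscale=0.3)
        rel = np.abs(x.sum(axis=0) - lib) / lib
        # Poisson CV of a ~5000-count total is ~1.4%; allow ~4 SD at the max
        assert rel.mean() < 0.02
        assert rel.max() < 0.07

    def test_overdispersion_when_bcv_positive(self):
        x, _, types = self._setup(bcv=0.4)
        block = x[:, types == 1]
        mu = block.mean(axis=1)
        ratio = block.var(axis=1, ddof=1)[mu > 1] / mu[mu > 1]
        assert ratio.mean() > 1.5  # var = mu + bcv * mu^2 with mu up to ~35

    def test_dropout_adds_zeros(self):
        rng = np.random.default_rng(10)
        means = np.ones((1, 300)) * 5
        lib = np.full(200, 1500.0)
        types = np.ones(200, dtype=int)
        dense = simulate_counts(means, lib, types, 0.0, rng).toarray()
        rng = np.random.default_rng(10)
        dropped = simulate_counts(means, lib, types, 0.0, rng,
                                  dropout_midpoint=2.0, dropout_shape=2.0).toarray()
        assert (dropped == 0).mean() > (dense == 0).mean()


class TestGenerateDataset:
    def test_structure(self, small_dataset, small_params):
        ds = small_dataset
        assert ds.counts.shape == (500, 200)
        assert ds.counts.min() >= 0
        sizes = np.bincount(ds.true_labels)[1:]
        np.testing.assert_array_equal(sizes, allocate_cells(small_params.proportions, 200))
        all_markers = np.concatenate([ds.marker_map[k] for k in sorted(ds.marker_map)])
        assert len(all_markers) == len(set(all_markers)) == 5 * 20

    def test_bit_identical_repeat(self, small_params, small_dataset):
        again = generate_dataset(small_params)
        assert (again.counts != small_dataset.counts).nnz == 0
        np.testing.assert_array_equal(again.true_labels, small_dataset.true_labels)

    def test_seed_changes_output(self, small_params, small_dataset):
        from dataclasses import replace
        other = generate_dataset(replace(small_params, seed=8))
        assert (other.counts != small_dataset.counts).nnz > 0

    def test_substreams_are_stable(self):
        a = _substreams(42)
        b = _substreams(42)
        for name in a:
            assert a[name].random() == b[name].random()

    def test_null_fold_change_is_no_injection(self):
        """fC = 1 untruncated: marker group-vs-rest mean ratios are located
        at 1, indistinguishable from non-marker genes (Welch test)."""
        pvals = []
        for seed in (21, 22, 23):
            p = SimulationParams(n_cells=500, proportions=(0.2,) * 5, n_genes=1000,
                                 n_markers_per_type=40, fold_change=1.0,
                                 truncate_fc_below_one=False, bcv_dispersion=0.0,
                                 seed=seed)
            ds = generate_dataset(p)
            x = ds.counts.toarray() / ds.counts.sum(axis=0).A1  # libsize-normalize
            in1 = ds.true_labels == 1
            ratio = (x[:, in1].mean(axis=1) + 1e-9) / (x[:, ~in1].mean(axis=1) + 1e-9)
            markers = ds.marker_map[1]
            rest = np.setdiff1d(np.arange(1000), np.concatenate(list(ds.marker_map.values())))
            pvals.append(stats.ttest_ind(ratio[markers], ratio[rest], equal_var=False).pvalue)
        assert all(p > 0.01 for p in pvals)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"proportions": (0.5, 0.6)},          # does not sum to 1
        {"proportions": (1.0,)},              # single type
        {"proportions": (0.0, 1.0)},          # zero proportion
        {"fold_change": 0.5},
        {"n_cells": 3},                       # fewer cells than types
        {"n_markers_per_type": 3000},         # markers exceed genes
        {"bcv_dispersion": -0.1},
        {"dropout_midpoint": 1.0},            # shape missing
        {"seed": -1},
    ])
    def test_invalid_params_rejected(self, kwargs):
        base = dict(n_cells=100, n_genes=1000, n_markers_per_type=10)
        base.update(kwargs)
        with pytest.raises(SimulationError):
            SimulationParams(**base)

    def test_roundtrip_dict(self):
        p = SimulationParams(n_cells=100, seed=3)
        assert SimulationParams.from_dict(p.to_dict()) == p

    def test_unknown_field_rejected(self):
        with pytest.raises(SimulationError, match="unknown"):
            SimulationParams.from_dict({"n_cells": 100, "bogus": 1})
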