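"""Unit tests for the greedy deletion/addition phases and the masking loop."""

import numpy as np
import pytest

import deltatrimax as dt
from deltatrimax.algorithm import MSR_TOL

from .conftest import make_tensor
from .oracles import oracle_stats


def block_tensor(dims=(12, 5, 4), seed=0, sigma=0.0):
    model = dt.random_shifting_model(dims, sigma=sigma, seed=seed)
    return make_tensor(dt.make_block(model, dims, seed=seed + 1))


class TestImputeMissing:
    def test_no_missing_returns_input_unchanged(self, rng):
        tensor = make_tensor(rng.normal(size=(4, 3, 3)))
        assert dt.impute_missing(tensor, seed=0) is tensor

    def test_deterministic_fill_within_range(self, rng):
        values = rng.uniform(-2, 7, size=(5, 4, 3))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 0, 0] = mask[2, 1, 2] = True
        values_masked = values.copy()
        values_masked[mask] = np.nan
        tensor = make_tensor(values_masked, mask=mask)
        a = dt.impute_missing(tensor, seed=42)
        b = dt.impute_missing(tensor, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        observed = values_masked[~mask]
        assert np.all(a.values[mask] >= observed.min())
        assert np.all(a.values[mask] <= observed.max())
        np.testing.assert_array_equal(a.values[~mask], values_masked[~mask])

    def test_fill_range_property(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            values = rng.uniform(-50, 50, size=(4, 3, 3))
            mask = rng.random(size=values.shape) < 0.3
            if mask.all() or not mask.any():
                continue
            masked = values.copy()
            masked[mask] = np.inf
            tensor = make_tensor(masked, mask=mask)
            filled = dt.impute_missing(tensor, seed=trial)
            obs = values[~mask]
            assert filled.values.min() >= obs.min() - 1e-12
            assert filled.values.max() <= obs.max() + 1e-12

    def test_all_missing_rejected(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        tensor = make_tensor(np.full((2, 2, 2), np.nan), mask=mask)
        with pytest.raises(dt.DataError):
            dt.impute_missing(tensor, seed=0)


class TestMultipleNodeDeletion:
    def test_already_coherent_returned_unchanged(self):
        tensor = block_tensor()
        params = dt.TrimaxParams(delta=1.0, lam=1.2, deletion_guard=1)
        start = tensor.full_tricluster()
        out = dt.multiple_node_deletion(tensor, start, params)
        assert out.same_indices(start)

    def test_noise_genes_batch_deleted_with_valid_trace(self, rng):
        dims = (100, 5, 5)
        model = dt.random_shifting_model(dims, seed=5)
        values = dt.make_block(model, dims)
        noise_genes = rng.choice(100, 20, replace=False)
        values[noise_genes] = rng.uniform(-30, 30, size=(20, 5, 5))
        tensor = make_tensor(values)
        params = dt.TrimaxParams(delta=1e-6, lam=1.2, deletion_guard=4)
        trace = []
        out = dt.multiple_node_deletion(tensor, tensor.full_tricluster(),
                                        params, trace=trace)
        assert set(out.gene_idx) == set(range(100)) - set(noise_genes.tolist())
        # every traced deletion satisfied mu > lam * S at its round
        for event in trace:
            if event["phase"] == "multiple":
                assert all(mu > event["threshold"] for mu in event["mu"])

    def test_guard_protects_small_modes(self, rng):
        values = rng.uniform(-10, 10, size=(80, 3, 3))
        tensor = make_tensor(values)
        params = dt.TrimaxParams(delta=1e-9, lam=1.1, deletion_guard=50)
        out = dt.multiple_node_deletion(tensor, tensor.full_tricluster(),
                                        params)
        assert out.sample_idx == tuple(range(3))
        assert out.time_idx == tuple(range(3))

    def test_never_shrinks_below_floor(self, rng):
        values = rng.uniform(-10, 10, size=(30, 4, 4))
        tensor = make_tensor(values)
        params = dt.TrimaxParams(delta=0.0, lam=1.0001, deletion_guard=1,
                                 min_genes=5, min_samples=2, min_times=2)
        out = dt.multiple_node_deletion(tensor, tensor.full_tricluster(),
                                        params)
        assert len(out.gene_idx) >= 5
        assert len(out.sample_idx) >= 2
        assert len(out.time_idx) >= 2


class TestSingleNodeDeletion:
    def test_already_coherent_returned_unchanged(self):
        tensor = block_tensor()
        start = tensor.full_tricluster()
        out = dt.single_node_deletion(tensor, start,
                                      dt.TrimaxParams(delta=1.0))
        assert out.same_indices(start)

    def test_noise_gene_deleted_first_and_only(self, rng):
        dims = (10, 4, 4)
        model = dt.random_shifting_model(dims, seed=9)
        values = dt.make_block(model, dims)
        values[6] = rng.uniform(-20, 20, size=(4, 4))
        tensor = make_tensor(values)
        # the noise row must hold the argmax mu over all three modes
        expected = oracle_stats(values)
        assert expected["mu_gene"][6] == max(
            expected["mu_gene"].max(), expected["mu_sample"].max(),
            expected["mu_time"].max())
        trace = []
        out = dt.single_node_deletion(tensor, tensor.full_tricluster(),
                                      dt.TrimaxParams(delta=1e-6),
                                      trace=trace)
        assert [e["deleted"] for e in trace] == [6]
        assert set(out.gene_idx) == set(range(10)) - {6}

    def test_termination_bound_and_floor_flagging(self, rng):
        values = rng.uniform(-10, 10, size=(6, 4, 3))
        tensor = make_tensor(values)
        trace = []
        out = dt.single_node_deletion(tensor, tensor.full_tricluster(),
                                      dt.TrimaxParams(delta=0.0),
                                      trace=trace)
        assert len(trace) <= 6 + 4 + 3 - 3
        assert min(out.shape) >= 1


class TestNodeAddition:
    def test_recovers_full_block_from_core(self):
        tensor = block_tensor(dims=(15, 6, 5))
        core = dt.Tricluster(tuple(range(5)), (0, 1, 2), (0, 1))
        out = dt.node_addition(tensor, core)
        assert out.same_indices(tensor.full_tricluster())
        assert out.msr == pytest.approx(0.0, abs=1e-12)

    def test_maximal_core_unchanged(self, rng):
        dims = (10, 4, 4)
        values = dt.make_block(dt.random_shifting_model(dims, seed=2), dims)
        values[9] = rng.uniform(-40, 40, size=(4, 4))
        tensor = make_tensor(values)
        core = dt.Tricluster(tuple(range(9)), tuple(range(4)),
                             tuple(range(4)))
        out = dt.node_addition(tensor, core)
        assert out.gene_idx == core.gene_idx

    @pytest.mark.parametrize("seed", range(10))
    def test_msr_never_increases_and_core_contained(self, seed):
        rng = np.random.default_rng(seed)
        tensor = make_tensor(rng.uniform(-10, 10, size=(20, 8, 6)))
        core = dt.Tricluster(
            tuple(np.sort(rng.choice(20, 6, replace=False)).tolist()),
            tuple(np.sort(rng.choice(8, 3, replace=False)).tolist()),
            tuple(np.sort(rng.choice(6, 3, replace=False)).tolist()))
        before = dt.msr(tensor, core)
        out = dt.node_addition(tensor, core)
        assert out.msr <= before + MSR_TOL
        assert set(core.gene_idx) <= set(out.gene_idx)
        assert set(core.sample_idx) <= set(out.sample_idx)
        assert set(core.time_idx) <= set(out.time_idx)


class TestDeltaTrimax:
    def test_single_perfect_block_found_whole(self):
        tensor = block_tensor(dims=(20, 5, 4))
        params = dt.TrimaxParams(delta=1e-6, lam=1.2, deletion_guard=1,
                                 max_triclusters=5)
        result = dt.delta_trimax(tensor, params)
        assert result.triclusters
        first = result.triclusters[0]
        assert first.same_indices(tensor.full_tricluster())
        assert first.msr == pytest.approx(0.0, abs=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(dt.ParameterError):
            dt.TrimaxParams(delta=-0.1)
        with pytest.raises(dt.ParameterError):
            dt.TrimaxParams(delta=0.1, lam=1.0)

    def test_bit_identical_reruns(self, rng):
        values = rng.uniform(-10, 10, size=(40, 6, 5))
        values[:10, :3, :3] = dt.make_block(
            dt.random_shifting_model((10, 3, 3), seed=0), (10, 3, 3))
        tensor = make_tensor(values)
        params = dt.TrimaxParams(delta=0.05, lam=1.2, deletion_guard=5,
                                 max_triclusters=8, seed=77)
        a = dt.delta_trimax(tensor, params)
        b = dt.delta_trimax(tensor, params)
        assert len(a.triclusters) == len(b.triclusters)
        for x, y in zip(a.triclusters, b.triclusters):
            assert x.same_indices(y)
            assert x.msr == y.msr

    def test_all_reported_triclusters_meet_delta_and_are_distinct(self, rng):
        values = rng.uniform(-10, 10, size=(60, 7, 6))
        tensor = make_tensor(values)
        params = dt.TrimaxParams(delta=0.5, lam=1.2, deletion_guard=5,
                                 max_triclusters=10, seed=3)
        result = dt.delta_trimax(tensor, params)
        boxes = set()
        found = [d for d in result.iterations if "data" in d]
        assert len(found) == len(result.triclusters)
        for tc, diag in zip(result.triclusters, found):
            expected = oracle_stats(diag["data"])
            assert expected["msr"] <= params.delta + 1e-9
            assert tc.msr == pytest.approx(expected["msr"], abs=1e-9)
            boxes.add((tc.gene_idx, tc.sample_idx, tc.time_idx))
        assert len(boxes) == len(result.triclusters)


class TestEstimateDelta:
    def test_constant_tensor_gives_zero(self):
        tensor = make_tensor(np.full((30, 4, 8), 2.5))
        assert dt.estimate_delta(tensor, k_genes=3, k_times=2,
                                 seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_trial_lands_inside_dominant_block(self):
        # a strong shifting block over most of the tensor: gene K-means
        # isolates its genes, so some probed cell lies inside the block
        rng = np.random.default_rng(4)
        values = rng.normal(0, 0.05, size=(40, 4, 8))
        block = dt.make_block(
            dt.random_shifting_model((30, 4, 6), seed=8), (30, 4, 6))
        values[:30, :, :6] = block
        tensor = make_tensor(values)
        est = dt.estimate_delta(tensor, k_genes=4, k_times=2, seed=1)
        assert est < 1e-9

    def test_minimum_non_increasing_in_trials(self, rng):
        tensor = make_tensor(rng.uniform(-10, 10, size=(30, 4, 8)))
        values = [dt.estimate_delta(tensor, k_genes=5, k_times=2,
                                    trials=n, seed=9)
                  for n in (1, 10, 50, 200)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        exhaustive = dt.estimate_delta(tensor, k_genes=5, k_times=2, seed=9)
        assert exhaustive <= min(values)

    def test_parameter_validation(self, rng):
        tensor = make_tensor(rng.normal(size=(5, 3, 4)))
        with pytest.raises(dt.ParameterError):
            dt.estimate_delta(tensor, k_genes=50, k_times=2)
        with pytest.raises(dt.ParameterError):
            dt.estimate_delta(tensor, k_genes=2, k_times=40)
        with pytest.raises(dt.ParameterError):
            dt.estimate_delta(tensor, k_genes=2, k_times=2, trials=0)
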