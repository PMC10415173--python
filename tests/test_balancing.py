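import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from _oracles import dense_grid_balance, identity_permutation_seed
from kbalance.balancing import (
    BalancerConfig,
    GridState,
    balance,
    cell_of,
    summarize_diagnostics,
)


class TestCellOf:
    @pytest.mark.parametrize("value,expected", [(0.0, 0), (0.999, 9), (1.0, 9), (0.05, 0)])
    def test_equidistant_bins_with_closed_last_bin(self, value, expected):
        assert cell_of([value], G=10) == (expected,)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cell_of([1.2], G=10)
        with pytest.raises(ValueError):
            cell_of([-0.1], G=10)

    def test_multidimensional_key(self):
        assert cell_of([0.0, 0.55, 1.0], G=4) == (0, 2, 3)


class TestGridState:
    def test_running_maximum_matches_true_maximum(self, rng):
        grid = GridState()
        keys = [bytes([rng.integers(0, 5)]) for _ in range(200)]
        for k in keys:
            grid.add(k)
        assert grid.c_max == max(grid.cell_counts.values())
        assert all(c >= 1 for c in grid.cell_counts.values())


class TestAcceptRejectContract:
    def test_sparse_cell_accepted_full_cell_rejected_at_cmax_5(self):
        """With C_max=5: a candidate in a 1-count cell is accepted, one in
        a 5-count cell is rejected."""
        # identity stream: 5 init samples fill cell 0 (C_max=5), then one
        # candidate in a 1-count cell and one in the 5-count cell
        seed = identity_permutation_seed(8)
        X = np.array([[0.05]] * 5 + [[0.15]] + [[0.16]] + [[0.05]])
        cfg = BalancerConfig(G=10, N=8, init_fraction=5 / 8, escape_threshold=99, seed=seed)
        res = balance(X, cfg)
        accepted = set(res.accepted_indices)
        assert {0, 1, 2, 3, 4} <= accepted       # init phase
        assert 5 in accepted                     # cell (1): 0 < C_max=5
        assert 6 in accepted                     # cell (1): 1 < C_max=5
        assert 7 not in accepted                 # cell (0): 5 == C_max
        assert res.diagnostics.rejections == 1

    def test_escape_hatch_forces_acceptance_after_threshold(self):
        n = 30
        seed = identity_permutation_seed(2)  # any seed; all samples share a cell
        X = np.full((n, 1), 0.05)
        cfg = BalancerConfig(G=10, N=n, init_fraction=0.2, escape_threshold=10, seed=seed)
        res = balance(X, cfg)
        n_init = int(0.2 * n)
        # after init every candidate is at C_max; only escapes get through
        assert res.diagnostics.escape_accepts == len(res.accepted_indices) - n_init
        assert res.diagnostics.escape_accepts == (n - n_init) // 11


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_grid_reference(self, seed):
        """Sparse streaming balancer == dense G^4 array replay, index for index."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(200, 501))
        X = rng.dirichlet([1.0, 0.8, 0.6, 0.4], size=n)
        cfg = BalancerConfig(G=4, N=100, seed=seed)
        res = balance(X, cfg)
        expected = dense_grid_balance(X, G=4, N=100, init_fraction=cfg.init_fraction,
                                      escape_threshold=cfg.escape_threshold, seed=seed)
        assert list(res.accepted_indices) == expected


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_pure_undersampling_budget_and_sparsity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((300, 5))
        res = balance(X, BalancerConfig(G=6, N=120, seed=seed))
        idx = res.accepted_indices
        assert len(idx) <= 120
        assert len(set(idx.tolist())) == len(idx)
        assert idx.min() >= 0 and idx.max() < 300
        for before, after in res.diagnostics.cells.values():
            assert 0 <= after <= before
        assert len(res.diagnostics.cells) <= 300  # occupied cells, never G^D

    def test_deterministic_under_seed(self, rng):
        X = rng.random((200, 3))
        r1 = balance(X, BalancerConfig(G=5, N=80, seed=11))
        r2 = balance(X, BalancerConfig(G=5, N=80, seed=11))
        np.testing.assert_array_equal(r1.accepted_indices, r2.accepted_indices)
        r3 = balance(X, BalancerConfig(G=5, N=80, seed=12))
        assert not np.array_equal(r1.accepted_indices, r3.accepted_indices)

    def test_distinct_cells_mean_no_rejections(self):
        # every sample in its own cell: C_g is always 0 <= running max
        X = (np.arange(20)[:, None] + 0.5) / 20.0
        res = balance(X, BalancerConfig(G=20, N=10, seed=3))
        assert res.diagnostics.rejections == 0
        expected = np.random.default_rng(3).permutation(20)[:10]
        np.testing.assert_array_equal(res.accepted_indices, expected)

    def test_budget_reached_exactly_when_no_rejections(self, rng):
        X = rng.random((50, 2))
        res = balance(X, BalancerConfig(G=1, N=50, seed=0))  # one big cell: all phase-1/escape
        assert len(res.accepted_indices) <= 50

    def test_overbudget_warns(self, rng):
        X = rng.random((10, 2))
        with pytest.warns(UserWarning, match="budget"):
            balance(X, BalancerConfig(G=4, N=50, seed=0))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            balance(np.empty((0, 4)), BalancerConfig(G=4, N=10, seed=0))

    @pytest.mark.parametrize("rep", range(10))
    def test_flattening_on_two_blob_data(self, rep):
        """Max/median occupied-cell count ratio must not grow under balancing."""
        rng = np.random.default_rng(rep)
        blob = rng.dirichlet([200, 5, 5, 5], size=270)   # 90% of mass in one region
        background = rng.dirichlet([1, 1, 1, 1], size=30)
        X = np.vstack([blob, background])
        res = balance(X, BalancerConfig(G=4, N=150, seed=rep))
        before = np.array([b for b, _ in res.diagnostics.cells.values()])
        after = np.array([a for _, a in res.diagnostics.cells.values() if a > 0])
        ratio_before = before.max() / np.median(before)
        ratio_after = after.max() / np.median(after)
        assert ratio_after <= ratio_before


class TestStratifiedInit:
    def test_init_covers_all_classes(self, rng):
        X = rng.random((120, 3))
        labels = np.repeat(["a", "b", "c", "d"], 30)
        cfg = BalancerConfig(G=5, N=40, seed=0, stratified_init=True)
        res = balance(X, cfg, labels=labels)
        n_init = int(0.3 * 40)
        init_labels = {labels[i] for i in res.accepted_indices[:n_init]}
        assert init_labels == {"a", "b", "c", "d"}

    def test_requires_labels(self, rng):
        X = rng.random((20, 2))
        with pytest.raises(ValueError, match="labels"):
            balance(X, BalancerConfig(G=4, N=10, seed=0, stratified_init=True))


class TestDiagnostics:
    def test_cbar_and_delta_arithmetic(self):
        rng = np.random.default_rng(5)
        X = np.vstack([np.full((10, 1), 0.05), np.full((3, 1), 0.55)])
        res = balance(X, BalancerConfig(G=10, N=7, seed=5))
        df = summarize_diagnostics(res)
        for _, row in df.iterrows():
            assert row["c_bar"] == (row["c_before"] + row["c_after"]) / 2
            assert row["delta_c"] == row["c_after"] - row["c_before"]
            assert row["delta_c"] <= 0
        assert df["c_bar"].is_monotonic_decreasing

    def test_untouched_cell_has_zero_delta(self):
        X = np.vstack([np.full((7, 1), 0.05), [[0.55]]])
        res = balance(X, BalancerConfig(G=10, N=6, seed=identity_permutation_seed(8)))
        df = summarize_diagnostics(res).set_index("cell_id")
        assert df.loc["5", "delta_c"] == 0  # single-sample cell kept intact

    def test_denser_cells_lose_more_samples(self):
        """Spearman(C_before, |delta C|) > 0 on blob + uniform background."""
        rng = np.random.default_rng(77)
        blob = rng.dirichlet([300, 8, 8, 8], size=400)
        background = rng.dirichlet([1, 1, 1, 1], size=100)
        X = np.vstack([blob, background])
        res = balance(X, BalancerConfig(G=5, N=200, seed=77))
        df = summarize_diagnostics(res)
        rho = spearmanr(df["c_before"], -df["delta_c"]).statistic
        assert rho > 0


def test_config_validation():
    with pytest.raises(ValueError):
        BalancerConfig(G=0, N=10)
    with pytest.raises(ValueError):
        BalancerConfig(G=5, N=0)
    with pytest.raises(ValueError):
        BalancerConfig(G=5, N=10, init_fraction=1.0)
    with pytest.raises(ValueError):
        BalancerConfig(G=5, N=10, escape_threshold=0)
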