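"""The optimization loop: initialization, iteration, stopping, reporting."""

import numpy as np
import pytest

import poolbo as pb
from poolbo.explorer import ExplorerError, resolve_count


class TestResolveCount:
    @pytest.mark.parametrize(
        ("frac", "pool_size", "expected"),
        [
            (0.01, 10_560, 106),
            (0.01, 50_240, 503),
            (0.01, 2_141_514, 21_416),
            (0.001, 50, 1),  # never below one molecule
        ],
    )
    def test_fraction_to_count(self, frac, pool_size, expected):
        assert resolve_count(frac, pool_size) == expected

    def test_absolute_counts_pass_through(self):
        assert resolve_count(25, 1000) == 25

    def test_nonpositive_rejected(self):
        with pytest.raises(ExplorerError):
            resolve_count(0, 100)


class TestInitialize:
    def test_seeded_initialization_is_deterministic(self, small_fixture):
        cfg = pb.ExplorerConfig(init_size=10, seed=5)
        s1 = pb.initialize(small_fixture.pool, small_fixture.lookup, cfg)
        s2 = pb.initialize(small_fixture.pool, small_fixture.lookup, cfg)
        assert s1.tested == s2.tested

    def test_init_count_and_log(self, small_fixture):
        cfg = pb.ExplorerConfig(init_size=0.05, seed=1)
        state = pb.initialize(small_fixture.pool, small_fixture.lookup, cfg)
        assert state.n_tested == 15  # ceil(0.05 * 300)
        assert len(state.topk_history) == 1
        assert state.log[0]["iteration"] == 0

    def test_oversized_init_is_fatal(self, small_fixture):
        cfg = pb.ExplorerConfig(init_size=10_000, seed=1)
        with pytest.raises(ExplorerError):
            pb.initialize(small_fixture.pool, small_fixture.lookup, cfg)


class TestRunIteration:
    def test_oracle_greedy_batch_is_true_top_b(self, small_fixture):
        """With a perfect surrogate and greedy acquisition, one iteration
        must acquire exactly the b best untested molecules by true score."""
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=20, batch_size=10, seed=3)
        state = pb.initialize(fx.pool, fx.lookup, cfg)
        tested_before = set(state.tested)
        pb.run_iteration(state, fx.pool, fx.lookup, cfg, surrogate=pb.OracleSurrogate(fx))
        acquired = state.tested - tested_before
        order = np.argsort(-fx.true_objective, kind="stable")
        expected = [int(i) for i in order if int(i) not in tested_before][:10]
        assert acquired == set(expected)

    def test_budget_accounting_six_percent(self, small_fixture):
        """1% init + five 1% batches tests 6% of the pool."""
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=0.01, batch_size=0.01, max_iterations=5,
                                seed=0)
        rep = pb.run(fx.pool, fx.lookup, cfg)
        per_batch = resolve_count(0.01, fx.pool.size)
        assert rep.n_tested == 6 * per_batch

    def test_tested_grows_by_batch_and_never_repeats(self, small_fixture):
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=10, batch_size=7, seed=2)
        state = pb.initialize(fx.pool, fx.lookup, cfg)
        oracle = pb.OracleSurrogate(fx)
        sizes = [state.n_tested]
        for _ in range(3):
            pb.run_iteration(state, fx.pool, fx.lookup, cfg, surrogate=oracle)
            sizes.append(state.n_tested)
        assert sizes == [10, 17, 24, 31]  # strict growth, exact batch size

    def test_ucb_with_zero_variance_oracle_matches_greedy(self, small_fixture):
        fx = small_fixture
        batches = {}
        for metric in ("greedy", "ucb"):
            cfg = pb.ExplorerConfig(
                init_size=20, batch_size=10, seed=3,
                acquisition=pb.AcquisitionConfig(metric=metric),
            )
            state = pb.initialize(fx.pool, fx.lookup, cfg)
            before = set(state.tested)
            pb.run_iteration(state, fx.pool, fx.lookup, cfg,
                             surrogate=pb.OracleSurrogate(fx))
            batches[metric] = state.tested - before
        assert batches["greedy"] == batches["ucb"]


class TestConvergence:
    def test_flat_history_converges(self):
        assert pb.check_convergence([10, 10, 10], current=10)

    def test_ten_percent_jump_does_not_converge(self):
        assert not pb.check_convergence([10, 10, 10], current=11)

    def test_hand_computed_fractional_difference(self):
        # |8.32 - mean(8.0, 8.2, 8.3)| / 8.1667 = 0.0188 >= 0.01
        assert not pb.check_convergence([8.0, 8.2, 8.3], current=8.32)
        # but a tighter threshold window passes
        assert pb.check_convergence([8.0, 8.2, 8.3], current=8.32, threshold=0.02)

    def test_too_short_history_never_converges(self):
        assert not pb.check_convergence([10, 10], current=10)
        assert not pb.check_convergence([])

    def test_last_entry_used_as_current_when_omitted(self):
        assert pb.check_convergence([10, 10, 10, 10])
        assert not pb.check_convergence([10, 10, 10, 11])

    def test_zero_rolling_mean_uses_absolute_difference(self):
        assert pb.check_convergence([0.0, 0.0, 0.0], current=0.005)
        assert not pb.check_convergence([0.0, 0.0, 0.0], current=0.5)

    def test_signed_mode_treats_drops_as_converged(self):
        # a drop below the rolling mean is "no improvement" under the signed
        # rule but a 10% change under the absolute rule
        assert pb.check_convergence([10, 10, 10], current=9.0, signed=True)
        assert not pb.check_convergence([10, 10, 10], current=9.0, signed=False)


class TestRun:
    def test_zero_iterations_is_the_random_baseline(self, small_fixture):
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=30, max_iterations=0, seed=9)
        rep = pb.run(fx.pool, fx.lookup, cfg)
        assert rep.n_tested == 30
        assert all(r["iteration_acquired"] == 0 for r in rep.explored)

    def test_single_iteration_mode_budget(self, small_fixture):
        """One random batch then one model-guided batch: a + b tested."""
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=20, batch_size=30, max_iterations=1, seed=4)
        rep = pb.run(fx.pool, fx.lookup, cfg, surrogate=pb.OracleSurrogate(fx))
        assert rep.n_tested == 50

    def test_fixed_seed_reports_identical(self, small_fixture):
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=10, batch_size=10, max_iterations=3, seed=21)
        r1 = pb.run(fx.pool, fx.lookup, cfg)
        r2 = pb.run(fx.pool, fx.lookup, cfg)
        assert r1.explored == r2.explored
        assert r1.log == r2.log

    def test_topk_history_nondecreasing(self, small_fixture):
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=10, batch_size=10, max_iterations=4,
                                k=10, seed=13)
        rep = pb.run(fx.pool, fx.lookup, cfg)
        history = [row["top_k_average"] for row in rep.log]
        assert all(b >= a - 1e-12 for a, b in zip(history, history[1:]))

    def test_oracle_identifies_full_top_k_at_budget_k_plus_init(self, small_fixture):
        """Perfect-model limit: greedy acquisition of k molecules after any
        random initialization covers the entire true top-k."""
        fx = small_fixture
        k = 20
        cfg = pb.ExplorerConfig(init_size=20, batch_size=k, max_iterations=1,
                                k=k, seed=6)
        rep = pb.run(fx.pool, fx.lookup, cfg, surrogate=pb.OracleSurrogate(fx))
        truth = pb.GroundTruth.from_lookup(fx.lookup)
        found = {r["smiles"]: r["objective"] for r in rep.explored}
        assert pb.top_k_smiles_fraction(found, truth, k) == 1.0

    def test_pool_exhaustion_terminates_cleanly(self):
        fx = pb.generate_pool(pb.LandscapeSpec(n_molecules=30), seed=7)
        cfg = pb.ExplorerConfig(init_size=10, batch_size=15, max_iterations=5, seed=1)
        with pytest.warns(UserWarning, match="truncat"):
            rep = pb.run(fx.pool, fx.lookup, cfg, surrogate=pb.OracleSurrogate(fx))
        assert rep.n_tested == 30

    def test_missing_scores_consume_budget_but_not_training(self):
        """Failed evaluations count as tested yet never reach the training
        set or the explored report."""
        fx = pb.generate_pool(
            pb.LandscapeSpec(n_molecules=200, missing_fraction=0.3), seed=31
        )
        cfg = pb.ExplorerConfig(init_size=40, batch_size=20, max_iterations=2, seed=8)
        state = pb.initialize(fx.pool, fx.lookup, cfg)
        assert state.n_tested == 40
        assert len(state.scores) < 40  # some of the 40 must be missing
        data = state.training_set(fx.pool)
        assert len(data) == len(state.scores)
        assert np.all(np.isfinite(data.targets))
        rep = pb.run(fx.pool, fx.lookup, cfg)
        assert rep.n_tested == 80
        assert len(rep.explored) < rep.n_tested
        missing_smiles = {
            smi for smi, raw in zip(fx.pool.smiles, fx.raw_scores) if raw is None
        }
        assert not missing_smiles & set(rep.found_smiles)

    def test_random_baseline_tested_set_uniform(self, small_fixture):
        """With metric=random the final tested set should include each
        candidate equally often across seeds."""
        fx = small_fixture
        counts = np.zeros(fx.pool.size)
        reps = 150
        for s in range(reps):
            cfg = pb.ExplorerConfig(
                init_size=10, batch_size=10, max_iterations=2, seed=s,
                acquisition=pb.AcquisitionConfig(metric="random"),
            )
            rep = pb.run(fx.pool, fx.lookup, cfg)
            for smi in rep.found_smiles:
                counts[fx.pool.index_of(smi)] += 1
        p = 30 / fx.pool.size
        se = np.sqrt(p * (1 - p) / reps)
        assert np.all(np.abs(counts / reps - p) <= 4 * se)

    def test_report_write_round_trip(self, tmp_path, small_fixture):
        fx = small_fixture
        cfg = pb.ExplorerConfig(init_size=10, batch_size=10, max_iterations=1, seed=2)
        rep = pb.run(fx.pool, fx.lookup, cfg)
        rep.write(tmp_path)
        assert (tmp_path / "explored.csv").exists()
        assert (tmp_path / "log.csv").exists()
        assert (tmp_path / "config.yaml").exists()

    def test_convergence_stopping_halts_run(self, small_fixture):
        """An oracle-driven greedy run plateaus once the top-k stops
        improving, so converged stopping must end before the cap."""
        fx = small_fixture
        cfg = pb.ExplorerConfig(
            init_size=50, batch_size=30, max_iterations=8, k=5,
            stopping="converged", seed=12,
        )
        rep = pb.run(fx.pool, fx.lookup, cfg, surrogate=pb.OracleSurrogate(fx))
        assert rep.converged
        assert rep.log[-1]["iteration"] < 8
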