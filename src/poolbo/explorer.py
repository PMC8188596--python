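"""Batched Bayesian-optimization loop over a molecular pool.

The explorer evaluates a random initial batch, then repeats: retrain the
surrogate on all scored acquisitions, predict over the whole pool, acquire
the top-b untested candidates by acquisition utility, and evaluate them
against the objective — until a fixed iteration budget is spent, the pool is
exhausted, or the observed top-k average stops improving (the convergence
criterion).  Candidates whose evaluation returns MISSING (e.g. molecules
that failed to dock) consume budget but never enter the training set.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import acquisition as acq
from . import surrogates as sg
from .objective import MISSING, LookupTable, evaluate
from .pool import MoleculePool


class ExplorerError(ValueError):
    """Raised for invalid explorer configuration or state."""


def resolve_count(size: float | int, pool_size: int) -> int:
    """Convert a batch/init size to a molecule count.

    Floats in (0, 1] are fractions of the pool, rounded up (so 1% of a
    10,560-molecule pool is 106 molecules); values >= 1 are absolute counts.
    Always at least 1.
    """
    if size <= 0:
        raise ExplorerError(f"size must be positive, got {size}")
    if isinstance(size, float) and size <= 1.0:
        return max(1, math.ceil(size * pool_size))
    return max(1, int(size))


@dataclass(frozen=True)
class ExplorerConfig:
    """Run configuration for the optimization loop.

    ``init_size`` and ``batch_size`` accept either a fraction of the pool
    (float in (0, 1]) or an absolute count (int).  ``max_iterations`` counts
    exploration batches after the random initialization (default 5, i.e.
    1% init + five 1% batches explores 6% of the pool).  ``k`` is the size
    of the tracked top-k.  With ``stopping="converged"`` the loop also stops
    once the fractional change of the top-k average relative to the rolling
    mean of the previous ``convergence_window`` iterations drops below
    ``convergence_threshold``.
    """

    init_size: float | int = 0.01
    batch_size: float | int = 0.01
    max_iterations: int = 5
    k: int = 100
    stopping: str = "fixed"
    convergence_threshold: float = 0.01
    convergence_window: int = 3
    convergence_signed: bool = False
    surrogate: sg.SurrogateSpec = field(default_factory=sg.SurrogateSpec)
    acquisition: acq.AcquisitionConfig = field(default_factory=acq.AcquisitionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stopping not in ("fixed", "converged"):
            raise ExplorerError(f"unknown stopping rule {self.stopping!r}")
        if self.convergence_window < 1:
            raise ExplorerError("convergence_window must be >= 1")
        if self.convergence_threshold <= 0:
            raise ExplorerError("convergence_threshold must be > 0")
        if self.max_iterations < 0:
            raise ExplorerError("max_iterations must be >= 0")
        if self.k < 1:
            raise ExplorerError("k must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["surrogate"] = dataclasses.asdict(self.surrogate)
        d["acquisition"] = dataclasses.asdict(self.acquisition)
        return d


@dataclass
class ExplorerState:
    """Mutable run state: the acquired dataset and its bookkeeping.

    ``scores`` maps pool index -> objective value (maximization convention)
    for successful evaluations only; ``tested`` holds every acquired index
    including MISSING evaluations; ``acquired_at`` records the iteration at
    which each index was acquired (0 = initialization).
    """

    scores: dict[int, float] = field(default_factory=dict)
    tested: set[int] = field(default_factory=set)
    acquired_at: dict[int, int] = field(default_factory=dict)
    iteration: int = 0
    topk_history: list[float] = field(default_factory=list)
    log: list[dict[str, Any]] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    model: Any = None

    @property
    def n_tested(self) -> int:
        return len(self.tested)

    @property
    def f_star(self) -> float:
        """Incumbent: the best objective value observed so far."""
        if not self.scores:
            raise ExplorerError("no scored acquisitions yet")
        return max(self.scores.values())

    def top_k_average(self, k: int) -> float:
        """Mean of the k best observed objective values (all, if fewer)."""
        vals = sorted(self.scores.values(), reverse=True)[:k]
        if not vals:
            return float("nan")
        return float(np.mean(vals))

    def training_set(self, pool: MoleculePool) -> sg.TrainingSet:
        idx = np.fromiter(self.scores.keys(), dtype=int)
        y = np.fromiter(self.scores.values(), dtype=float)
        return sg.TrainingSet(pool.fingerprints[idx], y)


def _record_batch(
    state: ExplorerState,
    pool: MoleculePool,
    objective: LookupTable,
    indices: np.ndarray | list[int],
    iteration: int,
) -> None:
    batch_smiles = [pool.smiles[int(i)] for i in indices]
    results = evaluate(objective, batch_smiles)
    for i, res in zip(indices, results):
        i = int(i)
        state.tested.add(i)
        state.acquired_at[i] = iteration
        if res.objective_value is not MISSING:
            state.scores[i] = float(res.objective_value)


def _log_iteration(state: ExplorerState, k: int) -> None:
    topk = state.top_k_average(k)
    state.topk_history.append(topk)
    state.log.append(
        {
            "iteration": state.iteration,
            "n_tested": state.n_tested,
            "n_scored": len(state.scores),
            "top_k_average": topk,
            "best_score": max(state.scores.values()) if state.scores else float("nan"),
        }
    )


def initialize(
    pool: MoleculePool, objective: LookupTable, config: ExplorerConfig
) -> ExplorerState:
    """Evaluate a uniformly random initial batch and build the run state."""
    n_init = resolve_count(config.init_size, pool.size)
    if n_init > pool.size:
        raise ExplorerError(f"init size {n_init} exceeds pool size {pool.size}")
    rng = np.random.default_rng(config.seed)
    state = ExplorerState(rng=rng)
    init_idx = rng.choice(pool.size, size=n_init, replace=False)
    _record_batch(state, pool, objective, init_idx, iteration=0)
    _log_iteration(state, config.k)
    return state


def run_iteration(
    state: ExplorerState,
    pool: MoleculePool,
    objective: LookupTable,
    config: ExplorerConfig,
    surrogate: Any = None,
) -> ExplorerState:
    """One explore step: retrain, predict the pool, acquire, evaluate.

    ``surrogate`` optionally supplies a pre-built model object with
    ``fit(TrainingSet)`` and ``predict(fingerprints)`` (e.g. the oracle test
    double); otherwise one is created from ``config.surrogate``.
    """
    untested = np.setdiff1d(np.arange(pool.size), np.fromiter(state.tested, dtype=int))
    if untested.size == 0:
        raise ExplorerError("untested pool exhausted")
    state.iteration += 1

    if config.acquisition.metric == "random":
        # the random baseline shares the loop and budget accounting but its
        # utilities ignore predictions, so no surrogate is fit
        utilities = state.rng.uniform(size=pool.size)
        b = resolve_count(config.batch_size, pool.size)
        batch = acq.select_batch(utilities, state.tested, b, state.rng)
        _record_batch(state, pool, objective, batch, iteration=state.iteration)
        _log_iteration(state, config.k)
        return state

    data = state.training_set(pool)
    if surrogate is not None:
        state.model = surrogate.fit(data)
    else:
        model_seed = int(
            np.random.SeedSequence([config.seed, state.iteration]).generate_state(1)[0]
            % (2**31)
        )
        if config.surrogate.retrain_mode == "online" and state.model is not None:
            new_idx = [
                i
                for i, it in state.acquired_at.items()
                if it == state.iteration - 1 and i in state.scores
            ]
            if new_idx:
                arr = np.asarray(new_idx, dtype=int)
                data = sg.TrainingSet(
                    pool.fingerprints[arr],
                    np.asarray([state.scores[i] for i in new_idx]),
                )
            state.model = sg.train(
                config.surrogate, data, seed=model_seed, previous=state.model
            )
        else:
            state.model = sg.train(config.surrogate, data, seed=model_seed)

    pred = state.model.predict(pool.fingerprints)
    if config.acquisition.needs_variance and pred.variance is None:
        raise acq.AcquisitionError(
            f"metric {config.acquisition.metric!r} needs variance but the "
            f"surrogate provides none"
        )
    utilities = acq.utility(
        config.acquisition.metric,
        pred.mean,
        pred.variance,
        state.f_star,
        config.acquisition,
        state.rng,
    )
    b = resolve_count(config.batch_size, pool.size)
    batch = acq.select_batch(utilities, state.tested, b, state.rng)
    _record_batch(state, pool, objective, batch, iteration=state.iteration)
    _log_iteration(state, config.k)
    return state


def check_convergence(
    topk_history: list[float],
    threshold: float = 0.01,
    window: int = 3,
    *,
    current: float | None = None,
    signed: bool = False,
) -> bool:
    """Has the observed top-k average stopped improving?

    Compares the current top-k average against the rolling mean of the
    previous ``window`` iterations: converged when the fractional difference
    is below ``threshold``.  If ``current`` is omitted, the last entry of
    ``topk_history`` is the current value and the rest is the history.
    Returns False while fewer than ``window`` prior iterations exist.  A
    rolling mean of exactly zero falls back to an absolute-difference test.
    With ``signed=True`` the signed improvement (not its magnitude) is
    compared, so a drop below the rolling mean also counts as converged.
    """
    history = list(topk_history)
    if current is None:
        if not history:
            return False
        current = history[-1]
        history = history[:-1]
    if len(history) < window:
        return False
    roll = float(np.mean(history[-window:]))
    diff = current - roll
    if not signed:
        diff = abs(diff)
    if roll == 0.0:
        return diff < threshold
    return diff / abs(roll) < threshold


@dataclass(frozen=True)
class RunReport:
    """Everything a finished run produced.

    ``explored`` lists every scored acquisition as (smiles, objective value,
    raw score, iteration acquired); ``top_k`` is the k best of those;
    ``log`` has one row per completed iteration (including initialization).
    """

    config: dict[str, Any]
    explored: list[dict[str, Any]]
    top_k: list[dict[str, Any]]
    log: list[dict[str, Any]]
    n_tested: int
    converged: bool

    @property
    def found_scores(self) -> list[float]:
        """Observed objective values (maximization convention)."""
        return [row["objective"] for row in self.explored]

    @property
    def found_smiles(self) -> list[str]:
        return [row["smiles"] for row in self.explored]

    def iteration_smiles(self) -> list[set[str]]:
        """Acquired SMILES per iteration (scored and MISSING alike are not
        distinguished here; only scored rows are recorded)."""
        n_iter = max((r["iteration_acquired"] for r in self.explored), default=0)
        out: list[set[str]] = [set() for _ in range(n_iter + 1)]
        for row in self.explored:
            out[row["iteration_acquired"]].add(row["smiles"])
        return out

    def write(self, outdir: str | Path) -> None:
        """Write explored.csv, log.csv and config.yaml to a directory."""
        import csv as _csv

        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "explored.csv", "w", newline="") as fh:
            w = _csv.DictWriter(
                fh, fieldnames=["smiles", "objective", "raw_score", "iteration_acquired"]
            )
            w.writeheader()
            w.writerows(self.explored)
        with open(outdir / "log.csv", "w", newline="") as fh:
            w = _csv.DictWriter(
                fh,
                fieldnames=["iteration", "n_tested", "n_scored", "top_k_average", "best_score"],
            )
            w.writeheader()
            w.writerows(self.log)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=False)


def _build_report(
    state: ExplorerState,
    pool: MoleculePool,
    objective: LookupTable,
    config: ExplorerConfig,
    converged: bool,
) -> RunReport:
    explored = []
    for i, val in state.scores.items():
        smi = pool.smiles[i]
        raw = objective.raw_score(smi)
        explored.append(
            {
                "smiles": smi,
                "objective": val,
                "raw_score": raw,
                "iteration_acquired": state.acquired_at[i],
            }
        )
    explored.sort(key=lambda r: (r["iteration_acquired"], r["smiles"]))
    top = sorted(explored, key=lambda r: (-r["objective"], r["smiles"]))[: config.k]
    return RunReport(
        config=config.to_dict(),
        explored=explored,
        top_k=top,
        log=list(state.log),
        n_tested=state.n_tested,
        converged=converged,
    )


def run(
    pool: MoleculePool,
    objective: LookupTable,
    config: ExplorerConfig,
    surrogate: Any = None,
    checkpoint_dir: str | Path | None = None,
) -> RunReport:
    """Execute the full optimization: initialize, iterate, stop, report.

    With ``stopping="fixed"`` exactly ``max_iterations`` exploration batches
    run (fewer if the pool runs out).  With ``stopping="converged"`` the
    loop also ends once :func:`check_convergence` fires;
    ``max_iterations`` then acts as a hard cap.  ``max_iterations=0`` yields
    the pure random baseline at the initialization budget.  Fixed seeds give
    bitwise-reproducible reports.  When ``checkpoint_dir`` is given the
    current model and state log are saved after each iteration so a long run
    can be inspected or resumed.
    """
    state = initialize(pool, objective, config)
    converged = False
    for _ in range(config.max_iterations):
        if state.n_tested >= pool.size:
            break
        run_iteration(state, pool, objective, config, surrogate=surrogate)
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            if state.model is not None and surrogate is None:
                sg.save_checkpoint(state.model, ckpt / f"model_iter{state.iteration}.joblib")
        if config.stopping == "converged" and check_convergence(
            state.topk_history,
            config.convergence_threshold,
            config.convergence_window,
            signed=config.convergence_signed,
        ):
            converged = True
            break
    return _build_report(state, pool, objective, config, converged)
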