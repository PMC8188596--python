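"""Synthetic pools and score tables with a controlled structure-score
landscape.

The generator enumerates small heteroatom-substituted alkyl chains (with
optional methyl branches and small rings appended for variety) from a fixed
grammar, giving 10^2-10^5 valid, unique, chemically plausible SMILES with no
external data.  Scores are a smooth deterministic function of the same
2048-bit atom-pair fingerprints the surrogates see — a random linear form in
the bits, optionally with a quadratic (bit-interaction) term — plus Gaussian
noise, written as a *raw* score in the minimization convention (more
negative is better) to mirror docking output.  Because signal lives in
fingerprint space, the landscape is learnable by construction, which is what
makes desk-scale enrichment experiments reproducible.

Optional knobs emulate real datasets' warts: quantizing scores to a fixed
decimal grid (docking programs print 0.1- or 0.01-precision scores, which
creates ties) and blanking a fraction of scores (molecules that failed to
dock: present in the table, selectable, but scoreless).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .objective import LookupTable
from .pool import FP_SIZE, MoleculePool, canonicalize
from .surrogates import Prediction, SurrogateError

_CHAIN_ATOMS = ("C", "N", "O", "S")
_DECORATIONS = ("", "C(C)", "C1CC1", "C1CCC1", "c1ccccc1")


class FixtureError(ValueError):
    """Raised when generation cannot meet its contract."""


@dataclass(frozen=True)
class LandscapeSpec:
    """What to generate and how scores depend on structure.

    ``noise_sigma`` is the absolute standard deviation of the additive
    Gaussian noise on the raw score; use :func:`signal_sd` to express it as
    a fraction of the signal spread.  ``tie_quantization`` rounds raw scores
    to that decimal precision (e.g. 0.1 to emulate AutoDock Vina's grid).
    ``missing_fraction`` blanks that share of scores at random.
    """

    n_molecules: int = 1000
    score_function: str = "linear-in-bits"  # or "quadratic-in-bits"
    noise_sigma: float = 0.0
    tie_quantization: float | None = None
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_molecules < 10:
            raise FixtureError("n_molecules must be >= 10")
        if self.score_function not in ("linear-in-bits", "quadratic-in-bits"):
            raise FixtureError(f"unknown score function {self.score_function!r}")
        if self.noise_sigma < 0:
            raise FixtureError("noise_sigma must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise FixtureError("missing_fraction must be in [0, 1)")


def _enumerate_chain_smiles(n: int) -> list[str]:
    """Deterministically enumerate ``n`` unique valid molecules.

    Grammar: linear chains over {C,N,O,S} of growing length, each optionally
    prefixed with a small carbon decoration (branch or ring).  Enumeration
    order is fixed, so the same ``n`` always yields the same list.
    """
    out: list[str] = []
    seen: set[str] = set()
    for length in itertools.count(2):
        if length > 12:
            raise FixtureError(f"grammar exhausted before reaching {n} molecules")
        for deco in _DECORATIONS:
            for atoms in itertools.product(_CHAIN_ATOMS, repeat=length):
                smi = deco + "".join(atoms)
                canon = canonicalize(smi)
                if canon is None or canon in seen:
                    continue
                seen.add(canon)
                out.append(canon)
                if len(out) == n:
                    return out
    raise FixtureError("unreachable")


@dataclass(frozen=True)
class Fixture:
    """A generated pool plus its score table and the underlying truth."""

    pool: MoleculePool
    lookup: LookupTable
    weights: np.ndarray  # linear coefficients over fingerprint bits
    true_objective: np.ndarray  # noiseless signal per pool index (max convention)
    raw_scores: list[float | None]  # as written to the lookup (min convention)
    spec: LandscapeSpec
    seed: int

    def true_top_k(self, k: int) -> set[str]:
        order = np.argsort(-self.true_objective, kind="stable")
        return {self.pool.smiles[i] for i in order[:k]}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write pool.smi, lookup.csv and truth.csv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pool": outdir / "pool.smi",
            "lookup": outdir / "lookup.csv",
            "truth": outdir / "truth.csv",
        }
        with open(paths["pool"], "w") as fh:
            for smi in self.pool.smiles:
                fh.write(smi + "\n")
        with open(paths["lookup"], "w") as fh:
            fh.write("smiles,score\n")
            for smi, raw in zip(self.pool.smiles, self.raw_scores):
                fh.write(f"{smi},{'' if raw is None else repr(raw)}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("smiles,true_objective\n")
            for smi, val in zip(self.pool.smiles, self.true_objective):
                fh.write(f"{smi},{val!r}\n")
        np.save(outdir / "weights.npy", self.weights)
        return paths


def signal_sd(fixture_or_signal) -> float:
    """Standard deviation of the noiseless signal (for scaling noise)."""
    sig = (
        fixture_or_signal.true_objective
        if isinstance(fixture_or_signal, Fixture)
        else np.asarray(fixture_or_signal)
    )
    return float(np.std(sig))


def generate_pool(spec: LandscapeSpec, seed: int) -> Fixture:
    """Generate a synthetic pool and lookup table per ``spec``.

    Deterministic per seed.  The raw score of molecule x with fingerprint
    bits phi(x) is ``-(w . phi(x) [+ q(phi(x))]) + Normal(0, noise_sigma)``,
    optionally quantized, so the maximization-convention objective is the
    (noisy, negated-back) signal and the true ranking is known exactly.
    """
    smiles = _enumerate_chain_smiles(spec.n_molecules)
    pool = MoleculePool(smiles)
    rng = np.random.default_rng(seed)

    fps = pool.fingerprints.astype(float)
    weights = rng.normal(0.0, 1.0, size=FP_SIZE)
    signal = fps @ weights
    if spec.score_function == "quadratic-in-bits":
        # a sparse bit-interaction term keeps the landscape smooth but
        # non-linear; pairs are drawn from bits co-occurring in actual
        # molecules so the term is non-degenerate on sparse fingerprints
        pair_list = []
        for row in rng.choice(len(fps), size=64, replace=True):
            on = np.flatnonzero(fps[row])
            if len(on) >= 2:
                pair_list.append(rng.choice(on, size=2, replace=False))
        pairs = np.asarray(pair_list, dtype=int)
        qw = rng.normal(0.0, 1.0, size=len(pairs))
        signal = signal + (fps[:, pairs[:, 0]] * fps[:, pairs[:, 1]]) @ qw
    # center so raw scores straddle zero like docking output
    signal = signal - signal.mean()

    noise = rng.normal(0.0, spec.noise_sigma, size=len(signal))
    raw = -(signal) + noise
    if spec.tie_quantization is not None:
        decimals = max(0, int(round(-np.log10(spec.tie_quantization))))
        raw = np.round(raw, decimals)

    raw_scores: list[float | None] = [float(v) for v in raw]
    if spec.missing_fraction > 0:
        n_missing = int(round(spec.missing_fraction * len(raw_scores)))
        for i in rng.choice(len(raw_scores), size=n_missing, replace=False):
            raw_scores[int(i)] = None

    lookup = LookupTable(
        dict(zip(pool.smiles, raw_scores)), minimize=True
    )
    return Fixture(
        pool=pool,
        lookup=lookup,
        weights=weights,
        true_objective=signal,
        raw_scores=raw_scores,
        spec=spec,
        seed=seed,
    )


class OracleSurrogate:
    """Test double whose predictions equal the true objective, with zero
    variance — the perfect-model limit.

    Relies on the explorer's full-pool inference: ``predict`` is handed the
    whole fingerprint matrix in pool order, so the oracle can answer from
    its index-aligned truth vector.
    """

    def __init__(self, fixture: Fixture, with_variance: bool = True):
        self._truth = np.asarray(fixture.true_objective, dtype=float)
        self._n = len(self._truth)
        self._with_variance = with_variance
        self.spec = None

    def fit(self, data) -> "OracleSurrogate":  # noqa: ARG002 - oracle needs no data
        return self

    def predict(self, fingerprints: np.ndarray) -> Prediction:
        if len(fingerprints) != self._n:
            raise SurrogateError(
                "oracle surrogate answers full-pool queries only "
                f"(got {len(fingerprints)} rows, pool has {self._n})"
            )
        variance = np.zeros(self._n) if self._with_variance else None
        return Prediction(self._truth.copy(), variance)
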