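"""Acquisition functions and batch selection.

Maps surrogate predictions (mean, variance) to per-candidate utilities and
selects the top-b untested candidates.  Implemented metrics, with
``sigma = sqrt(variance)``, incumbent ``f*`` (best objective value observed
so far) and improvement margin ``gamma = mu - f* - xi``:

- ``greedy``:  mu
- ``ucb``:     mu + beta * sigma
- ``ts``:      one draw from Normal(mu, sigma^2) per candidate
- ``ei``:      gamma * Phi(gamma/sigma) + sigma * phi(gamma/sigma)
- ``pi``:      Phi(gamma/sigma)
- ``random``:  Uniform(0, 1), independent of the predictions

``xi`` is a signed exploration offset (default 0.01: a small penalty on the
incumbent-relative improvement).  At sigma = 0 the EI/PI formulas take their
continuous limits: EI -> max(gamma, 0) and PI -> 1{gamma > 0}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

METRICS = ("random", "greedy", "ucb", "ts", "ei", "pi")
#: Metrics whose utility depends on the predictive variance.
VARIANCE_METRICS = ("ucb", "ts", "ei", "pi")


class AcquisitionError(ValueError):
    """Raised for invalid acquisition configuration or inputs."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition metric and its parameters.

    beta scales the exploration bonus in UCB; xi offsets the improvement
    threshold in EI/PI.  Defaults follow common practice for batched
    screening (beta=2, xi=0.01).
    """

    metric: str = "greedy"
    beta: float = 2.0
    xi: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise AcquisitionError(
                f"unknown metric {self.metric!r}; choose from {METRICS}"
            )
        if self.beta < 0:
            raise AcquisitionError("beta must be nonnegative")

    @property
    def needs_variance(self) -> bool:
        return self.metric in VARIANCE_METRICS


def utility(
    metric: str,
    mean: np.ndarray | float,
    variance: np.ndarray | float | None,
    f_star: float | None,
    config: AcquisitionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-candidate acquisition utilities (vectorized).

    Parameters
    ----------
    metric : str
        One of ``random, greedy, ucb, ts, ei, pi``.
    mean, variance : array-like
        Surrogate predictions; ``variance`` may be None for metrics that do
        not need it.
    f_star : float
        Incumbent (max observed objective); required for EI/PI.
    config : AcquisitionConfig, optional
        Supplies beta and xi (defaults used if omitted).
    rng : numpy Generator, optional
        Required for the stochastic metrics (ts, random).
    """
    if config is None:
        config = AcquisitionConfig(metric=metric)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))

    if metric == "greedy":
        return mean.copy()
    if metric == "random":
        if rng is None:
            raise AcquisitionError("random metric needs an rng")
        return rng.uniform(size=mean.shape)

    if variance is None:
        raise AcquisitionError(f"metric {metric!r} requires predictive variance")
    var = np.atleast_1d(np.asarray(variance, dtype=float))
    var = np.broadcast_to(var, mean.shape)
    if np.any(var < 0):
        raise AcquisitionError("negative variance passed to acquisition")
    sigma = np.sqrt(var)

    if metric == "ucb":
        return mean + config.beta * sigma
    if metric == "ts":
        if rng is None:
            raise AcquisitionError("ts metric needs an rng")
        return rng.normal(loc=mean, scale=sigma)

    if f_star is None:
        raise AcquisitionError(f"metric {metric!r} requires an incumbent f*")
    gamma = mean - f_star - config.xi

    if metric == "ei":
        out = np.maximum(gamma, 0.0)  # sigma = 0 limit
        pos = sigma > 0
        if np.any(pos):
            z = gamma[pos] / sigma[pos]
            out[pos] = gamma[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
        return out
    if metric == "pi":
        out = (gamma > 0).astype(float)  # sigma = 0 limit
        pos = sigma > 0
        if np.any(pos):
            out[pos] = norm.cdf(gamma[pos] / sigma[pos])
        return out
    raise AcquisitionError(f"unknown metric {metric!r}")


def select_batch(
    utilities: np.ndarray,
    acquired: np.ndarray | set[int],
    b: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select the b untested candidates with the largest utilities.

    ``acquired`` marks candidates already tested (boolean mask or index
    set); they are excluded from selection.  Ties at the batch boundary are
    broken uniformly at random with the run RNG, so a fixed seed gives a
    reproducible batch.  If fewer than b untested candidates remain the
    batch is truncated with a warning (final-iteration edge case).

    Returns the selected candidate indices, sorted by decreasing utility.
    """
    utilities = np.asarray(utilities, dtype=float)
    if b < 1:
        raise AcquisitionError("batch size must be >= 1")
    n = utilities.shape[0]
    if isinstance(acquired, np.ndarray) and acquired.dtype == bool:
        mask = acquired
    else:
        mask = np.zeros(n, dtype=bool)
        idx = list(acquired)
        if idx:
            mask[np.asarray(idx, dtype=int)] = True
    n_untested = int(n - mask.sum())
    if n_untested == 0:
        raise AcquisitionError("no untested candidates remain")
    if b > n_untested:
        warnings.warn(
            f"batch size {b} exceeds {n_untested} untested candidates; truncating",
            stacklevel=2,
        )
        b = n_untested

    # lexsort: primary key utility (descending), secondary a random
    # tie-breaker -> ties at the cut resolved uniformly at random
    tiebreak = rng.random(n)
    masked = np.where(mask, -np.inf, utilities)
    order = np.lexsort((tiebreak, -masked))
    return order[:b]
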