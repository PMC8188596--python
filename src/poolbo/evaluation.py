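"""Retrieval metrics for a completed screening run.

Performance is judged against the full ground-truth table via three top-k
metrics — the average top-k score ratio, the fraction of top-k SMILES
identified, and the (tie-robust) fraction of top-k score values identified —
plus the enrichment factor over a random search at equal budget, and a
repeat-overlap analysis of how similar the acquisitions of repeated trials
are.

Ties at rank k are resolved by a stable sort on (score, canonical SMILES),
so the true top-k is deterministic; the Scores metric is insensitive to that
choice by construction, which is why it is the headline metric for datasets
with low-precision scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .objective import LookupTable


class EvaluationError(ValueError):
    """Raised for unusable metric inputs."""


class GroundTruth:
    """Full-library truth: every (canonical SMILES, objective value) pair.

    Values are in the maximization convention.  ``raw_sign`` records the
    sign flip needed to report averages in the raw-score domain (-1 when the
    raw scores were minimized, e.g. docking).
    """

    def __init__(self, scores: Mapping[str, float], raw_sign: int = -1):
        if not scores:
            raise EvaluationError("ground truth is empty")
        self._scores = dict(scores)
        self.raw_sign = raw_sign
        # descending by value; ties broken by SMILES for determinism
        self._ranked = sorted(self._scores.items(), key=lambda kv: (-kv[1], kv[0]))

    @classmethod
    def from_lookup(cls, table: LookupTable) -> "GroundTruth":
        scores = {
            smi: (-raw if table.minimize else raw)
            for smi, raw in table.items()
            if raw is not None
        }
        return cls(scores, raw_sign=-1 if table.minimize else 1)

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._scores

    def value(self, smiles: str) -> float:
        return self._scores[smiles]

    def top_k_smiles(self, k: int) -> set[str]:
        self._check_k(k)
        return {smi for smi, _ in self._ranked[:k]}

    def top_k_values(self, k: int) -> list[float]:
        """The k best objective values (a multiset, as a sorted list)."""
        self._check_k(k)
        return [v for _, v in self._ranked[:k]]

    def _check_k(self, k: int) -> None:
        if not 0 < k <= len(self._ranked):
            raise EvaluationError(f"k={k} not in 1..{len(self._ranked)}")


@dataclass(frozen=True)
class MetricReport:
    """The three top-k metrics for one run (and the k they used)."""

    k: int
    average_ratio: float
    smiles_fraction: float
    scores_fraction: float
    partial: bool = False  # True when fewer than k molecules were found

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "average_ratio": self.average_ratio,
            "smiles_fraction": self.smiles_fraction,
            "scores_fraction": self.scores_fraction,
            "partial": self.partial,
        }


def _found_top_k(
    found: Mapping[str, float], k: int
) -> tuple[list[tuple[str, float]], bool]:
    if not found:
        raise EvaluationError("no scored molecules in the run")
    ranked = sorted(found.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k], len(ranked) < k


def top_k_average_ratio(found: Mapping[str, float], truth: GroundTruth, k: int) -> float:
    """Mean of the k best found scores over the mean of the true top-k.

    Computed in the raw-score domain with its sign preserved (for docking,
    the ratio of two negative averages), so a perfect run scores exactly 1
    and any miss pulls the ratio below 1.  With fewer than k found
    molecules the numerator averages what there is (flagged partial in
    :func:`report`).
    """
    top, _ = _found_top_k(found, k)
    found_avg = float(np.mean([v for _, v in top])) * truth.raw_sign
    true_avg = float(np.mean(truth.top_k_values(k))) * truth.raw_sign
    if true_avg == 0.0:
        raise EvaluationError("true top-k average is zero; ratio undefined")
    return found_avg / true_avg


def top_k_smiles_fraction(
    found: Mapping[str, float], truth: GroundTruth, k: int
) -> float:
    """|found-top-k SMILES ∩ true-top-k SMILES| / k."""
    top, _ = _found_top_k(found, k)
    return len({s for s, _ in top} & truth.top_k_smiles(k)) / k


def top_k_scores_fraction(
    found: Mapping[str, float], truth: GroundTruth, k: int
) -> float:
    """Multiset intersection of the k best found and true score lists, / k.

    Scores are compared exactly as parsed (no epsilon): datasets carry
    fixed printed precision, and the multiset form is what makes this
    metric robust to arbitrary ordering among tied molecules.
    """
    top, _ = _found_top_k(found, k)
    found_counts = Counter(v for _, v in top)
    true_counts = Counter(truth.top_k_values(k))
    overlap = sum((found_counts & true_counts).values())
    return overlap / k


def report(found: Mapping[str, float], truth: GroundTruth, k: int) -> MetricReport:
    """All three top-k metrics for one run."""
    _, partial = _found_top_k(found, k)
    return MetricReport(
        k=k,
        average_ratio=top_k_average_ratio(found, truth, k),
        smiles_fraction=top_k_smiles_fraction(found, truth, k),
        scores_fraction=top_k_scores_fraction(found, truth, k),
        partial=partial,
    )


def enrichment_factor(model_fraction: float, random_fraction: float) -> float:
    """Ratio of model-guided to random top-k recovery at equal budget.

    Undefined (raises) when the random baseline found nothing.
    """
    if random_fraction <= 0:
        raise EvaluationError(
            "enrichment factor undefined: random baseline fraction is zero"
        )
    return model_fraction / random_fraction


@dataclass(frozen=True)
class OverlapTrace:
    """Cumulative unique-SMILES counts across repeated trials, per
    iteration, with the theoretical extremes."""

    unique: list[int]
    minimum: list[int]  # identical acquisitions after distinct initializations
    maximum: list[int]  # pairwise-disjoint acquisitions, capped by the pool


def repeat_overlap(
    runs: Sequence[Sequence[set[str]]], pool_size: int | None = None
) -> OverlapTrace:
    """How much do repeated trials acquire the same molecules?

    ``runs`` holds, for each trial, the per-iteration sets of acquired
    SMILES (index 0 = random initialization).  All trials must follow the
    same batch schedule.  Returns the cumulative union size per iteration
    together with its theoretical bounds: the maximum has every trial
    acquiring disjoint sets (n_runs x cumulative batch, capped by the pool
    size if given); the minimum has every trial acquiring identical sets
    after its own random initialization (union of the actual
    initializations, plus one shared copy of each later batch).
    """
    if len(runs) < 2:
        raise EvaluationError("repeat_overlap needs at least 2 runs")
    n_iters = len(runs[0])
    schedules = [[len(batch) for batch in r] for r in runs]
    if any(len(r) != n_iters for r in runs) or any(
        s != schedules[0] for s in schedules[1:]
    ):
        raise EvaluationError("runs have mismatched batch schedules")

    unique: list[int] = []
    minimum: list[int] = []
    maximum: list[int] = []
    seen: set[str] = set()
    init_union = len(set().union(*(r[0] for r in runs)))
    cum_batch = 0
    for t in range(n_iters):
        for r in runs:
            seen |= r[t]
        cum_batch += schedules[0][t]
        unique.append(len(seen))
        mx = len(runs) * cum_batch
        if pool_size is not None:
            mx = min(mx, pool_size)
        maximum.append(mx)
        if t == 0:
            minimum.append(init_union)
        else:
            minimum.append(init_union + cum_batch - schedules[0][0])
    return OverlapTrace(unique=unique, minimum=minimum, maximum=maximum)
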