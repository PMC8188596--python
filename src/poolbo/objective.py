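"""Black-box objective evaluation via score lookup tables.

In retrospective screening the expensive objective (e.g. a docking run) has
already been computed for every library member, so evaluation replays a
CSV of (SMILES, score) rows.  Docking scores are "lower is better"; the
optimizer works in a maximization convention throughout, so negation happens
exactly once — here, at evaluation.  Library members that failed to dock are
present in the table without a score: selecting one consumes acquisition
budget but returns MISSING, and such molecules never enter surrogate
training or metric numerators.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .pool import MoleculePool, canonicalize

#: Sentinel for a molecule whose objective value could not be computed.
MISSING = None


class LookupError_(ValueError):
    """Raised for unusable lookup inputs (no parseable rows, bad column)."""


@dataclass(frozen=True)
class LookupReport:
    n_scored: int
    n_missing: int
    n_sentinel_dropped: int


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of evaluating one molecule.

    ``objective_value`` is in the maximization convention (negated raw score
    when the table minimizes) or MISSING when the molecule has no score.
    """

    smiles: str
    objective_value: float | None

    @property
    def missing(self) -> bool:
        return self.objective_value is MISSING


class LookupTable:
    """Mapping from canonical SMILES to raw score, replaying a precomputed
    dataset as the black-box objective.

    Parameters
    ----------
    scores : mapping of str -> float or None
        Raw scores keyed by SMILES (canonicalized on construction); None
        marks a molecule present in the dataset without a score.
    minimize : bool
        True when smaller raw scores are better (docking); the objective
        returned by :meth:`evaluate` is then the negated raw score.
    """

    def __init__(self, scores: Mapping[str, float | None], minimize: bool = True):
        self._scores: dict[str, float | None] = {}
        for smi, val in scores.items():
            canon = canonicalize(smi)
            if canon is None:
                continue
            if val is not None and not math.isfinite(val):
                val = None
            self._scores[canon] = val
        if not self._scores:
            raise LookupError_("lookup table has no usable rows")
        self.minimize = bool(minimize)

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._scores

    def raw_score(self, smiles: str) -> float | None:
        """Raw (as-parsed) score for a canonical SMILES, or None."""
        return self._scores.get(smiles)

    def objective(self, smiles: str) -> float | None:
        """Score in the maximization convention, or MISSING."""
        raw = self._scores.get(smiles)
        if raw is None:
            return MISSING
        return -raw if self.minimize else raw

    def items(self):
        return self._scores.items()

    def coverage(self, pool: MoleculePool) -> tuple[int, int]:
        """(n_covered, n_uncovered) pool members with a score in the table."""
        covered = sum(1 for s in pool.smiles if self._scores.get(s) is not None)
        return covered, pool.size - covered


def load_lookup(
    path: str | Path,
    smiles_column: int | str = "smiles",
    score_column: int | str = "score",
    minimize: bool = True,
    sentinel_values: Sequence[float] = (),
    delimiter: str | None = None,
) -> tuple[LookupTable, LookupReport]:
    """Load a lookup table from a CSV/CSV.gz of (SMILES, score) rows.

    Rows with an empty or unparseable score, and rows whose score equals one
    of ``sentinel_values`` (placeholder codes some pipelines emit for failed
    computations), are kept as key-present-score-missing so that selecting
    them still consumes budget.  Columns may be named (header required) or
    positional (0-based int).

    Returns the table plus a :class:`LookupReport`.
    """
    path = Path(path)
    if not path.exists():
        raise LookupError_(f"lookup file not found: {path}")
    opener = gzip.open if str(path).endswith(".gz") else open
    if delimiter is None:
        delimiter = "\t" if ".tsv" in str(path) else ","
    sentinels = {float(v) for v in sentinel_values}

    scores: dict[str, float | None] = {}
    n_scored = n_missing = n_sentinel = 0
    with opener(path, "rt") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = iter(reader)
        first = next(rows, None)
        if first is None:
            raise LookupError_(f"empty lookup file: {path}")
        if isinstance(smiles_column, str) or isinstance(score_column, str):
            header = [c.strip().lower() for c in first]
            try:
                s_col = (
                    header.index(str(smiles_column).lower())
                    if isinstance(smiles_column, str)
                    else int(smiles_column)
                )
                y_col = (
                    header.index(str(score_column).lower())
                    if isinstance(score_column, str)
                    else int(score_column)
                )
            except ValueError:
                raise LookupError_(
                    f"columns {smiles_column!r}/{score_column!r} not found in {path}"
                ) from None
        else:
            s_col, y_col = int(smiles_column), int(score_column)
            rows = iter([first] + list(rows))

        for row in rows:
            if not row or max(s_col, y_col) >= len(row):
                continue
            smi = row[s_col].strip()
            if not smi:
                continue
            text = row[y_col].strip()
            val: float | None
            if not text:
                val = None
                n_missing += 1
            else:
                try:
                    val = float(text)
                except ValueError:
                    val = None
                    n_missing += 1
                else:
                    if val in sentinels or not math.isfinite(val):
                        val = None
                        n_sentinel += 1
                    else:
                        n_scored += 1
            scores[smi] = val

    if n_scored == 0:
        raise LookupError_(f"no parseable scored rows in {path}")
    return LookupTable(scores, minimize=minimize), LookupReport(
        n_scored, n_missing, n_sentinel
    )


def evaluate(table: LookupTable, batch: Iterable[str]) -> list[EvaluationResult]:
    """Evaluate a batch of canonical SMILES against the objective.

    One result per input, order preserved.  A SMILES absent from the table,
    or present without a score, yields MISSING — a value, not an error: the
    candidate still counts against the acquisition budget downstream.
    """
    results = []
    for smi in batch:
        results.append(EvaluationResult(smi, table.objective(smi)))
    if not results:
        raise LookupError_("empty evaluation batch")
    return results
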