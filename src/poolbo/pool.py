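"""Molecular pools: loading, validation, featurization and indexing.

A :class:`MoleculePool` is the finite design space over which the optimization
runs — an ordered collection of unique, valid molecules, each carrying a
2048-bit atom-pair fingerprint.  SMILES are canonicalized at load time so that
duplicate detection here and score lookup in :mod:`poolbo.objective` agree on
molecular identity regardless of how the input strings were written.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

FP_SIZE = 2048
_MIN_DIST = 1
_MAX_DIST = 3

# Binary presence/absence of hashed (atom type, atom type, topological
# distance) pairs; distances 1-3 bonds, folded to 2048 bits.
_generator = rdFingerprintGenerator.GetAtomPairGenerator(
    minDistance=_MIN_DIST,
    maxDistance=_MAX_DIST,
    fpSize=FP_SIZE,
    countSimulation=False,
)


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class PoolError(ValueError):
    """Raised for unusable pool inputs (empty pool, missing column, ...)."""


def canonicalize(smiles: str) -> str | None:
    """Return the RDKit-canonical form of ``smiles``, or None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def featurize(smiles: str) -> np.ndarray:
    """Compute the 2048-bit atom-pair fingerprint of a molecule.

    Enumerates all heavy-atom pairs at topological distance 1-3 bonds,
    hashes each (atom type, atom type, distance) triple and folds into a
    binary vector of length 2048.  A molecule with a single heavy atom has
    no pairs and maps to the all-zero vector.

    Raises
    ------
    FeaturizationError
        If ``smiles`` does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"invalid SMILES: {smiles!r}")
    fp = _generator.GetFingerprint(mol)
    arr = np.zeros(FP_SIZE, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


@dataclass(frozen=True)
class Candidate:
    """One pool member: a stable index, canonical SMILES and fingerprint."""

    index: int
    smiles: str
    fingerprint: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("candidate index must be non-negative")
        if self.fingerprint.shape != (FP_SIZE,):
            raise ValueError(f"fingerprint must have length {FP_SIZE}")


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from a pool load: rows read, dropped as invalid, dropped
    as duplicates."""

    n_read: int
    n_invalid: int
    n_duplicate: int


class MoleculePool:
    """Ordered collection of unique candidate molecules with fingerprints.

    Parameters
    ----------
    smiles : sequence of str
        Canonical SMILES, already deduplicated (use :func:`load_pool` or
        :meth:`from_smiles` for raw input).
    fingerprints : ndarray of shape (n, 2048), optional
        Precomputed fingerprints; computed on construction if omitted.
    """

    def __init__(
        self,
        smiles: Sequence[str],
        fingerprints: np.ndarray | None = None,
    ) -> None:
        if len(smiles) == 0:
            raise PoolError("pool is empty")
        if len(set(smiles)) != len(smiles):
            raise PoolError("pool SMILES must be unique")
        self._smiles: list[str] = list(smiles)
        if fingerprints is None:
            fingerprints = np.stack([featurize(s) for s in self._smiles])
        if fingerprints.shape != (len(self._smiles), FP_SIZE):
            raise PoolError("fingerprint matrix shape mismatch")
        self._fps = np.ascontiguousarray(fingerprints, dtype=np.uint8)
        self._index: dict[str, int] = {s: i for i, s in enumerate(self._smiles)}

    # -- basic container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self._smiles)

    @property
    def size(self) -> int:
        return len(self._smiles)

    @property
    def smiles(self) -> list[str]:
        return list(self._smiles)

    @property
    def fingerprints(self) -> np.ndarray:
        """(n, 2048) uint8 matrix, row i belonging to candidate i."""
        return self._fps

    def __getitem__(self, index: int) -> Candidate:
        return Candidate(index, self._smiles[index], self._fps[index])

    def __iter__(self) -> Iterable[Candidate]:
        for i in range(len(self)):
            yield self[i]

    def index_of(self, smiles: str) -> int:
        """Index of a canonical SMILES; KeyError if absent."""
        return self._index[smiles]

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._index

    # -- construction -------------------------------------------------------
    @classmethod
    def from_smiles(cls, raw_smiles: Iterable[str]) -> tuple["MoleculePool", LoadReport]:
        """Build a pool from raw SMILES: canonicalize, drop invalid rows and
        duplicates (first occurrence wins), preserve input order."""
        kept: list[str] = []
        seen: set[str] = set()
        n_read = n_invalid = n_duplicate = 0
        for raw in raw_smiles:
            n_read += 1
            canon = canonicalize(raw)
            if canon is None:
                n_invalid += 1
                continue
            if canon in seen:
                n_duplicate += 1
                continue
            seen.add(canon)
            kept.append(canon)
        if not kept:
            raise PoolError("no valid molecules after filtering")
        return cls(kept), LoadReport(n_read, n_invalid, n_duplicate)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_smiles_file(path: Path, smiles_column: int | str | None) -> Iterable[str]:
    """Yield raw SMILES strings from a .smi or delimited file."""
    suffixes = Path(str(path).removesuffix(".gz")).suffixes
    is_delim = suffixes and suffixes[-1] in {".csv", ".tsv"}
    if is_delim:
        import csv

        delim = "\t" if suffixes[-1] == ".tsv" else ","
        with _open_text(path) as fh:
            reader = csv.reader(fh, delimiter=delim)
            rows = iter(reader)
            first = next(rows, None)
            if first is None:
                return
            col: int
            if isinstance(smiles_column, str):
                try:
                    col = [c.strip().lower() for c in first].index(smiles_column.lower())
                except ValueError:
                    raise PoolError(
                        f"column {smiles_column!r} not found in {path}"
                    ) from None
            else:
                col = 0 if smiles_column is None else int(smiles_column)
                # a header row never parses as a molecule; emit it and let
                # validation drop it only if it genuinely is not a SMILES
                if first and col < len(first) and canonicalize(first[col]) is not None:
                    yield first[col]
            for row in rows:
                if row and col < len(row):
                    yield row[col]
    else:
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                yield line.split()[0]


def load_pool(
    paths: Sequence[str | Path],
    smiles_column: int | str | None = None,
) -> tuple[MoleculePool, LoadReport]:
    """Load a molecular pool from one or more SMILES/CSV files.

    Accepts ``.smi`` (one SMILES per line, optional trailing ID column) and
    ``.csv``/``.tsv`` (optionally gzipped) with ``smiles_column`` given by
    name or position (default: first column).  Unparseable rows are skipped
    and counted; duplicate molecules (by canonical SMILES) keep their first
    occurrence.  Fingerprints are computed once per unique molecule.

    Returns the pool plus a :class:`LoadReport`.
    Raises :class:`PoolError` if nothing valid remains.
    """
    raw: list[str] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise PoolError(f"pool file not found: {p}")
        raw.extend(_iter_smiles_file(p, smiles_column))
    return MoleculePool.from_smiles(raw)


def subsample(pool: MoleculePool, n: int, seed: int) -> MoleculePool:
    """Uniform random subsample of ``n`` molecules without replacement.

    Deterministic for a fixed seed.  Membership, not order, is the contract:
    the returned pool lists the sampled molecules in their original pool
    order.
    """
    if not 0 < n <= pool.size:
        raise PoolError(f"subsample size {n} not in 1..{pool.size}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool.size, size=n, replace=False))
    smiles = [pool.smiles[i] for i in idx]
    return MoleculePool(smiles, pool.fingerprints[idx])


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, used to key the on-disk fingerprint cache."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def cached_load_pool(
    paths: Sequence[str | Path],
    cache_dir: str | Path,
    smiles_column: int | str | None = None,
) -> tuple[MoleculePool, LoadReport]:
    """Like :func:`load_pool` but memoizes fingerprints on disk.

    The cache key is the SHA-256 of the input files plus the column spec, so
    a changed input never reuses stale fingerprints.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = hashlib.sha256(
        ("|".join(file_checksum(p) for p in paths) + f"|{smiles_column}").encode()
    ).hexdigest()[:16]
    cache = cache_dir / f"pool-{key}.npz"
    if cache.exists():
        data = np.load(cache, allow_pickle=False)
        smiles = [s for s in data["smiles"]]
        pool = MoleculePool(smiles, data["fingerprints"])
        report = LoadReport(*(int(v) for v in data["report"]))
        return pool, report
    pool, report = load_pool(paths, smiles_column)
    np.savez_compressed(
        cache,
        smiles=np.array(pool.smiles),
        fingerprints=pool.fingerprints,
        report=np.array([report.n_read, report.n_invalid, report.n_duplicate]),
    )
    return pool, report
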