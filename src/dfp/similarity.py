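"""Similarity and distance computations on binary fingerprints.

Tanimoto similarity |a AND b| / |a OR b| is the field's standard
fingerprint comparison coefficient; city-block (Manhattan) distance
reduces to the Hamming distance on binary vectors.  Beyond the pairwise
primitives this module provides the library-level summaries used to
validate database fingerprints: exact or pair-sampled intra-set mean
Tanimoto, the mean similarity of each molecule against its library's
DFP, and inter-set distance matrices between DFPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import DatabaseFingerprint
from .errors import InputError, UsageError, ValidationError
from .schemes import BitMatrix

__all__ = [
    "SimilaritySummary",
    "DistanceMatrix",
    "tanimoto",
    "city_block",
    "intra_set_pairwise",
    "intra_set_vs_dfp",
    "inter_set_matrix",
]

logger = logging.getLogger(__name__)

METRICS = ("city_block", "one_minus_tanimoto")


@dataclass
class SimilaritySummary:
    """Mean/SD of a set of Tanimoto similarities for one library."""

    mean: float
    sd: float
    n_pairs_or_mols: int
    method: str  # pairwise_tanimoto | vs_dfp_tanimoto
    sampled: bool = False
    seed: int | None = None


@dataclass(eq=False)
class DistanceMatrix:
    """Symmetric inter-library distance matrix with database labels."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape must match label count")

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a label header row and column."""
        path = Path(path)
        is_int = self.metric == "city_block"
        with path.open("w") as handle:
            handle.write("\t".join(["label", *self.labels]) + "\n")
            for label, row in zip(self.labels, self.values):
                cells = [str(int(v)) if is_int else repr(float(v))
                         for v in row]
                handle.write("\t".join([label, *cells]) + "\n")


def _as_bit_vector(a: object) -> np.ndarray:
    if isinstance(a, DatabaseFingerprint):
        a = a.bits
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise ValidationError("expected a 1-D bit vector")
    return arr.astype(np.int64)


_warned_zero_zero = False


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    Two all-zero vectors compare as 0.0 by convention (logged once).
    """
    va, vb = _as_bit_vector(a), _as_bit_vector(b)
    if len(va) != len(vb):
        raise ValidationError(
            f"bit-vector lengths differ ({len(va)} vs {len(vb)})"
        )
    inter = int(np.bitwise_and(va, vb).sum())
    union = int(np.bitwise_or(va, vb).sum())
    if union == 0:
        global _warned_zero_zero
        if not _warned_zero_zero:
            logger.info("Tanimoto(all-zero, all-zero) defined as 0.0")
            _warned_zero_zero = True
        return 0.0
    return inter / union


def city_block(a, b) -> int:
    """City-block (Manhattan) distance; Hamming distance on binary bits."""
    va, vb = _as_bit_vector(a), _as_bit_vector(b)
    if len(va) != len(vb):
        raise ValidationError(
            f"bit-vector lengths differ ({len(va)} vs {len(vb)})"
        )
    return int(np.abs(va - vb).sum())


def _pairwise_tanimoto_values(bits: np.ndarray) -> np.ndarray:
    """All n(n-1)/2 pairwise Tanimoto values, popcount-accelerated."""
    fp = bits.astype(np.float64)
    inter = fp @ fp.T
    counts = bits.sum(axis=1).astype(np.float64)
    iu, ju = np.triu_indices(bits.shape[0], k=1)
    inter_pairs = inter[iu, ju]
    union_pairs = counts[iu] + counts[ju] - inter_pairs
    return np.where(union_pairs > 0,
                    inter_pairs / np.maximum(union_pairs, 1.0), 0.0)


def _sampled_tanimoto_values(bits: np.ndarray, sample_pairs: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Tanimoto over uniformly drawn distinct (i, j) pairs."""
    n = bits.shape[0]
    i = rng.integers(0, n, size=sample_pairs)
    j = rng.integers(0, n - 1, size=sample_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over j != i
    ai = bits[i].astype(np.int64)
    aj = bits[j].astype(np.int64)
    inter = np.bitwise_and(ai, aj).sum(axis=1)
    union = np.bitwise_or(ai, aj).sum(axis=1)
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def intra_set_pairwise(
    matrix: BitMatrix,
    max_exact_n: int = 3000,
    sample_pairs: int = 100_000,
    seed: int | None = None,
) -> SimilaritySummary:
    """Mean pairwise Tanimoto similarity within one library.

    Exact over all n(n-1)/2 pairs when n <= ``max_exact_n``; for larger
    libraries the mean is estimated over ``sample_pairs`` seeded
    uniformly drawn distinct pairs and the ``sampled`` flag is set.
    """
    if matrix.n < 2:
        raise InputError("pairwise similarity requires at least 2 molecules")
    if matrix.n <= max_exact_n:
        values = _pairwise_tanimoto_values(matrix.bits)
        return SimilaritySummary(
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            n_pairs_or_mols=len(values),
            method="pairwise_tanimoto",
        )
    rng = np.random.default_rng(seed)
    values = _sampled_tanimoto_values(matrix.bits, sample_pairs, rng)
    return SimilaritySummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_pairs_or_mols=sample_pairs,
        method="pairwise_tanimoto",
        sampled=True,
        seed=seed,
    )


def intra_set_vs_dfp(matrix: BitMatrix,
                     dfp: DatabaseFingerprint) -> SimilaritySummary:
    """Mean Tanimoto between each molecule and the library's DFP.

    A linear-cost approximation of the intra-set similarity: one
    comparison per molecule instead of one per pair.
    """
    if matrix.scheme != dfp.scheme:
        raise ValidationError(
            f"scheme mismatch: matrix {matrix.scheme.name} vs "
            f"DFP {dfp.scheme.name}"
        )
    ref = dfp.bits.astype(np.int64)
    rows = matrix.bits.astype(np.int64)
    inter = rows @ ref
    union = rows.sum(axis=1) + int(ref.sum()) - inter
    values = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return SimilaritySummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_pairs_or_mols=matrix.n,
        method="vs_dfp_tanimoto",
    )


def inter_set_matrix(dfps: list[DatabaseFingerprint],
                     metric: str = "city_block") -> DistanceMatrix:
    """Pairwise distance matrix between database fingerprints."""
    if len(dfps) < 2:
        raise InputError("need at least 2 DFPs to compare")
    if metric not in METRICS:
        raise UsageError(f"unknown metric {metric!r}; choose from {METRICS}")
    lengths = {d.length for d in dfps}
    if len(lengths) != 1:
        raise ValidationError(f"mixed DFP lengths: {sorted(lengths)}")
    k = len(dfps)
    values = np.zeros((k, k), dtype=np.float64)
    for i in range(k):
        for j in range(i + 1, k):
            if metric == "city_block":
                d = city_block(dfps[i].bits, dfps[j].bits)
            else:
                d = 1.0 - tanimoto(dfps[i].bits, dfps[j].bits)
            values[i, j] = values[j, i] = d
    labels = [d.source_label or f"dfp{i}" for i, d in enumerate(dfps)]
    return DistanceMatrix(labels=labels, values=values, metric=metric)
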