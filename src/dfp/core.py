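"""Construction of the database fingerprint (DFP).

The DFP compresses an entire compound library into a single length-L
binary vector: bit i of the DFP is set if and only if the fraction of
library molecules setting bit i *strictly exceeds* a probability
threshold t (a probability equal to the threshold yields 0).  Three
threshold strategies are supported:

``fixed``
    A user-supplied t in [0, 1); 0.5 is the conventional default for
    881-bit PubChem workflows.
``random_reference_mean``
    t is the mean per-bit probability of a seeded random reference set
    (by default 1500 random 166-bit vectors with each bit set with
    probability 0.5).
``mean_plus_sd``
    t is the mean of the library's own bit probabilities plus one
    sample standard deviation (denominator L-1), clipped below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .entropy import ProbabilityProfile, bit_probabilities
from .errors import UsageError
from .schemes import BitMatrix, FingerprintScheme, MACCS166

__all__ = [
    "DatabaseFingerprint",
    "build_dfp",
    "threshold_random_reference",
    "threshold_mean_plus_sd",
    "build_dfp_for_database",
    "STRATEGIES",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("fixed", "random_reference_mean", "mean_plus_sd")


@dataclass(eq=False)
class DatabaseFingerprint:
    """A length-L binary summary vector of a compound library."""

    bits: np.ndarray
    threshold: float
    strategy: str
    n_source: int
    scheme: FingerprintScheme
    source_label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)

    @property
    def popcount(self) -> int:
        """Number of set bits."""
        return int(self.bits.sum())

    @property
    def length(self) -> int:
        return len(self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatabaseFingerprint):
            return NotImplemented
        return (
            np.array_equal(self.bits, other.bits)
            and self.threshold == other.threshold
            and self.strategy == other.strategy
            and self.n_source == other.n_source
            and self.scheme == other.scheme
            and self.source_label == other.source_label
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DatabaseFingerprint(L={self.length}, popcount={self.popcount}, "
            f"t={self.threshold:.4g}, strategy={self.strategy}, "
            f"n={self.n_source}, label={self.source_label!r})"
        )


def _check_threshold(threshold: float) -> float:
    threshold = float(threshold)
    if not 0.0 <= threshold < 1.0:
        raise UsageError(
            f"threshold must lie in [0, 1); got {threshold} "
            "(a threshold >= 1 would produce an uninformative all-zero DFP)"
        )
    return threshold


def build_dfp(profile: ProbabilityProfile, threshold: float,
              strategy: str = "fixed") -> DatabaseFingerprint:
    """Threshold a probability profile into a database fingerprint.

    Bit i is 1 iff p_i > threshold (strict); p_i == threshold gives 0.
    """
    threshold = _check_threshold(threshold)
    bits = (profile.probabilities > threshold).astype(np.uint8)
    return DatabaseFingerprint(
        bits=bits,
        threshold=threshold,
        strategy=strategy,
        n_source=profile.n,
        scheme=profile.scheme,
        source_label=profile.source_label,
    )


def threshold_random_reference(
    scheme: FingerprintScheme = MACCS166,
    n_random: int = 1500,
    p: float = 0.5,
    seed: int | None = None,
) -> float:
    """Mean per-bit probability of a seeded random reference set.

    Generates ``n_random`` random fingerprints of length ``scheme.length``
    with independent Bernoulli(p) bits and returns the mean of the
    resulting per-bit probabilities.  The defaults mirror a reference of
    1500 random 166-bit vectors.
    """
    if n_random < 1:
        raise UsageError("n_random must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"p must lie in [0, 1]; got {p}")
    from .synthetic import generate_random_reference

    reference = generate_random_reference(
        n=n_random, scheme=scheme, p=p, seed=seed
    )
    return float(bit_probabilities(reference).probabilities.mean())


def threshold_mean_plus_sd(profile: ProbabilityProfile) -> float:
    """Library mean bit probability plus one sample standard deviation.

    The sample SD uses denominator L-1; the result is clipped into
    [0, 1) so it remains a usable strict threshold.
    """
    if profile.length < 2:
        raise UsageError("mean_plus_sd needs at least 2 bit positions")
    p = profile.probabilities
    value = float(p.mean() + p.std(ddof=1))
    return float(np.clip(value, 0.0, np.nextafter(1.0, 0.0)))


def build_dfp_for_database(
    matrix: BitMatrix,
    strategy: str = "fixed",
    threshold: float | None = None,
    n_random: int = 1500,
    p_random: float = 0.5,
    seed: int | None = None,
) -> DatabaseFingerprint:
    """Profile a library and build its DFP under the chosen strategy.

    ``fixed`` uses ``threshold`` (default 0.5); the other strategies
    derive the threshold as documented on their functions.
    """
    if strategy not in STRATEGIES:
        raise UsageError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        )
    profile = bit_probabilities(matrix)
    if strategy == "fixed":
        t = 0.5 if threshold is None else threshold
    elif strategy == "random_reference_mean":
        t = threshold_random_reference(
            scheme=matrix.scheme, n_random=n_random, p=p_random, seed=seed
        )
    else:
        t = threshold_mean_plus_sd(profile)
    dfp = build_dfp(profile, t, strategy=strategy)
    logger.info(
        "DFP for %s: n=%d, threshold=%.4f (%s), popcount=%d/%d",
        matrix.source_label or "<unnamed>", matrix.n, dfp.threshold,
        strategy, dfp.popcount, dfp.length,
    )
    return dfp
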