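"""Per-bit probability profiles and Shannon-entropy diversity metrics.

For a library of n molecules represented by length-L binary
fingerprints, the *probability profile* is the vector p with
p_i = (number of molecules setting bit i) / n.  The Shannon entropy (SE)
of the profile, summed over bit positions, serves as a fingerprint-based
diversity metric: a maximally diverse (random-like) library has p_i near
0.5 everywhere and high SE, while a homogeneous library drives p_i
toward 0 or 1 and SE toward 0.

Two per-bit entropy variants are exposed:

``binary`` (default)
    H(p) = -p log2 p - (1-p) log2 (1-p), the entropy of the Bernoulli
    bit; bounded by 1 bit per position, maximal at p = 0.5.
``ones_term``
    -p log2 p only; bounded by log2(e)/e ~ 0.5307 per position, maximal
    at p = 1/e.  Provided because some published SE magnitudes on
    166-bit fingerprints are consistent with this reduced sum.

Differential Shannon entropy (DSE) between two libraries is the entropy
of the pooled bit distribution minus the average entropy of the two
component distributions; under equal weighting it is non-negative by
concavity and flags bit positions whose usage differs between the
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, UsageError, ValidationError
from .schemes import BitMatrix, FingerprintScheme

__all__ = [
    "ProbabilityProfile",
    "EntropyReport",
    "DseVector",
    "bit_probabilities",
    "bernoulli_entropy",
    "shannon_entropy",
    "differential_shannon_entropy",
]

ENTROPY_MODES = ("binary", "ones_term")
DSE_WEIGHTINGS = ("equal", "size_weighted")


@dataclass(eq=False)
class ProbabilityProfile:
    """Per-bit set counts and probabilities of one library."""

    counts: np.ndarray
    n: int
    scheme: FingerprintScheme
    source_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n < 1:
            raise InputError("profile requires n >= 1")
        if self.counts.ndim != 1 or len(self.counts) != self.scheme.length:
            raise ValidationError("counts length must equal scheme length")
        if (self.counts < 0).any() or (self.counts > self.n).any():
            raise ValidationError("counts must lie in [0, n]")

    @property
    def probabilities(self) -> np.ndarray:
        """Exact per-bit probabilities counts / n (no smoothing)."""
        return self.counts / self.n

    @property
    def length(self) -> int:
        return len(self.counts)


@dataclass
class EntropyReport:
    """Per-bit and total Shannon entropy of a profile, in bits."""

    per_bit: np.ndarray
    mode: str
    source_label: str = ""

    @property
    def total(self) -> float:
        return float(self.per_bit.sum())

    @property
    def mean(self) -> float:
        return float(self.per_bit.mean())


@dataclass
class DseVector:
    """Per-bit differential Shannon entropy between two libraries."""

    per_bit: np.ndarray
    weighting: str
    labels: tuple[str, str]

    @property
    def total(self) -> float:
        return float(self.per_bit.sum())


def bit_probabilities(matrix: BitMatrix) -> ProbabilityProfile:
    """Record per-bit set frequencies and probabilities of a library."""
    counts = matrix.bits.sum(axis=0, dtype=np.int64)
    return ProbabilityProfile(
        counts=counts,
        n=matrix.n,
        scheme=matrix.scheme,
        source_label=matrix.source_label,
    )


def bernoulli_entropy(p: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Elementwise bit entropy in bits, with 0 * log2(0) := 0."""
    if mode not in ENTROPY_MODES:
        raise UsageError(
            f"unknown entropy mode {mode!r}; choose from {ENTROPY_MODES}"
        )
    p = np.asarray(p, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ones = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        if mode == "ones_term":
            return ones
        q = 1.0 - p
        zeros = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
    return ones + zeros


def shannon_entropy(profile: ProbabilityProfile,
                    mode: str = "binary") -> EntropyReport:
    """Shannon entropy of a library's bit-probability distribution.

    Returns per-bit entropies and, through :attr:`EntropyReport.total`,
    the total SE summed over the L bit positions.
    """
    per_bit = bernoulli_entropy(profile.probabilities, mode=mode)
    return EntropyReport(per_bit=per_bit, mode=mode,
                         source_label=profile.source_label)


def differential_shannon_entropy(
    a: ProbabilityProfile,
    b: ProbabilityProfile,
    weighting: str = "size_weighted",
) -> DseVector:
    """Per-bit DSE between two libraries.

    DSE_i = H(pooled p_i) - (H(p_a,i) + H(p_b,i)) / 2 with binary-mode
    bit entropy H.  ``size_weighted`` pools the raw counts,
    (c_a + c_b) / (n_a + n_b); ``equal`` weights both libraries equally
    regardless of size by pooling probabilities, (p_a + p_b) / 2, which
    guarantees DSE_i >= 0 by concavity of H.
    """
    if weighting not in DSE_WEIGHTINGS:
        raise UsageError(
            f"unknown weighting {weighting!r}; choose from {DSE_WEIGHTINGS}"
        )
    if a.length != b.length:
        raise ValidationError(
            f"profile lengths differ ({a.length} vs {b.length})"
        )
    pa, pb = a.probabilities, b.probabilities
    if weighting == "equal":
        pooled = (pa + pb) / 2.0
    else:
        pooled = (a.counts + b.counts) / (a.n + b.n)
    per_bit = bernoulli_entropy(pooled) - (
        bernoulli_entropy(pa) + bernoulli_entropy(pb)
    ) / 2.0
    return DseVector(
        per_bit=per_bit,
        weighting=weighting,
        labels=(a.source_label, b.source_label),
    )
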