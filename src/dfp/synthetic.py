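"""Seeded generators for random references and structured test libraries.

Real compound libraries are proprietary or large; these generators
produce Bernoulli bit matrices whose per-bit probability profiles and
optional within-block correlation emulate libraries of controlled
diversity.  All generators are pure functions of their parameters and a
seed, using NumPy's PCG64 generator, so outputs are reproducible across
runs and platforms.

The random reference — by default 1500 fingerprints of 166 bits with
every bit set independently with probability 0.5 — plays the role of a
maximally diverse library: it calibrates both the entropy scale (total
SE above 80 on 166 bits) and the Tanimoto scale (mean pairwise
similarity near 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError, ValidationError
from .schemes import BitMatrix, FingerprintScheme, MACCS166

__all__ = [
    "LibrarySpec",
    "generate_random_reference",
    "generate_library",
    "make_library_ladder",
]


@dataclass
class LibrarySpec:
    """Recipe for one synthetic library.

    ``profile`` gives the target marginal probability of each bit.
    ``blocks`` lists disjoint groups of bit indices with a target
    within-block pairwise correlation rho in [0, 1); correlation is
    induced by a shared latent uniform draw that each block bit copies
    with probability sqrt(rho), which yields pairwise correlation rho
    for equal-probability bits while preserving every marginal exactly.
    """

    n: int
    scheme: FingerprintScheme
    profile: np.ndarray
    seed: int
    label: str = "synthetic"
    blocks: list[tuple[list[int], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.n < 1:
            raise UsageError("library size n must be >= 1")
        if self.profile.shape != (self.scheme.length,):
            raise ValidationError("profile length must equal scheme length")
        if ((self.profile < 0) | (self.profile > 1)).any():
            raise UsageError("profile probabilities must lie in [0, 1]")
        seen: set[int] = set()
        for indices, rho in self.blocks:
            if not 0.0 <= rho < 1.0:
                raise UsageError("block correlation must lie in [0, 1)")
            idx = set(int(i) for i in indices)
            if not all(0 <= i < self.scheme.length for i in idx):
                raise ValidationError("block index out of range")
            if idx & seen:
                raise ValidationError("correlated blocks must be disjoint")
            seen |= idx


def generate_random_reference(
    n: int = 1500,
    scheme: FingerprintScheme = MACCS166,
    p: float = 0.5,
    seed: int | None = None,
) -> BitMatrix:
    """Random fingerprints with independent Bernoulli(p) bits.

    Defaults emulate the standard random reference: 1500 vectors of
    166 bits at p = 0.5.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"p must lie in [0, 1]; got {p}")
    rng = np.random.default_rng(seed)
    bits = (rng.random((n, scheme.length)) < p).astype(np.uint8)
    width = len(str(n))
    ids = [f"R{i:0{width}d}" for i in range(1, n + 1)]
    return BitMatrix(ids=ids, bits=bits, scheme=scheme,
                     source_label="random")


def generate_library(spec: LibrarySpec) -> BitMatrix:
    """Draw a synthetic library from a :class:`LibrarySpec`.

    Bits outside correlated blocks are independent Bernoulli draws from
    the profile; each block mixes an independent uniform with a shared
    per-molecule latent uniform so that empirical per-bit frequencies
    still converge to the profile as n grows.
    """
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n, spec.scheme.length
    uniforms = rng.random((n, length))
    for indices, rho in spec.blocks:
        if rho == 0.0:
            continue  # degenerate block: identical to independent draws
        idx = np.asarray(sorted(int(i) for i in indices))
        mix = np.sqrt(rho)
        shared = rng.random((n, 1))
        use_shared = rng.random((n, len(idx))) < mix
        uniforms[:, idx] = np.where(use_shared, shared, uniforms[:, idx])
    bits = (uniforms < spec.profile).astype(np.uint8)
    width = len(str(n))
    ids = [f"{spec.label}_{i:0{width}d}" for i in range(1, n + 1)]
    return BitMatrix(ids=ids, bits=bits, scheme=spec.scheme,
                     source_label=spec.label)


def make_library_ladder(
    k_levels: int,
    scheme: FingerprintScheme = MACCS166,
    seed: int | None = None,
    n_per_level: int = 500,
    d_max: float = 0.4,
) -> list[BitMatrix]:
    """Synthetic libraries of monotonically increasing homogeneity.

    Level j draws its per-bit profile uniformly from
    [0.5 - d_j, 0.5 + d_j] with d_j increasing linearly from 0 to
    ``d_max``.  The first level is statistically indistinguishable from
    the random reference; later levels push bit probabilities toward 0
    or 1, lowering entropy and raising mean pairwise similarity.  Used
    to test the inverse entropy-vs-similarity relationship.
    """
    if k_levels < 2:
        raise UsageError("ladder needs at least 2 levels")
    rng = np.random.default_rng(seed)
    spreads = np.linspace(0.0, d_max, k_levels)
    libraries = []
    for level, d in enumerate(spreads):
        profile = rng.uniform(0.5 - d, 0.5 + d, scheme.length)
        spec = LibrarySpec(
            n=n_per_level,
            scheme=scheme,
            profile=profile,
            seed=int(rng.integers(2**31)),
            label=f"ladder{level}",
        )
        libraries.append(generate_library(spec))
    return libraries
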