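"""Fingerprint schemes and the in-memory bit-matrix container.

A *scheme* names a fingerprint dictionary and fixes its length ``L``:
MACCS structural keys (166 bits), the PubChem substructure fingerprint
(881 bits), or a generic binary fingerprint of arbitrary length.  A
:class:`BitMatrix` holds one compound library as an ``n x L`` matrix over
{0, 1}, one molecule per row, together with unique molecule identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "FingerprintScheme",
    "MACCS166",
    "PUBCHEM881",
    "generic_scheme",
    "scheme_for_length",
    "BitMatrix",
]


@dataclass(frozen=True)
class FingerprintScheme:
    """A named binary-fingerprint dictionary of fixed length.

    Parameters
    ----------
    name:
        One of ``"MACCS166"``, ``"PUBCHEM881"`` or ``"GENERIC"``.
    length:
        Number of bit positions ``L``.  Forced to 166 for MACCS166 and
        881 for PUBCHEM881.
    """

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.name == "MACCS166" and self.length != 166:
            raise ValidationError("MACCS166 scheme requires length 166")
        if self.name == "PUBCHEM881" and self.length != 881:
            raise ValidationError("PUBCHEM881 scheme requires length 881")
        if self.name not in ("MACCS166", "PUBCHEM881", "GENERIC"):
            raise ValidationError(f"unknown scheme name {self.name!r}")
        if self.length < 1:
            raise ValidationError("scheme length must be >= 1")


MACCS166 = FingerprintScheme("MACCS166", 166)
PUBCHEM881 = FingerprintScheme("PUBCHEM881", 881)


def generic_scheme(length: int) -> FingerprintScheme:
    """A GENERIC scheme of the given bit length."""
    return FingerprintScheme("GENERIC", int(length))


def scheme_for_length(length: int) -> FingerprintScheme:
    """Map a bit length to its canonical scheme (166 and 881 are named)."""
    if length == 166:
        return MACCS166
    if length == 881:
        return PUBCHEM881
    return generic_scheme(length)


@dataclass(eq=False)
class BitMatrix:
    """A compound library as a binary fingerprint matrix.

    Rows are molecules, columns are fingerprint bit positions.  Values
    are stored as ``uint8`` over {0, 1}.  Identifiers must be unique
    within a matrix.
    """

    ids: list[str]
    bits: np.ndarray
    scheme: FingerprintScheme
    source_label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValidationError("bits must be a 2-D matrix")
        n, length = self.bits.shape
        if n < 1:
            raise ValidationError("a BitMatrix needs at least one molecule")
        if len(self.ids) != n:
            raise ValidationError(
                f"{len(self.ids)} ids for {n} fingerprint rows"
            )
        if length != self.scheme.length:
            raise ValidationError(
                f"matrix has {length} columns but scheme "
                f"{self.scheme.name} expects {self.scheme.length}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("bit matrix entries must be 0 or 1")
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate molecule identifier {dup!r}")

    @property
    def n(self) -> int:
        """Number of molecules."""
        return self.bits.shape[0]

    @property
    def length(self) -> int:
        """Number of bit positions L."""
        return self.bits.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BitMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.scheme == other.scheme
            and self.source_label == other.source_label
            and np.array_equal(self.bits, other.bits)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BitMatrix(n={self.n}, L={self.length}, "
            f"scheme={self.scheme.name}, label={self.source_label!r})"
        )
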