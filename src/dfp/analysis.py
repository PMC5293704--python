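"""Multi-library analytics: significant-bit selection, library summary
tables, and k-means grouping of libraries.

Working across several libraries at once, this module (a) selects the
informationally significant bit positions — those that either survive
some library's DFP threshold, carry pooled entropy above a cutoff, or
discriminate between libraries by differential Shannon entropy; (b)
summarizes each library by its average per-bit entropy and its mean
molecule-vs-DFP Tanimoto similarity; and (c) clusters libraries in that
two-dimensional entropy/similarity plane with seeded k-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .core import build_dfp
from .entropy import (
    ProbabilityProfile,
    bernoulli_entropy,
    bit_probabilities,
    differential_shannon_entropy,
)
from .errors import InputError, UsageError, ValidationError
from .schemes import BitMatrix, generic_scheme
from .similarity import intra_set_vs_dfp

__all__ = [
    "BitSelection",
    "LibrarySummaryRow",
    "ClusterResult",
    "select_significant_bits",
    "summarize_libraries",
    "kmeans_libraries",
    "SELECTION_RULES",
]

SELECTION_RULES = ("union_of_dfps", "pooled_entropy_cutoff", "dse_cutoff")


@dataclass
class BitSelection:
    """Sorted 0-based indices of informationally significant bits."""

    selected: list[int]
    rule: str
    threshold_used: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_text(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{i}\n" for i in self.selected)
        )


@dataclass
class LibrarySummaryRow:
    """One library's position in the entropy/similarity plane."""

    label: str
    n: int
    se_mean: float
    dfp_similarity_mean: float


@dataclass(eq=False)
class ClusterResult:
    """Seeded k-means assignment of libraries to clusters."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    inertia: float
    seed: int | None
    n_restarts: int
    standardized: bool


def select_significant_bits(
    profiles: list[ProbabilityProfile],
    dfp_threshold: float = 0.5,
    rule: str = "union_of_dfps",
    cutoff: float = 0.0,
    combine_with_dfp: bool = False,
) -> BitSelection:
    """Select the informationally significant bit positions.

    Rules:

    ``union_of_dfps`` (default)
        A bit is selected iff it is set in at least one library's DFP
        at ``dfp_threshold``.  Fully determined by the thresholding
        rule; raising the threshold can only shrink the selection.
    ``pooled_entropy_cutoff``
        Binary entropy of the size-weighted pooled profile >= ``cutoff``.
    ``dse_cutoff``
        Maximum pairwise equal-weighted DSE over all library pairs
        >= ``cutoff``.

    With ``combine_with_dfp`` the entropy/DSE rules are additionally
    restricted to bits surviving the DFP-union filter.
    """
    if len(profiles) < 2:
        raise InputError("bit selection requires at least 2 profiles")
    if rule not in SELECTION_RULES:
        raise UsageError(f"unknown rule {rule!r}; choose from {SELECTION_RULES}")
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise ValidationError(f"mixed profile lengths: {sorted(lengths)}")

    union = np.zeros(profiles[0].length, dtype=bool)
    for profile in profiles:
        union |= build_dfp(profile, dfp_threshold).bits.astype(bool)

    if rule == "union_of_dfps":
        mask = union
        threshold_used = dfp_threshold
    elif rule == "pooled_entropy_cutoff":
        total_counts = np.sum([p.counts for p in profiles], axis=0)
        total_n = sum(p.n for p in profiles)
        mask = bernoulli_entropy(total_counts / total_n) >= cutoff
        threshold_used = cutoff
    else:  # dse_cutoff
        best = np.zeros(profiles[0].length)
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                dse = differential_shannon_entropy(
                    profiles[i], profiles[j], weighting="equal"
                )
                best = np.maximum(best, dse.per_bit)
        mask = best >= cutoff
        threshold_used = cutoff
    if combine_with_dfp and rule != "union_of_dfps":
        mask &= union
    return BitSelection(
        selected=[int(i) for i in np.flatnonzero(mask)],
        rule=rule,
        threshold_used=float(threshold_used),
    )


def summarize_libraries(
    matrices: list[BitMatrix],
    dfp_threshold: float = 0.5,
    bit_selection: BitSelection | None = None,
) -> list[LibrarySummaryRow]:
    """Per-library average bit entropy and mean molecule-vs-DFP similarity.

    If a :class:`BitSelection` is given, both quantities are computed on
    the selected columns only (the library size n is unaffected).
    """
    if not matrices:
        raise InputError("no libraries to summarize")
    schemes = {m.scheme for m in matrices}
    if len(schemes) != 1:
        raise ValidationError("libraries must share a fingerprint scheme")
    rows = []
    for matrix in matrices:
        if bit_selection is not None:
            sub = BitMatrix(
                ids=matrix.ids,
                bits=matrix.bits[:, bit_selection.selected],
                scheme=generic_scheme(bit_selection.n_selected),
                source_label=matrix.source_label,
            )
        else:
            sub = matrix
        profile = bit_probabilities(sub)
        se_mean = float(bernoulli_entropy(profile.probabilities).mean())
        dfp = build_dfp(profile, dfp_threshold)
        summary = intra_set_vs_dfp(sub, dfp)
        rows.append(
            LibrarySummaryRow(
                label=matrix.source_label,
                n=matrix.n,
                se_mean=se_mean,
                dfp_similarity_mean=summary.mean,
            )
        )
    return rows


def kmeans_libraries(
    rows: list[LibrarySummaryRow],
    k: int = 5,
    seed: int | None = None,
    n_restarts: int = 10,
    standardize: bool = True,
) -> ClusterResult:
    """Cluster libraries in the (entropy, DFP-similarity) plane.

    Lloyd's algorithm with seeded random-point initialization, keeping
    the best inertia over ``n_restarts`` restarts (300 iterations max).
    With ``standardize`` (default) both axes are z-scored first so
    entropy and similarity contribute on comparable scales; centroids
    and inertia are then reported in the standardized space.
    """
    if k < 1:
        raise UsageError("k must be >= 1")
    if k > len(rows):
        raise UsageError(f"k={k} exceeds number of libraries ({len(rows)})")
    points = np.array(
        [[r.se_mean, r.dfp_similarity_mean] for r in rows], dtype=np.float64
    )
    if standardize:
        scale = points.std(axis=0)
        scale[scale == 0] = 1.0
        points = (points - points.mean(axis=0)) / scale
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        max_iter=300,
        algorithm="lloyd",
        random_state=None if seed is None else int(seed) % (2**32),
    ).fit(points)
    return ClusterResult(
        labels=km.labels_.astype(int),
        k=k,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
        standardized=standardize,
    )
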