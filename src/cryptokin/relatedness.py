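"""Matched-segment relatedness scoring and threshold classification.

For each 30 kb segment the number of identical haplotypes between two
individuals is 0, 1 or 2 (multiset intersection of the two-element segment
value multisets, cross-haplotype matches included).  Summed genome-wide this
gives the relatedness statistic ``total_matched`` ∈ [0, 2s]; a pair is
called related when ``total_matched >= t``.  The equivalent distance form is
``2s - total_matched`` (distance below a cut-off ⟺ similarity above it);
this module standardizes on the similarity form because that is what the
score histograms display.

The threshold t is calibrated from labeled training pairs: the floor
midpoint of the separating gap when the classes separate, otherwise the
error-minimizing cut found by exhaustive scan (ties broken toward lower t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_encoding import GenomicSet

__all__ = [
    "PairScore",
    "Threshold",
    "segment_score",
    "similarity",
    "similarity_from_values",
    "classify",
    "calibrate_threshold",
    "score_matrix",
    "score_histogram",
]


@dataclass(frozen=True)
class PairScore:
    """Per-segment 0/1/2 match scores and their genome-wide sum for one pair."""

    id_a: str
    id_b: str
    per_segment: Tuple[int, ...]
    total_matched: int

    def __post_init__(self) -> None:
        if self.total_matched != sum(self.per_segment):
            raise ValueError("total_matched must equal the per-segment sum")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


@dataclass(frozen=True)
class Threshold:
    """Classification threshold in matched-segment units."""

    t: int
    provenance: str = "configured"  # or "calibrated"

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("threshold must be non-negative")


def _pair_match(a1: int, a2: int, b1: int, b2: int) -> int:
    """Multiset intersection size of {a1,a2} and {b1,b2} (0, 1 or 2)."""
    direct = (a1 == b1) + (a2 == b2)
    crossed = (a1 == b2) + (a2 == b1)
    return min(2, max(direct, crossed))


def segment_score(a: GenomicSet, b: GenomicSet, j: int) -> int:
    """Shared-haplotype count for segment j between two individuals."""
    if a.params != b.params:
        raise ValueError("genomic sets were built with different encoding params")
    if not 0 <= j < a.n_segments:
        raise IndexError(f"segment index {j} out of range")
    a1, a2 = a.segment_elements(j)
    b1, b2 = b.segment_elements(j)
    return _pair_match(a1, a2, b1, b2)


def similarity(a: GenomicSet, b: GenomicSet) -> PairScore:
    """Genome-wide matched-segment score between two individuals."""
    if a.params != b.params:
        raise ValueError("genomic sets were built with different encoding params")
    per_seg = similarity_from_values(
        [a.segment_elements(j) for j in range(a.n_segments)],
        [b.segment_elements(j) for j in range(b.n_segments)],
    )
    return PairScore(a.individual_id, b.individual_id, tuple(per_seg), int(sum(per_seg)))


def similarity_from_values(
    a_segments: Sequence[Tuple[int, int]], b_segments: Sequence[Tuple[int, int]]
) -> List[int]:
    """Per-segment 0/1/2 scores from raw per-segment element value pairs."""
    if len(a_segments) != len(b_segments):
        raise ValueError("segment counts differ")
    return [
        _pair_match(a1, a2, b1, b2)
        for (a1, a2), (b1, b2) in zip(a_segments, b_segments)
    ]


def classify(score: PairScore, threshold: Threshold) -> str:
    """'related' iff total_matched >= t (the boundary itself counts as related)."""
    return "related" if score.total_matched >= threshold.t else "unrelated"


def calibrate_threshold(labeled: Iterable[Tuple[PairScore, str]]) -> Threshold:
    """Pick t from training pairs with known labels.

    Separable classes -> floor midpoint of [max unrelated, min related].
    Overlapping classes -> exhaustive scan over candidate cuts minimizing
    training misclassifications, ties resolved toward the lower t.
    """
    related = []
    unrelated = []
    for score, label in labeled:
        if label == "related":
            related.append(score.total_matched)
        elif label == "unrelated":
            unrelated.append(score.total_matched)
        else:
            raise ValueError(f"unknown label {label!r}")
    if not related or not unrelated:
        raise ValueError("calibration needs at least one pair of each class")
    lo, hi = max(unrelated), min(related)
    if lo < hi:
        return Threshold((lo + hi) // 2, provenance="calibrated")
    # overlapping: scan every candidate cut (each observed score and score+1)
    candidates = sorted(set(related) | set(unrelated) | {s + 1 for s in unrelated})
    best_t, best_err = None, None
    rel = np.array(related)
    unr = np.array(unrelated)
    for t in candidates:
        err = int((rel < t).sum() + (unr >= t).sum())
        if best_err is None or err < best_err or (err == best_err and t < best_t):
            best_t, best_err = t, err
    return Threshold(int(best_t), provenance="calibrated")


def score_matrix(
    scores: Iterable[PairScore], labels: dict | None = None
) -> pd.DataFrame:
    """Pairwise score table (id_a, id_b, total_matched, label) for TSV export."""
    rows = []
    for s in scores:
        label = labels.get(s.pair, "") if labels else ""
        rows.append((s.id_a, s.id_b, s.total_matched, label))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "total_matched", "label"])


def score_histogram(
    scores_by_label: dict, bin_width: int = 10
) -> pd.DataFrame:
    """Binned matched-segment counts per relationship class, long format
    (label, bin_left, count) — the data behind the separation histograms."""
    rows = []
    for label, values in scores_by_label.items():
        vals = np.asarray(list(values), dtype=np.int64)
        if vals.size == 0:
            continue
        bins = vals // bin_width
        for b, c in zip(*np.unique(bins, return_counts=True)):
            rows.append((label, int(b) * bin_width, int(c)))
    return pd.DataFrame(rows, columns=["label", "bin_left", "count"])
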