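"""Pairwise motif similarity via ungapped forward/reverse-complement alignment.

Two PWMs are compared by sliding one along the other at every ungapped
offset, in the forward orientation and (by default) also as the reverse
complement.  Each aligned column pair contributes

    colsim(a, b) = 1 - ||a - b||_2 / sqrt(2)

which is 1 for identical columns and 0 for maximally distant one-hot
columns (the largest possible Euclidean distance between two stochastic
4-vectors is sqrt(2)).  The alignment score is the mean column similarity
over the overlapping columns only; a minimum-overlap rule prevents
spurious high scores from one- or two-column overlaps.

The n x n matrix of best alignment scores is the similarity matrix fed to
affinity propagation, to cluster quality assessment and to database
search.  Its diagonal is left unset here; the clustering preference fills
it in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pwm import PWM, PWMCollection

SQRT2 = math.sqrt(2.0)


def column_similarity(a, b) -> float:
    """Similarity of two stochastic 4-vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for v in (a, b):
        if v.shape != (4,) or abs(v.sum() - 1.0) > 1e-6 or np.any(v < 0):
            raise ValueError("column_similarity expects stochastic 4-vectors")
    return float(1.0 - np.linalg.norm(a - b) / SQRT2)


def default_min_overlap(l_p: int, l_q: int) -> int:
    """max(4, half the shorter motif), never exceeding the shorter motif."""
    shorter = min(l_p, l_q)
    return min(shorter, max(4, math.ceil(0.5 * shorter)))


@dataclass(frozen=True)
class AlignmentResult:
    """Best ungapped alignment of a query PWM against a target PWM.

    ``offset`` is the shift of the (possibly reverse-complemented) query
    start relative to the target start; ``overlap`` counts aligned columns.
    """

    score: float
    offset: int
    orientation: str  # "forward" | "revcomp"
    overlap: int


def _colsims(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return 1.0 - np.linalg.norm(p - q, axis=1) / SQRT2


def _best_alignment(p: np.ndarray, q: np.ndarray, min_overlap: int,
                    orientation: str) -> Optional[AlignmentResult]:
    l_p, l_q = p.shape[0], q.shape[0]
    best = None
    for offset in range(-(l_q - min_overlap), l_p - min_overlap + 1):
        lo = max(0, offset)
        hi = min(l_p, offset + l_q)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        score = float(_colsims(p[lo:hi], q[lo - offset:hi - offset]).mean())
        key = (score, overlap, -abs(offset))
        if best is None or key > best[0]:
            best = (key, AlignmentResult(score, offset, orientation, overlap))
    return None if best is None else best[1]


def motif_similarity(p: PWM, q: PWM, min_overlap: Optional[int] = None,
                     use_revcomp: bool = True) -> AlignmentResult:
    """Best alignment of ``q`` against ``p`` over all offsets/orientations.

    Ties are broken by larger overlap, then smaller absolute offset, then
    the forward orientation.  The score is symmetric in ``p`` and ``q``.
    """
    if min_overlap is None:
        min_overlap = default_min_overlap(len(p), len(q))
    elif min_overlap > min(len(p), len(q)):
        raise ValueError(
            f"min_overlap {min_overlap} exceeds the shorter motif "
            f"({min(len(p), len(q))} columns): no feasible alignment"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    fwd = _best_alignment(p.matrix, q.matrix, min_overlap, "forward")
    if not use_revcomp:
        return fwd
    rev = _best_alignment(
        p.matrix, q.reverse_complement().matrix, min_overlap, "revcomp"
    )
    # strictly better reverse score wins; ties keep the forward orientation
    if (rev.score, rev.overlap, -abs(rev.offset)) > (
        fwd.score, fwd.overlap, -abs(fwd.offset)
    ):
        return rev
    return fwd


class SimilarityMatrix:
    """Symmetric n x n matrix of pairwise motif similarity scores.

    The diagonal is NaN until :func:`pwmclust.cluster.set_preference`
    fills it with the affinity-propagation preference.
    """

    def __init__(self, values: np.ndarray, names: Sequence[str],
                 diagonal_policy: str = "unset") -> None:
        values = np.asarray(values, dtype=float)
        n = len(names)
        if values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match names")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(values, values.T, atol=1e-9, equal_nan=True):
            raise ValueError("similarity matrix is not symmetric")
        if np.any(values[off] < -1e-9) or np.any(values[off] > 1 + 1e-9):
            raise ValueError("off-diagonal similarities outside [0, 1]")
        self.values = values
        self.names = list(names)
        self.diagonal_policy = diagonal_policy

    def __len__(self) -> int:
        return len(self.names)

    def submatrix(self, names: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.names.index(n) for n in names]
        return SimilarityMatrix(
            self.values[np.ix_(idx, idx)], list(names), self.diagonal_policy
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pwm\t" + "\t".join(self.names) + "\n")
            for i, name in enumerate(self.names):
                cells = [
                    "NA" if i == j or np.isnan(v) else f"{v:.6f}"
                    for j, v in enumerate(self.values[i])
                ]
                fh.write(name + "\t" + "\t".join(cells) + "\n")


def similarity_matrix(collection: PWMCollection,
                      min_overlap: Optional[int] = None,
                      use_revcomp: bool = True,
                      workers: int = 1) -> SimilarityMatrix:
    """All-pairs best alignment scores for a collection (n >= 2).

    The pair list may be evaluated in any order or partition; the result
    is identical regardless of ``workers`` (kept for interface parity —
    pairs are cheap enough that evaluation is sequential).
    """
    n = len(collection)
    if n < 2:
        raise ValueError("similarity matrix needs at least 2 PWMs")
    pwms = list(collection)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            s = motif_similarity(pwms[i], pwms[j], min_overlap, use_revcomp)
            values[i, j] = values[j, i] = s.score
    return SimilarityMatrix(values, collection.names)
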