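"""Core position weight matrix (PWM) data model.

A PWM is an L x 4 column-stochastic matrix over the alphabet A, C, G, T:
row i gives the probability of observing each nucleotide at position i of
a transcription-factor binding site.  All downstream computation
(similarity scoring, clustering, quality assessment, search) operates on
this one type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

ALPHABET = ("A", "C", "G", "T")

#: IUPAC degeneracy codes keyed by the sorted set of admitted bases.
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

ROW_TOL = 1e-6


class PWMError(ValueError):
    """Invalid PWM content (negative entries, bad shape, degenerate rows)."""


def normalize(matrix: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Row-normalize an L x 4 nonnegative matrix to a stochastic matrix.

    ``pseudocount`` is added to every cell before dividing by the row sum,
    so an all-zero row is admissible only with a positive pseudocount.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise PWMError(f"expected an L x 4 matrix, got shape {m.shape}")
    if np.any(m < 0):
        raise PWMError("negative entry in PWM matrix")
    if pseudocount < 0:
        raise PWMError("pseudocount must be >= 0")
    m = m + pseudocount
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums <= 0)[0])
        raise PWMError(f"row {bad} sums to zero and pseudocount is 0")
    return m / sums[:, None]


@dataclass(frozen=True)
class PWM:
    """A named L x 4 column-stochastic matrix in A,C,G,T order.

    ``counts_total`` keeps the original per-row count sums when the input
    was a count matrix, so that count-bearing files round-trip losslessly.
    """

    name: str
    matrix: np.ndarray
    source_format: str = "plain"
    counts_total: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise PWMError(
                f"PWM {self.name!r}: expected L x 4 with L >= 1, got {m.shape}"
            )
        if np.any(m < 0):
            raise PWMError(f"PWM {self.name!r}: negative probability")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > ROW_TOL):
            raise PWMError(f"PWM {self.name!r}: rows are not normalized")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        if self.counts_total is not None:
            ct = np.asarray(self.counts_total, dtype=float)
            ct.setflags(write=False)
            object.__setattr__(self, "counts_total", ct)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def tf_symbol(self) -> str:
        """TF symbol recovered from the PWM name.

        Collections commonly carry several matrices for one factor,
        distinguished by a trailing ``_<digits>`` suffix (ATF4, ATF4_1, ...);
        the suffix is stripped and the symbol upper-cased.
        """
        return re.sub(r"_\d+$", "", self.name).upper()

    def reverse_complement(self) -> "PWM":
        """PWM of the reverse strand: rows reversed, A<->T and C<->G swapped."""
        rc = self.matrix[::-1, [3, 2, 1, 0]]
        ct = None if self.counts_total is None else self.counts_total[::-1]
        return PWM(self.name, rc, self.source_format, ct)

    def counts(self) -> Optional[np.ndarray]:
        """Original count matrix, if the source carried counts."""
        if self.counts_total is None:
            return None
        return self.matrix * self.counts_total[:, None]

    def consensus(self) -> str:
        """IUPAC consensus: per row, all bases within 1e-9 of the max share
        the position; degenerate sets map to IUPAC codes."""
        out = []
        for row in self.matrix:
            top = row.max()
            bases = frozenset(
                b for b, p in zip(ALPHABET, row) if p >= top - 1e-9
            )
            out.append(IUPAC[bases])
        return "".join(out)

    def with_name(self, name: str) -> "PWM":
        return PWM(name, self.matrix, self.source_format, self.counts_total)


def reverse_complement(pwm: PWM) -> PWM:
    return pwm.reverse_complement()


class PWMCollection:
    """Ordered collection of uniquely named PWMs with name-based lookup."""

    def __init__(self, pwms: Iterable[PWM] = ()) -> None:
        self._pwms: list[PWM] = []
        self._index: dict[str, int] = {}
        for p in pwms:
            self.add(p)

    def add(self, pwm: PWM) -> None:
        if pwm.name in self._index:
            raise PWMError(f"duplicate PWM name {pwm.name!r}")
        self._index[pwm.name] = len(self._pwms)
        self._pwms.append(pwm)

    def __len__(self) -> int:
        return len(self._pwms)

    def __iter__(self) -> Iterator[PWM]:
        return iter(self._pwms)

    def __getitem__(self, key) -> PWM:
        if isinstance(key, str):
            return self._pwms[self._index[key]]
        return self._pwms[key]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [p.name for p in self._pwms]

    def index_of(self, name: str) -> int:
        return self._index[name]

    def subset(self, names: Iterable[str]) -> "PWMCollection":
        return PWMCollection(self[n] for n in names)

    def __repr__(self) -> str:
        return f"PWMCollection({len(self)} PWMs)"
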