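"""Affinity propagation clustering of PWMs by message passing.

Clustering works directly on the motif similarity matrix: no cluster
count is chosen in advance.  Each point exchanges two messages with every
other point — the responsibility R(i,k), how well suited k is to serve as
the exemplar for i, and the availability A(i,k), how appropriate it would
be for i to choose k — until the exemplar set stabilizes:

    R(i,k) <- S(i,k) - max_{k' != k} { A(i,k') + S(i,k') }
    A(k,k) <- sum_{i' != k} max(0, R(i',k))
    A(i,k) <- min(0, R(k,k) + sum_{i' not in {i,k}} max(0, R(i',k)))
    C(i,k) =  R(i,k) + A(i,k)

Messages are damped (convex mixing of old and new values) to avoid
oscillation.  Points whose criterion diagonal C(k,k) is positive become
exemplars; every other point is assigned to its most similar exemplar.

The similarity-matrix diagonal — the *preference* — controls how many
exemplars emerge: smaller preferences give fewer, larger ones more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .similarity import SimilarityMatrix


class ConvergenceError(RuntimeError):
    """No exemplar emerged; advise raising the preference."""


@dataclass
class APParams:
    preference: str = "median"      # "median" | "min" | "value"
    preference_value: Optional[float] = None
    damping: float = 0.9
    max_iter: int = 1000
    convergence_window: int = 50

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must be in [0.5, 1)")
        if self.preference == "value" and self.preference_value is None:
            raise ValueError("preference mode 'value' requires a value")


@dataclass
class MessageState:
    R: np.ndarray
    A: np.ndarray
    iteration: int
    converged: bool

    @property
    def C(self) -> np.ndarray:
        return self.R + self.A


@dataclass
class ClusteringResult:
    exemplars: list[int]
    labels: np.ndarray          # per-point exemplar index
    names: list[str]
    params: APParams
    n_iterations_run: int
    converged: bool
    state: MessageState

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, exemplar: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == exemplar)]

    def clusters(self) -> dict[int, list[str]]:
        """Exemplar index -> member PWM names (exemplar included)."""
        return {
            k: [self.names[i] for i in self.members(k)] for k in self.exemplars
        }


def set_preference(S: SimilarityMatrix, mode: str = "median",
                   value: Optional[float] = None) -> SimilarityMatrix:
    """Fill the similarity-matrix diagonal with the clustering preference."""
    n = len(S)
    off = S.values[~np.eye(n, dtype=bool)]
    if mode == "median":
        pref = float(np.median(off))
    elif mode == "min":
        pref = float(np.min(off))
    elif mode == "value":
        if value is None:
            raise ValueError("preference mode 'value' requires a value")
        pref = float(value)
    else:
        raise ValueError(f"unknown preference mode {mode!r}")
    values = S.values.copy()
    np.fill_diagonal(values, pref)
    return SimilarityMatrix(values, S.names, diagonal_policy="preference")


def update_responsibility(S: np.ndarray, A_prev: np.ndarray) -> np.ndarray:
    """Undamped responsibility update (A_prev is all zeros on iteration 1)."""
    AS = A_prev + S
    n = S.shape[0]
    idx_max = AS.argmax(axis=1)
    first = AS[np.arange(n), idx_max]
    AS_masked = AS.copy()
    AS_masked[np.arange(n), idx_max] = -np.inf
    second = AS_masked.max(axis=1)
    R = S - first[:, None]
    R[np.arange(n), idx_max] = S[np.arange(n), idx_max] - second
    return R


def update_availability(R: np.ndarray) -> np.ndarray:
    """Undamped availability update from the current responsibilities.

    A(i,k) = min(0, R(k,k) + sum over i' outside {i,k} of max(0, R(i',k)))
    off the diagonal and A(k,k) = sum_{i' != k} max(0, R(i',k)), evaluated
    as one column sum minus the excluded entry so results are bit-stable.
    """
    tmp = np.maximum(R, 0.0)
    np.fill_diagonal(tmp, R.diagonal())
    tmp -= tmp.sum(axis=0)
    dA = np.diag(tmp).copy()                    # -A(k,k)
    np.clip(tmp, 0, np.inf, out=tmp)
    np.fill_diagonal(tmp, dA)
    return -tmp


def cluster(S: SimilarityMatrix, params: Optional[APParams] = None
            ) -> ClusteringResult:
    """Run damped message passing until the exemplar set is stable.

    Deterministic given S and params.  Raises :class:`ConvergenceError`
    when no point ever attains a positive criterion diagonal.
    """
    params = params or APParams()
    if S.diagonal_policy != "preference":
        S = set_preference(S, params.preference, params.preference_value)
    M = S.values
    n = M.shape[0]
    # degenerate case: every pair equally similar — message passing is
    # indifferent, so decide directly: a preference above the shared
    # similarity keeps every point separate, otherwise all points merge
    off_mask = ~np.eye(n, dtype=bool)
    if n > 1 and np.all(M[off_mask] == M[off_mask][0]) \
            and np.all(np.diag(M) == M[0, 0]):
        if M[0, 0] > M[off_mask][0]:
            exemplar_idx = list(range(n))
            labels = np.arange(n)
        else:
            exemplar_idx = [0]
            labels = np.zeros(n, dtype=int)
        state = MessageState(R=np.zeros((n, n)), A=np.zeros((n, n)),
                             iteration=0, converged=True)
        return ClusteringResult(
            exemplars=exemplar_idx, labels=labels, names=list(S.names),
            params=params, n_iterations_run=0, converged=True, state=state,
        )
    # machine-epsilon-scale jitter breaks exact-tie degeneracies (e.g. all
    # similarities equal to the preference, where messages stay zero and no
    # exemplar can emerge); the scaling and fixed seed follow the standard
    # degeneracy-removal convention for these updates, keeping the result a
    # pure function of S and params
    jitter_rng = np.random.RandomState(0)
    M_msg = M + (
        (np.finfo(float).eps * M + np.finfo(float).tiny * 100)
        * jitter_rng.standard_normal((n, n))
    )
    lam = params.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    stable = 0
    prev_exemplars: Optional[frozenset[int]] = None
    it = 0
    converged = False
    for it in range(1, params.max_iter + 1):
        R = lam * R + (1 - lam) * update_responsibility(M_msg, A)
        A = lam * A + (1 - lam) * update_availability(R)
        exemplars = frozenset(np.flatnonzero(np.diag(R + A) > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= params.convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars
    C = R + A
    exemplar_idx = sorted(np.flatnonzero(np.diag(C) > 0).tolist())
    if not exemplar_idx:
        raise ConvergenceError(
            "no exemplar emerged (all criterion diagonals <= 0); "
            "try a higher preference"
        )
    # post-processing: assign points, refine each exemplar to the cluster
    # medoid (member maximizing the within-cluster similarity sum), then
    # run one final assignment sweep; ties -> lowest index
    ex = np.array(exemplar_idx)
    labels = np.empty(n, dtype=int)
    for i in range(n):
        labels[i] = ex[int(np.argmax(M_msg[i, ex]))]
    labels[ex] = ex
    refined = []
    for k in ex:
        members = np.flatnonzero(labels == k)
        within = M_msg[np.ix_(members, members)].sum(axis=0)
        refined.append(int(members[int(np.argmax(within))]))
    ex = np.array(sorted(set(refined)))
    exemplar_idx = ex.tolist()
    for i in range(n):
        labels[i] = ex[int(np.argmax(M_msg[i, ex]))]
    labels[ex] = ex                              # exemplar self-assignment
    state = MessageState(R=R, A=A, iteration=it, converged=converged)
    return ClusteringResult(
        exemplars=exemplar_idx, labels=labels, names=list(S.names),
        params=params, n_iterations_run=it, converged=converged, state=state,
    )


def net_similarity(S: np.ndarray, labels: np.ndarray) -> float:
    """Sum of similarities of every point to its exemplar (exemplars
    contribute their preference); the objective affinity propagation
    maximizes."""
    return float(S[np.arange(len(labels)), labels].sum())
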