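"""Cluster quality assessment, outlier removal and representative motifs.

The only feature available for judging a cluster is the within-cluster
motif similarity submatrix, so quality is assessed from statistical
summaries of it:

* the cluster *mean score* (mean of off-diagonal similarities) labels the
  cluster good when it reaches the ``mean_threshold`` (default 0.80,
  inclusive);
* a row-wise Z-score matrix standardizes each PWM's similarity row;
  entries below ``z_threshold`` (default -1) are counted per column — how
  often the other members find PWM j dissimilar — and the most-counted
  top fraction (default 15%) become removal candidates;
* a candidate is removed when enough co-members support the flag (at
  least ``support_fraction`` of the other members, default 5%, floor 1)
  and its own mean similarity to co-members falls below the good-cluster
  threshold.  The last gate keeps tight clusters intact: standardized
  noise always produces a few Z < -1 entries, but a member that agrees
  with its co-members at 0.95 is not poorly clustered.

After filtering, a representative motif (familial binding profile) is
built by projecting every member onto the exemplar's coordinate frame at
its best alignment offset/orientation and averaging the covering columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pwm import PWM, PWMCollection
from .similarity import AlignmentResult, SimilarityMatrix, motif_similarity


@dataclass
class QualityParams:
    mean_threshold: float = 0.80
    z_threshold: float = -1.0
    top_fraction: float = 0.15
    support_fraction: float = 0.05
    count_axis: str = "column"   # "column": how often others flag j; or "row"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (0 <= self.support_fraction <= 1):
            raise ValueError("support_fraction must be in [0, 1]")
        if self.count_axis not in ("column", "row"):
            raise ValueError("count_axis must be 'column' or 'row'")


@dataclass
class QualityReport:
    cluster_id: str
    members: list[str]
    mean_score: float
    label: str                       # good | average | bad | singleton
    z_matrix: Optional[np.ndarray]
    low_z_counts: dict[str, int]
    candidates: list[str]
    removed: list[str]
    member_mean_similarity: dict[str, float]

    @property
    def n_members(self) -> int:
        return len(self.members)


def z_score_matrix(cluster_S: np.ndarray) -> np.ndarray:
    """Row-standardized similarity submatrix (diagonal NaN).

    Each row's off-diagonal entries are centred and scaled by their
    population standard deviation; a zero-spread row yields all-zero Z.
    Requires n >= 3 — below that the spread is degenerate.
    """
    S = np.asarray(cluster_S, dtype=float)
    n = S.shape[0]
    if n < 3:
        raise ValueError("Z-scores need at least 3 members")
    Z = np.full((n, n), np.nan)
    for i in range(n):
        row = np.delete(S[i], i)
        mu = row.mean()
        sd = row.std()                       # population sd over n-1 entries
        mask = np.arange(n) != i
        Z[i, mask] = 0.0 if sd == 0 else (S[i, mask] - mu) / sd
    return Z


def _ceil_floor1(x: float) -> int:
    return max(1, math.ceil(x))


def assess_cluster(cluster_S: SimilarityMatrix, cluster_id: str = "0",
                   params: Optional[QualityParams] = None) -> QualityReport:
    """Quality-label one cluster and identify poorly clustered members."""
    params = params or QualityParams()
    names = cluster_S.names
    n = len(names)
    if n == 0:
        raise ValueError("empty cluster")
    S = cluster_S.values
    off_mask = ~np.eye(n, dtype=bool)
    member_mean = {
        names[i]: float(np.nanmean(S[i][off_mask[i]])) if n > 1 else 1.0
        for i in range(n)
    }
    mean_score = float(np.nanmean(S[off_mask])) if n > 1 else 1.0
    if n == 1:
        label = "singleton"
    elif mean_score >= params.mean_threshold:
        label = "good"
    elif mean_score >= 0.5:
        label = "average"
    else:
        label = "bad"

    if n < 3:
        # Z undefined: never filter clusters of size <= 2
        return QualityReport(cluster_id, list(names), mean_score, label,
                             None, {nm: 0 for nm in names}, [], [],
                             member_mean)

    Z = z_score_matrix(S)
    flags = np.asarray(Z < params.z_threshold)
    counts = flags.sum(axis=0 if params.count_axis == "column" else 1)
    low_z_counts = {names[j]: int(counts[j]) for j in range(n)}

    n_top = min(n, math.ceil(params.top_fraction * n))
    order = sorted(range(n), key=lambda j: (-counts[j], names[j]))
    candidates = [names[j] for j in order[:n_top] if counts[j] >= 1]
    support = _ceil_floor1(params.support_fraction * (n - 1))
    removed = [
        nm for nm in candidates
        if low_z_counts[nm] >= support
        and member_mean[nm] < params.mean_threshold
    ]
    return QualityReport(cluster_id, list(names), mean_score, label, Z,
                         low_z_counts, candidates, removed, member_mean)


def label_distribution(reports: Sequence[QualityReport],
                       member_similarity_cutoff: float = 0.80,
                       good_band: float = 0.85,
                       average_band: float = 0.50) -> dict[str, float]:
    """Fraction of clusters per quality band, in percent.

    A cluster is *good* when >= 85% of its members have mean similarity to
    their co-members above the cutoff, *average* when >= 50% do, *bad*
    otherwise; singletons are counted apart.
    """
    tally = {"good": 0, "average": 0, "bad": 0, "singleton": 0}
    for rep in reports:
        if rep.n_members == 1:
            tally["singleton"] += 1
            continue
        frac = np.mean([
            v >= member_similarity_cutoff
            for v in rep.member_mean_similarity.values()
        ])
        if frac >= good_band:
            tally["good"] += 1
        elif frac >= average_band:
            tally["average"] += 1
        else:
            tally["bad"] += 1
    total = max(1, len(reports))
    return {k: 100.0 * v / total for k, v in tally.items()}


@dataclass
class RepresentativePWM:
    pwm: PWM
    members: list[str]
    anchor: str
    support: np.ndarray      # per-column number of contributing members


def representative_motif(cluster: PWMCollection, anchor: str,
                         min_overlap: Optional[int] = None,
                         use_revcomp: bool = True,
                         name: Optional[str] = None) -> RepresentativePWM:
    """Average the cluster members in the anchor's coordinate frame.

    Every member is aligned to the anchor (the cluster exemplar); its
    matrix — reverse-complemented first when the best alignment is on the
    reverse strand — is laid onto anchor coordinates at the best offset.
    Extended coordinates cover member overhangs; positions covered by no
    member are dropped, covered positions are averaged elementwise over
    the members covering them and renormalized.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster after filtering")
    anchor_pwm = cluster[anchor]
    l_a = len(anchor_pwm)
    placements: list[tuple[int, np.ndarray]] = []   # (start offset, matrix)
    lo = 0
    hi = l_a
    for member in cluster:
        if member.name == anchor:
            aln = AlignmentResult(1.0, 0, "forward", l_a)
        else:
            aln = motif_similarity(anchor_pwm, member, min_overlap,
                                   use_revcomp)
        mat = (member.reverse_complement().matrix
               if aln.orientation == "revcomp" else member.matrix)
        placements.append((aln.offset, mat))
        lo = min(lo, aln.offset)
        hi = max(hi, aln.offset + mat.shape[0])
    width = hi - lo
    acc = np.zeros((width, 4))
    support = np.zeros(width, dtype=int)
    for offset, mat in placements:
        s = offset - lo
        acc[s:s + mat.shape[0]] += mat
        support[s:s + mat.shape[0]] += 1
    covered = support > 0
    avg = acc[covered] / support[covered, None]
    avg = avg / avg.sum(axis=1, keepdims=True)
    rep = PWM(name or f"rep_{anchor}", avg)
    return RepresentativePWM(rep, cluster.names, anchor, support[covered])
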