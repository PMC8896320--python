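"""Ensemble-learning motif discovery from weighted sequence data.

The loop mirrors how de-novo motif discovery scales to large ChIP-seq
experiments: repeatedly draw a random subsample of the weighted input
sequences (default 15%, 10 repetitions), predict enriched motifs on each
subsample with a pluggable predictor, then pool all predicted PWMs,
cluster them by affinity propagation, quality-assess the clusters, build
representative motifs of the good clusters and search them against a
database of known TF PWMs.

The predictor is a contract — any callable
``(WeightedSequenceSet, (min_len, max_len), seed) -> PWMCollection`` —
so an external binding-energy predictor can be plugged in.  A built-in
:func:`naive_predict` (weighted k-mer enrichment against a first-order
Markov background) keeps the loop runnable and testable end to end.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .cluster import APParams, ClusteringResult, cluster, set_preference
from .pwm import PWM, PWMCollection, normalize
from .quality import (QualityParams, QualityReport, RepresentativePWM,
                      assess_cluster, representative_motif)
from .search import SearchHit, search
from .similarity import similarity_matrix

BASES = "ACGT"


@dataclass(frozen=True)
class WeightedSequence:
    id: str
    sequence: str
    weight: float


class WeightedSequenceSet:
    """DNA sequences with abundance weights (e.g. called-peak read counts)."""

    def __init__(self, records: Sequence[WeightedSequence]):
        for r in records:
            if set(r.sequence) - set("ACGTN"):
                raise ValueError(f"sequence {r.id!r}: non-ACGTN characters")
            if not np.isfinite(r.weight):
                raise ValueError(f"sequence {r.id!r}: non-finite weight")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_tsv(cls, path) -> "WeightedSequenceSet":
        """Combined TSV: id, sequence, weight (header optional)."""
        recs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "id":
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}: expected 3 columns (id, seq, w)")
            recs.append(WeightedSequence(parts[0], parts[1].upper(),
                                         float(parts[2])))
        return cls(recs)

    @classmethod
    def from_fasta(cls, fasta_path, weights_path=None
                   ) -> "WeightedSequenceSet":
        """FASTA plus an optional two-column (id, weight) TSV."""
        from Bio import SeqIO
        weights: dict[str, float] = {}
        if weights_path is not None:
            for line in Path(weights_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                k, v = line.split("\t")[:2]
                if k.strip().lower() == "id":
                    continue
                weights[k] = float(v)
        recs = [
            WeightedSequence(rec.id, str(rec.seq).upper(),
                             weights.get(rec.id, 1.0))
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        ]
        return cls(recs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsequence\tweight\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.sequence}\t{r.weight:.6g}\n")


Predictor = Callable[[WeightedSequenceSet, tuple[int, int], int],
                     PWMCollection]


@dataclass
class EnsembleConfig:
    subsample_fraction: float = 0.15
    repetitions: int = 10
    motif_length_range: tuple[int, int] = (6, 10)
    seed: int = 0
    qa_enabled: bool = True
    workers: int = 1
    ap_params: APParams = field(default_factory=APParams)
    qa_params: QualityParams = field(default_factory=QualityParams)
    top_k: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        lo, hi = self.motif_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid motif length range")


def subsample(data: WeightedSequenceSet, fraction: float,
              seed: int) -> WeightedSequenceSet:
    """Draw ceil(fraction * n) records without replacement, reproducibly."""
    if len(data) == 0:
        raise ValueError("cannot subsample an empty sequence set")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(data)
    k = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return WeightedSequenceSet([data.records[i] for i in idx])


def _markov1_expected(seqs: list[str], weights: list[float],
                      w: int) -> Callable[[str], float]:
    """Expected weighted count of a w-mer under a first-order Markov
    model fitted to the input — the analytic stand-in for counting in
    dinucleotide-shuffled sequences."""
    base_w: Counter = Counter()
    di_w: Counter = Counter()
    n_pos = 0.0
    for s, wt in zip(seqs, weights):
        for ch in s:
            base_w[ch] += wt
        for i in range(len(s) - 1):
            di_w[s[i:i + 2]] += wt
        n_pos += wt * max(0, len(s) - w + 1)
    tot = sum(base_w.values()) or 1.0

    def expected(kmer: str) -> float:
        p = base_w[kmer[0]] / tot
        for i in range(len(kmer) - 1):
            denom = sum(di_w[kmer[i] + b] for b in BASES)
            p *= (di_w[kmer[i:i + 2]] / denom) if denom else 0.25
        return p * n_pos

    return expected


def naive_predict(data: WeightedSequenceSet,
                  length_range: tuple[int, int],
                  seed: int = 0) -> PWMCollection:
    """Built-in predictor: weighted k-mer enrichment.

    For each motif width w in the range, every w-mer occurring in the
    sequences is scored by its weight-summed occurrence count divided by
    its expected count under a first-order Markov background; the most
    enriched w-mer seeds a position-frequency matrix from its exact
    occurrences, normalized to a PWM.  Widths where no w-mer recurs are
    skipped with an empty result (low-complexity input).
    """
    out = PWMCollection()
    seqs = [r.sequence for r in data]
    weights = [r.weight for r in data]
    for w in range(length_range[0], length_range[1] + 1):
        counts: Counter = Counter()
        occur: Counter = Counter()
        for s, wt in zip(seqs, weights):
            for i in range(len(s) - w + 1):
                kmer = s[i:i + w]
                if "N" in kmer:
                    continue
                counts[kmer] += wt
                occur[kmer] += 1
        recurring = {k: v for k, v in counts.items() if occur[k] > 1}
        if not recurring:
            continue
        expected = _markov1_expected(seqs, weights, w)
        best = max(
            recurring,
            key=lambda k: (recurring[k] / (expected(k) + 1e-12), k),
        )
        pfm = np.zeros((w, 4))
        for i, ch in enumerate(best):
            pfm[i, BASES.index(ch)] = occur[best]
        out.add(PWM(f"L{w}_1", normalize(pfm, pseudocount=1e-6)))
    return out


@dataclass
class EnsembleResult:
    pooled: PWMCollection
    clustering: ClusteringResult
    reports: list[QualityReport]
    representatives: list[RepresentativePWM]
    hits: dict[str, list[SearchHit]]
    config: EnsembleConfig
    child_seeds: list[int]

    def manifest(self) -> str:
        """Deterministic JSON manifest of the run (config, seeds, pooled
        PWM names, cluster assignments, QA labels, top hits)."""
        doc = {
            "config": {
                "subsample_fraction": self.config.subsample_fraction,
                "repetitions": self.config.repetitions,
                "motif_length_range": list(self.config.motif_length_range),
                "seed": self.config.seed,
                "qa_enabled": self.config.qa_enabled,
            },
            "child_seeds": self.child_seeds,
            "pooled_pwms": self.pooled.names,
            "clusters": {
                str(k): v for k, v in sorted(self.clustering.clusters().items())
            },
            "labels": {r.cluster_id: r.label for r in self.reports},
            "removed": {r.cluster_id: r.removed for r in self.reports},
            "top_hits": {
                q: [[h.target_name, round(h.score, 9)] for h in hs[:3]]
                for q, hs in sorted(self.hits.items())
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def run_ensemble(data: WeightedSequenceSet, predictor: Predictor,
                 db: Optional[PWMCollection],
                 cfg: EnsembleConfig) -> EnsembleResult:
    """Full subsample -> predict -> cluster -> QA -> represent -> search loop.

    Child seed for repetition r is ``cfg.seed + r`` (r = 1..repetitions),
    so repetitions are independent and the pooled PWM set is invariant to
    execution order and worker count.
    """
    pooled = PWMCollection()
    child_seeds = []
    for r in range(1, cfg.repetitions + 1):
        child = cfg.seed + r
        child_seeds.append(child)
        sub = subsample(data, cfg.subsample_fraction, child)
        predicted = predictor(sub, cfg.motif_length_range, child)
        for k, pwm in enumerate(predicted, start=1):
            pooled.add(pwm.with_name(f"rep{r}_{pwm.name}"))
    if len(pooled) == 0:
        raise RuntimeError("predictor returned zero PWMs in every repetition")

    if len(pooled) == 1:
        # degenerate: one predicted motif is its own cluster
        only = pooled.names[0]
        reports = [QualityReport("0", [only], 1.0, "singleton", None,
                                 {only: 0}, [], [], {only: 1.0})]
        reps = [representative_motif(pooled, only, name=f"rep_c0")]
        clustering = None
        hits = search(
            PWMCollection([r.pwm for r in reps]), db, cfg.top_k
        ) if db is not None and len(db) else {}
        return EnsembleResult(pooled, clustering, reports, reps, hits, cfg,
                              child_seeds)

    S = similarity_matrix(pooled, workers=cfg.workers)
    clustering = cluster(set_preference(S, cfg.ap_params.preference,
                                        cfg.ap_params.preference_value),
                         cfg.ap_params)
    reports = []
    surviving: dict[int, list[str]] = {}
    for ex, members in sorted(clustering.clusters().items()):
        sub_S = S.submatrix(members)
        rep = assess_cluster(sub_S, cluster_id=str(ex), params=cfg.qa_params)
        if not cfg.qa_enabled:
            rep.removed = []
        reports.append(rep)
        keep = [m for m in members if m not in rep.removed]
        surviving[ex] = keep or members

    representatives = []
    for ex, members in sorted(surviving.items()):
        anchor = clustering.names[ex]
        if anchor not in members:
            anchor = members[0]
        rep = representative_motif(pooled.subset(members), anchor,
                                   name=f"rep_c{ex}")
        representatives.append(rep)

    hits: dict[str, list[SearchHit]] = {}
    if db is not None and len(db):
        good_ids = {r.cluster_id for r in reports
                    if r.label in ("good", "singleton")}
        query_reps = [r for r in representatives
                      if r.pwm.name.removeprefix("rep_c") in good_ids]
        if not query_reps:
            query_reps = representatives
        hits = search(PWMCollection([r.pwm for r in query_reps]), db,
                      cfg.top_k)
    return EnsembleResult(pooled, clustering, reports, representatives, hits,
                          cfg, child_seeds)
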