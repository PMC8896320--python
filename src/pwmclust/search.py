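"""Search unknown PWMs against a database of known motifs.

Each query is aligned against every database PWM with the motif
similarity score; the ranked top matches are reported together with the
alignment orientation/offset, the target's DBD family when known, and an
IUPAC consensus rendering of the motifs.  In practice a similarity score
of about 0.80 or above marks a confident match; the score floor is a
report filter, not part of the scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .pwm import PWMCollection
from .similarity import AlignmentResult, motif_similarity


@dataclass(frozen=True)
class SearchHit:
    query_name: str
    target_name: str
    score: float
    rank: int
    alignment: AlignmentResult
    target_dbd: Optional[str] = None


def search(queries: PWMCollection, database: PWMCollection,
           top_k: int = 10, score_floor: float = 0.0,
           min_overlap: Optional[int] = None, use_revcomp: bool = True,
           target_dbd: Optional[Mapping[str, str]] = None
           ) -> dict[str, list[SearchHit]]:
    """Top-k database matches per query, ranked by descending similarity.

    Ordering is deterministic: score descending, then target name
    ascending.  Hits below ``score_floor`` are dropped.
    """
    if len(database) == 0:
        raise ValueError("search database is empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    results: dict[str, list[SearchHit]] = {}
    for q in queries:
        scored = []
        for t in database:
            aln = motif_similarity(q, t, min_overlap, use_revcomp)
            scored.append((t.name, aln))
        scored.sort(key=lambda x: (-x[1].score, x[0]))
        hits = []
        for rank, (tname, aln) in enumerate(scored[:top_k], start=1):
            if aln.score < score_floor:
                break
            dbd = target_dbd.get(tname) if target_dbd else None
            hits.append(SearchHit(q.name, tname, aln.score, rank, aln, dbd))
        results[q.name] = hits
    return results


def write_hits_tsv(results: Mapping[str, Iterable[SearchHit]], path,
                   database: Optional[PWMCollection] = None) -> None:
    """TSV report: query, rank, target, score, orientation, offset,
    target_dbd, target_consensus."""
    with open(path, "w") as fh:
        fh.write("query\trank\ttarget\tscore\torientation\toffset"
                 "\ttarget_dbd\ttarget_consensus\n")
        for qname in results:
            for h in results[qname]:
                consensus = (
                    database[h.target_name].consensus()
                    if database is not None and h.target_name in database
                    else ""
                )
                fh.write(
                    f"{h.query_name}\t{h.rank}\t{h.target_name}"
                    f"\t{h.score:.6f}\t{h.alignment.orientation}"
                    f"\t{h.alignment.offset}\t{h.target_dbd or ''}"
                    f"\t{consensus}\n"
                )
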