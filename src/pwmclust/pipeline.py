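"""End-to-end orchestration: classify -> cluster -> assess -> represent
-> search, per DBD family or on all PWMs at once.

The with-DBD flow partitions the input PWMs into DBD-family buckets and
clusters each bucket separately; the no-DBD flow clusters the whole
collection directly (the two are compared in practice because per-family
clustering gives markedly more homogeneous clusters).  Failures in one
bucket do not abort the others.  Every run can be written to a fixed
output layout with per-cluster directories, QA reports, boxplot-ready
long-format similarity tables and a manifest echoing the effective
configuration, so that re-running an identical manifest reproduces
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .cluster import APParams, ClusteringResult, ConvergenceError, cluster, \
    set_preference
from .dbd import DBDRecord, UNKNOWN_DBD, assign_pwms_to_dbd
from .io import format_plain
from .pwm import PWMCollection
from .quality import (QualityParams, QualityReport, RepresentativePWM,
                      assess_cluster, label_distribution,
                      representative_motif)
from .search import SearchHit, search, write_hits_tsv
from .similarity import SimilarityMatrix, similarity_matrix

log = logging.getLogger("pwmclust")


@dataclass
class BucketResult:
    """Clustering + QA outcome for one DBD bucket (or the whole set)."""

    dbd: str
    collection: PWMCollection
    similarity: Optional[SimilarityMatrix]
    clustering: Optional[ClusteringResult]
    reports: list[QualityReport]
    representatives: list[RepresentativePWM]
    removed: list[str]
    error: Optional[str] = None

    def labels_by_name(self) -> dict[str, int]:
        if self.clustering is None:
            return {name: 0 for name in self.collection.names}
        return {
            name: int(lab)
            for name, lab in zip(self.clustering.names,
                                 self.clustering.labels)
        }


@dataclass
class PipelineResult:
    buckets: dict[str, BucketResult]

    def cluster_labels(self) -> dict[str, str]:
        """PWM name -> globally unique cluster id across buckets."""
        out = {}
        for dbd, b in self.buckets.items():
            for name, lab in b.labels_by_name().items():
                out[name] = f"{dbd}:{lab}"
        return out

    def all_reports(self) -> list[QualityReport]:
        return [r for b in self.buckets.values() for r in b.reports]

    def good_cluster_fraction(self,
                              member_similarity_cutoff: float = 0.80
                              ) -> float:
        dist = label_distribution(self.all_reports(),
                                  member_similarity_cutoff)
        return dist["good"] / 100.0


def analyze_bucket(dbd: str, coll: PWMCollection,
                   ap_params: Optional[APParams] = None,
                   qa_params: Optional[QualityParams] = None,
                   qa_enabled: bool = True,
                   min_overlap: Optional[int] = None,
                   use_revcomp: bool = True) -> BucketResult:
    """Cluster one bucket, assess cluster quality, remove poorly
    clustered PWMs and build representatives of the survivors."""
    # a low (min) preference is the pipeline default: PWM collections are
    # homogeneous within a DBD bucket, where the median similarity sits at
    # the within-family level and would over-fragment the bucket
    ap_params = ap_params or APParams(preference="min")
    qa_params = qa_params or QualityParams()
    if len(coll) == 1:
        only = coll.names[0]
        rep = QualityReport(f"{dbd}:0", [only], 1.0, "singleton", None,
                            {only: 0}, [], [], {only: 1.0})
        return BucketResult(dbd, coll, None, None, [rep],
                            [representative_motif(coll, only,
                                                  name=f"rep_{dbd}_0")],
                            [])
    try:
        S = similarity_matrix(coll, min_overlap=min_overlap,
                              use_revcomp=use_revcomp)
        clustering = cluster(
            set_preference(S, ap_params.preference,
                           ap_params.preference_value),
            ap_params,
        )
    except (ConvergenceError, ValueError) as exc:
        log.error("bucket %s failed: %s", dbd, exc)
        return BucketResult(dbd, coll, None, None, [], [], [],
                            error=str(exc))
    reports: list[QualityReport] = []
    representatives: list[RepresentativePWM] = []
    removed_all: list[str] = []
    for ex, members in sorted(clustering.clusters().items()):
        cid = f"{dbd}:{ex}"
        rep = assess_cluster(S.submatrix(members), cluster_id=cid,
                             params=qa_params)
        if not qa_enabled:
            rep.removed = []
        reports.append(rep)
        removed_all.extend(rep.removed)
        keep = [m for m in members if m not in rep.removed] or members
        anchor = clustering.names[ex]
        if anchor not in keep:
            anchor = keep[0]
        representatives.append(
            representative_motif(coll.subset(keep), anchor,
                                 min_overlap=min_overlap,
                                 use_revcomp=use_revcomp,
                                 name=f"rep_{dbd}_{ex}")
        )
    return BucketResult(dbd, coll, S, clustering, reports, representatives,
                        removed_all)


def run_pipeline(collection: PWMCollection,
                 dbd_db: Optional[Sequence[DBDRecord]] = None,
                 use_dbd: bool = True,
                 ap_params: Optional[APParams] = None,
                 qa_params: Optional[QualityParams] = None,
                 qa_enabled: bool = True,
                 search_db: Optional[PWMCollection] = None,
                 top_k: int = 10,
                 out_dir: Optional[Path] = None) -> PipelineResult:
    """Run the full workflow in memory, optionally writing the output tree.

    ``use_dbd=False`` skips the DBD assignment step and clusters the
    whole collection at once.
    """
    if len(collection) == 0:
        raise ValueError("no input PWMs")
    if use_dbd and dbd_db is not None:
        buckets_in = assign_pwms_to_dbd(collection, dbd_db)
    else:
        buckets_in = {"all": collection}
    buckets: dict[str, BucketResult] = {}
    for dbd, coll in sorted(buckets_in.items()):
        buckets[dbd] = analyze_bucket(dbd, coll, ap_params, qa_params,
                                      qa_enabled)
        log.info("bucket %s: %d PWMs, %d clusters, %d removed",
                 dbd, len(coll),
                 len(buckets[dbd].reports), len(buckets[dbd].removed))
    result = PipelineResult(buckets)
    if out_dir is not None:
        write_outputs(result, Path(out_dir), search_db=search_db,
                      top_k=top_k)
    return result


def write_outputs(result: PipelineResult, out_dir: Path,
                  search_db: Optional[PWMCollection] = None,
                  top_k: int = 10) -> None:
    """Fixed output layout:

    out/<dbd>/clusters/<id>/<pwm>.plain + manifest.tsv
    out/<dbd>/representatives/rep_<dbd>_<id>.plain
    out/<dbd>/filtered_out/        (removed PWMs, preserved not deleted)
    out/reports/qa_report.tsv, boxplot_data.tsv, summary.json
    out/reports/search_results.tsv (when a search database is given)
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(exist_ok=True)
    qa_rows = ["cluster_id\tn\tmean_score\tlabel\tremoved"]
    box_rows = ["cluster_id\tpwm_name\tmean_similarity"]
    for dbd, b in result.buckets.items():
        ddir = out_dir / dbd
        (ddir / "clusters").mkdir(parents=True, exist_ok=True)
        (ddir / "representatives").mkdir(exist_ok=True)
        (ddir / "filtered_out").mkdir(exist_ok=True)
        for rep_q in b.reports:
            cid = rep_q.cluster_id.split(":")[-1]
            cdir = ddir / "clusters" / cid
            cdir.mkdir(exist_ok=True)
            manifest = ["cluster_id\tpwm_name\texemplar_flag"]
            exemplar = (b.clustering.names[int(cid)]
                        if b.clustering is not None else rep_q.members[0])
            for m in rep_q.members:
                target = (ddir / "filtered_out" if m in rep_q.removed
                          else cdir)
                (target / f"{m}.plain").write_text(
                    format_plain(b.collection[m]))
                manifest.append(
                    f"{cid}\t{m}\t{int(m == exemplar)}")
            (cdir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
            qa_rows.append(
                f"{rep_q.cluster_id}\t{rep_q.n_members}"
                f"\t{rep_q.mean_score:.6f}\t{rep_q.label}"
                f"\t{','.join(rep_q.removed)}")
            for m, mean_sim in rep_q.member_mean_similarity.items():
                box_rows.append(f"{rep_q.cluster_id}\t{m}\t{mean_sim:.6f}")
        for rep in b.representatives:
            (ddir / "representatives" / f"{rep.pwm.name}.plain").write_text(
                format_plain(rep.pwm))
        if b.similarity is not None:
            b.similarity.to_tsv(ddir / "similarity_matrix.tsv")
    (reports_dir / "qa_report.tsv").write_text("\n".join(qa_rows) + "\n")
    (reports_dir / "boxplot_data.tsv").write_text("\n".join(box_rows) + "\n")
    dist = label_distribution(result.all_reports())
    summary = {
        "n_pwms": sum(len(b.collection) for b in result.buckets.values()),
        "per_dbd_counts": {d: len(b.collection)
                           for d, b in result.buckets.items()},
        "n_clusters": len(result.all_reports()),
        "n_removed": sum(len(b.removed) for b in result.buckets.values()),
        "label_distribution_pct": dist,
    }
    (reports_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if search_db is not None and len(search_db):
        reps = PWMCollection(
            r.pwm for b in result.buckets.values()
            for r in b.representatives)
        if len(reps):
            hits = search(reps, search_db, top_k=top_k)
            write_hits_tsv(hits, reports_dir / "search_results.tsv",
                           database=search_db)
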