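"""Cluster annotation by majority best-hit against a repeat library.

Each read in a cluster is scored against every library record with the
similarity module's scorer; the cluster label is the modal best-hit among
reads with a hit. A lower bit threshold than the graph stage is used by
default (annotation tolerates weaker hits than graph edges).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .similarity import DEFAULT_PARAMS, ScoringParams, score_pair
from .simulate import LibraryRecord, ReadSet

ANNOTATION_MIN_BITS = 50.0
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class ClusterAnnotation:
    cluster_id: int
    best_label: str
    class_label: str
    n_hit_reads: int
    n_reads: int
    tie: bool = False


def annotate_reads(
    reads: ReadSet,
    library: Sequence[LibraryRecord],
    params: ScoringParams | None = None,
) -> dict[str, str | None]:
    """Best-bitscore library label per read, or None without a hit.

    Ties on bit-score go to the lexicographically smallest record name.
    """
    if not library:
        raise ValueError("empty repeat library")
    if params is None:
        params = replace(DEFAULT_PARAMS, min_report_bits=ANNOTATION_MIN_BITS)
    records = sorted(library, key=lambda r: r.name)
    out: dict[str, str | None] = {}
    for read in reads:
        best_name: str | None = None
        best_bits = float("-inf")
        for rec in records:
            hit = score_pair(read.sequence, rec.sequence, params)
            if hit is not None and hit.bitscore > best_bits:
                best_bits = hit.bitscore
                best_name = rec.name
        out[read.id] = best_name
    return out


def annotate_cluster(
    cluster_id: int,
    read_hits: Mapping[str, str | None],
    library: Sequence[LibraryRecord],
) -> ClusterAnnotation:
    """Majority label over hit reads; zero hits -> 'unknown'."""
    classes = {rec.name: rec.class_label for rec in library}
    labels = [lab for lab in read_hits.values() if lab is not None]
    n_reads = len(read_hits)
    if not labels:
        return ClusterAnnotation(cluster_id, UNKNOWN_LABEL, UNKNOWN_LABEL, 0, n_reads)
    counts = Counter(labels)
    top = max(counts.values())
    modal = sorted(lab for lab, c in counts.items() if c == top)
    best = modal[0]
    return ClusterAnnotation(
        cluster_id=cluster_id,
        best_label=best,
        class_label=classes.get(best, UNKNOWN_LABEL),
        n_hit_reads=len(labels),
        n_reads=n_reads,
        tie=len(modal) > 1,
    )


def annotate_clusters(
    clusters: Sequence[ReadSet],
    library: Sequence[LibraryRecord],
    params: ScoringParams | None = None,
) -> list[ClusterAnnotation]:
    """Annotate each cluster's read set in rank order."""
    return [
        annotate_cluster(i, annotate_reads(reads, library, params), library)
        for i, reads in enumerate(clusters)
    ]


def annotation_table(annotations: Sequence[ClusterAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "cluster": f"cluster_{a.cluster_id}",
            "best_label": a.best_label,
            "class_label": a.class_label,
            "n_hit_reads": a.n_hit_reads,
            "n_reads": a.n_reads,
            "tie": a.tie,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows).set_index("cluster")


def aggregate_by_annotation(
    abundance: pd.DataFrame, annotations: Sequence[ClusterAnnotation]
) -> pd.DataFrame:
    """Sum cluster columns into annotation-class columns per individual.

    Every abundance column must have an annotation; the per-individual
    totals (and hence the grand total) are conserved by the grouping.
    """
    class_of = {f"cluster_{a.cluster_id}": a.class_label for a in annotations}
    missing = [c for c in abundance.columns if c not in class_of]
    if missing:
        raise KeyError(f"clusters missing from annotations: {missing}")
    grouped = abundance.T.groupby(
        abundance.columns.map(class_of)
    ).sum().T
    grouped.columns.name = None
    return grouped
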