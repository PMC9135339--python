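"""Cross-pair aggregation of pairwise peak labels into consistent calls.

Peaks from all subjects are grouped into clusters by single-linkage >= 1 bp
overlap ("the same peak" across subjects); each cluster then receives one
label per matched pair, and a cluster is consistently case-specific when it
is labeled case-specific in at least `min_pairs` pairs (default 3 of 6),
analogously for control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import ConfigurationError, GenomicInterval, PeakSet
from .diffpeaks import (CASE_SPECIFIC, CONTROL_SPECIFIC, SHARED,
                        PairwiseDifferentialResult)

ABSENT = "absent"


@dataclass
class PeakCluster:
    cluster_id: str
    interval: GenomicInterval               # union span
    members: list[tuple[str, str]] = field(default_factory=list)  # (subject, peak)
    pair_labels: dict[str, str] = field(default_factory=dict)


def cluster_across_subjects(peaksets: dict[str, PeakSet]) -> list[PeakCluster]:
    """Single-linkage clustering of all subjects' peaks by >= 1 bp overlap.

    For intervals, connected components of the overlap graph are exactly the
    chains found by one sorted sweep: a peak starting before the running
    maximum end of the open cluster joins it.
    """
    rows = []
    for subject, ps in peaksets.items():
        for iv in ps.intervals:
            rows.append((iv.chrom, iv.start, iv.end, subject,
                         iv.name or f"{subject}:{iv.start}"))
    rows.sort()
    clusters: list[PeakCluster] = []
    cur: list[tuple] = []
    cur_chrom, cur_end = None, -1

    def _flush() -> None:
        if not cur:
            return
        start = min(r[1] for r in cur)
        end = max(r[2] for r in cur)
        cid = f"cl{len(clusters):05d}"
        clusters.append(PeakCluster(cid,
                                    GenomicInterval(cur_chrom, start, end, cid),
                                    [(r[3], r[4]) for r in cur]))

    for row in rows:
        chrom, start, end = row[0], row[1], row[2]
        if chrom != cur_chrom or start >= cur_end:
            _flush()
            cur = [row]
            cur_chrom, cur_end = chrom, end
        else:
            cur.append(row)
            cur_end = max(cur_end, end)
    _flush()
    return clusters


def attach_pair_labels(clusters: list[PeakCluster],
                       results: dict[str, PairwiseDifferentialResult],
                       pairs: list[tuple[str, str]]) -> list[PeakCluster]:
    """Give each cluster one label per pair from the pairwise differential calls.

    A pair's label is case_specific (control_specific) when any member peak of
    that pair's subjects carries that label and none carries the opposite;
    conflicting or only-shared members give shared; no member peak at all in
    either subject of the pair gives absent (absent never counts toward a
    consistency threshold).
    """
    pair_ids = [f"pair{k+1}" for k in range(len(pairs))]
    label_of: dict[tuple[str, str], str] = {}
    for pid, result in results.items():
        for pt in result.points:
            label_of[(pt.subject_id, pt.peak_id)] = pt.label
    pair_of_subject = {}
    for pid, (case_id, ctrl_id) in zip(pair_ids, pairs):
        pair_of_subject[case_id] = pid
        pair_of_subject[ctrl_id] = pid
    for cl in clusters:
        member_labels: dict[str, set[str]] = {pid: set() for pid in pair_ids}
        members_present: dict[str, bool] = {pid: False for pid in pair_ids}
        for subject, peak in cl.members:
            pid = pair_of_subject.get(subject)
            if pid is None:
                continue
            members_present[pid] = True
            lab = label_of.get((subject, peak))
            if lab is not None:
                member_labels[pid].add(lab)
        for pid in pair_ids:
            labs = member_labels[pid]
            if not members_present[pid]:
                cl.pair_labels[pid] = ABSENT
            elif CASE_SPECIFIC in labs and CONTROL_SPECIFIC not in labs:
                cl.pair_labels[pid] = CASE_SPECIFIC
            elif CONTROL_SPECIFIC in labs and CASE_SPECIFIC not in labs:
                cl.pair_labels[pid] = CONTROL_SPECIFIC
            else:
                cl.pair_labels[pid] = SHARED if labs else ABSENT
    return clusters


def consistent_specific(clusters: list[PeakCluster], min_pairs: int = 3,
                        n_pairs: int | None = None
                        ) -> tuple[set[str], set[str]]:
    """Clusters labeled case- (control-) specific in >= min_pairs pairs."""
    if n_pairs is None:
        n_pairs = max((len(cl.pair_labels) for cl in clusters), default=0)
    if min_pairs > n_pairs:
        raise ConfigurationError(
            f"min_pairs={min_pairs} exceeds the {n_pairs} available pairs")
    case_set: set[str] = set()
    ctrl_set: set[str] = set()
    for cl in clusters:
        labels = list(cl.pair_labels.values())
        if labels.count(CASE_SPECIFIC) >= min_pairs:
            case_set.add(cl.cluster_id)
        if labels.count(CONTROL_SPECIFIC) >= min_pairs:
            ctrl_set.add(cl.cluster_id)
    return case_set, ctrl_set


def exclusive_consistent(case_set: set[str], control_set: set[str]) -> set[str]:
    """Consistently-case clusters that are not consistently-control."""
    return set(case_set) - set(control_set)


def clusters_to_frame(clusters: list[PeakCluster], case_set: set[str],
                      control_set: set[str]) -> pd.DataFrame:
    case_only = exclusive_consistent(case_set, control_set)
    rows = []
    for cl in clusters:
        row = {"cluster_id": cl.cluster_id, "chrom": cl.interval.chrom,
               "start": cl.interval.start, "end": cl.interval.end,
               "n_members": len(cl.members)}
        row.update(cl.pair_labels)
        row["consistently_case"] = cl.cluster_id in case_set
        row["consistently_control"] = cl.cluster_id in control_set
        row["case_only"] = cl.cluster_id in case_only
        rows.append(row)
    return pd.DataFrame(rows)
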