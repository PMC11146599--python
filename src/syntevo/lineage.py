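"""Lineage-conserved rearrangements via outgroup projection.

Each ingroup genome is classified against a common outgroup genome; the
outgroup imposes a single coordinate system, so rearrangement breakpoints
become directly comparable across genomes.  Events longer than 1 kbp whose
start and end breakpoints agree within +/-50 bp are clustered as the same
rearrangement; clusters supported by two or more genomes are "common", and
tracing clusters through the phylogeny counts, for every clade, the
rearrangements shared by all of its member genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from ._util import round_half_up
from .classification import PairAnnotation, REARRANGED_CLASSES
from .errors import ConsistencyError, InputError


@dataclass(frozen=True)
class ProjectedEvent:
    """A rearrangement of one ingroup genome in outgroup coordinates."""

    genome: str
    event_type: str  # INV | TRANS | DUP
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def project_rearrangements(
    pair: PairAnnotation, outgroup: str, min_length: int = 1000,
    merge_gap: int = 50,
) -> list[ProjectedEvent]:
    """Outgroup-side INV/TRANS/DUP annotations longer than ``min_length``
    bp (strictly), expressed in outgroup coordinates.

    Projection reads the two-sided event annotations, not the per-genome
    partition: a duplication's outgroup-side span is usually also part of
    the syntenic backbone and would be trimmed away in the partition, yet
    it is exactly the coordinate at which different ingroup genomes carrying
    the same duplication become comparable.
    """
    if outgroup not in pair.genome_ids:
        raise InputError(
            f"outgroup {outgroup!r} not in pair ({pair.ref_id}, {pair.qry_id})"
        )
    ingroup = pair.other(outgroup)
    oside = "ref" if outgroup == pair.ref_id else "qry"
    iside = "qry" if oside == "ref" else "ref"
    spans: dict[tuple[str, str], list[tuple[int, int, str, int, int]]] = {}
    for ann in pair.events:
        if ann.event_type not in REARRANGED_CLASSES:
            continue
        chrom = getattr(ann, f"{oside}_chrom")
        if chrom is None:
            continue
        spans.setdefault((ann.event_type, chrom), []).append(
            (
                getattr(ann, f"{oside}_start"), getattr(ann, f"{oside}_end"),
                getattr(ann, f"{iside}_chrom") or "",
                getattr(ann, f"{iside}_start") or 0,
                getattr(ann, f"{iside}_end") or 0,
            )
        )
    # combine unbroken same-type series: an ingroup-side disruption (e.g. an
    # insertion inside a moved segment) splits one event into annotations
    # that are contiguous on the outgroup.  Only spans whose ingroup sides
    # are also close (same chromosome, within one disrupting-event's reach)
    # are combined -- adjacent but unrelated events stay distinct.
    ingroup_window = 10_000
    out = []
    for (etype, chrom), recs in sorted(spans.items()):
        recs.sort()
        cur = list(recs[0])
        merged = []
        for s, e, ic, is_, ie in recs[1:]:
            near_outgroup = -merge_gap <= s - cur[1] <= merge_gap
            same_ingroup = ic == cur[2] and (
                min(abs(is_ - cur[4]), abs(cur[3] - ie)) <= ingroup_window
            )
            if near_outgroup and same_ingroup:
                cur[1] = max(cur[1], e)
                cur[3], cur[4] = min(cur[3], is_), max(cur[4], ie)
            else:
                merged.append(cur)
                cur = [s, e, ic, is_, ie]
        merged.append(cur)
        for s, e, *_ in merged:
            if e - s > min_length:
                out.append(ProjectedEvent(ingroup, etype, chrom, s, e))
    return out


@dataclass
class EventCluster:
    """Projected events from different genomes judged to be one event."""

    chrom: str
    start: int
    end: int
    event_type: str
    members: dict[str, ProjectedEvent] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.members)


def match_common_events(
    events: list[ProjectedEvent],
    tolerance: int = 50,
    require_same_type: bool = True,
) -> list[EventCluster]:
    """Seed-anchored greedy clustering of projected events.

    Events are processed sorted by (type, chrom, start, end, genome).  Each
    event joins the earliest-seeded cluster of matching type and chromosome
    whose seed breakpoints both lie within ``tolerance`` bp and which has no
    member from the event's genome yet; otherwise it seeds a new cluster.
    Two events further than ``tolerance`` from a seed can never share its
    cluster, so cluster extents are bounded.  With
    ``require_same_type=False`` type is ignored during matching (the seed's
    type labels the cluster).
    """
    clusters: list[EventCluster] = []
    by_key: dict[tuple, list[EventCluster]] = {}

    def key(ev: ProjectedEvent):
        return (ev.event_type if require_same_type else "", ev.chrom)

    for ev in sorted(events, key=lambda e: (e.event_type, e.chrom, e.start, e.end, e.genome)):
        placed = False
        for cl in by_key.get(key(ev), []):
            if (
                abs(ev.start - cl.start) <= tolerance
                and abs(ev.end - cl.end) <= tolerance
                and ev.genome not in cl.members
            ):
                cl.members[ev.genome] = ev
                placed = True
                break
        if not placed:
            cl = EventCluster(ev.chrom, ev.start, ev.end, ev.event_type, {ev.genome: ev})
            clusters.append(cl)
            by_key.setdefault(key(ev), []).append(cl)
    return clusters


def clade_shared_counts(
    tree: dendropy.Tree, clusters: list[EventCluster]
) -> dict[frozenset, int]:
    """For every internal node, the number of clusters whose member set
    contains all tips of that node's clade; keyed by the clade's tip set."""
    tips = {
        (leaf.taxon.label if leaf.taxon else leaf.label).replace(" ", "_")
        for leaf in tree.leaf_node_iter()
    }
    member_sets = []
    for cl in clusters:
        for gid in cl.members:
            if gid not in tips:
                raise InputError(f"cluster member {gid!r} is not a tip of the tree")
        member_sets.append(frozenset(cl.members))

    counts: dict[frozenset, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = frozenset(
            (leaf.taxon.label if leaf.taxon else leaf.label).replace(" ", "_")
            for leaf in node.leaf_iter()
        )
        counts[clade] = sum(1 for ms in member_sets if clade <= ms)
    return counts


@dataclass
class CommonSummary:
    total_events: int
    common_events: int  # clusters with support >= 2
    percent_common: float  # rounded half-up, 2 dp
    support_histogram: dict[int, int]  # k -> clusters shared by exactly k genomes
    support_percent: dict[int, float]  # percent of common clusters at each k

    def __post_init__(self):
        if sum(v for k, v in self.support_histogram.items() if k >= 2) != self.common_events:
            raise ConsistencyError("support histogram does not sum to common_events")


def common_summary(clusters: list[EventCluster], total_events: int) -> CommonSummary:
    """Tally common (support >= 2) rearrangements; percentages rounded
    half-up to 2 decimals as usually printed."""
    n_members = sum(cl.support for cl in clusters)
    if total_events < n_members:
        raise InputError(
            f"total_events={total_events} < clustered events {n_members}"
        )
    hist: dict[int, int] = {}
    for cl in clusters:
        if cl.support >= 2:
            hist[cl.support] = hist.get(cl.support, 0) + 1
    return _summarize(hist, total_events)


def common_summary_from_histogram(
    support_histogram: dict[int, int], total_events: int
) -> CommonSummary:
    """Same tally computed from pre-counted cluster supports (k >= 2)."""
    hist = {k: v for k, v in support_histogram.items() if k >= 2}
    n_members = sum(k * v for k, v in hist.items())
    if total_events < n_members:
        raise InputError(
            f"total_events={total_events} < clustered events {n_members}"
        )
    return _summarize(hist, total_events)


def _summarize(hist: dict[int, int], total_events: int) -> CommonSummary:
    common = sum(hist.values())
    percent = round_half_up(100.0 * common / total_events, 2) if total_events else 0.0
    support_percent = {
        k: round_half_up(100.0 * v / common, 2) if common else 0.0
        for k, v in sorted(hist.items())
    }
    return CommonSummary(total_events, common, percent, dict(sorted(hist.items())), support_percent)


# ---------------------------------------------------------------------------
# I/O


def write_clusters_tsv(clusters: list[EventCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\ttype\tchrom\tstart\tend\tsupport\tmembers\n")
        for i, cl in enumerate(clusters):
            members = ",".join(sorted(cl.members))
            fh.write(
                f"c{i:06d}\t{cl.event_type}\t{cl.chrom}\t{cl.start}\t{cl.end}\t"
                f"{cl.support}\t{members}\n"
            )


def write_clade_counts_tsv(counts: dict[frozenset, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_tips\tn_tips\tshared_rearrangements\n")
        for clade, n in sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            fh.write(f"{','.join(sorted(clade))}\t{len(clade)}\t{n}\n")
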