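"""Per-pair summaries and divergence-trend regressions.

Reduces a :class:`~syntevo.classification.PairAnnotation` to per-genome
class proportions, event counts and mean event sizes (the summary-table
view), computes patristic distances on the species tree, and regresses
class proportions or identities against phylogenetic distance with OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy import stats

from .classification import ALIGNED_CLASSES, CLASSES, PairAnnotation, REARRANGED_CLASSES
from .errors import InputError


@dataclass(frozen=True)
class ClassStats:
    percent: float
    count: int
    mean_kbp: float  # 0.0 when count == 0


@dataclass
class PairSummary:
    """Per-genome, per-class proportions/counts/sizes for one genome pair.

    Events shorter than ``min_event_length`` were excluded from counts,
    mean sizes and proportion numerators; proportions are over retained
    bases, so SYN + UNALIGNED + rearranged = 100 per genome.
    """

    ref_id: str
    qry_id: str
    min_event_length: int
    per_genome: dict[str, dict[str, ClassStats]]

    def percent(self, genome: str, cls: str) -> float:
        return self.per_genome[genome][cls].percent

    def rearranged_percent(self, genome: str) -> float:
        return sum(self.per_genome[genome][c].percent for c in REARRANGED_CLASSES)

    def shared_percent(self, genome: str) -> float:
        return sum(self.per_genome[genome][c].percent for c in ALIGNED_CLASSES)


def pair_summary(
    pair: PairAnnotation,
    min_event_length: int = 200,
    renormalize: bool = True,
) -> PairSummary:
    """Summarise one classified pair.

    Events shorter than ``min_event_length`` bp are dropped everywhere.
    With ``renormalize`` (default) proportions are computed over retained
    bases so they still sum to 100; otherwise raw genome length is the
    denominator.
    """
    per_genome: dict[str, dict[str, ClassStats]] = {}
    for gid in pair.genome_ids:
        kept = [r for r in pair.regions[gid] if r.length >= min_event_length]
        retained_bp = sum(r.length for r in kept)
        denom = retained_bp if renormalize else sum(pair.genome_lengths[gid].values())
        out: dict[str, ClassStats] = {}
        for cls in CLASSES:
            regs = [r for r in kept if r.event_type == cls]
            bp = sum(r.length for r in regs)
            n = len(regs)
            out[cls] = ClassStats(
                percent=100.0 * bp / denom if denom else 0.0,
                count=n,
                mean_kbp=bp / n / 1000.0 if n else 0.0,
            )
        per_genome[gid] = out
    return PairSummary(pair.ref_id, pair.qry_id, min_event_length, per_genome)


# ---------------------------------------------------------------------------
# tree distances


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between tips ``a`` and ``b``."""
    if a == b:
        _find_leaf(tree, a)  # validates tip exists
        return 0.0
    na, nb = _find_leaf(tree, a), _find_leaf(tree, b)
    anc_a = _ancestors(na)
    anc_b = _ancestors(nb)
    ids_a = {id(n): i for i, n in enumerate(anc_a)}
    mrca = next(n for n in anc_b if id(n) in ids_a)
    d = 0.0
    node = na
    while node is not mrca:
        d += node.edge.length or 0.0
        node = node.parent_node
    node = nb
    while node is not mrca:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon else leaf.label
        if lab is not None and lab.replace(" ", "_") == label.replace(" ", "_"):
            return leaf
    raise InputError(f"tip {label!r} not found in tree")


def _ancestors(node: dendropy.Node) -> list[dendropy.Node]:
    out = [node]
    while out[-1].parent_node is not None:
        out.append(out[-1].parent_node)
    return out


def distance_matrix(tree: dendropy.Tree, tips: list[str]) -> np.ndarray:
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = patristic_distance(tree, tips[i], tips[j])
    return d


# ---------------------------------------------------------------------------
# OLS


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def regress_vs_distance(points: list[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares of value on distance, with the two-sided
    t-test p-value for a nonzero slope."""
    if len(points) < 3:
        raise InputError(f"need >= 3 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise InputError("all x values equal; regression undefined")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(points))
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(res.pvalue), len(points),
    )


# ---------------------------------------------------------------------------
# identities


def identity_by_class(pair: PairAnnotation) -> dict[str, float]:
    """Length-weighted mean identity per aligned class, pooled over both
    genomes of the pair; classes with no events are absent."""
    sums: dict[str, float] = {}
    bps: dict[str, int] = {}
    for gid in pair.genome_ids:
        for r in pair.regions[gid]:
            if r.event_type == "UNALIGNED" or r.identity is None:
                continue
            sums[r.event_type] = sums.get(r.event_type, 0.0) + r.identity * r.length
            bps[r.event_type] = bps.get(r.event_type, 0) + r.length
    return {cls: sums[cls] / bps[cls] for cls in sums}


# ---------------------------------------------------------------------------
# long-format export


def summaries_to_table(
    summaries: list[PairSummary], tree: dendropy.Tree | None = None
):
    """Long-format DataFrame (one row per pair x focal genome x class) with
    the patristic distance of the pair when a tree is given."""
    import pandas as pd

    rows = []
    for s in summaries:
        dist = (
            patristic_distance(tree, s.ref_id, s.qry_id) if tree is not None else np.nan
        )
        for gid in (s.ref_id, s.qry_id):
            for cls in CLASSES:
                cs = s.per_genome[gid][cls]
                rows.append(
                    (s.ref_id, s.qry_id, gid, cls, cs.percent, cs.count, cs.mean_kbp, dist)
                )
            rows.append(
                (s.ref_id, s.qry_id, gid, "REARRANGED", s.rearranged_percent(gid),
                 sum(s.per_genome[gid][c].count for c in REARRANGED_CLASSES), np.nan, dist)
            )
            rows.append(
                (s.ref_id, s.qry_id, gid, "TOTAL_SHARED", s.shared_percent(gid),
                 np.nan, np.nan, dist)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genomeA", "genomeB", "focal_genome", "class", "percent",
            "count", "mean_kbp", "distance",
        ],
    )


def write_stats_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
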