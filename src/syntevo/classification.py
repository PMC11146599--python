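"""Partition both genomes of a pair into syntenic, inverted, translocated,
duplicated and unaligned regions.

The classifier works from filtered alignment blocks.  Homologous chromosome
pairs are identified by reciprocal-best aligned length, a syntenic backbone
is selected per chromosome pair as the maximum-weight chain of forward
blocks increasing in both genomes (weighted longest-increasing-subsequence),
and the remaining blocks become inversions, translocations or duplications.
Inverted duplications are recorded as duplications and inverted
translocations as translocations, so orientation is an attribute rather
than a class.  Per-base conflicts are resolved with the precedence
SYN > INV > TRANS > DUP; whatever sequence remains uncovered on each genome
is annotated UNALIGNED, so the five classes tile each genome exactly (the
partition property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._util import interval_overlap, merge_intervals, subtract_intervals
from .alignment import AlignConfig, AlignmentBlock, align_pair, read_paf
from .errors import ConsistencyError, InputError, ParseError
from .genome import Genome

CLASSES = ("SYN", "INV", "TRANS", "DUP", "UNALIGNED")
ALIGNED_CLASSES = ("SYN", "INV", "TRANS", "DUP")
REARRANGED_CLASSES = ("INV", "TRANS", "DUP")


@dataclass
class Annotation:
    """A classified region; SYN/INV/TRANS/DUP carry both sides, UNALIGNED one."""

    event_type: str
    ref_chrom: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None
    qry_chrom: str | None = None
    qry_start: int | None = None
    qry_end: int | None = None
    identity: float | None = None
    member_blocks: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class RegionAnnotation:
    """A classified interval on a single genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    event_type: str
    identity: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PairAnnotation:
    """Complete per-genome annotation sets for one genome pair."""

    ref_id: str
    qry_id: str
    regions: dict[str, list[RegionAnnotation]]
    genome_lengths: dict[str, dict[str, int]]
    events: list[Annotation] = field(default_factory=list)

    @property
    def genome_ids(self) -> tuple[str, str]:
        return (self.ref_id, self.qry_id)

    def other(self, genome_id: str) -> str:
        if genome_id == self.ref_id:
            return self.qry_id
        if genome_id == self.qry_id:
            return self.ref_id
        raise InputError(f"{genome_id!r} not in pair ({self.ref_id}, {self.qry_id})")

    def check_partition(self) -> None:
        """Raise unless annotations tile each genome exactly with no overlap."""
        for gid, regs in self.regions.items():
            per_chrom: dict[str, list[RegionAnnotation]] = {}
            for r in regs:
                per_chrom.setdefault(r.chrom, []).append(r)
            lengths = self.genome_lengths[gid]
            for chrom, L in lengths.items():
                rs = sorted(per_chrom.get(chrom, []), key=lambda r: r.start)
                pos = 0
                for r in rs:
                    if r.start != pos:
                        raise ConsistencyError(
                            f"{gid}:{chrom} gap/overlap at {pos}..{r.start}"
                        )
                    pos = r.end
                if pos != L:
                    raise ConsistencyError(
                        f"{gid}:{chrom} annotations end at {pos}, length {L}"
                    )


# ---------------------------------------------------------------------------
# chromosome homology


def assign_chromosome_homology(blocks: list[AlignmentBlock]) -> dict[str, str]:
    """Greedy reciprocal-best pairing of chromosomes by summed aligned length
    (min of the two spans per block); ties prefer the lexicographically
    smaller query chromosome."""
    weight: dict[tuple[str, str], int] = {}
    for b in blocks:
        weight[(b.ref_chrom, b.qry_chrom)] = weight.get((b.ref_chrom, b.qry_chrom), 0) + b.weight
    pairs = sorted(weight.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_ref: set[str] = set()
    used_qry: set[str] = set()
    mapping: dict[str, str] = {}
    for (rc, qc), _w in pairs:
        if rc in used_ref or qc in used_qry:
            continue
        mapping[rc] = qc
        used_ref.add(rc)
        used_qry.add(qc)
    return mapping


# ---------------------------------------------------------------------------
# backbone (weighted LIS)


def chain_gain(a: AlignmentBlock, b: AlignmentBlock) -> int | None:
    """Weight added by linking ``a -> b`` in a syntenic chain, or None when
    the link is invalid.

    A link requires forward progress in both genomes (starts and ends both
    non-decreasing / strictly increasing).  Blocks may overlap -- tandem
    duplications and breakpoint jitter produce overlapping block envelopes
    -- and the overlapped portion, which will be trimmed off ``b``, is
    deducted from ``b``'s weight.
    """
    if not (
        b.ref_start >= a.ref_start
        and b.qry_start >= a.qry_start
        and b.ref_end > a.ref_end
        and b.qry_end > a.qry_end
    ):
        return None
    overlap = max(0, a.ref_end - b.ref_start, a.qry_end - b.qry_start)
    gain = b.weight - overlap
    return gain if gain > 0 else None


def select_backbone(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Maximum-weight chain of '+' blocks advancing in both ref and qry
    coordinates (weighted longest-increasing-subsequence, weight = min span
    length minus any chain overlap; see :func:`chain_gain`).

    Blocks must share one ref chromosome and its homologous qry chromosome.
    Returns the untrimmed chain members in ref order; overlaps between
    successive members are resolved later by :func:`trim_chain`.
    """
    fwd = [b for b in blocks if b.orientation == "+"]
    if not fwd:
        return []
    fwd.sort(key=lambda b: (b.ref_start, b.ref_end, b.qry_start))
    n = len(fwd)
    score = [0] * n
    parent = [-1] * n
    for i, b in enumerate(fwd):
        score[i] = b.weight
        for j in range(i):
            gain = chain_gain(fwd[j], b)
            if gain is not None and score[j] + gain > score[i]:
                score[i] = score[j] + gain
                parent[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(fwd[i])
        i = parent[i]
    return chain[::-1]


def trim_chain(
    chain: list[AlignmentBlock], min_residual: int = 200
) -> tuple[list[AlignmentBlock], list[AlignmentBlock]]:
    """Resolve overlaps between successive chain members.

    Each member overlapping its predecessor is trimmed at its start by the
    overlap on both genomes (block coordinates are near-diagonal, so equal
    trims keep the correspondence).  Trimmed-off pieces of at least
    ``min_residual`` bp are returned as residual blocks: for a tandem
    duplication the trimmed piece is exactly the copy-to-source alignment,
    which downstream classification turns into a DUP call.
    """
    from dataclasses import replace as _replace

    trimmed: list[AlignmentBlock] = []
    residuals: list[AlignmentBlock] = []
    prev_re = prev_qe = 0
    for b in chain:
        t = max(0, prev_re - b.ref_start, prev_qe - b.qry_start)
        if t > 0:
            if t >= min(b.ref_len, b.qry_len):
                continue  # fully shadowed; defensive, links forbid this
            if t >= min_residual:
                frac = t / max(b.ref_len, b.qry_len)
                residuals.append(
                    _replace(
                        b,
                        ref_end=b.ref_start + t,
                        qry_end=b.qry_start + t,
                        anchor_count=1,
                        anchor_bp=int(b.anchor_bp * frac),
                    )
                )
            b = _replace(b, ref_start=b.ref_start + t, qry_start=b.qry_start + t)
        trimmed.append(b)
        prev_re, prev_qe = b.ref_end, b.qry_end
    return trimmed, residuals


# ---------------------------------------------------------------------------
# classification


def _inversion_runs(
    neg_blocks: list[AlignmentBlock],
    backbone: list[AlignmentBlock],
    ref_len: int,
    qry_len: int,
    tol: int = 100,
) -> tuple[list[list[AlignmentBlock]], list[AlignmentBlock]]:
    """Split '-' blocks of a homologous chromosome pair into inversion runs
    (maximal series lying between consecutive backbone blocks with reversed
    qry order) and leftovers.  Gap containment allows ``tol`` bp of
    breakpoint jitter."""
    # gap boundaries, with chromosome ends as virtual backbone
    bounds = []
    prev_re, prev_qe = 0, 0
    for bb in backbone:
        bounds.append(((prev_re, bb.ref_start), (prev_qe, bb.qry_start)))
        prev_re, prev_qe = bb.ref_end, bb.qry_end
    bounds.append(((prev_re, ref_len), (prev_qe, qry_len)))

    runs: list[list[AlignmentBlock]] = []
    leftovers: list[AlignmentBlock] = []
    assigned: dict[int, list[AlignmentBlock]] = {}
    for b in neg_blocks:
        placed = False
        for gi, ((rs, re_), (qs, qe)) in enumerate(bounds):
            if (
                rs - tol <= b.ref_start
                and b.ref_end <= re_ + tol
                and qs - tol <= b.qry_start
                and b.qry_end <= qe + tol
            ):
                assigned.setdefault(gi, []).append(b)
                placed = True
                break
        if not placed:
            leftovers.append(b)
    for gi in sorted(assigned):
        group = sorted(assigned[gi], key=lambda b: (b.ref_start, b.ref_end))
        # maximal runs with qry order reversed relative to ref order
        run = [group[0]]
        for b in group[1:]:
            if b.qry_end <= run[-1].qry_start:
                run.append(b)
            else:
                runs.append(run)
                run = [b]
        runs.append(run)
    return runs, leftovers


def classify_blocks(
    blocks: list[AlignmentBlock],
    backbones: dict[str, list[AlignmentBlock]],
    homology: dict[str, str],
    ref_lengths: dict[str, int] | None = None,
    qry_lengths: dict[str, int] | None = None,
    tol: int = 100,
) -> list[Annotation]:
    """Assign every block to SYN / INV / TRANS / DUP.

    ``backbones`` maps a ref chromosome to its selected backbone chain.
    Backbone blocks are syntenic.  '-' blocks sitting between consecutive
    backbone blocks with reversed qry order form inversions (one annotation
    per maximal run).  Remaining blocks, processed longest first, become
    translocations when both spans are otherwise uncovered (up to ``tol``
    bp of breakpoint jitter) and duplications when either span overlaps
    already-annotated sequence.
    """
    ref_lengths = ref_lengths or {}
    qry_lengths = qry_lengths or {}
    backbone_ids = {id(b) for chain in backbones.values() for b in chain}
    annotations: list[Annotation] = []
    ref_cov: dict[str, list[tuple[int, int]]] = {}
    qry_cov: dict[str, list[tuple[int, int]]] = {}
    residual_pool: list[AlignmentBlock] = []

    def covered(cov, chrom, span):
        return sum(interval_overlap(span, iv) for iv in cov.get(chrom, []))

    def add_cov(cov, chrom, span):
        cov[chrom] = merge_intervals(cov.get(chrom, []) + [span])

    # 1) backbone -> SYN (chain overlaps trimmed; trimmed-off pieces kept
    #    as residual blocks for the TRANS/DUP stage)
    trimmed_backbones: dict[str, list[AlignmentBlock]] = {}
    for rc, chain in sorted(backbones.items()):
        trimmed, residuals = trim_chain(chain)
        trimmed_backbones[rc] = trimmed
        residual_pool.extend(residuals)
        for b in trimmed:
            annotations.append(
                Annotation(
                    "SYN", b.ref_chrom, b.ref_start, b.ref_end,
                    b.qry_chrom, b.qry_start, b.qry_end, identity=b.identity,
                    member_blocks=[id(b)],
                )
            )
            add_cov(ref_cov, b.ref_chrom, (b.ref_start, b.ref_end))
            add_cov(qry_cov, b.qry_chrom, (b.qry_start, b.qry_end))

    # 2) inversions between backbone neighbours
    leftovers: list[AlignmentBlock] = []
    neg_by_pair: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if id(b) in backbone_ids:
            continue
        if b.orientation == "-" and homology.get(b.ref_chrom) == b.qry_chrom:
            neg_by_pair.setdefault((b.ref_chrom, b.qry_chrom), []).append(b)
        else:
            leftovers.append(b)
    leftovers.extend(residual_pool)
    for (rc, qc), negs in sorted(neg_by_pair.items()):
        runs, extra = _inversion_runs(
            negs, trimmed_backbones.get(rc, []),
            ref_lengths.get(rc, max(b.ref_end for b in negs)),
            qry_lengths.get(qc, max(b.qry_end for b in negs)),
            tol,
        )
        leftovers.extend(extra)
        for run in runs:
            rs = min(b.ref_start for b in run)
            re_ = max(b.ref_end for b in run)
            qs = min(b.qry_start for b in run)
            qe = max(b.qry_end for b in run)
            bp = sum(b.weight for b in run)
            ident = (
                sum((b.identity or 0.0) * b.weight for b in run) / bp if bp else None
            )
            annotations.append(
                Annotation("INV", rc, rs, re_, qc, qs, qe, identity=ident,
                           member_blocks=[id(b) for b in run])
            )
            # coverage is the member blocks' actual spans, not the run
            # envelope: a segment translocated out of an inverted region
            # leaves a hole that must stay claimable by its own block
            for b in run:
                add_cov(ref_cov, rc, (b.ref_start, b.ref_end))
                add_cov(qry_cov, qc, (b.qry_start, b.qry_end))

    # 3) leftovers: TRANS when both sides fresh, DUP when redundant
    leftovers.sort(key=lambda b: (-b.weight, b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    for b in leftovers:
        ov_ref = covered(ref_cov, b.ref_chrom, (b.ref_start, b.ref_end))
        ov_qry = covered(qry_cov, b.qry_chrom, (b.qry_start, b.qry_end))
        etype = "TRANS" if ov_ref <= tol and ov_qry <= tol else "DUP"
        annotations.append(
            Annotation(etype, b.ref_chrom, b.ref_start, b.ref_end,
                       b.qry_chrom, b.qry_start, b.qry_end, identity=b.identity,
                       member_blocks=[id(b)])
        )
        add_cov(ref_cov, b.ref_chrom, (b.ref_start, b.ref_end))
        add_cov(qry_cov, b.qry_chrom, (b.qry_start, b.qry_end))

    return annotations


_PRECEDENCE = {"SYN": 0, "INV": 1, "TRANS": 2, "DUP": 3}


def project_to_genomes(
    annotations: list[Annotation], ref_id: str, qry_id: str
) -> dict[str, list[RegionAnnotation]]:
    """Per-genome single-sided regions with per-base precedence
    SYN > INV > TRANS > DUP: later-processed overlaps are trimmed to
    still-unassigned sequence."""
    out: dict[str, list[RegionAnnotation]] = {ref_id: [], qry_id: []}
    for side, gid in (("ref", ref_id), ("qry", qry_id)):
        cov: dict[str, list[tuple[int, int]]] = {}
        ordered = sorted(
            annotations,
            key=lambda a: (
                _PRECEDENCE[a.event_type],
                -(getattr(a, f"{side}_end") or 0) + (getattr(a, f"{side}_start") or 0),
                getattr(a, f"{side}_chrom") or "",
                getattr(a, f"{side}_start") or 0,
            ),
        )
        for a in ordered:
            chrom = getattr(a, f"{side}_chrom")
            start = getattr(a, f"{side}_start")
            end = getattr(a, f"{side}_end")
            if chrom is None:
                continue
            pieces = subtract_intervals((start, end), cov.get(chrom, []))
            for s, e in pieces:
                if e > s:
                    out[gid].append(RegionAnnotation(chrom, s, e, a.event_type, a.identity))
            cov[chrom] = merge_intervals(cov.get(chrom, []) + [(start, end)])
        out[gid].sort(key=lambda r: (r.chrom, r.start))
    return out


def merge_adjacent(regions: list[RegionAnnotation]) -> list[RegionAnnotation]:
    """Merge unbroken runs of adjacent same-type regions into one; merged
    identity is the length-weighted mean."""
    out: list[RegionAnnotation] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if (
            out
            and out[-1].chrom == r.chrom
            and out[-1].event_type == r.event_type
            and out[-1].end == r.start
        ):
            prev = out[-1]
            if prev.identity is None or r.identity is None:
                ident = prev.identity if r.identity is None else r.identity
            else:
                ident = (
                    prev.identity * prev.length + r.identity * r.length
                ) / (prev.length + r.length)
            out[-1] = RegionAnnotation(prev.chrom, prev.start, r.end, prev.event_type, ident)
        else:
            out.append(r)
    return out


def annotate_unaligned(
    regions: dict[str, list[RegionAnnotation]],
    genome_lengths: dict[str, dict[str, int]],
    ref_id: str,
    qry_id: str,
    events: list[Annotation] | None = None,
) -> PairAnnotation:
    """Fill the complement of aligned sequence with UNALIGNED regions and
    assemble the PairAnnotation; verifies the partition property."""
    full: dict[str, list[RegionAnnotation]] = {}
    for gid, regs in regions.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regs:
            per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for chrom, ivs in per_chrom.items():
            merged = merge_intervals(ivs)
            if sum(e - s for s, e in merged) != sum(e - s for s, e in ivs):
                raise ConsistencyError(
                    f"overlapping aligned annotations on {gid}:{chrom}"
                )
        out = list(regs)
        for chrom, L in genome_lengths[gid].items():
            covered = merge_intervals(per_chrom.get(chrom, []))
            for s, e in subtract_intervals((0, L), covered):
                out.append(RegionAnnotation(chrom, s, e, "UNALIGNED", None))
        out.sort(key=lambda r: (r.chrom, r.start))
        full[gid] = out
    pair = PairAnnotation(ref_id, qry_id, full, genome_lengths, events or [])
    pair.check_partition()
    return pair


def classify_pair(
    ref: Genome,
    qry: Genome,
    config: AlignConfig | None = None,
    ref_id: str = "ref",
    qry_id: str = "qry",
    blocks: list[AlignmentBlock] | None = None,
) -> PairAnnotation:
    """End-to-end classification of one genome pair.

    When ``blocks`` is given (e.g. imported from PAF) the alignment stage is
    skipped.  Deterministic for fixed inputs and configuration.
    """
    config = config or AlignConfig()
    if blocks is None:
        blocks = align_pair(ref, qry, config)
    homology = assign_chromosome_homology(blocks)
    ref_lengths = ref.lengths()
    qry_lengths = qry.lengths()
    backbones: dict[str, list[AlignmentBlock]] = {}
    for rc, qc in homology.items():
        pair_blocks = [
            b for b in blocks if b.ref_chrom == rc and b.qry_chrom == qc
        ]
        backbones[rc] = select_backbone(pair_blocks)
    annotations = classify_blocks(blocks, backbones, homology, ref_lengths, qry_lengths)
    regions = project_to_genomes(annotations, ref_id, qry_id)
    regions = {gid: merge_adjacent(regs) for gid, regs in regions.items()}
    return annotate_unaligned(
        regions,
        {ref_id: ref_lengths, qry_id: qry_lengths},
        ref_id, qry_id, annotations,
    )


# ---------------------------------------------------------------------------
# I/O

_TSV_HEADER = (
    "genome", "chrom", "start", "end", "type", "identity", "pair_ref", "pair_qry",
)


def write_pair_tsv(pair: PairAnnotation, path: str | Path) -> None:
    """Per-genome annotation table, 1-based inclusive coordinates, type
    NOTAL for unaligned (SyRI naming)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for gid in pair.genome_ids:
            for r in pair.regions[gid]:
                typ = "NOTAL" if r.event_type == "UNALIGNED" else r.event_type
                ident = "." if r.identity is None else f"{r.identity:.4f}"
                fh.write(
                    f"{gid}\t{r.chrom}\t{r.start + 1}\t{r.end}\t{typ}\t{ident}\t"
                    f"{pair.ref_id}\t{pair.qry_id}\n"
                )


def read_pair_tsv(path: str | Path) -> PairAnnotation:
    regions: dict[str, list[RegionAnnotation]] = {}
    ref_id = qry_id = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_HEADER:
            raise ParseError(f"unexpected header in {path}")
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_HEADER):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            gid, chrom, s, e, typ, ident, ref_id, qry_id = parts
            typ = "UNALIGNED" if typ == "NOTAL" else typ
            regions.setdefault(gid, []).append(
                RegionAnnotation(
                    chrom, int(s) - 1, int(e), typ,
                    None if ident == "." else float(ident),
                )
            )
    lengths = {
        gid: _lengths_from_regions(regs) for gid, regs in regions.items()
    }
    return PairAnnotation(ref_id, qry_id, regions, lengths)


def _lengths_from_regions(regs: list[RegionAnnotation]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in regs:
        out[r.chrom] = max(out.get(r.chrom, 0), r.end)
    return out


def write_bed(pair: PairAnnotation, outdir: str | Path) -> list[Path]:
    """One BED file per genome per class (0-based half-open)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gid in pair.genome_ids:
        by_type: dict[str, list[RegionAnnotation]] = {}
        for r in pair.regions[gid]:
            by_type.setdefault(r.event_type, []).append(r)
        for typ, regs in sorted(by_type.items()):
            p = outdir / f"{gid}.{typ}.bed"
            with open(p, "w") as fh:
                for r in sorted(regs, key=lambda r: (r.chrom, r.start)):
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{typ}\n")
            paths.append(p)
    return paths
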