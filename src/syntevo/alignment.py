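"""Anchor discovery, chaining into collinear blocks, identity filtering.

The pipeline mirrors a classic maximal-exact-match aligner: find all shared
k-mers between two genomes on both strands (``--maxmatch`` semantics:
non-unique seeds are reported too, up to a per-seed copy cap), merge them
into maximal exact matches, chain nearby matches into collinear blocks, and
drop blocks that are short or too diverged.  Defaults follow the
conventional parameter set k=40, cluster gap 500 bp, minimum cluster 200 bp,
then a post-filter removing blocks <200 bp or <80% identity.

Anchor discovery is vectorised: chromosomes are concatenated with N spacers
(N never matches), every valid k-mer window is grouped with ``np.unique``,
and shared windows are merged into maximal runs along alignment diagonals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import edlib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import revcomp_codes
from .errors import ConfigError, ParseError
from .genome import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignConfig:
    min_match_length: int = 40
    cluster_gap: int = 500
    min_cluster_length: int = 200
    min_block_length: int = 200
    min_identity: float = 80.0
    copy_cap: int = 50  # max reported matches per distinct seed (repeat guard)
    identity_mode: str = "auto"  # exact | fast | auto
    exact_identity_max_span: int = 50_000

    def validate(self) -> None:
        for name in (
            "min_match_length", "cluster_gap", "min_cluster_length",
            "min_block_length", "copy_cap",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.min_identity <= 100:
            raise ConfigError("min_identity must be in (0, 100]")
        if self.identity_mode not in ("exact", "fast", "auto"):
            raise ConfigError(f"unknown identity mode {self.identity_mode!r}")


@dataclass(frozen=True)
class Anchor:
    """One maximal exact match (query coordinates on the forward strand)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AlignmentBlock:
    """A chained cluster of anchors: one collinear aligned segment."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str
    identity: float | None = None
    anchor_count: int = 1
    anchor_bp: int = 0  # summed anchor length, used by fast identity

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def weight(self) -> int:
        return min(self.ref_len, self.qry_len)


# ---------------------------------------------------------------------------
# maximal exact matches


def _concat_genome(genome: Genome, k: int) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Concatenate chromosomes with k-long N spacers; returns (codes, names,
    offsets) where offsets[i] is the global start of chromosome i."""
    names = genome.names
    parts = []
    offsets = []
    pos = 0
    spacer = np.full(k, 4, dtype=np.uint8)
    for i, n in enumerate(names):
        if i > 0:
            parts.append(spacer)
            pos += k
        offsets.append(pos)
        arr = genome.codes(n)
        parts.append(arr)
        pos += len(arr)
    if not parts:
        return np.empty(0, dtype=np.uint8), names, np.empty(0, dtype=np.int64)
    return np.concatenate(parts), names, np.asarray(offsets, dtype=np.int64)


def _valid_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(window bytes as void array, window start positions) for all windows
    free of N."""
    if len(codes) < k:
        return np.empty(0, dtype=np.dtype((np.void, k))), np.empty(0, dtype=np.int64)
    isn = (codes == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(isn)])
    bad = cs[k:] - cs[:-k]
    pos = np.flatnonzero(bad == 0)
    if len(pos) == 0:
        return np.empty(0, dtype=np.dtype((np.void, k))), pos
    win = np.ascontiguousarray(sliding_window_view(codes, k)[pos])
    return win.view(np.dtype((np.void, k))).ravel(), pos


def _match_pairs(
    ref_win: np.ndarray, ref_pos: np.ndarray,
    qry_win: np.ndarray, qry_pos: np.ndarray,
    copy_cap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """All (ref position, qry position) pairs of shared k-mer windows,
    capping each seed's positions per genome at ``copy_cap``."""
    if len(ref_win) == 0 or len(qry_win) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    allwin = np.concatenate([ref_win, qry_win])
    _, inverse, counts = np.unique(allwin, return_inverse=True, return_counts=True)
    nref = len(ref_win)
    inv_r, inv_q = inverse[:nref], inverse[nref:]
    u = len(counts)
    cnt_r = np.bincount(inv_r, minlength=u)
    cnt_q = np.bincount(inv_q, minlength=u)
    shared = (cnt_r > 0) & (cnt_q > 0)

    # fast path: seeds unique in both genomes
    uniq = shared & (cnt_r == 1) & (cnt_q == 1)
    pos_r = np.zeros(u, dtype=np.int64)
    pos_r[inv_r] = ref_pos
    pos_q = np.zeros(u, dtype=np.int64)
    pos_q[inv_q] = qry_pos
    out_r = [pos_r[uniq]]
    out_q = [pos_q[uniq]]

    # repeat seeds: group positions and emit the cross product (capped)
    rep = shared & ~uniq
    if rep.any():
        rep_ids = np.flatnonzero(rep)
        order_r = np.argsort(inv_r, kind="stable")
        order_q = np.argsort(inv_q, kind="stable")
        sorted_r, sorted_q = inv_r[order_r], inv_q[order_q]
        capped = False
        for uid in rep_ids:
            lo = np.searchsorted(sorted_r, uid, "left")
            hi = np.searchsorted(sorted_r, uid, "right")
            rs = ref_pos[order_r[lo:hi]]
            lo = np.searchsorted(sorted_q, uid, "left")
            hi = np.searchsorted(sorted_q, uid, "right")
            qs = qry_pos[order_q[lo:hi]]
            if len(rs) > copy_cap or len(qs) > copy_cap:
                capped = True
                rs, qs = rs[:copy_cap], qs[:copy_cap]
            out_r.append(np.repeat(rs, len(qs)))
            out_q.append(np.tile(qs, len(rs)))
        if capped:
            logger.warning("copy cap %d hit for some repeat seeds", copy_cap)
    return np.concatenate(out_r), np.concatenate(out_q)


def _merge_runs(rpos: np.ndarray, qpos: np.ndarray, k: int):
    """Merge k-mer match pairs into maximal runs along diagonals; yields
    (ref_start, qry_start, length) triples."""
    if len(rpos) == 0:
        return np.empty((0, 3), dtype=np.int64)
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    r, q, d = rpos[order], qpos[order], diag[order]
    brk = np.flatnonzero((np.diff(d) != 0) | (np.diff(q) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(r) - 1]])
    out = np.empty((len(starts), 3), dtype=np.int64)
    out[:, 0] = r[starts]
    out[:, 1] = q[starts]
    out[:, 2] = q[ends] - q[starts] + k
    return out


def _global_to_chrom(pos: np.ndarray, offsets: np.ndarray, names: list[str]):
    idx = np.searchsorted(offsets, pos, side="right") - 1
    return idx, pos - offsets[idx]


def find_max_matches(
    ref: Genome, qry: Genome, min_match_length: int = 40, copy_cap: int = 50
) -> list[Anchor]:
    """All maximal exact matches >= ``min_match_length`` between two genomes,
    on both strands.  N never matches.  Non-unique seeds are reported up to
    ``copy_cap`` copies per genome."""
    if min_match_length < 1:
        raise ConfigError("min_match_length must be positive")
    k = min_match_length
    ref_cat, ref_names, ref_off = _concat_genome(ref, k)
    qry_cat, qry_names, qry_off = _concat_genome(qry, k)
    ref_win, ref_pos = _valid_windows(ref_cat, k)
    anchors: list[Anchor] = []
    for orientation in ("+", "-"):
        if orientation == "+":
            q_cat = qry_cat
        else:
            q_cat = revcomp_codes(qry_cat)
        q_win, q_pos = _valid_windows(q_cat, k)
        rp, qp = _match_pairs(ref_win, ref_pos, q_win, q_pos, copy_cap)
        runs = _merge_runs(rp, qp, k)
        if len(runs) == 0:
            continue
        rstart, qstart, length = runs[:, 0], runs[:, 1], runs[:, 2]
        if orientation == "-":
            # map run on the reverse-complemented query back to forward coords
            total = len(qry_cat)
            qstart = total - (qstart + length)
        ri, rlocal = _global_to_chrom(rstart, ref_off, ref_names)
        qi, qlocal = _global_to_chrom(qstart, qry_off, qry_names)
        for j in range(len(runs)):
            m = int(length[j])
            anchors.append(
                Anchor(
                    ref_names[int(ri[j])], int(rlocal[j]), int(rlocal[j]) + m,
                    qry_names[int(qi[j])], int(qlocal[j]), int(qlocal[j]) + m,
                    orientation,
                )
            )
    anchors.sort(key=lambda a: (a.ref_chrom, a.ref_start, a.qry_chrom, a.qry_start, a.orientation))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def cluster_anchors(anchors: list[Anchor], config: AlignConfig) -> list[AlignmentBlock]:
    """Greedy chaining of same-orientation anchors into collinear blocks.

    Anchors are processed per (ref chrom, qry chrom, orientation) group in
    ref order.  An anchor joins an open chain when the ref gap and qry gap to
    the chain's last anchor are both <= ``cluster_gap`` and the diagonal
    offset between them is consistent (|ref gap - qry gap| <= cluster_gap);
    among eligible chains the one with the larger summed anchor length wins
    (ties: smaller chain ref start).  Chains whose summed anchor length falls
    below ``min_cluster_length`` are dropped; block spans are anchor
    envelopes.
    """
    config.validate()
    groups: dict[tuple, list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.qry_chrom, a.orientation), []).append(a)

    blocks: list[AlignmentBlock] = []
    for (rc, qc, orient), group in sorted(groups.items()):
        group.sort(key=lambda a: (a.ref_start, a.qry_start))
        chains: list[dict] = []  # open chains
        for a in group:
            best = None
            for ch in chains:
                last: Anchor = ch["last"]
                gap_ref = a.ref_start - last.ref_end
                if gap_ref > config.cluster_gap:
                    ch["open"] = False
                    continue
                if not ch["open"]:
                    continue
                if orient == "+":
                    gap_qry = a.qry_start - last.qry_end
                    if a.qry_start < last.qry_start:
                        continue
                else:
                    gap_qry = last.qry_start - a.qry_end
                    if a.qry_end > last.qry_end:
                        continue
                if gap_qry > config.cluster_gap:
                    continue
                if abs(gap_ref - gap_qry) > config.cluster_gap:
                    continue
                if best is None or (ch["bp"], -ch["start"]) > (best["bp"], -best["start"]):
                    best = ch
            if best is None:
                chains.append(
                    {"anchors": [a], "last": a, "bp": a.length, "start": a.ref_start,
                     "open": True}
                )
            else:
                best["anchors"].append(a)
                best["last"] = a
                best["bp"] += a.length
        for ch in chains:
            if ch["bp"] < config.min_cluster_length:
                continue
            mem = ch["anchors"]
            blocks.append(
                AlignmentBlock(
                    rc, min(m.ref_start for m in mem), max(m.ref_end for m in mem),
                    qc, min(m.qry_start for m in mem), max(m.qry_end for m in mem),
                    orient, anchor_count=len(mem), anchor_bp=ch["bp"],
                )
            )
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return blocks


# ---------------------------------------------------------------------------
# identity


def estimate_identity(
    block: AlignmentBlock, ref: Genome, qry: Genome, mode: str = "exact",
    exact_max_span: int = 50_000,
) -> float:
    """Percent identity of a block.

    ``exact``: global end-gap-free alignment of the two spans (matches over
    alignment columns).  ``fast``: summed anchor length over the longer span
    -- a lower bound that avoids alignment.  ``auto``: exact when both spans
    are <= ``exact_max_span``, else fast.
    """
    if mode not in ("exact", "fast", "auto"):
        raise ConfigError(f"unknown identity mode {mode!r}")
    if mode == "auto":
        mode = (
            "exact"
            if max(block.ref_len, block.qry_len) <= exact_max_span
            else "fast"
        )
    if mode == "fast":
        denom = max(block.ref_len, block.qry_len)
        return 100.0 * min(block.anchor_bp, denom) / denom if denom else 0.0
    rseq = ref.seq(block.ref_chrom, block.ref_start, block.ref_end)
    qseq = qry.seq(block.qry_chrom, block.qry_start, block.qry_end)
    if block.orientation == "-":
        from ._util import revcomp

        qseq = revcomp(qseq)
    res = edlib.align(qseq, rseq, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _cigar_ops(res["cigar"]))
    if cols == 0:
        return 0.0
    return 100.0 * (cols - res["editDistance"]) / cols


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def annotate_identity(
    blocks: list[AlignmentBlock], ref: Genome, qry: Genome, config: AlignConfig
) -> list[AlignmentBlock]:
    out = []
    for b in blocks:
        ident = estimate_identity(
            b, ref, qry, mode=config.identity_mode,
            exact_max_span=config.exact_identity_max_span,
        )
        out.append(replace_identity(b, ident))
    return out


def replace_identity(block: AlignmentBlock, identity: float) -> AlignmentBlock:
    return replace(block, identity=identity)


def filter_blocks(blocks: list[AlignmentBlock], config: AlignConfig) -> list[AlignmentBlock]:
    """Keep blocks with min span >= ``min_block_length`` and identity >=
    ``min_identity`` (inclusive thresholds); order preserved."""
    config.validate()
    return [
        b
        for b in blocks
        if min(b.ref_len, b.qry_len) >= config.min_block_length
        and b.identity is not None
        and b.identity >= config.min_identity
    ]


def align_pair(
    ref: Genome, qry: Genome, config: AlignConfig | None = None
) -> list[AlignmentBlock]:
    """Anchors -> chained blocks -> identity -> filtered blocks."""
    config = config or AlignConfig()
    config.validate()
    anchors = find_max_matches(ref, qry, config.min_match_length, config.copy_cap)
    blocks = cluster_anchors(anchors, config)
    blocks = annotate_identity(blocks, ref, qry, config)
    return filter_blocks(blocks, config)


# ---------------------------------------------------------------------------
# PAF import/export


def write_paf(
    blocks: list[AlignmentBlock], path: str | Path,
    ref_lengths: dict[str, int] | None = None,
    qry_lengths: dict[str, int] | None = None,
) -> None:
    """PAF lines (query first, 0-based half-open, strand column).  Identity
    is preserved exactly in an ``id:f`` tag in addition to the standard
    matches/alignment-length columns."""
    ref_lengths = ref_lengths or {}
    qry_lengths = qry_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            alen = max(b.ref_len, b.qry_len)
            nmatch = int(round((b.identity or 0.0) / 100.0 * alen))
            fields = [
                b.qry_chrom, str(qry_lengths.get(b.qry_chrom, b.qry_end)),
                str(b.qry_start), str(b.qry_end), b.orientation,
                b.ref_chrom, str(ref_lengths.get(b.ref_chrom, b.ref_end)),
                str(b.ref_start), str(b.ref_end),
                str(nmatch), str(alen), "255",
                f"cm:i:{b.anchor_count}", f"ab:i:{b.anchor_bp}",
            ]
            if b.identity is not None:
                fields.append(f"id:f:{b.identity:.6f}")
            fh.write("\t".join(fields) + "\n")


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(parts)}")
            try:
                qc, _, qs, qe, strand, rc, _, rs, re_, nmatch, alen = (
                    parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4],
                    parts[5], parts[6], int(parts[7]), int(parts[8]),
                    int(parts[9]), int(parts[10]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            identity = 100.0 * nmatch / alen if alen else 0.0
            anchor_count, anchor_bp = 1, 0
            for tag in parts[12:]:
                if tag.startswith("id:f:"):
                    identity = float(tag[5:])
                elif tag.startswith("cm:i:"):
                    anchor_count = int(tag[5:])
                elif tag.startswith("ab:i:"):
                    anchor_bp = int(tag[5:])
            blocks.append(
                AlignmentBlock(
                    rc, rs, re_, qc, qs, qe, strand, identity=identity,
                    anchor_count=anchor_count, anchor_bp=anchor_bp,
                )
            )
    return blocks
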