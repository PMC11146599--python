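"""Ground-truth bookkeeping: where should a planted event show up?

Event coordinates in the journal refer to the genome state at application
time; later events on the same lineage shift, mirror or relocate them.
This module tracks a planted rearrangement's expected footprint into tip
coordinates and scores whether a classified pair recovered it (correct
type, breakpoints within a tolerance).

Tracking is exact for events that later events do not overlap.  An event
whose footprint is later disrupted (e.g. its span partially deleted or
re-translocated) no longer exists as a distinct signal in the tip genome;
such events are reported separately as "confounded" and excluded from
recovery denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classification import PairAnnotation
from .simulate import SimulationResult, TrueEvent

Interval = tuple[str, int, int]  # chrom, start, end


def expected_footprint(ev: TrueEvent) -> Interval:
    """The annotation interval an event should produce at application time:
    the inverted span for INV, the relocated/new copy for TRANS/DUP."""
    if ev.event_type == "INV":
        return (ev.chrom, ev.start, ev.end)
    if ev.event_type in ("TRANS", "DUP"):
        return (ev.dest_chrom, ev.dest_start, ev.dest_start + ev.size)
    raise ValueError(f"no footprint defined for {ev.event_type}")


def complementary_footprint(ev: TrueEvent) -> Interval | None:
    """Post-application footprint of the complementary chunk of a
    short-range intra-chromosomal translocation (see
    :func:`complementary_translocation_span`), or None when inapplicable."""
    if ev.event_type != "TRANS" or ev.dest_chrom != ev.chrom:
        return None
    if ev.dest_start >= ev.start:
        return (ev.chrom, ev.start, ev.dest_start)
    return (ev.chrom, ev.dest_start + ev.size, ev.start + ev.size)


def transform_interval(iv: Interval, ev: TrueEvent) -> Interval | None:
    """Coordinates of ``iv`` after applying ``ev``; None when the event
    overlaps ``iv`` in a way that destroys it as a distinct signal."""
    chrom, s, e = iv
    t = ev.event_type
    if t == "SUB":
        return iv
    if t == "INV":
        if ev.chrom != chrom or ev.end <= s or e <= ev.start:
            return iv
        if ev.start <= s and e <= ev.end:
            return (chrom, ev.start + ev.end - e, ev.start + ev.end - s)
        return None
    if t == "DEL" or (t == "INDEL" and ev.detail == "-"):
        return _after_deletion(iv, ev.chrom, ev.start, ev.end)
    if t == "INS" or (t == "INDEL" and ev.detail.startswith("+")):
        return _after_insertion(iv, ev.chrom, ev.start, ev.size)
    if t == "DUP":
        return _after_insertion(iv, ev.dest_chrom, ev.dest_start, ev.size)
    if t == "TRANS":
        if ev.chrom == chrom and ev.start <= s and e <= ev.end:
            off = ev.dest_start
            if ev.detail == "inverted":
                return (ev.dest_chrom, off + (ev.end - e), off + (ev.end - s))
            return (ev.dest_chrom, off + (s - ev.start), off + (e - ev.start))
        out = _after_deletion(iv, ev.chrom, ev.start, ev.end)
        if out is None:
            return None
        return _after_insertion(out, ev.dest_chrom, ev.dest_start, ev.size)
    raise ValueError(f"unknown event type {t}")


def _after_deletion(iv: Interval, c: str, a: int, b: int) -> Interval | None:
    chrom, s, e = iv
    if chrom != c or e <= a:
        return iv
    if s >= b:
        return (chrom, s - (b - a), e - (b - a))
    return None


def _after_insertion(iv: Interval, c: str, p: int, size: int) -> Interval | None:
    chrom, s, e = iv
    if chrom != c or e <= p:
        return iv
    if s >= p:
        return (chrom, s + size, e + size)
    return None  # insertion lands inside the tracked interval


def untransform_interval(iv: Interval, ev: TrueEvent) -> Interval | None:
    """Coordinates of ``iv`` in the genome state *before* ``ev`` was applied;
    None when the mapping is ambiguous or the sequence did not exist yet.
    Intervals inside a duplication's copy map back to its source."""
    chrom, s, e = iv
    t = ev.event_type
    if t == "SUB":
        return iv
    if t == "INV":
        if ev.chrom != chrom or ev.end <= s or e <= ev.start:
            return iv
        if ev.start <= s and e <= ev.end:
            return (chrom, ev.start + ev.end - e, ev.start + ev.end - s)
        return None
    if t == "DEL" or (t == "INDEL" and ev.detail == "-"):
        # inverse of a deletion is an insertion at its start
        if chrom != ev.chrom or e <= ev.start:
            return iv
        if s >= ev.start:
            return (chrom, s + ev.size, e + ev.size)
        return (chrom, s, e + ev.size)  # straddles: restored span re-enters
    if t == "INS" or (t == "INDEL" and ev.detail.startswith("+")):
        pos = ev.start
        if chrom != ev.chrom or e <= pos:
            return iv
        if s >= pos + ev.size:
            return (chrom, s - ev.size, e - ev.size)
        return None  # lies (partly) in novel sequence
    if t == "DUP":
        if chrom == ev.dest_chrom and ev.dest_start <= s and e <= ev.dest_start + ev.size:
            rel_s, rel_e = s - ev.dest_start, e - ev.dest_start
            if ev.detail == "inverted":
                return (ev.chrom, ev.end - rel_e, ev.end - rel_s)
            return (ev.chrom, ev.start + rel_s, ev.start + rel_e)
        out = _after_insertion_inverse(iv, ev.dest_chrom, ev.dest_start, ev.size)
        return out
    if t == "TRANS":
        if chrom == ev.dest_chrom and ev.dest_start <= s and e <= ev.dest_start + ev.size:
            rel_s, rel_e = s - ev.dest_start, e - ev.dest_start
            if ev.detail == "inverted":
                return (ev.chrom, ev.end - rel_e, ev.end - rel_s)
            return (ev.chrom, ev.start + rel_s, ev.start + rel_e)
        out = _after_insertion_inverse(iv, ev.dest_chrom, ev.dest_start, ev.size)
        if out is None:
            return None
        # undo the excision: positions at/after the source shift right
        chrom, s, e = out
        if chrom != ev.chrom or e <= ev.start:
            return out
        if s >= ev.start:
            return (chrom, s + ev.size, e + ev.size)
        return None
    raise ValueError(f"unknown event type {t}")


def _after_insertion_inverse(iv: Interval, c: str, p: int, size: int) -> Interval | None:
    """Undo an insertion of ``size`` bp at ``p`` for an interval outside it."""
    chrom, s, e = iv
    if chrom != c or e <= p:
        return iv
    if s >= p + size:
        return (chrom, s - size, e - size)
    return None


def track_to_tip(
    simres: SimulationResult,
    ev: TrueEvent,
    tip: str,
    footprint: Interval | None = None,
) -> Interval | None:
    """Expected footprint of ``ev`` in the coordinates of ``tip``'s genome.

    ``footprint`` (default :func:`expected_footprint`) is given in the
    frame immediately *after* ``ev`` was applied."""
    path_events = simres.events_for_tip(tip)
    idx = next(i for i, e in enumerate(path_events) if e is ev)
    iv: Interval | None = footprint if footprint is not None else expected_footprint(ev)
    for later in path_events[idx + 1 :]:
        iv = transform_interval(iv, later)
        if iv is None:
            return None
    return iv


def _forward_flip(iv: Interval, ev: TrueEvent) -> bool:
    """Does applying ``ev`` mirror ``iv`` (reverse its orientation)?"""
    chrom, s, e = iv
    if ev.event_type == "INV":
        return ev.chrom == chrom and ev.start <= s and e <= ev.end
    if ev.event_type == "TRANS":
        return (
            ev.detail == "inverted"
            and ev.chrom == chrom and ev.start <= s and e <= ev.end
        )
    return False


def _inverse_flip(iv: Interval, ev: TrueEvent) -> bool:
    """Does undoing ``ev`` mirror ``iv``?  (Copy-to-source mapping of an
    inverted TRANS/DUP also flips.)"""
    chrom, s, e = iv
    if ev.event_type == "INV":
        return ev.chrom == chrom and ev.start <= s and e <= ev.end
    if ev.event_type in ("TRANS", "DUP"):
        return (
            ev.detail == "inverted"
            and ev.dest_chrom == chrom
            and ev.dest_start <= s and e <= ev.dest_start + ev.size
        )
    return False


def relative_inversion_parity(
    simres: SimulationResult, ev: TrueEvent, tip: str, partner: str
) -> int | None:
    """Number (mod 2) of *additional* orientation flips the source region
    of ``ev`` accumulates between ``tip`` and ``partner`` after the event.

    An odd parity means a later inversion (or inverted move) on either
    lineage re-mirrors the region, so a planted inversion no longer
    appears inverted in this pair.  None when tracking is disrupted.
    """
    tip_events = simres.events_for_tip(tip)
    partner_events = simres.events_for_tip(partner)
    shared = {id(e) for e in tip_events} & {id(e) for e in partner_events}
    idx = next(i for i, e in enumerate(tip_events) if e is ev)
    flips = 0
    # tip side: footprint forward through later tip events
    iv: Interval | None = expected_footprint(ev)
    for later in tip_events[idx + 1 :]:
        if _forward_flip(iv, later):
            flips += 1
        iv = transform_interval(iv, later)
        if iv is None:
            return None
    # partner side: source span back to the ancestor, then forward
    iv = (ev.chrom, ev.start, ev.end)
    for earlier in reversed(tip_events[:idx]):
        if id(earlier) in shared:
            break
        if _inverse_flip(iv, earlier):
            flips += 1
        iv = untransform_interval(iv, earlier)
        if iv is None:
            return None
    for later in partner_events:
        if id(later) in shared:
            continue
        if _forward_flip(iv, later):
            flips += 1
        iv = transform_interval(iv, later)
        if iv is None:
            return None
    return flips % 2


def partner_region(
    simres: SimulationResult,
    ev: TrueEvent,
    tip: str,
    partner: str,
    interval: Interval | None = None,
) -> Interval | None:
    """The homologous region of ``ev`` in ``partner``'s genome.

    ``interval`` (default: the event's source span, in the frame just
    before ``ev`` was applied) is mapped back through the earlier events of
    ``tip``'s lineage to the common-ancestor frame and forward through
    ``partner``'s lineage; None when either direction disrupts it, in which
    case the pair no longer carries an intact two-genome signal of the
    event.
    """
    tip_events = simres.events_for_tip(tip)
    partner_events = simres.events_for_tip(partner)
    shared = {id(e) for e in tip_events} & {id(e) for e in partner_events}
    idx = next(i for i, e in enumerate(tip_events) if e is ev)
    iv: Interval | None = interval if interval is not None else (ev.chrom, ev.start, ev.end)
    for earlier in reversed(tip_events[:idx]):
        if id(earlier) in shared:
            break
        iv = untransform_interval(iv, earlier)
        if iv is None:
            return None
    for later in partner_events:
        if id(later) in shared:
            continue
        iv = transform_interval(iv, later)
        if iv is None:
            return None
    return iv


def complementary_translocation_span(ev: TrueEvent) -> Interval | None:
    """The complementary description of a short-range intra-chromosomal
    translocation, in the frame just before ``ev`` was applied.

    Moving segment X past its neighbour Y is indistinguishable from moving
    Y past X in a pairwise alignment; the classifier may report either
    chunk as translocated.  Returns Y's span, or None when the move is
    inter-chromosomal (no such ambiguity)."""
    if ev.event_type != "TRANS" or ev.dest_chrom != ev.chrom:
        return None
    if ev.dest_start >= ev.start:
        # moved right: Y is the chunk between old and new location
        return (ev.chrom, ev.end, ev.end + (ev.dest_start - ev.start))
    return (ev.chrom, ev.dest_start, ev.start)


@dataclass
class RecoveryReport:
    n_planted: int  # trackable planted events of sufficient size
    n_recovered: int
    n_confounded: int  # disrupted by later events; excluded from n_planted
    misses: list[tuple[str, str, Interval]]  # (tip, type, expected interval)

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0


def score_recovery(
    simres: SimulationResult,
    pair: PairAnnotation,
    min_size: int = 1000,
    tol: int = 100,
) -> RecoveryReport:
    """Score recovery of planted rearrangements for one classified pair.

    Considers INV/TRANS/DUP events of at least ``min_size`` bp planted on
    branches private to one side of the pair; an event is recovered when
    the genome it occurred in carries an annotation of the same type whose
    breakpoints both lie within ``tol`` bp of the tracked footprint.
    """
    a, b = pair.genome_ids
    path_a, path_b = set(simres.branch_path(a)), set(simres.branch_path(b))
    n = rec = conf = 0
    misses: list[tuple[str, str, Interval]] = []
    for tip, partner, private in (
        (a, b, path_a - path_b),
        (b, a, path_b - path_a),
    ):
        side = "ref" if tip == pair.ref_id else "qry"
        calls = [
            (
                ann.event_type,
                getattr(ann, f"{side}_chrom"),
                getattr(ann, f"{side}_start"),
                getattr(ann, f"{side}_end"),
            )
            for ann in pair.events
            if ann.event_type in ("INV", "TRANS", "DUP")
        ]
        for ev in simres.journal:
            if ev.branch_id not in private:
                continue
            if ev.event_type not in ("INV", "TRANS", "DUP") or ev.size < min_size:
                continue
            iv = track_to_tip(simres, ev, tip)
            if iv is None or partner_region(simres, ev, tip, partner) is None:
                conf += 1  # no intact two-genome signal left
                continue
            if (
                ev.event_type == "INV"
                and relative_inversion_parity(simres, ev, tip, partner) != 0
            ):
                conf += 1  # re-mirrored: no longer inverted in this pair
                continue
            n += 1
            # a short-range intra-chromosomal translocation may equally be
            # reported as its complementary chunk moving the other way
            candidates = [iv]
            comp = complementary_footprint(ev)
            if comp is not None:
                comp_tip = track_to_tip(simres, ev, tip, footprint=comp)
                if comp_tip is not None:
                    candidates.append(comp_tip)
            hit = any(
                typ == ev.event_type
                and c == chrom
                and abs(cs - s) <= tol
                and abs(ce - e) <= tol
                for chrom, s, e in candidates
                for typ, c, cs, ce in calls
            )
            if hit:
                rec += 1
            else:
                misses.append((tip, ev.event_type, iv))
    return RecoveryReport(n, rec, conf, misses)
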