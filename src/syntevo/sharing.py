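"""Per-base sharing across all pairwise comparisons of a focal genome.

For each base of the focal genome, counts in how many other genomes that
base is shared, where "shared" means the base falls in an aligned class
(SYN, INV, TRANS or DUP; a flag can exclude DUP) of the focal genome in the
focal-vs-other pair.  Bases unaligned in every comparison are unique to the
focal genome; bases shared with all n-1 others are core sequence.

Counts are accumulated with per-chromosome difference arrays, so memory and
time scale with the number of annotations, not their lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classification import PairAnnotation
from .errors import InputError


@dataclass
class SharingProfile:
    focal: str
    n_genomes: int  # including the focal genome
    counts: dict[str, np.ndarray]  # chrom -> per-base count in [0, n-1]

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.counts.values())


def sharing_profile(
    focal: str,
    pairs: list[PairAnnotation],
    include_duplications: bool = True,
) -> SharingProfile:
    """Combine all pairwise annotations of ``focal`` into per-base counts."""
    others = []
    for p in pairs:
        if focal not in p.genome_ids:
            raise InputError(
                f"pair ({p.ref_id}, {p.qry_id}) does not involve focal {focal!r}"
            )
        others.append(p.other(focal))
    if len(set(others)) != len(others):
        raise InputError(f"duplicate comparisons for focal {focal!r}")
    if not pairs:
        raise InputError("no pairs given")

    lengths = pairs[0].genome_lengths[focal]
    for p in pairs[1:]:
        if p.genome_lengths[focal] != lengths:
            raise InputError(f"inconsistent chromosome lengths for {focal!r}")

    shared_classes = {"SYN", "INV", "TRANS"} | ({"DUP"} if include_duplications else set())
    diffs = {c: np.zeros(L + 1, dtype=np.int32) for c, L in lengths.items()}
    for p in pairs:
        for r in p.regions[focal]:
            if r.event_type in shared_classes:
                diffs[r.chrom][r.start] += 1
                diffs[r.chrom][r.end] -= 1
    counts = {c: np.cumsum(d[:-1]).astype(np.int32) for c, d in diffs.items()}
    return SharingProfile(focal, len(pairs) + 1, counts)


@dataclass
class SharingSummary:
    focal: str
    n_genomes: int
    unique_percent: float  # bases shared with no other genome
    core_percent: float  # bases shared with all n-1 others
    histogram: np.ndarray  # histogram[k] = bases shared with exactly k others

    @property
    def genome_length(self) -> int:
        return int(self.histogram.sum())


def sharing_summary(profile: SharingProfile) -> SharingSummary:
    n = profile.n_genomes
    hist = np.zeros(n, dtype=np.int64)
    for arr in profile.counts.values():
        hist += np.bincount(arr, minlength=n)[:n]
    L = int(hist.sum())
    return SharingSummary(
        profile.focal, n,
        unique_percent=100.0 * hist[0] / L if L else 0.0,
        core_percent=100.0 * hist[n - 1] / L if L else 0.0,
        histogram=hist,
    )


def write_bedgraph(profile: SharingProfile, path: str | Path) -> None:
    """Per-base counts as a bedGraph (runs of equal count collapsed)."""
    with open(path, "w") as fh:
        for chrom in profile.counts:
            arr = profile.counts[chrom]
            if len(arr) == 0:
                continue
            brk = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate([[0], brk + 1])
            ends = np.concatenate([brk + 1, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(arr[s])}\n")
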