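"""Genome evolution simulator.

Generates a random root genome and evolves it along a rooted phylogeny,
applying substitutions, small indels, inversions, translocations,
duplications, insertions and deletions on every branch.  Every mutation is
journalled as a :class:`TrueEvent`; replaying the journal against the root
genome reproduces each tip exactly, which is what makes the downstream
classification stages testable against known ground truth.

The default rearrangement regime mirrors what is seen between congeneric
plant genomes with a conserved karyotype: duplications are short and very
common, translocations intermediate in both size and count, and inversions
long and very rare.  Rates are expressed per genome per unit branch length
(substitution and small-indel rates per bp per unit), so the branch lengths
of the input tree set the molecular clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from ._util import decode_seq, derive_seed, revcomp_codes
from .errors import ConfigError, InputError
from .genome import Genome

logger = logging.getLogger(__name__)

RETRY_CAP = 100

EVENT_TYPES = ("SUB", "INDEL", "INV", "TRANS", "DUP", "INS", "DEL")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Root-genome parameters.

    ``n_chromosomes`` defaults to 11, the conserved eucalypt karyotype;
    ``gc_fraction`` defaults to 0.39, a typical eucalypt GC content.
    """

    n_chromosomes: int = 11
    chromosome_length: int = 100_000
    gc_fraction: float = 0.39
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        if self.chromosome_length < 1000:
            raise ConfigError(
                f"chromosome_length must be >= 1000, got {self.chromosome_length}"
            )
        if not 0.0 < self.gc_fraction < 1.0:
            raise ConfigError(f"gc_fraction must be in (0,1), got {self.gc_fraction}")


@dataclass(frozen=True)
class SizeDist:
    """Event-size distribution: 'constant', 'uniform' or 'lognormal' (bp)."""

    name: str = "uniform"
    low: float = 1
    high: float = 1
    mean_log: float = 0.0
    sigma_log: float = 1.0

    def validate(self) -> None:
        if self.name not in ("constant", "uniform", "lognormal"):
            raise ConfigError(f"unknown size distribution {self.name!r}")
        if self.name == "uniform" and not (1 <= self.low <= self.high):
            raise ConfigError("uniform size distribution needs 1 <= low <= high")
        if self.name == "constant" and self.low < 1:
            raise ConfigError("constant size must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        if self.name == "constant":
            return int(self.low)
        if self.name == "uniform":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        return max(1, int(round(rng.lognormal(self.mean_log, self.sigma_log))))

    def mean(self) -> float:
        if self.name == "constant":
            return float(self.low)
        if self.name == "uniform":
            return (self.low + self.high) / 2.0
        return float(np.exp(self.mean_log + self.sigma_log**2 / 2.0))


@dataclass(frozen=True)
class EvolutionRates:
    """Mutation regime.

    Structural rates are events per genome per unit branch length;
    ``substitution_rate`` and ``small_indel_rate`` are per bp per unit
    branch length.  ``fixed_counts`` overrides the Poisson draw with an
    exact per-branch count for the named classes (used to plant events).
    """

    substitution_rate: float = 0.01
    small_indel_rate: float = 2e-4
    inversion_rate: float = 2.0
    translocation_rate: float = 20.0
    duplication_rate: float = 40.0
    insertion_rate: float = 15.0
    deletion_rate: float = 15.0
    inversion_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 5000, 10000))
    translocation_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 1000, 3000))
    duplication_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 500, 2000))
    insertion_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 500, 2000))
    deletion_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 500, 2000))
    small_indel_size: SizeDist = field(default_factory=lambda: SizeDist("uniform", 1, 10))
    p_inter_chromosomal: float = 0.5  # translocation destination on another chromosome
    p_tandem: float = 0.5  # duplication inserted immediately after the source
    fixed_counts: dict[str, int] | None = None

    def validate(self) -> None:
        for name in (
            "substitution_rate",
            "small_indel_rate",
            "inversion_rate",
            "translocation_rate",
            "duplication_rate",
            "insertion_rate",
            "deletion_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "inversion_size",
            "translocation_size",
            "duplication_size",
            "insertion_size",
            "deletion_size",
            "small_indel_size",
        ):
            getattr(self, name).validate()
        if self.fixed_counts:
            bad = set(self.fixed_counts) - {"INV", "TRANS", "DUP", "INS", "DEL"}
            if bad:
                raise ConfigError(f"fixed_counts has unknown classes: {sorted(bad)}")

    def with_fixed_counts(self, **counts: int) -> "EvolutionRates":
        return replace(self, fixed_counts=dict(counts))


# ---------------------------------------------------------------------------
# events


@dataclass
class TrueEvent:
    """One applied mutation; coordinates refer to the genome state at the
    moment the event was applied (0-based half-open)."""

    branch_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None
    dest_start: int | None = None
    size: int = 0
    detail: str = ""  # replay payload: new base (SUB), inserted sequence, etc.

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ConfigError(f"unknown event type {self.event_type!r}")


def apply_event(genome: Genome, ev: TrueEvent, rng: np.random.Generator | None = None) -> None:
    """Mutate ``genome`` in place according to ``ev``.

    The simulator and the replay path share this single implementation, so
    journal replay reproduces tips by construction.
    """
    arr = genome.chroms[ev.chrom]
    if ev.event_type == "SUB":
        arr[ev.start] = "ACGTN".index(ev.detail)
    elif ev.event_type == "INV":
        arr[ev.start : ev.end] = revcomp_codes(arr[ev.start : ev.end])
    elif ev.event_type == "DEL" or (ev.event_type == "INDEL" and ev.detail == "-"):
        genome.chroms[ev.chrom] = np.concatenate([arr[: ev.start], arr[ev.end :]])
    elif ev.event_type == "INS" or (ev.event_type == "INDEL" and ev.detail.startswith("+")):
        ins = _encode_payload(ev.detail[1:] if ev.event_type == "INDEL" else ev.detail)
        genome.chroms[ev.chrom] = np.concatenate([arr[: ev.start], ins, arr[ev.start :]])
    elif ev.event_type == "TRANS":
        payload = arr[ev.start : ev.end].copy()
        genome.chroms[ev.chrom] = np.concatenate([arr[: ev.start], arr[ev.end :]])
        if ev.detail == "inverted":
            payload = revcomp_codes(payload)
        dest = genome.chroms[ev.dest_chrom]
        genome.chroms[ev.dest_chrom] = np.concatenate(
            [dest[: ev.dest_start], payload, dest[ev.dest_start :]]
        )
    elif ev.event_type == "DUP":
        payload = arr[ev.start : ev.end].copy()
        if ev.detail == "inverted":
            payload = revcomp_codes(payload)
        dest = genome.chroms[ev.dest_chrom]
        genome.chroms[ev.dest_chrom] = np.concatenate(
            [dest[: ev.dest_start], payload, dest[ev.dest_start :]]
        )
    else:
        raise ConfigError(f"cannot apply event type {ev.event_type!r}")


def _encode_payload(seq: str) -> np.ndarray:
    from ._util import encode_seq

    return encode_seq(seq)


# ---------------------------------------------------------------------------
# root genome


def make_root_genome(config: SimulationConfig) -> Genome:
    """Random genome of ``n_chromosomes`` x ``chromosome_length`` bp with the
    requested GC content; chromosomes named chr1..chrN."""
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "root"))
    gc, at = config.gc_fraction / 2.0, (1.0 - config.gc_fraction) / 2.0
    probs = np.array([at, gc, gc, at])  # A C G T
    g = Genome()
    for i in range(config.n_chromosomes):
        codes = rng.choice(4, size=config.chromosome_length, p=probs).astype(np.uint8)
        g.chroms[f"chr{i + 1}"] = codes
    return g


# ---------------------------------------------------------------------------
# branch evolution


def _weighted_chrom(rng: np.random.Generator, genome: Genome) -> str:
    names = genome.names
    lens = np.array([genome.length(n) for n in names], dtype=float)
    return names[rng.choice(len(names), p=lens / lens.sum())]


def _sample_span(
    rng: np.random.Generator, genome: Genome, dist: SizeDist, what: str
) -> tuple[str, int, int] | None:
    """A (chrom, start, end) span with end-start drawn from ``dist``; spans
    that do not fit their chromosome are resampled up to RETRY_CAP times."""
    for _ in range(RETRY_CAP):
        chrom = _weighted_chrom(rng, genome)
        size = dist.sample(rng)
        L = genome.length(chrom)
        if size <= L:
            start = int(rng.integers(0, L - size + 1))
            return chrom, start, start + size
    logger.warning("could not place %s event after %d tries; skipped", what, RETRY_CAP)
    return None


def _random_seq(rng: np.random.Generator, size: int) -> str:
    return decode_seq(rng.integers(0, 4, size=size).astype(np.uint8))


def evolve_branch(
    genome: Genome, branch_length: float, rates: EvolutionRates, seed: int,
    branch_id: str = "branch",
) -> tuple[Genome, list[TrueEvent]]:
    """Evolve a copy of ``genome`` for ``branch_length`` time units.

    Event counts per class are Poisson(rate x branch_length) unless
    ``rates.fixed_counts`` pins them.  Structural events are applied first
    (INV, TRANS, DUP, INS, DEL in that order), then small indels, then
    substitutions; the journal lists events in application order.
    """
    rates.validate()
    if branch_length < 0:
        raise InputError(f"branch_length must be >= 0, got {branch_length}")
    rng = np.random.default_rng(seed)
    out = genome.copy()
    journal: list[TrueEvent] = []
    t = branch_length

    def n_events(cls: str, rate: float) -> int:
        if rates.fixed_counts is not None and cls in rates.fixed_counts:
            return rates.fixed_counts[cls]
        return int(rng.poisson(rate * t)) if rate * t > 0 else 0

    # --- inversions
    for _ in range(n_events("INV", rates.inversion_rate)):
        span = _sample_span(rng, out, rates.inversion_size, "INV")
        if span is None:
            continue
        c, s, e = span
        ev = TrueEvent(branch_id, "INV", c, s, e, size=e - s)
        apply_event(out, ev)
        journal.append(ev)

    # --- translocations
    for _ in range(n_events("TRANS", rates.translocation_rate)):
        span = _sample_span(rng, out, rates.translocation_size, "TRANS")
        if span is None:
            continue
        c, s, e = span
        if len(out.names) > 1 and rng.random() < rates.p_inter_chromosomal:
            others = [n for n in out.names if n != c]
            dchrom = others[int(rng.integers(0, len(others)))]
            dlen = out.length(dchrom)
        else:
            dchrom = c
            dlen = out.length(c) - (e - s)  # post-excision length
        dstart = int(rng.integers(0, dlen + 1))
        inverted = rng.random() < 0.5
        ev = TrueEvent(
            branch_id, "TRANS", c, s, e, dest_chrom=dchrom, dest_start=dstart,
            size=e - s, detail="inverted" if inverted else "",
        )
        apply_event(out, ev)
        journal.append(ev)

    # --- duplications
    for _ in range(n_events("DUP", rates.duplication_rate)):
        span = _sample_span(rng, out, rates.duplication_size, "DUP")
        if span is None:
            continue
        c, s, e = span
        if rng.random() < rates.p_tandem:
            dchrom, dstart, inverted = c, e, False
        else:
            dchrom = _weighted_chrom(rng, out)
            dstart = int(rng.integers(0, out.length(dchrom) + 1))
            inverted = rng.random() < 0.5
        ev = TrueEvent(
            branch_id, "DUP", c, s, e, dest_chrom=dchrom, dest_start=dstart,
            size=e - s, detail="inverted" if inverted else "",
        )
        apply_event(out, ev)
        journal.append(ev)

    # --- novel insertions
    for _ in range(n_events("INS", rates.insertion_rate)):
        chrom = _weighted_chrom(rng, out)
        size = rates.insertion_size.sample(rng)
        pos = int(rng.integers(0, out.length(chrom) + 1))
        ev = TrueEvent(
            branch_id, "INS", chrom, pos, pos + size, size=size,
            detail=_random_seq(rng, size),
        )
        apply_event(out, ev)
        journal.append(ev)

    # --- deletions
    for _ in range(n_events("DEL", rates.deletion_rate)):
        span = _sample_span(rng, out, rates.deletion_size, "DEL")
        if span is None:
            continue
        c, s, e = span
        ev = TrueEvent(branch_id, "DEL", c, s, e, size=e - s)
        apply_event(out, ev)
        journal.append(ev)

    # --- small indels (per-bp rate)
    total = len(out)
    n_indel = int(rng.poisson(rates.small_indel_rate * t * total)) if total else 0
    for _ in range(n_indel):
        chrom = _weighted_chrom(rng, out)
        size = rates.small_indel_size.sample(rng)
        if rng.random() < 0.5 and out.length(chrom) > size:
            s = int(rng.integers(0, out.length(chrom) - size + 1))
            ev = TrueEvent(branch_id, "INDEL", chrom, s, s + size, size=size, detail="-")
        else:
            pos = int(rng.integers(0, out.length(chrom) + 1))
            ev = TrueEvent(
                branch_id, "INDEL", chrom, pos, pos + size, size=size,
                detail="+" + _random_seq(rng, size),
            )
        apply_event(out, ev)
        journal.append(ev)

    # --- substitutions (per-bp rate; never change genome length)
    total = len(out)
    n_sub = int(rng.poisson(rates.substitution_rate * t * total)) if total else 0
    if n_sub:
        names = out.names
        lens = np.array([out.length(n) for n in names], dtype=float)
        chrom_idx = rng.choice(len(names), size=n_sub, p=lens / lens.sum())
        for ci in chrom_idx:
            chrom = names[ci]
            pos = int(rng.integers(0, out.length(chrom)))
            old = int(out.chroms[chrom][pos])
            new = int(rng.integers(0, 3))
            if new >= old:
                new += 1  # pick uniformly among the 3 other bases
            new = min(new, 3)
            ev = TrueEvent(
                branch_id, "SUB", chrom, pos, pos + 1, size=1, detail="ACGT"[new]
            )
            apply_event(out, ev)
            journal.append(ev)

    return out, journal


# ---------------------------------------------------------------------------
# clade simulation


@dataclass
class SimulationResult:
    tip_genomes: dict[str, Genome]
    journal: list[TrueEvent]
    tree: dendropy.Tree
    root_genome: Genome
    gene_sets: dict[str, list["GeneInterval"]] | None = None
    og_table: "object | None" = None  # pandas DataFrame (og_id, species, gene_id)

    def branch_path(self, tip: str) -> list[str]:
        """Branch ids on the root-to-tip path."""
        for leaf in self.tree.leaf_node_iter():
            if _node_id(leaf) == tip:
                path = []
                node = leaf
                while node.parent_node is not None:
                    path.append(_node_id(node))
                    node = node.parent_node
                return path[::-1]
        raise InputError(f"tip {tip!r} not in tree")

    def events_for_tip(self, tip: str) -> list[TrueEvent]:
        branches = set(self.branch_path(tip))
        return [ev for ev in self.journal if ev.branch_id in branches]


def _node_id(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label.replace(" ", "_")
    return node.label


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"n{i}"
        i += 1


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree, preserving underscores in labels."""
    return dendropy.Tree.get(
        path=str(source), schema="newick", preserve_underscores=True
    )


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_clade(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rates: EvolutionRates,
    seed: int | None = None,
) -> SimulationResult:
    """Evolve a root genome down every edge of ``tree`` (pre-order).

    Per-edge seeds are derived from the master seed and the edge's head-node
    label, so results do not depend on traversal order.
    """
    config.validate()
    rates.validate()
    if seed is None:
        seed = config.seed
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise InputError("tree must have at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError("negative branch length in tree")
    _label_internal_nodes(tree)

    root_genome = make_root_genome(replace(config, seed=seed))
    journal: list[TrueEvent] = []
    tips: dict[str, Genome] = {}

    def recurse(node: dendropy.Node, genome: Genome) -> None:
        for child in node.child_nodes():
            branch_id = _node_id(child)
            t = child.edge.length if child.edge.length is not None else 0.0
            child_genome, evs = evolve_branch(
                genome, t, rates, derive_seed(seed, "branch", branch_id), branch_id
            )
            journal.extend(evs)
            if child.is_leaf():
                tips[_node_id(child)] = child_genome
            else:
                recurse(child, child_genome)

    recurse(tree.seed_node, root_genome)
    return SimulationResult(tips, journal, tree, root_genome)


def replay(root_genome: Genome, events: list[TrueEvent]) -> Genome:
    """Apply ``events`` in order to a copy of the root genome."""
    g = root_genome.copy()
    for ev in events:
        apply_event(g, ev)
    return g


# ---------------------------------------------------------------------------
# gene synthesis


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int
    end: int
    gene_id: str
    og_id: str | None  # None = unplaced in any orthogroup


def synthesize_genes(
    simres: SimulationResult,
    gene_density: float = 0.05,
    core_fraction: float = 0.2133,
    private_fraction: float = 0.0267,
    seed: int = 0,
    gene_length: tuple[int, int] = (1000, 3000),
    unplaced_fraction: float = 0.02,
) -> tuple[dict[str, list[GeneInterval]], "object"]:
    """Plant non-overlapping gene intervals on every tip and assign
    orthogroup membership.

    ``gene_density`` is genes per kbp.  Orthogroup classes are drawn per OG:
    core (all tips), private (one tip) or dispensable (2..n-1 tips) with the
    requested fractions; defaults follow the eucalypt pangenome proportions
    (21.33% core / 76.00% dispensable / 2.67% private).  A small fraction of
    genes is left unplaced in any OG, mimicking orthology-clustering dropout.
    """
    import pandas as pd

    if not (0 <= core_fraction <= 1 and 0 <= private_fraction <= 1):
        raise InputError("fractions must lie in [0,1]")
    if core_fraction + private_fraction > 1 + 1e-12:
        raise InputError("core_fraction + private_fraction must be <= 1")
    rng = np.random.default_rng(derive_seed(seed, "genes"))
    tips = sorted(simres.tip_genomes)
    n = len(tips)
    disp_fraction = 1.0 - core_fraction - private_fraction
    if n < 3 and disp_fraction > 0:
        # no k in 2..n-1 exists; fold dispensable mass into core
        core_fraction += disp_fraction
        disp_fraction = 0.0

    mean_len = sum(len(g) for g in simres.tip_genomes.values()) / n
    genes_per_tip = gene_density * mean_len / 1000.0
    exp_presence = (
        core_fraction * n + private_fraction * 1 + disp_fraction * (2 + n - 1) / 2.0
    )
    n_ogs = max(1, int(round(genes_per_tip * n / exp_presence)))

    classes = rng.choice(
        3, size=n_ogs, p=[core_fraction, disp_fraction, private_fraction]
    )
    membership: dict[str, list[str]] = {t: [] for t in tips}  # tip -> og ids
    for i, cls in enumerate(classes):
        og = f"OG{i:05d}"
        if cls == 0:
            present = tips
        elif cls == 2:
            present = [tips[int(rng.integers(0, n))]]
        else:
            k = int(rng.integers(2, n))  # 2..n-1
            present = [tips[j] for j in sorted(rng.choice(n, size=k, replace=False))]
        for t in present:
            membership[t].append(og)

    gene_sets: dict[str, list[GeneInterval]] = {}
    rows = []
    for tip in tips:
        genome = simres.tip_genomes[tip]
        ogs = membership[tip]
        n_placed = len(ogs)
        n_unplaced = int(round(n_placed * unplaced_fraction / max(1e-12, 1 - unplaced_fraction)))
        og_ids: list[str | None] = list(ogs) + [None] * n_unplaced
        order = rng.permutation(len(og_ids))
        og_ids = [og_ids[i] for i in order]
        lengths = rng.integers(gene_length[0], gene_length[1] + 1, size=len(og_ids))

        # distribute genes over chromosomes proportional to length
        names = genome.names
        chrom_lens = np.array([genome.length(c) for c in names], dtype=float)
        assignment = rng.choice(len(names), size=len(og_ids), p=chrom_lens / chrom_lens.sum())
        genes: list[GeneInterval] = []
        gi = 0
        for ci, chrom in enumerate(names):
            idx = np.flatnonzero(assignment == ci)
            if len(idx) == 0:
                continue
            lens_here = lengths[idx]
            total = int(lens_here.sum())
            L = genome.length(chrom)
            free = L - total
            if free < 0:
                raise InputError(
                    f"gene density too high: {total} gene bp > {L} bp on {chrom} of {tip}"
                )
            cuts = np.sort(rng.integers(0, free + 1, size=len(idx)))
            offset = 0
            for j, k in enumerate(idx):
                start = int(cuts[j]) + offset
                end = start + int(lens_here[j])
                offset += int(lens_here[j])
                gene_id = f"{tip}.g{gi:05d}"
                gi += 1
                genes.append(GeneInterval(chrom, start, end, gene_id, og_ids[k]))
                if og_ids[k] is not None:
                    rows.append((og_ids[k], tip, gene_id))
        gene_sets[tip] = sorted(genes, key=lambda g: (g.chrom, g.start))

    og_table = pd.DataFrame(rows, columns=["og_id", "species", "gene_id"])
    simres.gene_sets = gene_sets
    simres.og_table = og_table
    return gene_sets, og_table


# ---------------------------------------------------------------------------
# fixture I/O

JOURNAL_COLUMNS = (
    "branch", "type", "chrom", "start", "end", "dest_chrom", "dest_start", "size", "detail",
)


def write_journal(journal: list[TrueEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(JOURNAL_COLUMNS) + "\n")
        for ev in journal:
            fh.write(
                "\t".join(
                    [
                        ev.branch_id, ev.event_type, ev.chrom,
                        str(ev.start), str(ev.end),
                        ev.dest_chrom or ".", "." if ev.dest_start is None else str(ev.dest_start),
                        str(ev.size), ev.detail or ".",
                    ]
                )
                + "\n"
            )


def read_journal(path: str | Path) -> list[TrueEvent]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != JOURNAL_COLUMNS:
            raise InputError(f"unexpected journal header in {path}")
        for line in fh:
            b, t, c, s, e, dc, ds, sz, det = line.rstrip("\n").split("\t")
            out.append(
                TrueEvent(
                    b, t, c, int(s), int(e),
                    dest_chrom=None if dc == "." else dc,
                    dest_start=None if ds == "." else int(ds),
                    size=int(sz),
                    detail="" if det == "." else det,
                )
            )
    return out


def write_gff3(genes: list[GeneInterval], path: str | Path) -> None:
    """Gene features only; OG id carried in the OG= attribute (OG=unplaced
    for genes outside every orthogroup).  1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            og = g.og_id if g.og_id is not None else "unplaced"
            fh.write(
                f"{g.chrom}\tsyntevo\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id};OG={og}\n"
            )


def write_fixture(simres: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-tip FASTA, the tree, the truth journal, per-tip gene GFF3
    and the orthogroup table.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    for tip, genome in simres.tip_genomes.items():
        p = gdir / f"{tip}.fa"
        genome.to_fasta(p)
        paths[f"genome:{tip}"] = p
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(
        simres.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["tree"] = tree_path
    jpath = outdir / "journal.tsv"
    write_journal(simres.journal, jpath)
    paths["journal"] = jpath
    if simres.gene_sets is not None:
        adir = outdir / "genes"
        adir.mkdir(exist_ok=True)
        for tip, genes in simres.gene_sets.items():
            p = adir / f"{tip}.gff3"
            write_gff3(genes, p)
            paths[f"genes:{tip}"] = p
        ogp = outdir / "orthogroups.tsv"
        simres.og_table.to_csv(ogp, sep="\t", index=False)
        paths["orthogroups"] = ogp
    return paths
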