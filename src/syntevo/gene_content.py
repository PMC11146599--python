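"""Genic content of events and sequence-level pangenome classes.

An event is *genic* when at least 1 bp of a gene that was placed in an
orthogroup overlaps it (full-containment mode available); events too short
to plausibly contain a gene (default < 1 kbp) are discarded first, as are
genes unplaced in any orthogroup.  Orthogroups themselves are classified as
core (present in all species), dispensable (2..n-1) or private (exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from ._util import round_half_up
from .classification import CLASSES, PairAnnotation
from .errors import InputError, ParseError
from .simulate import GeneInterval


@dataclass
class GeneSet:
    genome_id: str
    genes: list[GeneInterval]

    def placed(self) -> list[GeneInterval]:
        return [g for g in self.genes if g.og_id is not None]


def load_genes(
    gff_path: str | Path,
    og_table_path: str | Path | None = None,
    genome_id: str | None = None,
) -> GeneSet:
    """Read gene features from GFF3 and attach orthogroup ids.

    OG membership comes from the ``OG=`` attribute when present, otherwise
    from the orthogroup table (og_id, species, gene_id).  Genes found in
    neither are flagged unplaced.
    """
    import gffutils

    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.stem
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted exceptions on bad input
        raise ParseError(f"cannot parse {gff_path}: {exc}") from exc

    og_map: dict[str, str] = {}
    if og_table_path is not None:
        table = pd.read_csv(og_table_path, sep="\t")
        table = table[table["species"] == genome_id]
        og_map = dict(zip(table["gene_id"], table["og_id"]))

    genes: list[GeneInterval] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise InputError(f"duplicate gene id {gene_id!r} in {gff_path}")
        seen.add(gene_id)
        og = feat.attributes.get("OG", [None])[0]
        if og in (None, "unplaced"):
            og = og_map.get(gene_id)
        genes.append(GeneInterval(feat.seqid, feat.start - 1, feat.end, gene_id, og))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GeneSet(genome_id, genes)


def gene_set_from_intervals(genome_id: str, genes: list[GeneInterval]) -> GeneSet:
    return GeneSet(genome_id, sorted(genes, key=lambda g: (g.chrom, g.start)))


# ---------------------------------------------------------------------------
# genic classification


def genic_classify(
    pair: PairAnnotation,
    gene_sets: dict[str, GeneSet],
    min_event_length: int = 1000,
    containment: bool = False,
) -> dict[str, dict[str, tuple[float, int, int]]]:
    """Per-genome, per-class genic proportions for one pair.

    Returns genome -> class -> (genic %, retained events, genic events);
    classes with no retained events are absent for that genome.  An event is
    genic when >= 1 bp of an orthogroup-placed gene overlaps it, or, with
    ``containment=True``, when a placed gene lies entirely inside it.
    """
    for gid in pair.genome_ids:
        if gid not in gene_sets:
            raise InputError(f"no gene set for genome {gid!r}")
    out: dict[str, dict[str, tuple[float, int, int]]] = {}
    for gid in pair.genome_ids:
        trees: dict[str, IntervalTree] = {}
        for g in gene_sets[gid].placed():
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        stats: dict[str, tuple[float, int, int]] = {}
        for cls in CLASSES:
            regs = [
                r for r in pair.regions[gid]
                if r.event_type == cls and r.length >= min_event_length
            ]
            if not regs:
                continue
            genic = 0
            for r in regs:
                tree = trees.get(r.chrom)
                if tree is None:
                    continue
                if containment:
                    if any(iv.begin >= r.start and iv.end <= r.end
                           for iv in tree.overlap(r.start, r.end)):
                        genic += 1
                elif tree.overlaps(r.start, r.end):
                    genic += 1
            stats[cls] = (100.0 * genic / len(regs), len(regs), genic)
        out[gid] = stats
    return out


@dataclass(frozen=True)
class GenicClassSummary:
    mean: float
    min: float
    max: float
    n_pairs: int


def average_genic(
    per_pair: list[dict[str, tuple[float, int, int]]]
) -> dict[str, GenicClassSummary]:
    """Average one genome's per-pair genic proportions; pairs in which a
    class had no retained events are skipped for that class."""
    if not per_pair:
        raise InputError("no pair results given")
    out: dict[str, GenicClassSummary] = {}
    for cls in CLASSES:
        vals = [res[cls][0] for res in per_pair if cls in res]
        if vals:
            out[cls] = GenicClassSummary(
                sum(vals) / len(vals), min(vals), max(vals), len(vals)
            )
    return out


# ---------------------------------------------------------------------------
# pangenome


def og_matrix_from_table(og_table: pd.DataFrame, species: list[str] | None = None) -> pd.DataFrame:
    """Orthogroup x species gene-count matrix from a long (og_id, species,
    gene_id) table."""
    mat = og_table.pivot_table(
        index="og_id", columns="species", values="gene_id", aggfunc="count", fill_value=0
    )
    if species is not None:
        for sp in species:
            if sp not in mat.columns:
                mat[sp] = 0
        mat = mat[list(species)]
    return mat


@dataclass
class PangenomeSummary:
    n_species: int
    total_ogs: int
    core: int
    dispensable: int
    private: int
    core_percent: float
    dispensable_percent: float
    private_percent: float
    placed_gene_percent: float | None = None  # given total/placed gene counts


def pangenome_classify(
    matrix: pd.DataFrame,
    total_genes: int | None = None,
    placed_genes: int | None = None,
) -> PangenomeSummary:
    """Core / dispensable / private orthogroup tallies.

    ``matrix`` is orthogroups x species (counts or presence).  Percentages
    are of total orthogroups, rounded half-up to 2 decimals.  When total and
    OG-placed gene counts are supplied, the percent of genes placed in any
    orthogroup is reported too.
    """
    if matrix.empty:
        raise InputError("empty orthogroup matrix")
    presence = matrix.astype(bool)
    n_species = presence.shape[1]
    per_og = presence.sum(axis=1)
    if (per_og < 1).any():
        raise InputError("orthogroup present in no species")
    core = int((per_og == n_species).sum())
    private = int((per_og == 1).sum()) if n_species > 1 else 0
    total = int(len(per_og))
    dispensable = total - core - private
    placed_pct = None
    if total_genes is not None and placed_genes is not None:
        placed_pct = round_half_up(100.0 * placed_genes / total_genes, 2)
    return PangenomeSummary(
        n_species, total, core, dispensable, private,
        round_half_up(100.0 * core / total, 2),
        round_half_up(100.0 * dispensable / total, 2),
        round_half_up(100.0 * private / total, 2),
        placed_pct,
    )


def write_genic_tsv(
    rows: dict[str, dict[str, GenicClassSummary]], path: str | Path
) -> None:
    """rows: genome -> class -> summary."""
    with open(path, "w") as fh:
        fh.write("genome\tclass\tmean\tmin\tmax\tn_pairs\n")
        for gid in sorted(rows):
            for cls, s in rows[gid].items():
                fh.write(f"{gid}\t{cls}\t{s.mean:.4f}\t{s.min:.4f}\t{s.max:.4f}\t{s.n_pairs}\n")


def write_pangenome_tsv(summary: PangenomeSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tcount\tpercent\n")
        fh.write(f"core\t{summary.core}\t{summary.core_percent}\n")
        fh.write(f"dispensable\t{summary.dispensable}\t{summary.dispensable_percent}\n")
        fh.write(f"private\t{summary.private}\t{summary.private_percent}\n")
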