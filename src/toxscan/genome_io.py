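"""Genome/scaffold/gene data model and readers/writers.

Internal coordinates are 0-based half-open throughout the package; every
text format written for humans (gene table, island TSV) is 1-based
inclusive, and BED output is 0-based half-open, so ``length == end - start``
holds on both sides of the conversion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "scaffold_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "is_toxin",
    "is_antitoxin",
]

ISLAND_TSV_COLUMNS = [
    "genome_id",
    "scaffold_id",
    "start",
    "end",
    "length_bp",
    "n_toxins",
    "n_antitoxins",
    "T",
    "G",
    "score",
    "p_value",
    "passed_filters",
    "cluster_id",
    "representative",
]


class LabelSource(str, Enum):
    """Evidence class behind a gene's toxin/antitoxin flags."""

    DOMAIN = "domain"
    HOMOLOGY = "homology"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class Gene:
    """A located coding feature, optionally labeled toxin and/or antitoxin.

    ``start``/``end`` are 0-based half-open scaffold coordinates. A gene
    carrying either flag is a *toxinome gene*; a gene may carry both.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    product: str = ""
    is_toxin: bool = False
    is_antitoxin: bool = False
    label_source: LabelSource = LabelSource.NONE

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def is_toxinome(self) -> bool:
        return self.is_toxin or self.is_antitoxin

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.gene_id)


@dataclass
class Scaffold:
    """A contiguous DNA sequence carrying an ordered gene list.

    Genes are kept sorted by (start, end, gene_id) so segment boundaries are
    reproducible. ``length`` defaults to the maximum gene end when the true
    scaffold length is unknown.
    """

    scaffold_id: str
    length: int = 0
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=Gene.sort_key)
        if self.length <= 0:
            self.length = max((g.end for g in self.genes), default=0)
            if self.genes:
                logger.debug(
                    "scaffold %s: length unknown, using max gene end %d",
                    self.scaffold_id,
                    self.length,
                )
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id!r} ends at {g.end} beyond scaffold "
                    f"{self.scaffold_id!r} length {self.length}"
                )

    @property
    def toxinome_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.is_toxinome]


@dataclass
class Genome:
    """A bacterial genome: one or more scaffolds plus optional taxonomy."""

    genome_id: str
    scaffolds: list[Scaffold] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.scaffold_id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id!r}: duplicate scaffold ids")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.scaffolds)

    @property
    def genes(self) -> list[Gene]:
        return [g for s in self.scaffolds for g in s.genes]


def _parse_bool(value: str, line_no: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no", ""):
        return False
    raise ValueError(f"line {line_no}: cannot parse boolean {column}={value!r}")


def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[Genome]:
    """Read a tab-separated gene table into Genome objects.

    The file carries 1-based inclusive coordinates; genes come back in
    internal 0-based half-open coordinates, sorted per scaffold. An optional
    ``scaffold_length`` column sets scaffold lengths; otherwise the maximum
    gene end is used.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    path = Path(path)
    per_genome: dict[str, dict[str, list[Gene]]] = {}
    scaffold_lengths: dict[tuple[str, str], int] = {}
    seen_gene_ids: dict[str, set[str]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header line")
        required = set(GENE_TABLE_COLUMNS[:7])
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                start_1 = int(row["start"])
                end_1 = int(row["end"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} line {line_no}: malformed row: {exc}") from exc
            if start_1 > end_1:
                raise ValueError(
                    f"{path} line {line_no}: start {start_1} > end {end_1}"
                )
            genome_id = row["genome_id"]
            gene = Gene(
                gene_id=row["gene_id"],
                scaffold_id=row["scaffold_id"],
                start=start_1 - 1,
                end=end_1,
                strand=row["strand"] or ".",
                product=row.get("product") or "",
                is_toxin=_parse_bool(row.get("is_toxin") or "0", line_no, "is_toxin"),
                is_antitoxin=_parse_bool(
                    row.get("is_antitoxin") or "0", line_no, "is_antitoxin"
                ),
            )
            seen = seen_gene_ids.setdefault(genome_id, set())
            if gene.gene_id in seen:
                raise ValueError(
                    f"{path} line {line_no}: duplicate gene_id {gene.gene_id!r} "
                    f"in genome {genome_id!r}"
                )
            seen.add(gene.gene_id)
            per_genome.setdefault(genome_id, {}).setdefault(
                gene.scaffold_id, []
            ).append(gene)
            if row.get("scaffold_length"):
                scaffold_lengths[(genome_id, gene.scaffold_id)] = int(
                    row["scaffold_length"]
                )
    genomes = []
    for genome_id in sorted(per_genome):
        scaffolds = [
            Scaffold(
                scaffold_id=sid,
                length=scaffold_lengths.get((genome_id, sid), 0),
                genes=genes,
            )
            for sid, genes in sorted(per_genome[genome_id].items())
        ]
        genomes.append(Genome(genome_id=genome_id, scaffolds=scaffolds))
    return genomes


def write_gene_table(genomes: Iterable[Genome], path: str | Path) -> None:
    """Write genomes as a 1-based inclusive gene table (round-trips with
    :func:`read_gene_table`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS + ["scaffold_length"])
        for genome in genomes:
            for scaffold in genome.scaffolds:
                for g in scaffold.genes:
                    writer.writerow(
                        [
                            genome.genome_id,
                            scaffold.scaffold_id,
                            g.gene_id,
                            g.start + 1,
                            g.end,
                            g.strand,
                            g.product,
                            int(g.is_toxin),
                            int(g.is_antitoxin),
                            scaffold.length,
                        ]
                    )


def read_labels_table(path: str | Path) -> dict[str, tuple[bool, bool]]:
    """Read a gene_id → (is_toxin, is_antitoxin) label table (TSV)."""
    labels: dict[str, tuple[bool, bool]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_id" not in reader.fieldnames:
            raise ValueError(f"{path}: expected columns gene_id, is_toxin, is_antitoxin")
        for line_no, row in enumerate(reader, start=2):
            labels[row["gene_id"]] = (
                _parse_bool(row.get("is_toxin") or "0", line_no, "is_toxin"),
                _parse_bool(row.get("is_antitoxin") or "0", line_no, "is_antitoxin"),
            )
    return labels


def read_gff3(
    path: str | Path, label_table: str | Path | None = None
) -> list[Genome]:
    """Read gene/CDS features from a GFF3 file.

    Labels come from an optional TSV mapping gene IDs to toxin/antitoxin
    flags; genes absent from it stay unlabeled, label rows naming unknown
    genes are warned about and ignored. Features without an ID are skipped
    with a warning.
    """
    import gffutils

    path = Path(path)
    # pre-validate so parse failures carry a line number
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # embedded FASTA section
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"{path} line {line_no}: not a 9-column GFF3 line")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    labels = read_labels_table(label_table) if label_table else {}
    per_scaffold: dict[str, list[Gene]] = {}
    region_lengths: dict[str, int] = {}
    seen_ids: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype in ("region", "chromosome", "contig"):
            region_lengths[feat.seqid] = max(
                region_lengths.get(feat.seqid, 0), feat.end
            )
            continue
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            logger.warning("%s: %s feature without ID skipped", path, feat.featuretype)
            continue
        if gid in seen_ids:
            continue  # gene + its CDS share an ID once merged
        seen_ids.add(gid)
        is_tox, is_anti = labels.get(gid, (False, False))
        per_scaffold.setdefault(feat.seqid, []).append(
            Gene(
                gene_id=gid,
                scaffold_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                product=feat.attributes.get("product", [""])[0],
                is_toxin=is_tox,
                is_antitoxin=is_anti,
            )
        )
    for unknown in sorted(set(labels) - seen_ids):
        logger.warning("label table names unknown gene id %r; ignored", unknown)
    genome_id = path.stem
    scaffolds = [
        Scaffold(sid, length=region_lengths.get(sid, 0), genes=genes)
        for sid, genes in sorted(per_scaffold.items())
    ]
    return [Genome(genome_id=genome_id, scaffolds=scaffolds)]


def apply_labels(genome: Genome, labels: dict[str, tuple[bool, bool]]) -> Genome:
    """Return a copy of *genome* with toxin/antitoxin flags from *labels*."""
    scaffolds = []
    for scaffold in genome.scaffolds:
        genes = []
        for g in scaffold.genes:
            if g.gene_id in labels:
                is_tox, is_anti = labels[g.gene_id]
                g = replace(g, is_toxin=is_tox, is_antitoxin=is_anti)
            genes.append(g)
        scaffolds.append(Scaffold(scaffold.scaffold_id, scaffold.length, genes))
    return Genome(genome.genome_id, scaffolds, dict(genome.taxonomy))


def write_islands(islands: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write classified islands as TSV (1-based inclusive) or BED6.

    BED score is ``min(1000, round(score))`` and the name field is
    ``genome_id:island_index``.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(ISLAND_TSV_COLUMNS)
            for isl in islands:
                writer.writerow(
                    [
                        isl.genome_id,
                        isl.scaffold_id,
                        isl.start + 1,
                        isl.end,
                        isl.end - isl.start,
                        isl.n_toxins,
                        isl.n_antitoxins,
                        isl.T,
                        isl.G,
                        f"{isl.score:.6g}",
                        f"{isl.p_value:.6g}",
                        int(isl.passed),
                        getattr(isl, "cluster_id", "") or "",
                        int(getattr(isl, "representative", False)),
                    ]
                )
    elif format == "bed":
        with path.open("w") as fh:
            for i, isl in enumerate(islands):
                fh.write(
                    "\t".join(
                        [
                            isl.scaffold_id,
                            str(isl.start),
                            str(isl.end),
                            f"{isl.genome_id}:{i}",
                            str(min(1000, round(isl.score))),
                            ".",
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown island output format {format!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read scaffold sequences (uppercased) keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
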