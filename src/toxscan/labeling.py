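"""Toxin/antitoxin label assignment from domain and homology evidence.

Two evidence channels label a gene as toxin and/or antitoxin (immunity):

* **domain** — a Pfam domain hit whose accession is on a curated toxin or
  antitoxin accession list;
* **homology** — an alignment hit to a labeled reference protein passing
  identity > 30%, query and subject coverage >= 0.95 and e-value <= 0.05.

A third filter set (identity >= 40%, query cover >= 0.90, subject cover
>= 0.60, e <= 0.001, best 25 by bitscore) serves interactive homology
search, and a structure-hit filter (e < 0.003, TM-score > 0.6, query cover
>= 0.90) handles annotation of hypothetical proteins. Strict-vs-inclusive
boundaries follow the wording of each rule and are covered by tests.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .genome_io import Gene, LabelSource

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainHit:
    """One domain alignment on a gene's protein (HMMER per-domain row)."""

    gene_id: str
    domain_acc: str
    domain_name: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if self.ali_start >= self.ali_end:
            raise ValueError("alignment start must precede end")


@dataclass(frozen=True)
class HomologyHit:
    """One protein alignment hit with query/subject coverage fractions."""

    query_id: str
    subject_id: str
    pident: float
    qcov: float
    scov: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.pident <= 100:
            raise ValueError("pident must be a percentage in [0, 100]")
        if not (0 <= self.qcov <= 1 and 0 <= self.scov <= 1):
            raise ValueError("coverages must be fractions in [0, 1]")


@dataclass(frozen=True)
class StructureHit:
    """One structural-alignment hit (e.g. a Foldseek row)."""

    query_id: str
    target_id: str
    evalue: float
    tm_score: float
    qcov: float

    def __post_init__(self) -> None:
        if not 0 <= self.tm_score <= 1:
            raise ValueError("TM-score must be in [0, 1]")


def _load_accessions(name: str) -> frozenset[str]:
    text = resources.files("toxscan.data").joinpath(name).read_text()
    return frozenset(
        line.split()[0]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass
class LabelConfig:
    """Curated domain lists plus every hit-filter threshold.

    Defaults are the published operating points; all are overridable from
    YAML. The two domain sets are expected to be disjoint — an overlap is
    reported, not rejected.
    """

    toxin_domains: frozenset[str] = field(default_factory=lambda: _load_accessions("toxin_domains.txt"))
    antitoxin_domains: frozenset[str] = field(default_factory=lambda: _load_accessions("antitoxin_domains.txt"))
    homology_min_pident: float = 30.0  # strict >
    homology_min_cov: float = 0.95  # applied to both qcov and scov
    homology_max_e: float = 0.05
    search_min_pident: float = 40.0
    search_min_qcov: float = 0.90
    search_min_scov: float = 0.60
    search_max_e: float = 0.001
    search_top_n: int = 25
    struct_max_e: float = 0.003  # strict <
    struct_min_tm: float = 0.6  # strict >
    struct_min_qcov: float = 0.90

    def __post_init__(self) -> None:
        overlap = self.toxin_domains & self.antitoxin_domains
        if overlap:
            logger.warning(
                "%d accessions on both domain lists: %s",
                len(overlap),
                sorted(overlap)[:5],
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("toxin_domains", "antitoxin_domains"):
            if key in raw:
                val = raw.pop(key)
                if isinstance(val, str):  # path to an accession file
                    kwargs[key] = frozenset(
                        line.split()[0]
                        for line in Path(val).read_text().splitlines()
                        if line.strip() and not line.startswith("#")
                    )
                else:
                    kwargs[key] = frozenset(val)
        kwargs.update(raw)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# parsers

_DOMTBL_MIN_COLS = 22


def read_domtblout(path: str | Path, orientation: str = "hmmscan") -> list[DomainHit]:
    """Parse HMMER per-domain tabular output (``--domtblout``).

    ``orientation="hmmscan"`` reads the target columns as the domain and the
    query columns as the gene (protein); ``"hmmsearch"`` swaps them. The
    per-domain independent e-value and alignment coordinates are kept.
    """
    if orientation not in ("hmmscan", "hmmsearch"):
        raise ValueError(f"unknown domtblout orientation {orientation!r}")
    hits = []
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path} line {line_no}: expected >= {_DOMTBL_MIN_COLS} "
                    f"columns, got {len(cols)}"
                )
            if orientation == "hmmscan":
                domain_name, domain_acc, gene_id = cols[0], cols[1], cols[3]
            else:
                gene_id, domain_name, domain_acc = cols[0], cols[3], cols[4]
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    domain_acc=domain_acc.split(".")[0],  # strip Pfam version
                    domain_name=domain_name,
                    evalue=float(cols[12]),
                    ali_start=int(cols[17]),
                    ali_end=int(cols[18]),
                )
            )
    return hits


def read_homology_table(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tabular alignment output with two appended coverage
    columns (query coverage, subject coverage, as fractions): columns
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore qcov scov."""
    hits = []
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 14:
                raise ValueError(
                    f"{path} line {line_no}: need 14 columns (12-column "
                    "alignment format plus qcov and scov fractions), got "
                    f"{len(cols)}"
                )
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pident=float(cols[2]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    qcov=float(cols[12]),
                    scov=float(cols[13]),
                )
            )
    return hits


def read_structure_table(path: str | Path) -> list[StructureHit]:
    """Parse a structure-hit TSV: query, target, evalue, tm_score, qcov."""
    hits = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hits.append(
                StructureHit(
                    query_id=row["query"],
                    target_id=row["target"],
                    evalue=float(row["evalue"]),
                    tm_score=float(row["tm_score"]),
                    qcov=float(row["qcov"]),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# filters

def filter_homology_hits(
    hits: list[HomologyHit], cfg: LabelConfig | None = None
) -> list[HomologyHit]:
    """Database-mapping filter: identity strictly above 30%, both coverages
    >= 0.95, e-value <= 0.05. Order is preserved; idempotent."""
    cfg = cfg or LabelConfig()
    return [
        h
        for h in hits
        if h.pident > cfg.homology_min_pident
        and min(h.qcov, h.scov) >= cfg.homology_min_cov
        and h.evalue <= cfg.homology_max_e
    ]


def rank_search_hits(
    hits: list[HomologyHit], cfg: LabelConfig | None = None
) -> list[HomologyHit]:
    """Interactive-search filter and ranking: qcov >= 0.90, scov >= 0.60,
    identity >= 40%, e <= 0.001; best hits by descending bitscore (ties:
    ascending e-value, then subject id), at most 25 returned."""
    cfg = cfg or LabelConfig()
    passing = [
        h
        for h in hits
        if h.qcov >= cfg.search_min_qcov
        and h.scov >= cfg.search_min_scov
        and h.pident >= cfg.search_min_pident
        and h.evalue <= cfg.search_max_e
    ]
    passing.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return passing[: cfg.search_top_n]


def filter_structure_hits(
    hits: list[StructureHit], cfg: LabelConfig | None = None
) -> list[StructureHit]:
    """Structure-annotation filter: e strictly below 0.003, TM-score strictly
    above 0.6, query coverage at least 0.90."""
    cfg = cfg or LabelConfig()
    return [
        h
        for h in hits
        if h.evalue < cfg.struct_max_e
        and h.tm_score > cfg.struct_min_tm
        and h.qcov >= cfg.struct_min_qcov
    ]


# ---------------------------------------------------------------------------
# label assignment

def assign_labels(
    genes: list[Gene],
    domain_hits: list[DomainHit] | None = None,
    homology_hits: list[HomologyHit] | None = None,
    reference_labels: dict[str, str] | None = None,
    cfg: LabelConfig | None = None,
) -> list[Gene]:
    """Set toxin/antitoxin flags on genes from both evidence channels.

    A gene becomes a toxin if any of its domain hits is on the toxin list or
    any (pre-filtered) homology hit points at a toxin-labeled reference;
    antitoxin analogously. Evidence only ever adds flags — a flag already
    true on input stays true. ``label_source`` records which channel(s)
    contributed. Homology hits whose subject is missing from
    *reference_labels* are warned about and ignored.
    """
    cfg = cfg or LabelConfig()
    domain_hits = domain_hits or []
    homology_hits = homology_hits or []
    reference_labels = reference_labels or {}

    dom_tox: set[str] = set()
    dom_anti: set[str] = set()
    for h in domain_hits:
        if h.domain_acc in cfg.toxin_domains:
            dom_tox.add(h.gene_id)
        if h.domain_acc in cfg.antitoxin_domains:
            dom_anti.add(h.gene_id)

    hom_tox: set[str] = set()
    hom_anti: set[str] = set()
    for h in homology_hits:
        kind = reference_labels.get(h.subject_id)
        if kind is None:
            logger.warning(
                "homology hit %s -> %s: subject not in reference labels; ignored",
                h.query_id,
                h.subject_id,
            )
            continue
        if kind == "toxin":
            hom_tox.add(h.query_id)
        elif kind == "antitoxin":
            hom_anti.add(h.query_id)
        else:
            raise ValueError(f"reference label must be toxin/antitoxin, got {kind!r}")

    out = []
    for g in genes:
        from_domain = g.gene_id in dom_tox or g.gene_id in dom_anti
        from_homology = g.gene_id in hom_tox or g.gene_id in hom_anti
        is_toxin = g.is_toxin or g.gene_id in dom_tox or g.gene_id in hom_tox
        is_antitoxin = g.is_antitoxin or g.gene_id in dom_anti or g.gene_id in hom_anti
        if from_domain and from_homology:
            source = LabelSource.BOTH
        elif from_domain:
            source = LabelSource.DOMAIN
        elif from_homology:
            source = LabelSource.HOMOLOGY
        else:
            source = g.label_source
        out.append(
            replace(g, is_toxin=is_toxin, is_antitoxin=is_antitoxin, label_source=source)
        )
    return out
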