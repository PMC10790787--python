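"""Seeded and deterministic generators of labeled gene maps.

Everything downstream (labeling, scanning, dedup, profiling) is testable
against these maps without any external download. The background model is
the one the Poisson enrichment test assumes: toxinome genes scattered
uniformly at a fixed per-bp rate. Islands are planted as dense runs of
alternating toxin/antitoxin genes, optionally interleaved with unlabeled
cargo genes, mimicking real toxin islands. All generators are pure
functions of their parameters — the same seed always yields the same map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome_io import Gene, Genome, Scaffold

#: products of the non-toxinome cargo genes carried by the reference island
CARGO_PRODUCTS = (
    "type IV pilus assembly protein",
    "transposase",
    "glycosyltransferase",
    "hypothetical protein",
    "hypothetical protein",
    "hypothetical protein",
    "hypothetical protein",
    "hypothetical protein",
)


@dataclass(frozen=True)
class SimParams:
    """Background-map parameters.

    ``toxinome_rate`` is the target toxinome gene density per bp; each
    tiled gene is labeled with probability ``rate * (mean_gene_len +
    mean_intergenic)``, which reproduces that per-bp rate in expectation.
    """

    scaffold_length: int = 2_000_000
    mean_gene_len: int = 900
    mean_intergenic: int = 100
    toxinome_rate: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaffold_length <= 0 or self.mean_gene_len <= 0 or self.mean_intergenic <= 0:
            raise ValueError("lengths must be positive")
        if self.toxinome_rate < 0:
            raise ValueError("toxinome_rate must be >= 0")

    @property
    def label_prob(self) -> float:
        return self.toxinome_rate * (self.mean_gene_len + self.mean_intergenic)


def make_background_scaffold(params: SimParams, scaffold_id: str = "s1") -> Scaffold:
    """Tile genes left to right with geometric length/gap jitter.

    Each gene is independently a toxinome gene with probability
    ``params.label_prob`` (toxin or antitoxin, equal odds). Same params,
    same scaffold — bit for bit.
    """
    p = params.label_prob
    if p > 1:
        raise ValueError(
            f"toxinome_rate {params.toxinome_rate} implies per-gene label "
            f"probability {p:.3f} > 1"
        )
    rng = np.random.default_rng(params.seed)
    genes = []
    pos = int(rng.geometric(1 / params.mean_intergenic))
    i = 0
    while True:
        length = int(rng.geometric(1 / params.mean_gene_len))
        if pos + length > params.scaffold_length:
            break
        labeled = rng.random() < p
        as_toxin = bool(rng.random() < 0.5)
        genes.append(
            Gene(
                gene_id=f"{scaffold_id}_g{i:05d}",
                scaffold_id=scaffold_id,
                start=pos,
                end=pos + length,
                strand="+" if rng.random() < 0.5 else "-",
                product="toxin" if labeled and as_toxin else (
                    "antitoxin" if labeled else "hypothetical protein"
                ),
                is_toxin=labeled and as_toxin,
                is_antitoxin=labeled and not as_toxin,
            )
        )
        pos += length + int(rng.geometric(1 / params.mean_intergenic))
        i += 1
    return Scaffold(scaffold_id, length=params.scaffold_length, genes=genes)


def _island_genes(
    scaffold_id: str,
    at: int,
    n_toxins: int,
    n_antitoxins: int,
    n_other: int,
    span: int,
    arrangement: str,
    prefix: str,
) -> list[Gene]:
    nt = n_toxins + n_antitoxins
    if nt < 1:
        raise ValueError("an island needs at least one toxinome gene")
    m = nt + n_other
    if nt == 1 and n_other > 0:
        raise ValueError("need >= 2 toxinome genes to bracket cargo genes")
    if span < 2 * m:
        raise ValueError(f"span {span} too small for {m} genes")
    if arrangement == "alternating":
        kinds = []
        t_left, a_left = n_toxins, n_antitoxins
        for j in range(nt):
            if (j % 2 == 0 and t_left) or not a_left:
                kinds.append("toxin")
                t_left -= 1
            else:
                kinds.append("antitoxin")
                a_left -= 1
    elif arrangement == "toxins_first":
        kinds = ["toxin"] * n_toxins + ["antitoxin"] * n_antitoxins
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    # toxinome genes occupy evenly spread slots including both endpoints, so
    # the first/last toxinome genes pin the island span exactly
    if nt == 1:
        tox_slots = [0]
    else:
        tox_slots = sorted({round(i * (m - 1) / (nt - 1)) for i in range(nt)})
        assert len(tox_slots) == nt, "slot collision; span/gene count mismatch"
    other_slots = [s for s in range(m) if s not in set(tox_slots)]

    glen = max(1, int(span / m * 0.8))
    if m > 1 and (span - glen) / (m - 1) <= glen:
        raise ValueError(f"span {span} too small for {m} genes of length {glen}")
    genes = []
    tox_iter = iter(kinds)
    cargo_idx = 0
    for slot in range(m):
        start = at if m == 1 else at + round(slot * (span - glen) / (m - 1))
        end = at + span if slot == m - 1 or m == 1 else start + glen
        if slot in set(tox_slots):
            kind = next(tox_iter)
            genes.append(
                Gene(
                    gene_id=f"{prefix}_{slot:03d}",
                    scaffold_id=scaffold_id,
                    start=start,
                    end=end,
                    strand="+",
                    product=kind,
                    is_toxin=kind == "toxin",
                    is_antitoxin=kind == "antitoxin",
                )
            )
        else:
            product = CARGO_PRODUCTS[cargo_idx % len(CARGO_PRODUCTS)]
            cargo_idx += 1
            genes.append(
                Gene(
                    gene_id=f"{prefix}_{slot:03d}",
                    scaffold_id=scaffold_id,
                    start=start,
                    end=end,
                    strand="+",
                    product=product,
                )
            )
    return genes


def plant_island(
    scaffold: Scaffold,
    at: int,
    n_toxins: int,
    n_antitoxins: int,
    n_other: int = 0,
    span: int = 10_000,
    arrangement: str = "alternating",
    prefix: str | None = None,
) -> Scaffold:
    """Insert a dense toxin/antitoxin island into [at, at+span).

    Genes are spread evenly; the first toxinome gene starts at ``at`` and
    the last toxinome gene ends at ``at + span``, so the detected segment
    length equals ``span`` exactly. The window must be free of existing
    genes; all pre-existing genes are preserved.
    """
    if any(g.start < at + span and g.end > at for g in scaffold.genes):
        raise ValueError(f"window [{at}, {at + span}) overlaps existing genes")
    if at + span > scaffold.length:
        raise ValueError("island extends beyond scaffold")
    prefix = prefix or f"isl{at}"
    new = _island_genes(
        scaffold.scaffold_id, at, n_toxins, n_antitoxins, n_other, span, arrangement, prefix
    )
    return Scaffold(scaffold.scaffold_id, scaffold.length, scaffold.genes + new)


def clear_interval(scaffold: Scaffold, start: int, end: int) -> Scaffold:
    """Drop genes overlapping [start, end) — makes room for planting."""
    kept = [g for g in scaffold.genes if g.end <= start or g.start >= end]
    return Scaffold(scaffold.scaffold_id, scaffold.length, kept)


def thauera_fixture() -> Genome:
    """Deterministic reference genome with one known toxin island.

    One 1 Mb scaffold tiled with background genes (900 bp genes, 200 bp
    gaps), exactly two background toxinome genes placed far (> 100 kb) from
    the island and from each other, and one island of nine toxins and nine
    antitoxins whose toxinome span is exactly 15,000 bp (1-based
    coordinates 500,001-515,000) plus eight cargo genes (pilus assembly,
    transposase, glycosyltransferase, hypotheticals). No RNG anywhere:
    byte-identical across runs. Toxinome density is 20 / 1 Mb = 2e-5 per
    bp, so the island's expected count is lambda = 0.3.
    """
    length = 1_000_000
    island_at, island_span = 500_000, 15_000
    pitch, glen = 1100, 900
    tox_background = {136, 772}  # tile indices; ~150 kb and ~849 kb
    genes = []
    k = 0
    while k * pitch + glen <= length:
        start = k * pitch
        if not (start < island_at + island_span and start + glen > island_at):
            is_bg_tox = k in tox_background
            genes.append(
                Gene(
                    gene_id=f"bg_{k:05d}",
                    scaffold_id="scaffold_1",
                    start=start,
                    end=start + glen,
                    strand="+" if k % 2 == 0 else "-",
                    product="toxin" if is_bg_tox else "hypothetical protein",
                    is_toxin=is_bg_tox,
                )
            )
        k += 1
    scaffold = Scaffold("scaffold_1", length=length, genes=genes)
    scaffold = plant_island(
        scaffold,
        at=island_at,
        n_toxins=9,
        n_antitoxins=9,
        n_other=8,
        span=island_span,
        arrangement="alternating",
        prefix="isl",
    )
    return Genome(
        genome_id="thauera_synthetic",
        scaffolds=[scaffold],
        taxonomy={"phylum": "Pseudomonadota", "class": "Betaproteobacteria", "genus": "Thauera"},
    )


def null_genome_set(n: int, params: SimParams) -> list[Genome]:
    """n independent background-only genomes, seeds ``seed .. seed+n-1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    genomes = []
    for i in range(n):
        p = replace(params, seed=params.seed + i)
        scaffold = make_background_scaffold(p)
        genomes.append(Genome(genome_id=f"null_{p.seed}", scaffolds=[scaffold]))
    return genomes


def planted_genome(
    seed: int,
    n_islands: int = 20,
    scaffold_length: int = 5_000_000,
    toxinome_rate: float = 1e-5,
    island_span: int = 10_000,
    n_toxins: int = 4,
    n_antitoxins: int = 4,
) -> tuple[Genome, list[tuple[int, int]]]:
    """Background genome with evenly spaced planted islands.

    Returns the genome and the list of planted (start, end) windows.
    Background genes overlapping an island window are cleared before
    planting, so each window holds exactly the planted genes.
    """
    params = SimParams(
        scaffold_length=scaffold_length, toxinome_rate=toxinome_rate, seed=seed
    )
    scaffold = make_background_scaffold(params)
    windows = []
    for i in range(n_islands):
        at = (i + 1) * scaffold_length // (n_islands + 1)
        scaffold = clear_interval(scaffold, at, at + island_span)
        scaffold = plant_island(
            scaffold,
            at=at,
            n_toxins=n_toxins,
            n_antitoxins=n_antitoxins,
            span=island_span,
            prefix=f"isl{i:02d}",
        )
        windows.append((at, at + island_span))
    genome = Genome(genome_id=f"planted_{seed}", scaffolds=[scaffold])
    return genome, windows


def random_sequence(length: int, seed: int) -> str:
    """Uniform A/C/G/T sequence of the given length."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def scaffold_sequences(genome: Genome, seed: int = 0) -> dict[str, str]:
    """Random nucleotide sequence per scaffold, seeded per scaffold id.

    Passing islands detected later get distinct sequence blocks by virtue
    of distinct coordinates, so dedup behaves as on real data.
    """
    seqs = {}
    for i, scaffold in enumerate(genome.scaffolds):
        seqs[scaffold.scaffold_id] = random_sequence(scaffold.length, seed + i)
    return seqs
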