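"""Toxin-island detection: segment merging, scoring, Poisson enrichment.

The scan walks each scaffold's toxinome genes left to right and merges
consecutive genes whose intergenic gap (next start minus previous end) is at
most ``max_gap_bp`` into one candidate segment. Each segment of T toxinome
genes among G total genes over L bp gets

* a density score ``S = T^4 / (G * L) * 1000``, and
* an enrichment P-value ``P(X >= T)`` for ``X ~ Poisson(lambda)`` with
  ``lambda = rho * L``, where ``rho`` is the genome-wide toxinome gene
  density per bp (all scaffolds pooled).

A segment is a toxin island when S > 4, P <= 0.05 and it carries at least
four toxinome genes. Dual-labeled genes (toxin and antitoxin evidence)
count once in T — one gene is one Poisson observation — but appear in both
``n_toxins`` and ``n_antitoxins``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .genome_io import Gene, Genome, Scaffold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Scan parameters: merge distance D and the three island thresholds.

    ``max_gap_bp`` is the maximum intergenic distance between consecutive
    toxinome genes inside one segment (inclusive; tested range 10-60 kb,
    default 10 kb). ``min_score`` is strict (>), ``max_p`` inclusive (<=).
    ``min_toxinome`` counts toxinome genes (T) by default; with
    ``min_toxins_strict`` the count criterion applies to toxin-flagged genes
    only.
    """

    max_gap_bp: int = 10_000
    min_score: float = 4.0
    max_p: float = 0.05
    min_toxinome: int = 4
    min_toxins_strict: bool = False

    def __post_init__(self) -> None:
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        if self.min_toxinome < 1:
            raise ValueError("min_toxinome must be >= 1")


@dataclass
class CandidateSegment:
    """A merged run of toxinome genes with its T, G, L metrics."""

    genome_id: str
    scaffold_id: str
    start: int
    end: int
    member_genes: list[str] = field(default_factory=list)
    T: int = 0
    n_toxins: int = 0
    n_antitoxins: int = 0
    G: int = 0
    lambda_: float = float("nan")
    score: float = float("nan")
    p_value: float = float("nan")

    @property
    def L(self) -> int:
        return self.end - self.start


@dataclass
class ToxinIsland(CandidateSegment):
    """A classified candidate segment with pass/fail bookkeeping."""

    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)
    cluster_id: str | None = None
    representative: bool = False


def genome_density(genome: Genome) -> float:
    """Genome-wide toxinome gene density per bp (all scaffolds pooled)."""
    total_length = genome.total_length
    if total_length <= 0:
        raise ValueError(f"genome {genome.genome_id!r} has zero total length")
    n_toxinome = sum(len(s.toxinome_genes) for s in genome.scaffolds)
    return n_toxinome / total_length


def find_candidate_segments(
    scaffold: Scaffold, params: ScanParams, genome_id: str = ""
) -> list[CandidateSegment]:
    """Merge consecutive toxinome genes with intergenic gap <= D.

    Single left-to-right pass; segment boundaries run from the first member
    gene's start to the last member's end. Singletons are kept here (the
    count threshold is applied at classification). Segments are disjoint,
    ordered, and jointly cover every toxinome gene exactly once.
    """
    toxinome = scaffold.toxinome_genes
    if not toxinome:
        return []
    runs: list[list[Gene]] = [[toxinome[0]]]
    for gene in toxinome[1:]:
        if gene.start - runs[-1][-1].end <= params.max_gap_bp:
            runs[-1].append(gene)
        else:
            runs.append([gene])
    segments = []
    for run in runs:
        seg = CandidateSegment(
            genome_id=genome_id,
            scaffold_id=scaffold.scaffold_id,
            start=run[0].start,
            end=max(g.end for g in run),
            member_genes=[g.gene_id for g in run],
        )
        segments.append(segment_metrics(seg, scaffold))
    return segments


def segment_metrics(segment: CandidateSegment, scaffold: Scaffold) -> CandidateSegment:
    """Fill T, G and the per-kind counts for a segment.

    G counts every gene (labeled or not) overlapping [start, end) by at
    least one bp; T and the per-kind counts run over member toxinome genes.
    """
    member_ids = set(segment.member_genes)
    members = [g for g in scaffold.genes if g.gene_id in member_ids]
    segment.T = len(members)
    segment.n_toxins = sum(g.is_toxin for g in members)
    segment.n_antitoxins = sum(g.is_antitoxin for g in members)
    segment.G = sum(
        1 for g in scaffold.genes if g.start < segment.end and g.end > segment.start
    )
    return segment


def island_score(T: int, G: int, L: int) -> float:
    """Density score S = T^4 / (G * L) * 1000 with L in bp."""
    if G <= 0 or L <= 0:
        raise ValueError("G and L must be positive")
    if T < 1:
        raise ValueError("T must be >= 1")
    return T**4 * 1000.0 / (G * L)


def poisson_pvalue(K: int, lambda_: float) -> float:
    """Upper-tail Poisson probability P(X >= K), inclusive of K.

    Uses the survival function (not 1 - CDF) so values far in the tail keep
    full relative precision.
    """
    if K < 0 or lambda_ < 0:
        raise ValueError("K and lambda must be non-negative")
    if K == 0:
        return 1.0
    return float(stats.poisson.sf(K - 1, lambda_))


def classify_islands(
    segments: Iterable[CandidateSegment],
    density: float,
    params: ScanParams | None = None,
) -> list[ToxinIsland]:
    """Score each segment and apply the three island thresholds.

    For each segment: lambda = density * L, P = P(X >= T), S = T^4/(G*L)*1000.
    Pass requires S > min_score (strict), P <= max_p (inclusive), and the
    count criterion (T, or toxin count in strict mode) >= min_toxinome.
    """
    params = params or ScanParams()
    islands = []
    for seg in segments:
        assert density > 0 or seg.T == 0, "segments imply nonzero density"
        lam = density * seg.L
        score = island_score(seg.T, seg.G, seg.L)
        p = poisson_pvalue(seg.T, lam)
        counted = seg.n_toxins if params.min_toxins_strict else seg.T
        fail = []
        if not score > params.min_score:
            fail.append("score")
        if not p <= params.max_p:
            fail.append("pvalue")
        if counted < params.min_toxinome:
            fail.append("count")
        islands.append(
            ToxinIsland(
                genome_id=seg.genome_id,
                scaffold_id=seg.scaffold_id,
                start=seg.start,
                end=seg.end,
                member_genes=list(seg.member_genes),
                T=seg.T,
                n_toxins=seg.n_toxins,
                n_antitoxins=seg.n_antitoxins,
                G=seg.G,
                lambda_=lam,
                score=score,
                p_value=p,
                passed=not fail,
                fail_reasons=fail,
            )
        )
    return islands


def scan_genome(genome: Genome, params: ScanParams | None = None) -> list[ToxinIsland]:
    """Scan every scaffold of a labeled genome for toxin islands.

    Returns all candidate segments (passing and failing), ordered by
    (scaffold_id, start); the same genome and parameters always give the
    same result.
    """
    params = params or ScanParams()
    n_toxinome = sum(len(s.toxinome_genes) for s in genome.scaffolds)
    if n_toxinome == 0:
        return []
    density = genome_density(genome)
    islands: list[ToxinIsland] = []
    for scaffold in sorted(genome.scaffolds, key=lambda s: s.scaffold_id):
        segs = find_candidate_segments(scaffold, params, genome_id=genome.genome_id)
        islands.extend(classify_islands(segs, density, params))
    return islands


def passing_islands(islands: Iterable[ToxinIsland]) -> list[ToxinIsland]:
    return [i for i in islands if i.passed]


def sweep_gap(genome: Genome, gaps: Sequence[int]) -> pd.DataFrame:
    """Scan one genome at several merge distances D.

    Returns one row per distinct gap (duplicates dropped with a warning),
    ordered by gap: segment count, passing count, and the mean P-value over
    all segments (NaN when there are none).
    """
    if not gaps:
        raise ValueError("gaps must be nonempty")
    unique = sorted(set(gaps))
    if len(unique) != len(gaps):
        logger.warning("duplicate gap values removed: %s", sorted(gaps))
    rows = []
    for gap in unique:
        islands = scan_genome(genome, ScanParams(max_gap_bp=gap))
        pvals = [i.p_value for i in islands]
        rows.append(
            {
                "gap": gap,
                "n_segments": len(islands),
                "n_passing": sum(i.passed for i in islands),
                "mean_p": float(pd.Series(pvals, dtype=float).mean()) if pvals else math.nan,
            }
        )
    return pd.DataFrame(rows)


def threshold_curve(
    segments: Sequence[CandidateSegment], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Survivor count and mean P-value as the score threshold rises.

    For each threshold t the survivors are segments with score > t;
    ``delta_mean_p`` is the drop in mean P-value relative to the previous
    grid point (NaN for the first point or around empty survivor sets). The
    threshold with the largest drop — the best improvement in average
    P-value — is stored in ``DataFrame.attrs["best_threshold"]``.
    """
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    grid = sorted(thresholds)
    rows = []
    prev_mean = math.nan
    for t in grid:
        surv = [s for s in segments if s.score > t]
        mean_p = (
            math.fsum(s.p_value for s in surv) / len(surv) if surv else math.nan
        )
        delta = prev_mean - mean_p if surv and not math.isnan(prev_mean) else math.nan
        rows.append(
            {
                "threshold": t,
                "n_surviving": len(surv),
                "mean_p": mean_p,
                "delta_mean_p": delta,
            }
        )
        prev_mean = mean_p
    df = pd.DataFrame(rows)
    deltas = df["delta_mean_p"]
    best = (
        float(df.loc[deltas.idxmax(), "threshold"]) if deltas.notna().any() else math.nan
    )
    df.attrs["best_threshold"] = best
    return df
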