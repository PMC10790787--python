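"""Redundancy removal across islands: cluster at 99% identity, keep the
best-scoring representative.

Islands from closely related genomes are often byte-identical or nearly so.
Greedy centroid clustering visits islands in descending score order; an
island joins the first existing cluster whose founding representative it
matches at >= ``min_id`` global-alignment identity, otherwise it founds a
new cluster. The founder (the max-score member, ties broken by larger T
then lexicographic location) is the cluster representative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .island_scan import ToxinIsland

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class IslandCluster:
    cluster_id: str
    members: list[ToxinIsland]
    representative: ToxinIsland


def island_key(island: ToxinIsland) -> tuple[str, str, int, int]:
    return (island.genome_id, island.scaffold_id, island.start, island.end)


def island_seq_name(island: ToxinIsland) -> str:
    """FASTA header convention for island sequences."""
    return f"{island.genome_id}:{island.scaffold_id}:{island.start + 1}-{island.end}"


def extract_island_sequence(island: ToxinIsland, scaffold_seq: str) -> str:
    """Slice the island's nucleotide sequence out of its scaffold.

    No strand flipping: islands are clustered as plus-strand genomic
    intervals.
    """
    if island.end > len(scaffold_seq):
        raise ValueError(
            f"island [{island.start}, {island.end}) extends beyond scaffold "
            f"sequence of length {len(scaffold_seq)}"
        )
    return scaffold_seq[island.start : island.end].upper()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: match columns / alignment columns.

    If the length ratio is already below 0.99 the identity cannot reach
    0.99 (matches are bounded by the shorter length, columns by the
    longer), so the ratio is returned as an upper bound without aligning.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    ratio = min(len(a), len(b)) / max(len(a), len(b))
    if ratio < 0.99:
        return ratio
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches / columns


def cluster_islands(
    islands: list[ToxinIsland],
    seqs: dict[tuple[str, str, int, int], str],
    min_id: float = 0.99,
) -> list[IslandCluster]:
    """Greedy centroid clustering of island sequences at >= min_id identity.

    *seqs* maps :func:`island_key` to the island's nucleotide sequence.
    Visit order (descending score, descending T, then location) is a total
    order, so the partition does not depend on input order.
    """
    for isl in islands:
        if island_key(isl) not in seqs:
            raise ValueError(f"no sequence for island {island_seq_name(isl)}")
    ordered = sorted(
        islands,
        key=lambda i: (-i.score, -i.T, i.genome_id, i.scaffold_id, i.start),
    )
    clusters: list[IslandCluster] = []
    for isl in ordered:
        seq = seqs[island_key(isl)]
        for cluster in clusters:
            rep_seq = seqs[island_key(cluster.representative)]
            if pairwise_identity(seq, rep_seq) >= min_id:
                cluster.members.append(isl)
                break
        else:
            clusters.append(
                IslandCluster(
                    cluster_id=f"C{len(clusters):05d}",
                    members=[isl],
                    representative=isl,
                )
            )
    return clusters


def select_representatives(clusters: list[IslandCluster]) -> list[ToxinIsland]:
    """One representative per cluster, sorted by genomic location; the
    cluster id and representative flag are stamped onto the members."""
    reps = []
    for cluster in clusters:
        for member in cluster.members:
            member.cluster_id = cluster.cluster_id
            member.representative = member is cluster.representative
        reps.append(cluster.representative)
    reps.sort(key=island_key)
    return reps


def dedup_islands(
    islands: list[ToxinIsland],
    seqs: dict[tuple[str, str, int, int], str],
    min_id: float = 0.99,
) -> list[ToxinIsland]:
    """Cluster and return representatives in one call."""
    return select_representatives(cluster_islands(islands, seqs, min_id))
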