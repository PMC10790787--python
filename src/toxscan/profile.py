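"""Descriptive toxinome statistics over labeled genomes.

Per-genome gene counts and proportions (toxin and antitoxin genes as a
fraction of all genes), per-taxonomic-class averages (total toxinome genes
divided by genomes in the class), and the Pearson correlation between
toxin and antitoxin content. Group-comparison statistics (ANOVA/Tukey) are
left to external stats packages; the tidy per-genome table this module
exports is their input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .genome_io import Genome

TEMPERATURE_RANGES = ("mesophile", "thermophile", "hyperthermophile", "psychrophile")


@dataclass(frozen=True)
class GenomeProfile:
    """One genome's toxinome content summary.

    Dual-labeled genes count in both ``n_toxins`` and ``n_antitoxins``;
    proportions are per-kind counts over total genes.
    """

    genome_id: str
    class_name: str
    n_genes: int
    n_toxins: int
    n_antitoxins: int
    toxin_prop: float
    antitoxin_prop: float
    temperature_range: str | None = None


def per_genome_profile(
    genome: Genome, metadata: dict[str, str] | None = None
) -> GenomeProfile:
    """Count toxin/antitoxin genes and normalize by total gene number."""
    genes = genome.genes
    if not genes:
        raise ValueError(f"genome {genome.genome_id!r} has no genes")
    metadata = metadata or {}
    n_tox = sum(g.is_toxin for g in genes)
    n_anti = sum(g.is_antitoxin for g in genes)
    temp = metadata.get("temperature_range") or genome.taxonomy.get("temperature_range")
    if temp is not None and temp not in TEMPERATURE_RANGES:
        raise ValueError(f"unknown temperature range {temp!r}")
    return GenomeProfile(
        genome_id=genome.genome_id,
        class_name=metadata.get("class") or genome.taxonomy.get("class", ""),
        n_genes=len(genes),
        n_toxins=n_tox,
        n_antitoxins=n_anti,
        toxin_prop=n_tox / len(genes),
        antitoxin_prop=n_anti / len(genes),
        temperature_range=temp,
    )


def profiles_to_frame(profiles: Sequence[GenomeProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def write_profiles(profiles: Sequence[GenomeProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def per_class_average(profiles: Sequence[GenomeProfile]) -> pd.DataFrame:
    """Mean toxinome gene count per genome, by taxonomic class.

    Per class: sum of (n_toxins + n_antitoxins) over genomes divided by the
    number of genomes; per-kind means are also reported. Classes sorted.
    """
    if not profiles:
        return pd.DataFrame(
            columns=["class_name", "n_genomes", "mean_toxinome", "mean_toxins", "mean_antitoxins"]
        )
    df = profiles_to_frame(profiles)
    df["n_toxinome"] = df["n_toxins"] + df["n_antitoxins"]
    out = (
        df.groupby("class_name", sort=True)
        .agg(
            n_genomes=("genome_id", "size"),
            mean_toxinome=("n_toxinome", "mean"),
            mean_toxins=("n_toxins", "mean"),
            mean_antitoxins=("n_antitoxins", "mean"),
        )
        .reset_index()
    )
    return out


def toxin_antitoxin_correlation(
    profiles: Sequence[GenomeProfile], level: str = "genome"
) -> tuple[float, int]:
    """Pearson correlation of toxin vs antitoxin counts.

    ``level="genome"`` correlates per-genome counts; ``level="class"``
    correlates per-class mean counts. Returns (r, n units); significance is
    left to external stats.
    """
    if level == "genome":
        df = profiles_to_frame(profiles)
        x, y = df["n_toxins"], df["n_antitoxins"]
    elif level == "class":
        table = per_class_average(profiles)
        x, y = table["mean_toxins"], table["mean_antitoxins"]
    else:
        raise ValueError(f"level must be 'genome' or 'class', got {level!r}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 units, got {n}")
    if x.nunique() < 2 or y.nunique() < 2:
        raise ValueError("zero variance in toxin or antitoxin counts")
    r = stats.pearsonr(x, y).statistic
    return float(r), n
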