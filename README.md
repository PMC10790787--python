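# toxscan

Detection and profiling of **toxin islands** — genomic segments enriched
in toxin and antitoxin genes — in bacterial gene maps.

Toxin–antitoxin (TA) systems and related toxins defend bacteria against
phages and competitors and stabilize mobile elements; they often travel
together, forming dense clusters on chromosomes and plasmids. `toxscan`
takes gene annotations with toxin/antitoxin labels (or the domain- and
homology-hit tables needed to assign them) and finds, scores and
deduplicates these clusters. It is aimed at comparative genomicists and
mobile-element researchers working from standard annotation files.

## Method

On each scaffold, consecutive toxinome genes (toxin and/or antitoxin
labeled) are merged into one candidate segment when the intergenic gap is
at most *D* (default 10 kb). A segment with *T* toxinome genes among *G*
total genes over *L* bp is scored

```
S = T^4 / (G · L) · 1000
```

and tested for enrichment against a Poisson background: with genome-wide
toxinome density ρ per bp, the expected count in the segment is
λ = ρ·L and the P-value is P(X ≥ T) for X ~ Poisson(λ). A segment is a
**toxin island** when S > 4, P ≤ 0.05 and it holds at least four toxinome
genes. Near-identical islands across genomes are collapsed by greedy
clustering at 99 % nucleotide identity, keeping the best-scoring
representative. See `docs/methods.md` for assumptions and parameter
rationale.

## Worked example

The package ships a deterministic 1 Mb reference genome carrying one
known island (nine toxins, nine antitoxins and eight cargo genes over
exactly 15 kb) plus two stray background toxinome genes:

```
$ toxscan simulate --preset thauera --out genes.tsv
1 genome(s) written to genes.tsv
$ toxscan scan --genes genes.tsv --out islands.tsv
1 island(s) written to islands.tsv
```

`islands.tsv` then contains (columns abridged):

```
genome_id          start   end     length_bp  n_toxins  n_antitoxins  T   G   score    p_value
thauera_synthetic  500001  515000  15000      9         9             18  26  269.169  4.5547e-26
```

Read: the island spans 15 000 bp (1-based 500 001–515 000) and holds 18
toxinome genes among 26 genes total. Its score 18⁴·1000/(26·15000) ≈ 269
is far above the threshold of 4, and with genome density 2·10⁻⁵/bp the
expected count in 15 kb is λ = 0.3, making 18 observed genes
astronomically unlikely by chance (P ≈ 4.6·10⁻²⁶). The two stray
background genes form singleton segments and fail the score and count
thresholds.

Other subcommands: `toxscan sweep` (segment counts across merge
distances), `toxscan thresholds` (score-threshold selection curve),
`toxscan dedup` (redundancy removal), `toxscan profile` (per-genome and
per-class toxinome content tables), `toxscan simulate --preset
null|planted` (calibration and recovery test data). Python API mirrors
the CLI: `toxscan.scan_genome`, `toxscan.cluster_islands`, etc.

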