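# Methods

## The model

Toxin–antitoxin (TA) systems and other toxin genes cluster on bacterial
chromosomes and plasmids. `toxscan` detects such clusters — *toxin
islands* — as segments of a scaffold significantly enriched in *toxinome
genes* (genes labeled toxin and/or antitoxin).

**Segment construction.** On each scaffold, toxinome genes are visited
left to right and merged into one candidate segment whenever the
intergenic gap (next gene's start minus previous gene's end) is at most
the merge distance *D*. The gap test is inclusive (gap = *D* merges).
Segment boundaries run from the first member gene's start to the last
member's end, with no flanking padding, so the segment length *L* equals
the span of its toxinome genes. Segments are disjoint and jointly cover
every toxinome gene exactly once; scaffolds are treated as linear (no
wrap-around).

**Score.** Each segment of *T* toxinome genes among *G* total genes
(any gene overlapping the segment by ≥ 1 bp) over *L* bp gets

    S = T^4 / (G · L) · 1000,      L in base pairs.

S grows steeply with the toxinome count and is penalized by dilution
(more unrelated genes) and by spread (longer span). With L in bp the
classification threshold S > 4 sits in a discriminating regime — e.g. a
tight 4-gene cluster over 8 kb with 8 genes total scores exactly 4.0,
while a loose 4-gene run over 30 kb scores well below 1.

**Enrichment P-value.** Under the null, toxinome genes fall uniformly
along the genome, so the count in a window of length *L* is Poisson with
mean λ = ρ·L, where ρ is the genome-wide toxinome density per bp (all
scaffolds pooled — density is a property of the genome, not of one
scaffold). The P-value is the inclusive upper tail P(X ≥ T), computed via
the Poisson survival function rather than 1 − CDF so values of order
1e-26 keep full relative precision.

**Classification.** A segment is a toxin island iff

* S > 4 (strict),
* P ≤ 0.05 (inclusive), and
* it carries at least 4 toxinome genes.

A gene with both toxin and antitoxin evidence counts **once** in *T* (one
gene is one Poisson observation) but appears in both per-kind counts.
The count criterion applies to *T* by default; `min_toxins_strict`
switches it to toxin-flagged genes only, for users who read "four toxins"
narrowly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap_bp` (D) | 10 000 bp | max intergenic gap inside a segment; 10–60 kb is the sensible range, and 10 kb matches the observation that most islands are shorter than 15 kb |
| `min_score` | 4.0 | strict score threshold; on a score-threshold sweep this grid point gives the largest drop in mean P-value (see `toxscan thresholds`) |
| `max_p` | 0.05 | inclusive Poisson P-value threshold |
| `min_toxinome` | 4 | minimum toxinome genes per island |
| `min_id` (dedup) | 0.99 | nucleotide identity for collapsing redundant islands |

Labeling thresholds (module `labeling`): database mapping keeps hits with
identity strictly > 30 %, query **and** subject coverage ≥ 0.95 and
e ≤ 0.05 ("alignment coverage" is read conservatively as both-sided, and
both knobs are exposed); interactive search keeps identity ≥ 40 %, query
cover ≥ 0.90, subject cover ≥ 0.60, e ≤ 0.001 and returns the best 25 by
bitscore (ties: e-value, then subject id); structure hits require
e < 0.003, TM-score > 0.6 (both strict) and query coverage ≥ 0.90.
Domain-hit tables are taken as provided — no extra e-value re-thresholding
is applied to them. The shipped Pfam accession lists are small editable
illustrative sets, not an exhaustive curation.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates labeled gene maps, not sequences with realistic
composition:

* `make_background_scaffold` tiles genes with geometric length/gap jitter
  (defaults 900 bp genes, 100 bp gaps ≈ one gene per kb, bacteria-like)
  and labels each gene toxinome independently with probability
  rate × (mean gene length + mean gap), reproducing the target per-bp
  rate in expectation. This **is** the null model of the Poisson test, so
  null-calibration results show internal consistency, not field
  performance on real genomes (where TA genes are themselves clustered,
  mobile-element-borne, and labeling is noisy).
* `plant_island` inserts a dense alternating toxin/antitoxin run whose
  first toxinome gene starts at the given position and whose last ends
  exactly span bp later, so detected boundaries are known a priori.
* `thauera_fixture` is a fully deterministic 1 Mb genome holding one
  island of nine toxins + nine antitoxins interleaved with eight cargo
  genes (pilus assembly protein, transposase, glycosyltransferase,
  hypotheticals) spanning exactly 15 000 bp at 1-based coordinates
  500 001–515 000, plus exactly two background toxinome genes placed
  > 100 kb away from the island and from each other. Fixing the
  background count at 2 (rather than sampling it) makes the density
  exactly 2e-5/bp and hence λ = 0.3 and the island's score and P-value
  exactly reproducible. The island's internal gene order is an arbitrary
  choice: any arrangement within the span yields identical T, G, L.
* `planted_genome` (recovery experiments) plants 20 islands of eight
  toxinome genes over 10 kb into 5 Mb backgrounds at 1e-5/bp. Eight genes
  per island (rather than the minimal six) keeps detection robust when a
  chance background toxinome gene merges into an island's segment and
  stretches L; that merging is a property of real scans too, not an
  artifact.

Problem sizes used by the test suite — 100 null genomes of 2 Mb for
calibration, 50 seeded 300–400 kb scaffolds for merge-refinement
properties, 10 seeds for recovery — are desk-scale choices that keep the
whole suite under half a minute while leaving each property statistically
meaningful.

## Deduplication

Islands are clustered on their **nucleotide** sequences (plus strand, no
flipping). Identity is global-alignment identity, match columns over
alignment columns, computed with edlib's Needleman–Wunsch path; a length
ratio below 0.99 already bounds identity below 0.99, so such pairs skip
alignment. Clustering is greedy centroid: islands sorted by descending
score (ties: larger T, then genome/scaffold/start), each joining the
first founded cluster whose representative it matches at ≥ 0.99, else
founding its own. The founder is the representative, so the
representative is always the max-score member and the result does not
depend on input order. This is a deliberate, testable, dependency-free
stand-in for external clustering tools whose internal tie-breaking is
unspecified; an external clusterer can be swapped in behind the same
contract.

## Numerical and degenerate-input choices

* Internal coordinates 0-based half-open; gene-table and island TSV
  1-based inclusive; BED6 0-based half-open.
* Unknown scaffold length → max gene end on the scaffold (logged); the
  density denominator must exist.
* `threshold_curve` reports NaN for the mean P-value of an empty survivor
  set and for deltas adjacent to one; the "best" threshold is the grid
  point with the largest P-value drop.
* Zero toxinome genes → zero density, no segments, empty scan.
* Duplicate gap values in a sweep are deduplicated with a warning.
* All generators are pure functions of their parameters; the CLI records
  every parameter and input checksum in a JSON run manifest.

## Known limitations

* The scanner consumes gene labels; it is only as good as the upstream
  domain/homology evidence. The shipped domain lists are illustrative.
* λ is genome-wide; genomes with strong regional density differences
  (e.g. plasmid-heavy assemblies) may be over- or under-called locally.
  Plasmid and chromosome scaffolds are deliberately treated identically.
* Dedup clusters nucleotide sequences; islands conserved only at the
  protein level remain separate.
* Group-comparison statistics over profiles (ANOVA/Tukey) are not
  reimplemented; `toxscan profile` exports the tidy per-genome table for
  any stats package.
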