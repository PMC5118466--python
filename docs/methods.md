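# Methods

## The measurement

A mariner (himar1) transposon inserts only at TA dinucleotides, so a pooled
mutant library is a population over the genome's TA sites.  Sequencing the
transposon–genome junctions after a period of competitive growth measures
each insertion mutant's relative abundance: insertions in genes required
for growth are depleted, insertions in dispensable genes drift with the
pool.  Contrasting two growth conditions splits the impaired genes into a
condition-independent core and condition-specific sets.

## Coordinates and site model

Internally all coordinates are 0-based half-open; GFF3 input (1-based
closed) is converted on load, and wiggle output is 1-based, the format's
convention.  A TA site is keyed by the forward-strand position of its T and
is strand-symmetric (TA is its own reverse complement).  A site belongs to
a gene only when both the T and the A fall inside the gene span; gene
strand is ignored, since a mariner insertion disrupts the gene in either
orientation.  Overlapping genes may share sites.

## Assayability and duplicated genes

A junction tag of length `tag_len` (default 16: TA plus 14 genomic bases)
is extracted per site in both orientations.  A site is *assayable* iff at
least one of its two tags occurs exactly once among all site tags
genome-wide; tags containing N, or truncated by a replicon end, do not
count.  This deterministic rule is the package's automated replacement for
manual reciprocal-BLAST curation of duplicated sequence: inside an exact
repeat every tag occurs at least twice, so multi-map suppression guarantees
such sites can never collect reads, and treating them as "essential" would
be an artifact.  A gene whose assayable-site fraction falls below
`min_assayable_frac` (default 0.5) is flagged *duplicated* and reported but
never assigned a phenotype.  The 0.5 default excludes genes mostly composed
of unmappable sites while tolerating genes that merely border a repeat; a
separate report lists all genes with insertion density < 0.30 and whether
duplication explains them, mirroring the curation trigger used for such
datasets.  Duplication detection is exact-tag only — no homology search —
and circular-replicon wrap-around tags are not modelled.

## Trimming and mapping

A read is [IR terminus][TA + tag][adapter].  Trimming finds the IR terminus
(exact match by default; a substitution tolerance is configurable), cuts
the tag at the adapter if present (otherwise the tag runs to the read end —
on 200 bp chemistry the tag may or may not reach the adapter), and applies
two filters in order: the tag must start with TA, and must be ≥ 15 bp.
Every read receives exactly one status (`accepted`, `no_ir`, `no_ta`,
`too_short`); the counts partition the input.  Base qualities are ignored:
the filters are structural.

Mapping is exact string matching against the precomputed site tags of both
orientations, the in-package equivalent of aligning short tags with a
suppress-multiple-alignments policy: a tag matching exactly one locus
increments that site; more than one, it is discarded (`multi`); zero,
`unmapped`.  Tags longer than `tag_len` are compared over their first
`tag_len` bases; shorter accepted tags (15 bp) must be unique at their own
length.  Both orientations of a site accumulate into the one canonical
(forward-strand) counter.  Mismatch-tolerant alignment, SAM/BAM output and
PCR-duplicate removal are out of scope — for fixed-length junction tags
duplicates are indistinguishable from genuine repeated sampling.

## The growth-state HMM

Per replicon, ordered site counts are decoded with a four-state HMM:

* emissions: geometric on the count, P(c | s) = θ_s (1 − θ_s)^c, support
  {0, 1, 2, …}, with θ_s = 1 / (1 + m_s) so m_s is the state mean;
* state means: ES = `m_es` (absolute, default 0.05 — essentially empty),
  GD = μ/10, NE = μ, GA = 5μ, where μ is the mean count over
  insertion-bearing sites (sites with count > 0) of the whole library;
* transitions: stay with probability 1 − ε, switch to each other state
  with ε/3 (default ε = 10⁻³); initial distribution uniform;
* decoding: Viterbi in log space; ties break toward the more impaired
  state (ES > GD > NE > GA).

Counts enter untransformed; estimating μ from insertion-bearing sites only
keeps the neutral state centred on the actual sequencing depth even when a
large fraction of sites is empty.  An all-zero track is a fatal error (no
library signal).  With default ε, a run of zeros needs to be about six
sites long before an ES segment beats the double switch penalty — isolated
empty sites inside a neutral gene are absorbed, which is the point of using
an HMM rather than per-site thresholds.  A gene's state is the *modal*
state of its sites (ties toward severity, ES > GD > GA > NE), not a
mean-count rule, so a long gene with one permissive hot spot is not
miscalled.  Genes without TA sites are `no_sites`; duplicated genes are
`unassayed`.  Posterior decoding, replicate-aware variance models and
Bayesian alternatives are deliberately not implemented.

The emission/transition constants are this package's own fixed, documented
instance of the four-state model; published percentages produced by other
HMM implementations on real data are not expected to be bit-reproducible
here.

## Summaries and classification

Per gene and condition: N (TA sites), hit sites (count > 0), insertion
density = hit/N, and average read depth = total reads / hit sites — the
mean over insertion-bearing sites only, the only definition consistent with
published per-gene tables (e.g. density 0.57 of N = 7 gives 4 hit sites and
29.75 × 4 = 119 reads, an integer).  Values are kept at full precision and
rounded half-up to 2 decimals only at serialization.

Classification is a pure function of (replicon kind, impaired-A,
impaired-B) with impaired = state ∈ {ES, GD}: both → GI (core functional
genome), A only → VGI, B only → TGI, neither → GN, and a P prefix on
plasmids.  GA counts as not impaired, pooled into GN.  `no_sites` and
`unassayed` genes are excluded from all phenotype counts and Venn totals
but listed with their exclusion reason.  Condition labels are
configuration; the engine is generic over any two conditions.  Riley
functional-class distributions are raw per-category fractions (no
enrichment statistics), and the hypothetical-protein report selects
impaired genes whose product matches configurable patterns (default
substring "hypothetical"), grouped into the five impaired sections plus a
separate duplicated section.

## The simulator

The generator's defaults are the study conditions used throughout the
tests: 200 genes (180 chromosomal + 20 plasmid), gene lengths 350–500 bp
(median TA sites per gene ≥ 10 at random-sequence TA density), 16
generations of selection (the selection plates of such screens span roughly
15–18 generations), mean depth 25 reads per site, planted fractions 8% ES /
3% GD / 1% GA per condition with half of each condition's impaired set
shared (the planted core), 2% of genes in exact duplicate pairs and 0.5%
without any TA.  States are planted by assignment, not sampling, so the
fractions are exact.

Selection follows the simplest exponential competition model: a mutant in a
gene of fitness w changes relative abundance by 2^(G·(w−1)) after G
generations, with default fitness ES = 0 (mutant eliminated), GD = 0.5,
NE = 1, GA = 1.1; intergenic insertions are neutral and sites in
overlapping genes take the minimum fitness.  Read counts are one
multinomial draw over sites with probabilities proportional to abundance
and total `depth × n_sites`.  Reads are emitted one per counted insertion
in a uniformly chosen orientation, with optional planted junk reads (no IR
/ no TA / too short) at configured fractions of the final pool; all
randomness flows from a single seed and reruns are byte-identical.

What the simulator does *not* emulate — sequencing errors inside tags,
conjugation-efficiency and bottleneck effects, plate-spatial structure,
biased TA usage, GC-dependent coverage — bounds what passing tests show:
they validate the algorithmic chain (trimming, unique mapping, HMM
segmentation, classification) under the stated noise model, not robustness
to every artifact of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end recovery at the
default 200-gene conditions over five seeds, the Viterbi-vs-exhaustive
oracle on instances of ≤ 8 sites (where 4^n enumeration is exact), and
round-trip identities on ~80-gene repeat-free genomes — sizes chosen so the
whole suite completes in well under a minute per property while the
quantities measured (recovery fractions, oracle agreement) are already
stable.  All HMM arithmetic is in log space; `np.argmax`'s first-index tie
rule implements the severity tie-break because states are stored in
severity order.  Oracle comparisons use an absolute log-probability
tolerance of 1e-9.

## Known limitations

* Exact-match mapping cannot place tags containing sequencing errors; on
  real data a small unmapped fraction is expected that the simulator does
  not produce.
* The genome-wide percentages of the original screen depend on the
  original raw data and aligner builds and are not desk-reproducible; the
  published in-paper hypothetical-protein table is the printed-number
  surface the package recomputes.
* A handful of published rows were manually curated against their own
  printed states (RL0456A, RL3259, RL4065); the engine reproduces every
  state-consistent row and deliberately never overrides state-derived
  calls.
* GD genes at default depth are frequently decoded ES (their expected
  count, depth/256, is below 1 read); the GI pooling makes the downstream
  partition insensitive to this, but individual ES-vs-GD labels at low
  depth should not be over-interpreted.
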