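# Methods

This note documents the models, conventions and design choices behind
`dietbarcode`, in the order the pipeline runs.

## Synthetic study design

The simulator generates the complete data a camera-validated diet
metabarcoding study produces, with known ground truth.

**Reference library.** Barcodes are grown hierarchically from one random
root amplicon (default 270 bp): per-rank substitution fractions (order 0.30,
family 0.15, genus 0.08, species 0.01) are applied walking down the
taxonomy.  The genus-level fraction must exceed twice the 3% OTU radius so
distinct genera form distinct OTUs; with the defaults, between-genus
identity stays below ~0.86 and within-genus identity above 0.97.  Real
arthropod order names (including the five parasite orders Mesostigmata,
Prostigmata, Sarcoptiformes, Siphonaptera and Trombidiformes when
requested) are used so parasite exclusion and class pruning run exactly as
on real data.  A single avian (Ficedula) reference provides host reads.

**Mock community.** Biomass proportions are symmetric Dirichlet
(default concentration 1, i.e. uniform on the simplex); per-taxon
amplification efficiencies are lognormal(0, 0.3) — a moderate PCR bias
consistent with a well-matched, validated primer set, where recovered
abundances deviate well within one order of magnitude; mean prey sizes are
lognormal(log 0.5, 0.8) clipped to the camera scoring range [0.04, 6.0]
(prey mostly smaller than the bill).

**Camera sessions.** Delivery probability is proportional to
biomass / mean size, and each item contributes its (noisy, clipped) size
multiplier.  Size-weighted counts therefore estimate biomass without bias
by construction — the design assumption under which RSBC is the benchmark —
while raw counts over-represent small prey.  Taxonomic precision is a
categorical distribution over ranks; unresolved items become "unknown".
The default precision (order 0.25 / family 0.35 / genus 0.20 / species
0.10, remainder unknown) leaves ~10% of items unknown at order rank and
~35% at family rank, comparable to field camera scoring; the validation
experiment instead uses order-only precision 0.9.  Parasite-order taxa are
secondary prey (inside other prey) and never appear on camera.

**Reads.** Per-read templates are drawn multinomially with expected
per-taxon counts proportional to biomass × efficiency.  Forward/reverse
reads cover the template from both ends (300 bp read length, so a 270 bp
amplicon is fully covered by both mates); per-base errors are i.i.d. at the
configured rate with Phred qualities encoding exactly that rate (constant Q
by default, optional Gaussian jitter with per-base error following the
jittered quality).  Chimeras splice two parents of the same sample at a
uniform breakpoint in [30%, 70%] of the amplicon.  Negative controls
contain only contamination reads drawn from a designated subset (default:
the seven lowest-biomass members); the same subset contaminates samples at
a low level so control subtraction has something to remove.  A truth table
labels every read (taxon / chimera / host / contaminant).  All stages
derive child seeds deterministically from one master seed; outputs are
byte-identical under a fixed seed.

What the simulator does **not** model: PCR-cycle thermodynamics (bias is a
single multiplier), Illumina quality decay along the read, indel errors,
and length variation among amplicons.  Passing tests therefore demonstrate
correctness of the analysis logic under the stated statistical model, not
robustness to every artifact of real sequencing.

## Read processing

* **Merging.** Best ungapped overlap of the forward read against the
  reverse-complemented reverse read, maximizing matching columns (ties to
  the longer overlap, then the smaller shift).  Overlaps shorter than 16
  columns or with mismatch rate > 0.1 drop the pair.  Consensus takes the
  higher-quality base (forward on ties); posterior quality is the sum of
  qualities on agreement and their absolute difference on disagreement,
  capped at 41.  A disagreement between equal qualities therefore yields
  Q0 — maximal uncertainty — which is what routes those reads out of the
  clustering input via the EE filter while they remain available for
  mapping.  Read-through overhangs (adaptor segments) are trimmed.
* **Truncation.** 25 bp (the longest primer) off both ends, then cut to
  220 bp from the 5′ end; shorter reads are discarded and counted.
* **Quality filter.** Expected errors EE = Σ 10^(−Q/10) over the truncated
  read; retained iff EE ≤ 0.4.  The filter partitions exhaustively and is
  monotone in the threshold.
* **Dereplication.** Canonical orientation is the lexicographically smaller
  of sequence and reverse complement, which merges reads present in both
  orientations; singletons are then removed; output ordered by (abundance
  desc, sequence asc).  Because canonicalization can store near-identical
  sequences in opposite orientations, *every* later comparison against a
  centroid is strand-aware.
* **Clustering.** Greedy centroid clustering at 97%: visit uniques in
  order; join the best-identity centroid at or above the radius (ties to
  the earliest-created centroid); otherwise discard if chimeric; otherwise
  found a new OTU.  Identity is matching columns / alignment columns over
  an edit-distance-optimal global alignment with terminal gaps excluded and
  internal gaps counted as mismatch columns (computed with edlib).
* **Chimera model.** A query is chimeric iff no single centroid explains it
  at ≥ 99% but some breakpoint splits it into a prefix and suffix each
  ≥ 99% identical to two distinct centroids whose sizes are at least twice
  the query's abundance.  Segments are compared positionally (the inputs
  are equal-length amplicons) after orienting each candidate parent to the
  query; every breakpoint is checked via cumulative mismatch counts.  The
  2× parent-abundance factor and 99% segment identity are this package's
  parameters for an otherwise standard two-parent model.
* **Mapping.** All merged + truncated reads (regardless of filter status)
  are assigned to their best-identity centroid at ≥ 97%, strand-aware, with
  a banded edit-distance screen for speed; unassigned reads are counted.
  Clustering input, by contrast, is the filtered, dereplicated set.
* **Control subtraction.** Per-OTU counts observed in the pooled negative
  controls are deducted from every cell, floored at zero.

## Taxonomic assignment

Candidates must share a 28-bp exact word with the query on either strand.
Each candidate is aligned (infix of the reference, linear gap cost with
open = extend); the raw score uses reward +1 / penalty −2 and the e-value
follows Karlin–Altschul (λ = 1.28, K = 0.46) with the library's total
length as search space — for a small local library only ordering and
thresholding matter.  The grade maps the e-value to a 0–100 score linearly
in −log10(e) between e = 1 (0) and e = 1e-50 (100); this mapping is a
documented knob, since no published convention exists, and nothing
downstream depends on its exact shape beyond the 0.5/0.25/0.25 weights.
Hits with e-value above 0.1 are discarded; the best hit has the highest
grade (ties: bit score, then accession order).  Grades ≥ 97 are flagged
reliable, 90–97 genus-uncertain, < 90 unreliable; species-level calls are
always indicative-only.

## Diet metrics

RRA sums reads by taxon at the chosen rank per sample, drops the five
parasite orders (they are secondary prey), and renormalizes.  OTUs
unresolved at the rank pool into an explicit "unknown" taxon, kept for
composition displays but excluded (with renormalization) before
cross-method correlations, which pair named taxa only — the same rule is
applied to camera profiles, and it is also how the headline RRA-vs-RSBC
correlation treats the camera "unknown" category at family level.
Aggregation over samples is the two-step rule (percentage per sample, then
unweighted mean), deliberately not weighted by read depth.  FOO counts
units with at least `min_reads` (default 1 — a knob, since presence
thresholds are study-specific).  Camera diversity statistics round scaled
biomass half-up to integers first, dropping taxa that round to zero.
Rarefaction subsamples reads without replacement; the hypergeometric
closed form serves as its analytic cross-check.

## Community statistics

Pearson r uses the textbook estimator with a Fisher-z 95% CI
(tanh(atanh r ± 1.96/√(n−3))) and a two-sided t test.  Bray–Curtis is
Σ|u−v| / Σ(u+v) (not a metric; the triangle inequality is neither used nor
asserted).  NMDS minimizes Kruskal stress-1 with isotonic regression over
20 random starts (scikit-learn's nonmetric MDS under the package surface);
coordinates are centered and the reported stress is independently
re-computable from the returned configuration.  The beta-dispersion test
embeds the distance matrix by principal coordinates (positive eigenvalues),
measures distances to group centroids and compares the between/within F to
its group-label permutation distribution.  PERMANOVA partitions the sum of
squared distances (SS_total = Σd²/n; within-group analogously) into a
pseudo-F with group and residual mean squares reported.  All permutation
p-values follow (1 + #{F* ≥ F}) / (n_perm + 1) with 999 permutations by
default and seeded generators, so p is never exactly zero and every test is
reproducible.  The FOO contingency chi-square uses no continuity
correction — required to match the published 3.721 — and restricts to taxa
with FOO ≥ 3 in at least one sample type; df = T − 1.

## Settings sweep

The sweep re-runs truncation + filtering + clustering per variant on the
same merged reads (EE values at the default truncation, truncation values
at the default EE — a one-factor-at-a-time design) and compares per-taxon
read counts across variants with a one-way within-subject F (taxa as
subjects): F = MS_treatment / MS_treatment×subject.  Identical variants
give F = 0 by convention (0/0).

## Problem sizes and numerical choices

The end-to-end validation experiment uses 8 orders (one parasitic), 12
taxa, 20 camera sessions × 150 items at order precision 0.9, and one
10,000-pair sample per session with 0.5% per-base error, 2% chimeras, 5%
host reads, 70 pooled control reads and 5 shared contamination reads per
sample — a study of roughly half the sequencing effort of a typical field
season, which keeps a 10-seed replication to a few minutes on one CPU while
leaving all sampling-noise regimes represented.  Unit tests run on smaller
communities (6 orders, ≤ 1,000 reads per sample).

Degenerate inputs are defined, not crashed on: empty read sets partition
into empty sets; an all-zero diversity unit has richness 0 and H = 0; a
sample losing all reads to exclusions yields an empty profile with a
warning.  Constant vectors, single-member groups, all-zero count rows and
invalid configurations raise informative errors.  Tie-breaks are
deterministic everywhere (abundance desc / sequence asc; earliest-created
centroid; forward base on equal merge qualities), so fixed seeds give
byte-identical outputs.

## Known limitations

* The identity convention (terminal gaps excluded, internal gaps as
  mismatch columns) follows common usage but is not the only possible one;
  alignments are edit-distance optimal, which for the equal-length
  amplicons this pipeline produces coincides with the free-end-gap optimum.
* The e-value→score mapping inside the grade is a package convention.
* Amplification bias is a single per-taxon multiplier; no cycle-level PCR
  simulation, no quality-decay error profiles, no indel errors.
* The beta-dispersion embedding keeps positive eigenvalues only; for
  strongly non-Euclidean distance matrices this differs slightly from
  corrections that retain negative eigenvalues.
* Absolute intake is out of scope: all metrics are relative contributions.
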