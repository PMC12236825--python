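# Methods

## Assay model

Each designed element is a 100-bp candidate cis-regulatory sequence
carried by a lentiviral reporter. Three measurement channels exist per
element and replicate:

* **MPRA** — each element is coupled to many random 15-bp barcodes;
  transcriptional activity is read out as the RNA/DNA barcode-count
  ratio, UMI-deduplicated per barcode.
* **Inserted** — UMIs per element amplified from genomic DNA; a proxy
  for lentiviral integration frequency.
* **Enriched (ATAC, H3K27ac)** — UMIs per element from Tn5-tagmented
  chromatin; epigenetic activity is the enriched/inserted ratio.

Counting assigns reads to elements only on exact full-length sequence
identity (the references are the designed oligos, so a mismatch means a
synthesis or sequencing error, not a variant). Barcodes must be seen in
at least `min_cov = 3` association reads mapping to a single element;
elements need at least 5 unique barcodes per replicate in the MPRA
channels. UMI deduplication defaults to exact-sequence collapse; a
directional-adjacency mode (1-mismatch neighbours absorbed when
`count_parent >= 2*count_child - 1`) is available for error-prone UMIs.

## Normalization and activity scores

Counts are depth-normalized to counts per million (CPM) per (replicate,
channel). A scaling factor *f* is then computed as a trimmed mean of
M-values over designated negative-control elements (random genomic
sequences): with `M_i = log2(enriched_i/inserted_i)` and
`A_i = ½·log2(enriched_i·inserted_i)`, the lowest/highest 30% by M and
5% by A are discarded and `f = 2^mean(M)` of the survivors, unweighted
(controls are few, so the precision-weight refinement of classic TMM is
omitted). Dividing enriched values by *f* fixes the expected control
log2 activity at 0 in every sample; recomputing the factor on anchored
values returns exactly 1, which is the invariant the tests check.

Epigenetic activity per replicate is `log2((enriched/f)/inserted)` on
the CPM scale. Elements with zero inserted count are missing for that
replicate; when enriched is 0 but inserted positive, 0.5 is added to
both raw channels so zero-enrichment elements stay in the
distributions. Replicates are pooled by summing raw counts per channel,
re-normalizing, and recomputing the ratio — preferable to averaging
per-replicate ratios because single-UMI shot noise dominates the
per-replicate epigenetic scores. Pooled scores require a pooled inserted
count of at least 10 (configurable); this implements the exclusion of
elements essentially absent from genomic DNA, and
`exclude_unobserved_motifs` extends it to dropping a grammar motif
wholesale when the median pooled inserted count of its elements falls
below the threshold (the fate of GC-rich motifs whose sequences amplify
poorly).

MPRA activity averages per-barcode log2(RNA/DNA) ratios within an
element (log of the geometric mean; variance-stabilizing across
barcodes), plus the CPM depth correction, minus log2 *f* from the same
control-anchored TMM. The both-channels rule guarantees both counts are
at least 1, so no pseudocount is needed; a ratio-of-sums aggregation is
available by option. Pooling sums barcode counts across replicates
before the same computation.

## Grammar statistics

The two neutral templates are treated as additional replicates, so a
complete design yields templates × infection replicates observations
per element; all regressions and tests use per-replicate activities,
not pooled scores.

* **Homotypic trend** — Spearman correlation between motif copy number
  (1/2/4) and log2 activity per motif and assay;
  Benjamini–Hochberg (BH) within assay, significance at FDR 0.05.
* **Synergy regression** — per unordered motif pair, ordinary least
  squares `log2Activity ~ countTF1 + countTF2 + k` with intercept over
  the pair's homotypic (Class 1, k = 0) and heterotypic (Class 2)
  elements. `k` is encoded as the per-motif copy count of Class 2
  elements — 2 under the default 2:2 arrangements (AABB, ABAB, ABBA,
  BBAA per pair) — so a planted pair boost δ appears as `beta_k = δ/2`;
  a 0/1 encoding is available by option. Two-sided t-test on `beta_k`,
  BH within assay, FDR 0.01. With only Class 1 data k is constant and
  the model is declared unidentifiable rather than silently dropped.
* **Motif-order ANOVA** — one-way ANOVA with the permutation of a
  four-motif set as the factor (24 levels), one test per set and assay;
  BH within assay; the range of per-permutation means is reported as
  the effect size.
* **Positional enrichment** — elements are ranked by pooled
  transcriptional activity (ties broken deterministically by element
  id); for each motif, slot (1 distal … 4 proximal to the minimal
  promoter) and tail (top/bottom 200 by default), the upper
  hypergeometric tail P(X ≥ x) and the odds ratio
  `(x/(n−x)) / ((K−x)/((N−K)−(n−x)))` are computed against the pooled
  background of all ranked sequences; BH across motif × position within
  each tail.

## Variant-effect model

For one CRE's substitution library, a single joint OLS fit per assay:
response `log2(enriched + 0.5)`, covariates `log2(inserted + 0.5)` with
a free slope, an intercept, and one 0/1 indicator per variant;
observations are element × replicate rows and the wild type is the
baseline (its absence in any replicate is an error, since the intercept
would then be confounded). The "offset" term of the model is read as a
free intercept by default; an alternative mode fixes the coefficient of
log2(inserted) at 1 and moves it to the left-hand side (a true
exposure offset) — on proportional data both agree. The pseudocount
keeps zero-enriched variants in the design matrix. Effects are the
indicator coefficients in log2 units with raw two-sided t-test
p-values; the significance flag uses p < 0.01 without multiplicity
correction, matching how such per-variant maps are conventionally
drawn. `winsorize_wt` optionally caps anomalously deep WT counts at a
quantile of the variant counts (off by default).

## Functional-site calling

The perturbation profile assigns position *i* the median pooled
activity of all window variants covering *i* — up to 12 sequences for
interior positions with two randomization replicates. All covering
sequences are used rather than a single replicate set's six, because
the median over 12 is strictly more stable; uncovered positions are
linearly interpolated and logged. The MAD score is
`(effect − reference)/median|effect − reference|` with no normality
constant; the reference is the WT activity for MPRA, and the median of
the CRE's 300 substitution activities for the fragment-count assays,
whose WT measurements are unreliable (WT molecules amplify anomalously
deeply). A fully flat profile has MAD 0 and is rejected as degenerate.

Sites are called by a one-dimensional Canny adaptation: Gaussian
smoothing (σ = 1.5 positions, truncated at 4σ, reflect padding — σ of
about a quarter of the 6-bp window keeps single-window features
resolvable), central-difference derivative, non-maximum suppression on
|derivative| (a position survives if its |derivative| is ≥ both
neighbours; ends compare to their single neighbour), and hysteresis:
strong edges are NMS survivors with |derivative| strictly above the
median of |derivative| (the median of the *absolute* values — a signed
median would be ≈ 0 and admit half of all positions), weak edges are
all positions above that median, and weak edges chain-connected to a
strong edge at distance 1 are promoted recursively. Peak candidates are
local extrema of the smoothed score with |smoothed| > 0.75; each peak
extends to the nearest strong edge on each side (or stays a point if
none exists on that side), overlapping regions merge, and the site
direction is the sign of the strongest merged peak. A constant profile
yields no sites because the strict median inequality fails everywhere.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume.
Latent log2 activities are additive: category baseline + per-copy motif
effects + pairwise synergies for co-occurring motifs + variant/window
effects + optional element-level Gaussian noise; negative-control
categories (random genomic, scrambled) are pinned to exactly 0. Counts
follow: inserted ~ negative binomial (mean 300 UMIs/element, dispersion
α = 0.1, var = m + αm²) per element and replicate; enriched ~ Poisson
with rate inserted × (mean 80/300) × 2^(latent + replicate offset);
barcodes per element ~ truncated Poisson (mean 80, ≥ 1) with per-barcode
DNA ~ NB(mean 30, α = 0.1) and RNA ~ Poisson(DNA × 2^(latent +
offset)). Per-(assay, replicate) log2 offsets with sd 0.1 emulate
between-replicate depth/efficiency drift. The depth defaults (~80
barcodes, ~300 inserted and ~50–100 enriched UMIs per element)
correspond to the coverage a typical run of the assay achieves, and
they reproduce its qualitative replicate behaviour: per-replicate
epigenetic activity correlations of ~0.4–0.5 against ~0.95 for the
barcode-averaged MPRA scores.

What the generator does **not** emulate: sequencing errors, PCR
jackpots, GC-dependent amplification bias (motif dropout is injected
directly as zero inserted counts via `zero_inserted_for_motif`),
barcode collisions between elements, and position effects of genomic
integration. Passing tests therefore demonstrate that the estimators
recover the truth under the assumed error model, not that real
libraries are free of those artefacts.

## Calibration behaviour and limitations

* Under the null, the synergy regression's significant fraction at FDR
  0.01 stays well below 2%, and the variant model flags well below its
  nominal 1% of variants at p < 0.01. Both are *conservative*: the
  shared per-replicate offsets are not modelled as fixed effects, so
  they inflate residual variance without inflating the per-coefficient
  contrasts. Observed null flag rates for the variant model are
  ~0.0–0.3%.
* Conversely, with ~80–160 barcodes per element the MPRA channel
  resolves activity differences of ~0.02 log2 units, so tiny
  normalization imperfections can occasionally reach statistical
  significance in the synergy family; effect sizes should be inspected
  alongside adjusted p-values.
* BH at FDR 0.05 mathematically admits a false flag in a minority of
  experiments whenever true signals are present (FDR controls the
  expected false fraction, not the per-experiment error), so "exactly
  the planted motifs and nothing else" holds in most but not all runs;
  recovery is validated as sensitivity plus a bound on the null flag
  rate.
* The window-perturbation motif screen rejects a candidate whenever any
  screen motif matches the mutated window ± 6 bp context; a window whose
  *unchanged* flank already contains a screen motif can therefore never
  be satisfied and errors out after 1000 redraws — by design, since
  such windows cannot meet the no-motif invariant.
* Motif scanning uses exact IUPAC-consensus matching on both strands as
  the screening primitive; a PWM-based caller can be substituted by
  passing its hits through the same interface.

## Validation problem sizes

The test suite and the acceptance script validate at these scales:
design arithmetic at full library size (6,590 grammar + control
elements); control anchoring on the 400-element pilot at 3 replicates
(~360k inserted UMIs); null calibration over 500 simulated grammar
datasets (4 motifs, 2 templates) and 20 substitution datasets (6,000
null variants); recovery over 100 simulations each for the copy-number
trend (8 motifs), the variant model (300 variants, 10 planted effects
of −1.5 at ~10³ UMIs/element) and the site caller (10-position planted
depressions of 2 score units in sd-0.2 noise).
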