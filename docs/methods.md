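# Methods

## The measurement problem

Cells fractionated into nucleus and cytosol, with and without an
oxidative-stress treatment, yield small-RNA sequencing libraries in which
each tRNA-derived read carries two pieces of information: which gene it
came from, and where it ends relative to the mature 3′ CCA terminus.
Because retrograde transport preferentially moves 3′-truncated ("defective")
tRNAs into the nucleus, the analysis must resolve the 3′ end at
single-nucleotide precision rather than just count reads per gene. The
imaging arm asks the complementary single-cell question: how much probe
fluorescence sits in the nucleus relative to the cytoplasm of each cell.

## Reference model

A tRNA gene contributes a mature transcript that ends in CCA; genomically
encoded CCA is treated identically to the enzymatically added one (the
mature form is simply "ends in CCA"). For each gene the reference
enumerates the mature sequence and all variants missing k = 1..K 3′
nucleotides (K defaults to 13, covering the acceptor stem plus the NCCA
end). k is defined against the mature transcript: k = 1 lacks the
terminal A, k = 3 the whole CCA. Mature lengths outside 60–120 nt are
rejected as implausible for cytoplasmic-type tRNAs. Pseudogenes can be
dropped at load time, mirroring how curated gene sets are usually built.
All sequences are normalized to DNA (U→T) because reads are in DNA space.

## Read assignment

Two routes exist. The built-in exact matcher looks a read up among all
truncated variants; a read is assigned when exactly one gene matches
("uniquely mapped reads only"), and ties between genes are discarded.
This is intended for synthetic or error-free reads, where it is exact by
construction. Real libraries should be aligned by any external aligner
against either the truncation reference (variant names encode k) or the
mature reference, in which case k is inferred from the alignment end.
Soft-clipped 3′ bases do not count toward the end: clipping is treated as
absence of evidence. Reads ending more than K nt short are binned at K;
reads shorter than 15 nt are discarded (tRNA-fragment biology is out of
scope). Coordinates are 1-based inclusive transcript coordinates
internally, with SAM conventions honoured at the boundary. 5′ truncation
(e.g. from reverse-transcription stops at modified bases) is ignored for
assignment, which rests on the 3′ suffix evidence.

## Counting statistics

Size factors are median-of-ratios: factor_j = median over genes of
count_gj / (per-gene geometric mean across samples), genes containing a
zero excluded from the median. Note these factors are identified only up
to a common multiplicative gauge — rescaling one sample by s moves all
factors, but factor *ratios* scale by s and every normalized quantity
changes only by a sample-independent constant; tests assert the
gauge-invariant statements.

Two depth filters are exposed because both are in common use: a strict
base-mean filter (mean normalized count across all samples > threshold,
default 20) and a cytosolic-control filter (raw count ≥ threshold in the
cytosolic control samples — per-sample by default, with a mean-based
sub-mode, since "depth of at least 20 reads in the cytosolic controls" is
ambiguous between the two).

Log₂ fold changes are computed within a compartment as
log2((mean normalized treated + c)/(mean normalized control + c)) with
pseudocount c = 0.5 to keep zero-count genes finite; per-replicate values
pair replicate i treated with replicate i control, and the consistency
call is "up"/"down" only when every replicate clears ±0.75 with one sign
(strict inequality at the boundary).

The differential test is a deliberately transparent simplification of a
full NB-GLM framework: a Wald test on the log ratio of mean normalized
counts under Var = μ + αμ². The dispersion α is a method-of-moments
estimate pooled across genes: Σ(s² − x̄) / Σ(x̄² − s²/n) over genes and
conditions, where the denominator uses the unbiased estimator of μ²
(plain x̄² would bias α downward at n = 2); a per-gene option exists but
is far too noisy at two replicates. The SE evaluates the variance at the
pooled mean (score-type, avoiding inflation from plugging tiny-n group
means into their own variances) and includes the second-order
delta-method term for Var(log mean). α is floored at 1e-8; with fewer
than two samples in a condition the model degrades to Poisson with a
warning; a label-permutation option exists for designs where the normal
approximation is in doubt. Under null simulation at the study's design
(two replicates per condition, NB mean 100, dispersion 0.1) the empirical
type-I error is ≈ 0.05. Multiple testing uses Benjamini–Hochberg step-up
(adjusted p ≥ p, monotone in rank), the conventional reading of an
"adjusted p value". Intact (k = 0) and defective (k ≥ 1 pooled) classes
are analysed separately; per-k analysis is available through the variant
matrix. The nuclear fraction is the default test compartment, where the
localization changes concentrate.

Amino-acid aggregation sums counts per isotype (20 standard + Sec) and
normalizes per sample; row ordering for heatmap-style output uses
hierarchical clustering (Euclidean distance, complete linkage), leaf
order from the deterministic linkage.

## Image quantification

Nucleus segmentation follows an ImageJ-macro recipe: Otsu threshold with
dark background, one 3×3 binary dilation, hole filling, 8-connected
labelling, particles < 500 px and border-touching particles removed.
Cytoplasm segmentation blanks the nuclear regions on the probe channel,
Otsu-thresholds, median-filters (radius 2), labels, size-filters, then
applies a constrained non-merging dilation (2 iterations): a background
pixel joins a component only when exactly one label claims it *and* no
same-sweep claim of a different label would become adjacent, so the
binary component count is invariant. The dilation exists to bridge each
cytoplasm component to its nucleus for matching (each component is
assigned to the nucleus its filled, grown outline overlaps most); the
returned masks keep the thresholded footprint, so intensity statistics
are computed over evidence pixels only — on a noise-free uniform-ratio
cell the measured N/C is exact. Manual background correction and
freehand cell separation of the original interactive workflow are not
reproduced; the automated path is a stated deviation, and nuclei without
cytoplasm are dropped with a warning rather than fixed by hand.

Mask mode divides the mean probe intensity over the nucleus by the mean
over the cytoplasm-only region; formula mode measures nucleus and whole
cell and applies
N/C = (RID_Nuc/Area_Nuc) / ((RID_Cyt − RID_Nuc)/(Area_Cyt − Area_Nuc)).
The two are algebraically identical on the same masks, which is asserted
to 1e-9.

Group statistics: unpaired two-tailed t test for two groups, Dunnett's
many-to-one comparisons otherwise. Dunnett p-values are computed by
deterministic quadrature over the one-factor multivariate-t structure
(Gauss–Hermite over the shared control deviate × Gauss–Legendre over the
pooled scale in quantile space, 80 nodes each); with a single comparison
the test reduces exactly to the pooled two-sample t test.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular library preparation. Genes are random
sequences of 62–90 nt plus CCA with isotypes over the 21 amino acids and
anticodons back-translated from the standard genetic code; the default
count of 323 matches the size of a pseudogene-free human tRNA gene set.
Reads: per-gene baselines are log-normal (σ = 1), gene counts
negative-binomial (dispersion 0.1) around each sample's expected share of
the depth (default 10⁵ reads/sample — a desk-scale stand-in for the
millions of a real run), split across k by per-(fraction, condition)
spectra. The default spectra encode the qualitative stressed-cell
picture: ~50 % intact in the cytosol throughout, nuclear intact fraction
dropping from 60 % to 30 % under treatment with extra mass at k = 5–8;
the default effect palette is null everywhere except one "Sec-like" gene
with an 8.6-fold nuclear gain and 2.7-fold cytosolic loss. A noise-free
mode emits largest-remainder-rounded expected counts summing exactly to
the depth, giving the profiler an exact identity target. Optional uniform
substitution errors (off by default) exist; reverse-transcription stops,
demethylase effects and quality-score realism are not modelled — so
passing tests demonstrate correctness of the measurement pipeline, not
robustness to alignment artefacts of real TGIRT libraries.

Images: non-overlapping elliptical nuclei (semi-axes 20–28 px, area well
above the 500 px particle floor) inside elliptical cells (1.55–1.95×),
DAPI bright in nuclei, probe at cyt_mean = 40 with nuclear mean =
ratio × 40 over background 5, additive Gaussian noise (default SD 5, SNR
8). Placement is rejection sampling with bounded retries. Because the
synthetic cells have hard edges, the macro's 1-px nucleus dilation — which
compensates for understained nuclear peripheries in real images — dilutes
the nuclear mean by the rim fraction (~5–8 % at ratio 4); end-to-end
recovery is therefore asserted to 10 % while the mask/formula identity is
exact.

## Problem sizes and determinism

All generators are deterministic per seed. Tests and the acceptance
script use 300-gene references at 5×10⁴–10⁵ reads/sample, 700–2 000-gene
count-level simulations, 15–20-cell fields, and 600–1 000-replicate
Monte-Carlo calibrations — sizes chosen so the full suite runs in well
under a minute per module on one CPU while keeping Monte-Carlo standard
errors small relative to the asserted bands.

## Known limitations

- The NB test is not a DESeq2 reimplementation: no shrinkage of
  dispersions or fold changes, no Cook's-distance outlier handling; on
  real data its p-values will differ from a DESeq2 run.
- The exact matcher requires error-free reads; real libraries need an
  external aligner.
- Coverage is reported in transcript coordinates; covariance-model
  (structure-aligned) coverage is out of scope.
- Single-plane images only; no 3-D stacks, no colocalization analysis,
  no manual mask correction.
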