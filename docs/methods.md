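# Methods

This note documents the models, parameter choices and numerical decisions
behind `canidcnv`, and what the synthetic-data generator does and does not
emulate.

## Signal model

aCGH probes report log2(test copy / reference copy) plus noise. The
package works relative to the diploid reference state, so the expected
signal of a locus with diploid copy number c is log2(c/2): −1 for a
hemizygous loss, 0 for two copies, +0.585 for three, +1 for four. A
homozygous deletion (c = 0) is clamped to −3.0 — finite, yet far below
any loss-calling threshold. Probe noise is modelled as homoscedastic
Gaussian, the standard first-order assumption for aCGH; dye bias,
GC-waves and spatial artifacts are deliberately out of scope.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis relies
on, at desk scale:

* **Panel**: 23 canids — 4 purebred dogs + 1 dingo (group `dog`),
  15 gray wolves, and red wolf / coyote / golden jackal as outgroups; one
  reference dog whose own track is pure noise around zero (self-self
  semantics). The dingo is grouped with dogs throughout.
* **Genome**: i.i.d. bases at a configurable GC fraction (default 0.41,
  the canine genome-wide value) with exactly implanted GC peaks, N-gap
  runs, and repeat/gene annotations placed uniformly at configurable
  densities. Repeats carry family labels, with L1 elements stratified
  into five age classes (CanisFamiliaris, Canis, Canidae, Carnivora,
  OlderMammalia) taken as input labels, not inferred.
* **Truth CNVs**: diploid genotypes drawn per group under Hardy–Weinberg
  with haplotype alleles L = 0, N = 1, G = 2 copies; the per-group
  (loss, normal, gain) allele frequencies are the experiment's dials and
  default to a fixed mixture of archetypes (shared polymorphic,
  dog-specific, wolf-specific, strongly differentiated with dog gain
  frequency 0.9, and monomorphic loci).
* **Array design**: probes tile the CNV loci (± 10 kb flanks) and 42
  single-copy control regions, with spacing set by the tiled region's
  length — 50 bp below 100 kb, 150 bp at 100–300 kb, 1 kb above 300 kb —
  matching the design rule of the study's 720K chip. Default noise SD is
  0.15 on the log2 scale.

It does **not** emulate breed pedigree structure, ascertainment bias of
the array content, GC-dependent intensity waves, or diverged (non-exact)
repeat copies. Passing tests therefore demonstrate the correctness of the
algorithms under the stated noise model, not robustness to every real
array artifact.

Every output is a pure function of (config, seed); pipeline stages get
sub-seeds derived from CRC32(master seed, stage name), so stages are
reproducible in isolation and report files are byte-identical across
reruns.

## Discovery

RJ-MCMC segmentation is replaced by a fixed-architecture 3-state Gaussian
HMM — the downstream filters only require per-probe posterior
probabilities of the called state, which forward–backward supplies:

* emission means −0.6 / 0.0 / +0.45 (loss / normal / gain); the gain mean
  sits below |loss| because a single-copy gain (log2 3/2 ≈ 0.585) is
  weaker than a single-copy loss (−1);
* shared emission SD estimated per chromosome from the track's median
  absolute deviation (×1.4826), robust to the CNV probes themselves;
* self-transition 0.999, a prior run length of ~1,000 probes that
  suppresses isolated outliers.

Maximal non-normal Viterbi runs become segments. The second caller flags
runs of ≥ 30 consecutive probes beyond ±2 robust SDs of the chromosome
median. Combination is conservative *intersection*: an HMM segment
survives only if same-state segments of the run-length caller cover at
least half of it (the segment keeps the HMM coordinates). Union was the
other defensible reading of "combination of two methods"; intersection
was chosen because the study describes its approach as conservative and
its self-self false-call counts are low.

Confidence filtering keeps segments with average posterior > 0.60 at
≥ 50 probes and > 0.75 at 30–49 probes; segments under 30 probes are
discarded. Within a sample, same-state segments merge (transitively) when
separated by < 3 kb or when the *open* interval between them is > 80 %
covered by repeats or assembly gaps. Across samples, any ≥ 1 bp overlap
joins segments into a region regardless of state — a region genotyped per
sample afterwards may legitimately hold gains in one sample and losses in
another.

## Genotyping and polarization

Per sample and region: mean log2 over the region's probes, called gain at
≥ median + 1.5 SD and loss at ≤ median − 1.5 SD, with median and SD taken
over **all** log2 values of that sample's chip. Values exactly at a
threshold are non-equal (deterministic tie rule). Sharing classes compare
dogs (incl. dingo) against all wild canids; the post-domestication
polarization test is stricter — a dog gain/loss is flagged duplication/
deletion only when absent from all *gray wolves* (outgroups neither veto
nor contribute), and one region can carry both flags.

## Allele frequencies, He, VST

The three genotype categories map onto diploid copy arithmetic: sum 2 =
equal (NN or GL), < 2 = loss (LL, NL), > 2 = gain (NG, GG). Under HWE the
category probabilities are P(loss) = r² + 2pr, P(equal) = p² + 2qr,
P(gain) = q² + 2pq. EM alternates the genotype-posterior E-step with
allele counting, stopping at a log-likelihood change < 1e-10 or 1,000
iterations. Two numerical facts shape the implementation:

* the exact uniform point (1/3, 1/3, 1/3) is a fixed point of the EM map
  for symmetric data, so EM starts from smoothed category proportions;
* the category map is not injective and the likelihood can carry several
  local (and even tied global) maxima — counts (1, 2, 1) are fitted
  exactly by both (p,q,r) = (2/3, 1/6, 1/6) and (0, 1/2, 1/2). EM
  therefore runs from four fixed starts (smoothed proportions plus one
  start dominant in each allele) and returns the best likelihood. A
  corollary: allele frequencies are only estimable up to this ambiguity,
  and parameter-recovery guarantees hold at identifiable points of the
  parameter space.

He = 1 − (p² + q² + r²) ∈ [0, 2/3]. Both EM-based and direct
category-proportion He are exposed; the wolf-subsampling comparison uses
direct proportions, averaging He over polymorphic regions for 1,000
random groups of 5 gray wolves (matching the dog group size of 5) and
reporting the add-one fraction of draws at or below the dog value.

V<sub>ST</sub> uses unbiased (n−1) variances for both V<sub>T</sub> (all
dogs + gray wolves) and the size-weighted within-group mean V<sub>S</sub>,
on per-sample mean log2 values — not genotype categories. V<sub>T</sub> = 0
defines V<sub>ST</sub> = 0. Ranking is by descending V<sub>ST</sub> with
(chrom, start) tie-breaks for determinism; the default report keeps the
top 25.

## Breakpoints

Breakpoint windows are 400 bp (the smallest detectable CNV) centred on
region boundaries; CNVs shorter than the window are skipped, edge windows
clipped. GC peaks slide a 500 bp peak window and a centred 10 kb
background window together at a 100 bp step (the step is a free choice);
a window qualifies when its GC exceeds 1.5× the background GC (background
*includes* the peak span), and overlapping/adjacent qualifying windows
merge into maximal peaks — a merged span is re-verified and falls back to
its strongest constituent window if merging diluted it below the
criterion, so every reported peak re-checks directly against the
sequence. N bases never enter GC denominators; windows > 50 % N are
dropped from profiles.

Longest perfect homology between two windows is the longest common
substring (N never matches), computed by binary search over the answer
length with exact substring-set membership — O((n+m)·L·log L) — and
verified in tests against the O(nm) dynamic-programming oracle. The
permutation null re-places each pair uniformly on its own chromosome with
the intra-pair distance preserved exactly; significance is a two-sample
Wilcoxon rank-sum between observed per-pair values and the pooled
redistributed values (exact distribution below 30 combined observations,
tie-corrected normal approximation otherwise). Repeat enrichment counts
breakpoint windows overlapping ≥ 1 repeat of a family, across a
configurable list of window sizes, against the same redistribution null.

## Randomization p-values

Null statistics of interval redistributions are small tied integers. The
classical add-one rule p = (#{null ≥ obs} + 1)/(n + 1) is then markedly
conservative (ties pile into the tail), visibly breaking null uniformity;
all enrichment tests therefore use the mid-p convention, ties counting
half, with two-sided p doubling the smaller tail (capped at 1). p never
equals 0. Calibration of these p-values is itself tested: under
self-sampled nulls the reported p-values are uniform by Kolmogorov–
Smirnov at α = 0.01. Note that uniformity is only observable when the
null statistic has a reasonably rich support; a scenario whose observed
count takes four values with 40 % atoms cannot yield uniform p-values
from any deterministic rule.

The gene-overlap test draws each null set by re-placing every target
region as a same-length window uniformly inside a universe region chosen
uniformly among those long enough to contain it — the universe being the
assayed-array footprint, so null sets live on the array, not anywhere in
the genome.

## QC conventions

Control-region FDR is 100 × calls/tests, floor-truncated to two decimals
(17/966 → 1.75 %); other report percentages print to one decimal.
Self-self chips run the full discovery stack and count every call as a
false positive. qPCR concordance calls the qPCR state gain/loss/equal
against a reference copy of 2 and reports false-positive and
false-negative fractions over all paired comparisons.

## Problem sizes

Defaults for the synthetic study are two 1.5 Mb chromosomes, 30 CNV loci
of 3–20 kb, 42 control regions of 10 kb and 0.15 noise SD; the acceptance
script runs 24 loci on two 1.2 Mb chromosomes with 200 resamples per
randomization test and 1,000 wolf-subsample draws, and the test suite's
calibration checks use 200 replicates × 200 resamples. These sizes were
chosen so a complete run is a desk-scale computation while every rate
being tested (recovery, calibration, FDR) still has enough trials to be
meaningful.

## Known limitations

* Gains above four copies and mosaic states are not modelled; "gain" is a
  single category.
* The HMM's fixed emission means are tuned to single-copy events; a locus
  whose only carriers are homozygous-gain samples is still detected but
  its mean log2 is underfitted by the +0.45 gain state.
* Allele-frequency non-identifiability (above) is a property of the
  3-category observable, not of the optimizer.
* Real-mode inputs assume the probe tracks are already normalized
  (median-centred); no within-chip normalization is applied.
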