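# canidcnv

Copy-number variant (CNV) analysis for wolf-like canid aCGH panels:
discovery and genotyping of CNVs from log2 probe ratios, population
differentiation between dogs and gray wolves, breakpoint-architecture
analyses, and randomization enrichment tests — with a synthetic-data
generator that emulates the array experiment so the whole pipeline is
testable without any external download.

## The problem

Array comparative genomic hybridization (aCGH) measures, probe by probe,
the log2 ratio of a test genome's copy number against a reference
individual. Given such tracks for a panel of domestic dogs (including a
dingo), gray wolves and outgroup canids (red wolf, coyote, golden
jackal), one wants to know:

* **where** the CNVs are (discovery), and which samples carry a gain or a
  loss at each locus (genotyping);
* **who shares them** — dog-specific vs wild-specific vs shared — and,
  using wolves to polarize ancestral state, which gains/losses are
  candidate post-domestication duplications and deletions;
* **how differentiated** each CNV region is between dogs and wolves, to
  flag candidate targets of selection during domestication;
* **what the breakpoints look like** — GC-rich peaks, stretches of perfect
  homology between the two breakpoints of a CNV (the signature of
  non-allelic homologous recombination, NAHR), and repeat-family
  enrichment — against chromosome-wise randomization nulls.

## Methods at the core

* **Discovery** (per sample): a fixed 3-state Gaussian hidden Markov model
  (loss / normal / gain) decoded per chromosome, with forward–backward
  posteriors, combined conservatively with an independent robust
  run-length caller; segments are filtered on the average posterior of the
  called state (> 0.60 at ≥ 50 probes, > 0.75 at 30–49 probes, < 30 probes
  discarded), joined within a sample when < 3 kb apart or when the gap is
  > 80 % repeats/gaps, and unioned across samples into regions.
* **Genotyping**: a sample is called *gain* at a region when its mean log2
  over the region's probes reaches median + 1.5 SD of all values of its
  chip, *loss* at median − 1.5 SD, otherwise *equal*.
* **Allele frequencies and heterozygosity**: with haplotype alleles
  L (0 copies), N (1), G (2) at frequencies r, p, q under Hardy–Weinberg,
  the observable categories have probabilities
  P(loss) = r² + 2pr, P(equal) = p² + 2qr, P(gain) = q² + 2pq;
  a multi-start EM maximizes the multinomial likelihood of the category
  counts, and He = 1 − (p² + q² + r²).
* **Differentiation**: V<sub>ST</sub> = (V<sub>T</sub> − V<sub>S</sub>)/V<sub>T</sub>,
  where V<sub>T</sub> is the variance of per-sample region log2 means over
  dogs + wolves and V<sub>S</sub> the population-size-weighted mean of the
  within-group variances; regions are ranked and the top k reported.
* **Breakpoints**: 400 bp windows centred on each CNV boundary; GC peaks
  (≥ 500 bp spans exceeding 1.5× the GC of a centred 10 kb background);
  longest perfect homology between paired windows with a Wilcoxon rank-sum
  test against pairs re-placed uniformly on their own chromosome (intra-pair
  distance preserved); repeat-family and L1-age-class enrichment by the
  same redistribution.

## Worked example

A synthetic end-to-end run on a two-chromosome genome with 12 implanted
CNV loci and the full 23-canid panel:

```python
from canidcnv import run_pipeline, validate_config

config = validate_config({
    "seed": 7,
    "simulation": {
        "chrom_lengths": {"chr1": 600_000, "chr2": 600_000},
        "n_cnv_loci": 12,
        "n_control_regions": 10,
    },
    "n_resamples": 50,
    "he_draws": 200,
})
res = run_pipeline(config)
```

prints (via the summary fields shown):

```
CNV regions discovered: 10
sharing classes: {'dog_specific': 4, 'wild_specific': 2, 'shared': 4, 'monomorphic': 0}
self-self false calls: 0
control FDR: 0 / 230 = 0.0%
dog He 0.380 vs wolf subsamples 0.420 +/- 0.034 (p = 0.144)
     vst chrom  start    end   region_id       vt       vs
0.689545  chr1 130822 133823 region_0001 0.168725 0.052382
0.644563  chr2 347062 352713 region_0007 0.088798 0.031562
0.626080  chr2 218694 234895 region_0006 0.111822 0.041813
breakpoint homology: 7.5 bp observed vs 8.7 bp expected (Wilcoxon p = 0.28)
```

Ten of the twelve implanted loci are polymorphic by construction and all
ten are recovered; the reference sample's own (self-self) track produces
zero false calls; no control region is mis-genotyped in any sample; and
the most differentiated regions are the loci implanted with dog-private
gain alleles. The same pipeline is exposed on the command line as
`canid-cnv run|discover|genotype|popgen|breakpoints|enrich|qc`.

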