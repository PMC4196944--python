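# Methods

## Scope and model

`poolsweep` analyses pooled-sequencing (Pool-seq) data from several domestic
strain pools and one wild population pool. Allele frequencies are estimated
from read counts, never from genotypes: every statistic downstream of the
counts treats reads as the sampling unit. The pipeline looks for hard
domestication sweeps — genomic windows where the domestic pools have been
driven to (near-)fixation while the wild pool remains polymorphic — via a
windowed pooled-heterozygosity statistic computed over
differentiation-significant SNPs. Soft sweeps, which leave diversity largely
intact, are outside its sensitivity by construction.

## Read cleaning

Quality trimming uses a running-sum ("modified Mott") criterion. With
threshold quality A (default Phred 20), each base contributes
`v = 10^(-A/10) - 10^(-Q/10)`; the running sum of `v` is clamped at zero,
and the retained span runs from its first positive value to its rightmost
maximum. Two behaviours are deliberate choices where the criterion itself is
underspecified:

* **Clamping.** Without the clamp a long low-quality prefix drives the sum
  so negative that a following high-quality stretch can never surface; the
  zero floor makes trimming local. `TrimConfig(clamp=False)` gives the
  literal unclamped sum for comparison.
* **Rightmost maximum.** Trailing bases with Q exactly equal to A add zero
  value; taking the rightmost maximum keeps them rather than discarding
  ties. Under the clamped sum, trimming is then exactly idempotent (property
  tested).

After trimming, reads shorter than `min_length` (default 30 bp) or whose
span still contains an N are discarded. A whole-read mean-quality floor is
available (`mean_quality_min`) but off by default: the threshold already
enters through the running sum, and a second mean filter would double-count
it. Adapter removal is out of scope; inputs are assumed adapter-trimmed.

## SNP calling and screening

Candidate calling sums A/C/G/T counts over the in-scope pools (N and
deletion reads never form alleles and are excluded from depth). The
major/minor alleles are the top two counts, ties broken alphabetically so
results are order-independent. A site is a candidate when the minor count is
at least 2; it is dropped when the third-ranked count also reaches the minor
floor, since a credible third allele violates the biallelic model the
downstream 2x2 tests assume — below that floor, third-allele reads are
treated as sequencing noise.

Screening applies three factors: minimum total depth, maximum total depth,
and minimum minor-allele read count (defaults 30 / 300 / 5). The maximum may
be a quantile spec such as `top2%`, resolved as the 98th percentile of the
observed site-depth distribution. `pct_reads_included` is depth-weighted
coverage retained — the sum of depths at sites passing the depth bounds over
the total depth of all sites — the quantity that makes a depth ceiling far
below the mean collapse toward a few percent while minor-count changes barely
move it. Screening is monotone by construction: tightening any one factor
can only shrink the SNP set (property tested across the standard 8-setting
grid).

Depth thresholds are applied to combined counts for the genome-wide
catalogue and to per-pool counts for per-strain calls; both scopes are
exposed because printed per-strain totals could arise from either. For the
common / strain-specific classification, a pool is *polymorphic* at a site
when its own depth is in bounds and its minor count reaches the threshold,
*monomorphic* when depth qualifies but the minor count falls short, and
*unclassifiable* otherwise; strain-specific status requires every other pool
to be adequately covered and monomorphic — a site cannot be declared
strain-specific on missing evidence.

MAF spectrum bins are left-open/right-closed — (0,5], (5,10], (10,20], …,
(40,50] percent — and SNPs at exactly MAF 0.5 are additionally counted on
their own, because the balanced case is a boundary of the minor/major
orientation.

## Differentiation

The test statistic per SNP is the two-tailed Fisher's exact p-value of
`[[dom_major, dom_minor], [wild_major, wild_minor]]` with the four domestic
pools' reads summed (one list of significant SNPs implies one test per SNP;
a per-strain union mode exists behind a flag). The implementation sums the
hypergeometric pmf over the support directly (log-binomials via `gammaln`),
which is an order of magnitude faster than per-table library calls at 1e5
tests per panel; a unit test cross-checks it against
`scipy.stats.fisher_exact` and the acceptance suite against exact
integer-weight enumeration for all margins <= 30. Tables whose pmf ties the
observed one within a relative 1e-7 are included in the tail, the standard
tie convention. A zero margin yields p = 1 with a warning.

FDR correction is Benjamini–Hochberg (the Benjamini–Yekutieli variant is
selectable); significance is q <= 0.01. Because reads are the test units,
pseudo-replication relative to individuals is inherent: reads from the same
chromosome of the same individual are not independent draws, so p-values
are anti-conservative in absolute terms. This is inherent to the pooled
design; within the pipeline the threshold functions as a ranking cut, and
the null-calibration test shows the FDR holds under the read-level null.

Location categories use only coding intervals (CDS/exon): `coding` inside,
`near_coding` within 100 bp of a boundary — inclusive at exactly 100 bp —
else `non_coding`. Counts always sum to the input total (tested).

## Sweep scan

`Hp = 2*sum_maj*sum_min/(sum_maj+sum_min)^2` is computed per window from
the domestic pools' reads only; the wild pool never enters the sums.
Major/minor orientation is recomputed per SNP within the domestic counts,
since the scan must reflect the scanned population's own allele balance.
Windows tile each chromosome from 0 with size = step = 20 kb by default
(non-overlapping tiles; `step` allows sliding scans), restarting at every
chromosome or scaffold. Windows with fewer than five significant SNPs are
not scored — small windows cannot estimate heterozygosity. The transform is
`-log2(Hp)`, with a window at exactly Hp = 0 assigned the cap value 7;
positive Hp values are never capped. The sweep threshold is inclusive
(>= 4); flagged windows that touch or overlap merge into regions, ranked by
minimum Hp ascending so fully fixed regions come first regardless of the
cap. Gene annotation attaches any overlapping feature (1-bp overlap
counts); regions in gene deserts keep empty lists.

## Synthetic data

The generator emulates the assumed study design: 5 pools (4 domestic,
1 wild) of 30 diploids, mean 30X per pool, one SNP per 116 bp placed by a
geometric spacing process on a 10-Mb five-chromosome toy genome (about
86,000 sites — desk scale in seconds).

* **Wild spectrum.** Minor-allele frequency log-uniform on
  [1/(2*pool_size), 0.5]: a neutral-like 1/f shape concentrated at low MAF
  with a closed-form CDF, so the spectrum is testable by a KS check.
* **Domestic drift.** Each domestic pool's frequency is Beta-distributed
  around the wild value under the Balding–Nichols parameterisation with a
  single differentiation coefficient `drift_c` (default 0.05 — a realistic
  FST for strains some decades into domestication). `drift_c = 0` is the
  exact no-differentiation limit used for null calibration. A
  bottleneck-style alternative can be emulated by raising `drift_c`.
* **Sweeps.** Three planted regions (40–60 kb, window-aligned) where every
  domestic pool is fixed for the same allele while the wild frequency is
  drawn from the ordinary spectrum.
* **Counts.** Depth ~ Poisson(coverage); alternate reads ~ Binomial(depth,
  frequency); each read then flips to a uniformly chosen other base with
  probability 0.002. Errors are applied read-wise after sampling, so the
  minor-allele-count filter has true errors to reject.
* **Reads.** The FASTQ stage plants a 4% bad-read fraction split over three
  failure modes (all-low-quality, embedded N, usable stretch < 30 bp), so
  the expected clean fraction after QC is 96%.
* **Annotation.** Non-overlapping genes with CDS children; two of every
  three sweep regions receive a gene and the third is left a desert, so
  sweep annotation exercises both outcomes.

Everything is deterministic under the configured seed (integer-state
generator streams per stage; same seed gives byte-identical sync output).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (sites are independent), mapping artefacts and
repetitive-element pileups (the motivation for the depth ceiling in real
data — here the depth distribution is clean Poisson), reference bias,
indels, and scaffold fragmentation. Passing recovery tests therefore shows
the statistics behave correctly under the model's assumptions, not that the
thresholds are optimal for any particular real genome.

## Problem sizes and numerical choices

The validation suites run the full pipeline on the 10-Mb default genome
over ten seeds (sweep recovery: all planted regions, no region beyond one
window of a planted one), a ~1e5-site panel for grid monotonicity, and a
~1e4-SNP null panel for FDR calibration — sizes chosen to give stable
statistics in minutes on one CPU. Report formatting: Hp to 3 decimals,
transformed Hp to 2, percentages to 1, MAF to 4; positions are 1-based in
reports except sweep-region tables, which follow the BED convention.
Internally all coordinates are 0-based half-open.

## Known limitations

* Read-level testing overstates independence (see above); no
  individual-level resampling is provided.
* No FST or haplotype-based differentiation statistics; no soft-sweep
  sensitivity.
* The sync reader requires sorted, per-chromosome-contiguous input and
  does not random-access compressed files.
* Window tiling from coordinate 0 means sweep boundaries are resolved only
  to window granularity.
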