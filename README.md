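# poolsweep

Detection of domestication signatures from pooled sequencing (Pool-seq) of
domestic and wild populations. The package takes per-pool nucleotide counts
for a set of domestic pools and one wild pool, screens single-nucleotide
polymorphisms with a three-factor filter, identifies SNPs whose allele
frequencies differ between domestic and wild pools, and scans those SNPs for
windows of extreme pooled homozygosity that mark putative hard selective
sweeps. It is written for population-genomics analyses of livestock and
aquaculture species where individuals are sequenced as pooled strain
libraries rather than genotyped one by one.

## The method

Pool-seq estimates allele frequencies from read counts. The pipeline's
stages are:

1. **Read cleaning.** Base qualities Q are converted to error probabilities
   `P = 10^(-Q/10)` and scored against a threshold quality A (default
   Phred 20) as `v = P(A) - P(Q)`. A running sum of `v`, clamped at zero,
   is accumulated along each read; the retained span runs from the first
   positive value of the sum to its (rightmost) maximum. Reads shorter than
   30 bp after trimming, or still containing ambiguous bases, are dropped.
2. **SNP screening.** Candidates are sites whose second-ranked nucleotide
   count (over all pools) is at least 2 with no credible third allele.
   Candidates are screened by minimum total depth, maximum total depth
   (absolute, or "exclude the deepest q%"), and minimum minor-allele read
   count — defaults (30, 300, 5). A criteria grid reports the SNP count and
   the depth-weighted percentage of reads retained under each setting, and
   SNPs are summarised by minor-allele-frequency spectrum and by
   common / strain-specific classification across pools.
3. **Differentiation.** Each screened SNP's summed domestic major/minor
   read counts vs the wild pool's form a 2x2 table tested with a two-tailed
   Fisher's exact test; Benjamini–Hochberg correction at q <= 0.01 defines
   the *significant* SNPs, which are categorised as coding, near-coding
   (within 100 bp of a coding interval), or non-coding.
4. **Sweep scan.** Over each 20-kb window holding at least five significant
   SNPs, the pooled heterozygosity of the domestic pools

       Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2

   sums major and minor allele reads over the window's SNPs; `-log2(Hp)`
   >= 4 flags a window as a putative hard sweep (a fully fixed window,
   Hp = 0, is assigned the cap score 7), and adjacent flagged windows merge
   into sweep regions annotated with overlapping genes.

A fully seeded synthetic-data generator produces the study design end to
end — 4 domestic pools + 1 wild pool of 30 diploids at ~30X, one SNP per
116 bp, Balding–Nichols drift of domestic frequencies, planted hard-sweep
regions — so every stage can be validated against ground truth.

## Worked example

`python examples/full_pipeline.py` simulates the default study (10-Mb
genome, three planted sweeps, seed 1) and runs the whole analysis:

```
sites               86054
candidate SNPs      80158
screened SNPs       67543  (100.0% reads included)
significant SNPs    406
scored windows      8
sweep regions       3
```

86,054 polymorphic sites yield 80,158 candidates (sites whose minor allele
is seen at least twice); the (30, 300, 5) screen keeps 67,543 SNPs, of
which 406 differ significantly between the domestic and wild pools at
q <= 0.01. Eight 20-kb windows hold five or more significant SNPs, and the
three merged regions with `-log2(Hp) >= 4` coincide exactly with the three
planted sweeps — `examples/sweep_scan_demo.py` prints them with their
minimum Hp, maximum transformed score and overlapping genes. The other
examples (`trim_reads.py`, `call_and_filter_snps.py`,
`differentiation_test.py`) exercise each stage on its own.

A thin CLI wraps the same functions: `poolsweep simulate`, `poolsweep trim`,
`poolsweep callsnps`, `poolsweep grid`, `poolsweep scan` (see `--help`).

## Documentation

`docs/methods.md` describes the statistical model, the parameter defaults
and their rationale, what the synthetic generator does and does not
emulate, and known limitations.
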