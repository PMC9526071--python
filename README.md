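# wolbscan

Reduced-representation sequencing of a host animal incidentally captures
reads from its intracellular symbionts. **wolbscan** turns those incidental
reads into an endosymbiont survey: it detects *Wolbachia* infection in host
insects from counts of endosymbiont-mapped reads, calls haploid *Wolbachia*
haplotypes from per-site allele depths, groups haplotypes into strains with
95% statistical-parsimony networks, and tabulates infection prevalence and
strain distributions across sampling localities and host lineages. It is
written for population geneticists who have genotyping-by-sequencing (GBS)
or similar resequencing data for hundreds-to-thousands of host individuals
and want symbiont prevalence and strain structure without dedicated assays.

A seeded synthetic-data generator reproduces the statistical structure of
such surveys (read-count mixtures, strain clouds, imperfect PCR labels),
so every stage is testable with no sequencing data. The package also ships
a transcription of a 107-locality *Lycaeides* butterfly survey table used
by the summary routines.

## The method

**Detection.** For host individual $i$, let $n_i$ be the number of
endosymbiont-mapped reads with MAPQ $> 20$, length $\ge \ell$ bp and no
secondary/supplementary/QC-fail flag (samtools mask 2432). The individual
is called infected iff $n_i \ge t$; the defaults $t = 5$, $\ell = 80$ are
calibrated by sweeping a threshold grid against gold-standard (PCR) labels
and scoring accuracy, FNR and FPR.

**Haplotype calling.** *Wolbachia* is effectively clonal within a single
infection, so a haploid model applies: at each biallelic site the called
allele is the argmax of quality-passing allele depths (missing when
uncovered, conservative on ties). Sites with more than 25% missingness
among infected hosts are dropped, then individuals with any missing call.

**Strains.** Distinct haplotypes are joined when their Hamming distance is
at most the statistical-parsimony connection limit — the largest number of
observed differences $j$ over $m$ sites for which
$P(\text{no superimposed change} \mid j, m) \ge 0.95$, evaluated under a
geometric (coalescent) prior on the true mutation count and a uniform-rate
finite-sites substitution model. Connected components of that graph are
strains; at $m = 115$ sites the 95% limit is 5 steps. Strain divergence is
summarised as uncorrected p-distance and visualised by classical PCoA
(Gower double-centering and eigendecomposition of the squared-distance
matrix, negative eigenvalues reported).

## Worked example

Run the whole chain on a synthetic survey (8 localities, 15 hosts each):

```bash
wolbscan all --outdir demo --seed 17
```

The manifest reports per-stage counts; with seed 17 the run prints stages
equivalent to:

```
simulate:   120 individuals, 38,382 reads
summarize:  120 individuals
detect:     106/120 infected at >=5 reads of >=80 bp
haplotypes: 44 complete individuals x 115 sites
network:    18 haplotypes, 3 components at connection limit 5
```

The three network components recover the three planted strains exactly.
`demo/divergence_mean.csv` gives mean percent divergence within strain A
of 3.5% versus 31.7% and 31.3% between strains — deeply divergent strains
each carrying a star-like cloud of closely related haplotypes.
`demo/threshold_sweep.csv` scores each read threshold against the
simulated PCR subset; with imperfect PCR labels on only ~120 hosts the
accuracy differences between small thresholds are within assay noise,
which is exactly why the calibration reports the full sweep rather than a
single number.

Survey-table summaries run without any sequencing input:

```bash
wolbscan summarize-table
```

prints, for the packaged 107-locality table: 105 localities with at least
one infected host, 85 above 90% infection, 64 at 100%, a mean per-locality
infection rate of 91.2%, and 2,117 of 2,377 individuals infected.

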