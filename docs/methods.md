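# Methods

This note documents the models and procedures implemented in wolbscan,
the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Infection detection from mapped-read counts

A host individual is classified infected when it carries at least
`min_reads` endosymbiont-mapped reads that pass three filters: mapping
quality strictly greater than `mapq_min` (default 20, i.e. <1% chance of
misplacement), read length at least `len_min` (default 80 bp, close to the
87 bp maximum of typical single-end GBS reads, so the filter is
stringent), and SAM flag clear of the exclusion mask (default 2432:
secondary + QC-fail + supplementary, the standard samtools idiom).
The MAPQ comparison is strict and the length comparison inclusive; both
are flags, not hard-coded semantics.

Calibration sweeps `(min_reads, min_len)` grids against gold-standard
labels. Rates are exact rationals internally (rendered to three decimals):
accuracy = concordant/compared, FNR = P(called uninfected | gold
infected), FPR = P(called infected | gold uninfected); a rate with an
empty denominator is reported missing, never zero. Gold-labelled
individuals absent from the alignment output are treated as having zero
mapped reads — that is what absence means bioinformatically — and their
number is reported. Accuracy ties are broken toward the smallest read
threshold, the conservative choice when larger thresholds buy nothing.

The default sweep grid is log-style, `1, 5, 10, 20, 50, 100, 200, 500,
1000`. Read counts of infected hosts are heavy-tailed (negative binomial
with dispersion near 1), so neighbouring small thresholds differ by about
one misclassification per two thousand hosts; a decade-style grid reflects
the resolution at which the sweep is actually informative, and any denser
grid can be supplied explicitly.

## Haploid haplotype calling

Endosymbiont infections are treated as clonal: one haplotype per host.
At each biallelic site the called allele is the argmax of quality-passing
reference/alternate depths; zero total depth is missing. Equal non-zero
depths are missing under the default tie rule — a deliberately
conservative stance mirroring what a likelihood caller would flag as
uncertain — with `tie='ref'`/`'alt'` available. Multiple infections would
need a polyploid model and phasing and are out of scope; hosts carrying
two strains are genotyped as whichever strain dominates their depths.

Filtering order is fixed and idempotent: sites first (missing fraction
≤ `max_missing`, default 0.25), then complete-case individuals. The
missingness denominator is the *infected* subset when provided: uninfected
hosts have no endosymbiont reads at all, and counting their all-missing
rows would discard every site. This interpretation is a documented choice;
the denominator is an explicit argument.

Formats: haploid VCF 4.2 (GT `0`/`1`/`.`; diploid or multi-allelic input
is rejected with the offending record named), NEXUS DATA blocks with
symbols `01` for downstream coalescent tools, and a FASTA rendering with
0→A, 1→C (encoding recorded in every record description) for tools that
insist on nucleotide alphabets.

## Statistical-parsimony networks and strains

Distinct haplotypes are nodes weighted by multiplicity. Every pair within
the connection limit is a candidate edge; connected components of the
candidate graph define strains, and within each component a minimum
spanning tree is retained for rendering, with ties broken by larger joint
multiplicity then lexical labels so output is reproducible. Multi-step
edges carry `steps − 1` inferred (unsampled) intermediate haplotypes;
these are cosmetic and never affect components or statistics.

The connection limit is the largest difference count `j` whose estimated
probability of a parsimonious connection reaches the confidence level
(default 0.95). The probability model: the true number of mutations `q`
separating two sequences of length `m` has a geometric prior with mean
equal to the observed `j` (the coalescent pairwise-mutation-count
distribution, with the observed divergence as the plug-in estimate);
mutations fall uniformly over sites and follow a symmetric 4-state
substitution scheme. A connection is counted parsimonious when no site
reverted to its ancestral state. The reasoning: a repeated hit that leaves
a site divergent underestimates the step count but leaves the connection
topology intact, whereas a reversion hides real changes and is what makes
too-distant haplotypes look spuriously close — the failure mode the limit
exists to control. The posterior P(no reversion | j observed differences)
is evaluated exactly with generating functions (per-site exponential
generating functions for "mutated and divergent" vs "mutated but
reverted", a binomial factor for which sites differ, and the prior summed
to convergence). Under this estimator the 95% limit is 5 steps at 115
sites and grows roughly with the square root of length (13 steps at 658
sites). The limit is exposed as a manual override, and the stricter
reading in which *any* repeated hit breaks parsimony (limit 3 at 115
sites) can be recovered by raising the confidence.

Strains are labelled A, B, C, … by decreasing individual count; components
below `min_major` individuals (default 11) are flagged rare. The default
makes a component a "major" strain only when it is more than a handful of
singletons, while leaving genuinely rare strains visible.

## Ordination and divergence

PCoA is classical metric scaling: double-centering of −½D², symmetric
eigendecomposition, coordinates scaled by √eigenvalue. Hamming matrices
need not be Euclidean-embeddable, so negative eigenvalues occur; they are
reported in full (a warning is emitted), excluded from variance
proportions, and their axes carry zero coordinates. Numerically-zero
eigenvalues are clipped at a relative 1e-12 tolerance.

Divergence tables report mean and SD of uncorrected p-distance × 100
within and between strains. Pairs are weighted per distinct haplotype by
default (a strain's divergence should not be dominated by its most common
haplotype); per-individual weighting, in which same-haplotype pairs
contribute zero distances, is a flag. A strain with a single haplotype has
no within-strain pair and reports missing, and a single pair has no SD
(ddof = 1).

## Synthetic-data generator

The generator emulates the statistical structure of an endosymbiont
survey built on host GBS data:

- **Scale.** 107 localities of 8–36 hosts (roughly 2,400 individuals),
  planted prevalence 0.9 per locality — the magnitudes of a
  continental-scale survey.
- **Read counts.** Infected hosts draw quality-passing read counts from a
  negative binomial with mean 3,500 and dispersion 1.0 (the observed
  median mapped-read count, with the heavy tail library-prep stochasticity
  produces); uninfected hosts draw from Poisson(0.2), a background
  contamination model chosen because the data offer no direct estimate —
  it is a config field, not an assumption baked in. Failing and
  flag-masked reads are added so marginal length/MAPQ distributions match
  the configured ones: 92% of read lengths above 80 bp (max 87), 90% of
  MAPQs above 20.
- **Strains.** Founders flip disjoint site blocks of a shared random
  background, giving every founder pair an identical Hamming separation of
  about `strain_divergence × n_sites` (default 0.30 × 115 ≈ 36 steps;
  the observed between-strain range is 11–38%). Within a strain,
  haplotypes arise by preferential attachment: each infected host either
  reuses an existing haplotype (probability proportional to its count) or
  mutates a fresh variant off the founder with a Poisson(1.5) number of
  site flips, right-truncated at ⌈3 × mean⌉. The truncation enforces the
  separability radius the configuration validation assumes (configs where
  3 × mean reaches the founder separation are rejected as inseparable).
  The result is the right-skewed spectrum real strains show: one to a few
  dominant haplotypes and a tail of rare ones.
- **Lineage structure.** Localities are partitioned into contiguous
  lineage blocks, each dominated by one strain, emulating strain dominance
  by host lineage.
- **Depths.** Per-site depths for infected hosts are Poisson with mean 5.5
  scaled by the host's relative read count (more reads, more depth), so
  complete-case retention after filtering lands near the ~60% a real
  survey achieves. Depth can be decoupled from read counts
  (`depth_scaled_by_reads=False`) and given any supported distribution,
  e.g. a uniform ≥3 floor for calling-fidelity checks.
- **PCR labels.** An imperfect assay with configurable sensitivity (0.96)
  and specificity (0.98) on a subset (default 128 hosts).

One integer seed drives everything; named substreams (truth, reads,
depths, labels) are derived deterministically from it, so identical
configurations are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: base-level sequencing error (allele
depths always support the true allele; calling fidelity on real data also
depends on the upstream caller), wet-lab GBS artefacts (restriction-site
dropout, barcode effects), multiple infections within a host, uneven
strain divergences (planted founders are equidistant), spatial
autocorrelation beyond the lineage blocks, and nuclear insertions of
endosymbiont fragments.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration check on
cohorts of 2,000 hosts over 20 (tests) or 10 (script) seeds, strain
recovery on ~120-host surveys at the minimal 14-step founder separation
over 20 seeds, and calling fidelity on 40-host surveys over 20 seeds —
sizes chosen so each check exercises the study conditions while the whole
suite stays inside a few minutes. Parsimony probabilities truncate the
prior sum at `j + 60` terms (geometric tail < 1e-6 of the total);
the estimator's series arithmetic is exact double-precision convolution.
Checksummed pipeline manifests make reruns verifiable bit-for-bit.

## Known limitations

- The infection caller is a hard threshold, not a mixture model; hosts
  with genuinely low titres are indistinguishable from contamination.
- The haploid model hides one strain of any doubly-infected host.
- The connection-limit estimator is one defensible reading of
  statistical parsimony; published implementations do not document their
  recursion precisely enough to guarantee step-for-step agreement, which
  is why the limit is also a manual flag.
- Survey tables are summarised verbatim; internal inconsistencies in a
  source table (e.g. haplotype tallies exceeding infected counts) are
  surfaced as warnings and reported, never corrected.
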