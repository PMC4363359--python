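# Methods

This note documents the models behind `tillseq`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic screens do
and do not establish about real data.

## Pooling model and deconvolution

A population arrayed in `n_plates` plates of `n_rows × n_cols` wells is
pooled three ways: dimension A (one pool per plate), B (one pool per column,
across plates), C (one pool per row, across plates).  Each individual
belongs to exactly one pool per dimension, so pool sizes are
`n_rows·n_cols` (A), `n_rows·n_plates` (B) and `n_cols·n_plates` (C); the
canonical 8×8×12 screen has 28 pools of 96/64/96 members.  A scheme may
carry an explicit set of occupied wells, in which case pools are computed
over occupied wells only.

Deconvolution inverts a set of flagged pools: pools flagged within a
dimension are unioned first (two independent carriers in one run can light
up two pools of the same dimension), then member sets are intersected
across the represented dimensions.  Three dimensions intersecting in one
well resolve an `INDIVIDUAL`; two dimensions (or an ambiguous triple)
resolve a `SUBSET` to re-test individually; fewer yield `NONE`.  Candidates
with more than one compatible well are marked ambiguous rather than
guessed — the screen's wet-lab follow-up (Sanger of the subset) is the
disambiguation step, and it is out of scope here.

## Dilution arithmetic

`copies_per_allele = (mass_pg / genome_2C_pg) / pool_size`, reported to one
decimal.  The 2C mass is treated as the diploid genome mass, so `mass/2C`
counts diploid genome copies and no extra allele factor is applied; this
convention reproduces the reference values 204.5 (1:64) and 136.3 (1:96)
for 10 ng at 2C = 0.764 pg.  Expected carrier frequency in an equimolar
pool of N individuals is `dose/(2N)` with dose 1 (HET) or 2 (HOM).  The
picomolar-to-molecules conversion is Avogadro-exact
(`c·1e-12·N_A/1e6` per µL); note that 26 pM gives 1.566×10⁷ molecules/µL,
slightly above the 15.5×10⁶ figure quoted in sequencing protocol sheets,
whose rounding basis is not stated — the physically derived value is
returned.

## Error model

Substitution errors are parameterized per substitution type.  The mean
rate defaults to 0.1% per base — the platform's background substitution
level — with type multipliers 2.5 for G>A and T>C (the transitions this
chemistry inflates) and 0.7 for the remaining ten types, so the 12-type
mean equals the configured mean.  Each simulated run draws every type's
realized rate from a normal with SD equal to `d × mean`, `d` uniform in
0.26–0.56, truncated at zero and capped at 5%: this reproduces the
reported run-to-run dispersion of substitution noise and is the reason a
run can be globally "hot" in one substitution type (visible in demo runs
as a burst of same-type false flags).

Indel artifacts are concentrated in homopolymers: inside runs ≥ 3 bases,
insertion and deletion observations are generated at 5× the mean
substitution rate (the dominant artifact of the platform; no quantitative
rate is published, so the multiplier is configurable), with a small
background of 2×10⁻⁴ elsewhere.

## Coverage model

Per-pool read depth is lognormal with configurable mean and CV (default
0.5), reflecting the strong pool-to-pool variability of pooled amplicon
runs; coverage decays linearly to 50% over the final 10% of each amplicon
(the 3' fall-off of sequencing-by-synthesis reads).  In FASTQ mode a
configurable fraction (default 20%) of reads are ~50 bp primer-dimer
artifacts carrying no target insert and no pool barcode (failed second-step
priming), matching the short-read population that must be filtered before
mapping.  The default mean of 3000× per pool corresponds to a 314-chip-class
run; scale-up (316-chip-class) screens run an order of magnitude deeper.

## Mutation planting

In density mode each (individual × amplicon) receives a Poisson number of
mutations with mean `density × length`, density defaulting to 1/300 kb (the
classic EMS genome-wide estimate).  With probability 0.99 a mutation is an
EMS-type G/C→A/T transition at a G/C site; otherwise a random non-EMS
substitution.  Zygosity is homozygous with probability 1/3 — the 1:2
HOM:HET split expected among M2 carriers after selfing of the mutagenized
M1 (a genetics-based default, configurable).  Explicit mutation lists and a
one-HET-singleton-per-amplicon helper support controlled experiments.

## Count simulation: SAMPLED vs EXPECTED

A carrier contributes `dose/(2 × pool members)` to its three pools' true
alternate fraction; the observed alternate count is
`Binomial(coverage, fraction + error)` in SAMPLED mode.  EXPECTED mode
replaces every draw by its rounded expectation (numpy half-even rounding)
and uses the mean rates without jitter, making it deterministic and equal
to the closed-form fractions — it is the oracle the sampled path and the
read-level pipeline are tested against.  Counts at each position sum
exactly to coverage (base + indel observations); on the rare occasion that
independent alternate draws overshoot, the excess is shaved off the
largest alternate counts to preserve conservation.

## Read processing

Reads are laid out `barcode + universal tag + forward primer + target +
rc(reverse primer) + trP1`.  Demultiplexing matches the barcode prefix
exactly by default (no mismatch tolerance is published for the original
barcodes; exactness maximizes pool specificity at a small read loss) and
strips it; ambiguous matches are unassigned.  Trimming locates the
universal tag and one forward primer (≤ 1 mismatch each), removes any
complete or 3'-truncated adapter suffix, and rejects inserts under 30 bp —
which is what removes primer-dimer reads.

Alignment is cost-minimizing with the screen's mapping costs — mismatch 2,
insertion 3, deletion 3, linear gaps — expressed as score maximization
(match +1, mismatch −2, gap −3) with free end gaps on both sequences, via
`Bio.Align.PairwiseAligner`.  The unit match reward is required because a
0/−2/−3 scheme is degenerate under free end gaps; it preserves the 2:3
mismatch:gap ratio of the stated costs.  The best-scoring reference wins,
exact ties are broken by a seeded uniform choice, and an alignment is
accepted only if ≥ 80% of the read aligns with ≥ 80% identity over aligned
columns; reverse-complement alignment is a fallback when the forward
orientation fails.  Pileup counts an aligned base only if its quality is
≥ 20, the mean quality in a ±5 window is ≥ 15, and the read has ≤ 5
combined gaps+mismatches in that window; indel observations are tallied at
the left-flanking reference position.  Reads overlapping only part of an
amplicon contribute at the positions they cover.

## Variant calling

The frequency table keeps, for positions with base coverage ≥ 100, every
substitution (and indel observation) at frequency ≥ 0.1%, at most 4
alleles per position; the denominator is base coverage, excluding indels.
Indel variants inside or adjacent to homopolymer runs ≥ 3 are removed;
substitutions never are.

Outlier detection works per (amplicon, position, substitution): the mean μ
and population SD σ (ddof 0) of the frequency are computed across **all**
pools of the scheme, pools absent from the table counting as zero, and a
pool is flagged when it clears the candidate gates (coverage ≥ 500,
frequency ≥ 0.5%) and its z-score lies within [2, 10].  Frequencies are
only ever compared within one substitution type — each type has its own
background.  Design points worth stating explicitly:

* μ and σ include the tested pool (no leave-one-out) by default; a `loo`
  switch is provided.  With include-self σ over n pools, z is bounded by
  `(n−1)/√n` ≈ 5.1 for n = 28, so the upper cutoff of 10 (which discards
  systematic artifacts such as mismapping) effectively bites in `loo` mode
  and via the σ = 0 sentinel (all pools identical and above the gate →
  flagged with z = +∞).
* The 0.5% frequency gate is applied per pool *before* z-scoring; whether
  the original screens gated before or after is not published, and the
  per-pool-first order is the stricter reading.
* Replicate runs are merged by unioning flags per substitution before
  deconvolution, so complementary intersecting pools found in different
  technical replicates still combine into a three-dimensional intersection.
* Confidence tiers 99/85/75 map the deconvolution resolution
  (individual / subset / single pool).  They are ordinal labels, not
  calibrated probabilities — the exact confidence computation of the
  original analysis script is not published.

## Detection limits

A heterozygous singleton in a 96-pool sits at `1/192 ≈ 0.52%`, essentially
on top of the 0.5% candidate gate, and its three carrier pools themselves
inflate the include-self σ, capping the carrier z-score near 2.5 — just
above the lower cutoff of 2.  Reliable single-well resolution therefore
needs per-pool depth high enough that binomial noise on a ~0.5% frequency
is small compared to that margin: at 314-chip-class depth (~3000× per
pool) the binomial SD of the observed frequency (~0.13 percentage points)
repeatedly drops carrier pools below one gate or the other, while at
scale-up depth (≥ ~13,000×, as in the deep-chip screens where
individual-level detection was actually practiced) the z-band signal
separates cleanly.  The end-to-end recovery and null false-call tests
accordingly simulate screens at a scale-up mean of 20,000× per pool with
two replicate runs: there the pipeline traces ≥ 95% of heterozygous
singletons to their exact well at tier 99 across 50 seeded screens, with
fewer than 0.1 spurious tier-99 calls per amplicon on mutation-free
screens.  At shallower depth the correct individual typically still
appears, but as a tier-85 subset or with additional ambiguous wells.

## Problem sizes and runtime choices

The test suite exercises full 768-individual schemes for design checks;
simulation-heavy properties use one 200 bp amplicon, 50 seeded screens and
two replicates (count mode, fully vectorized), and the read-level pipeline
is validated on small populations (4–12 individuals, ~100 bp amplicons,
dozens to hundreds of reads) where the pileup can be compared base-by-base
against the closed-form oracle.  The acceptance script's spike-in uses 100
seeded runs of a 60 bp amplicon at 4000× — the pilot-scale configuration.

## What the simulator does not emulate

Flowgram-level signal, polyclonal sphere artifacts, GC- or
length-dependent amplification bias between amplicons, mutations in primer
sites, and the original barcode sequences (regenerated here as random
Hamming-distance-3 sets) are all outside the model.  Passing tests
demonstrate that the pipeline's logic is correct under the stated error
structure; they do not certify performance on a real run whose biases
exceed that structure — in particular, amplicon-to-amplicon coverage
imbalance on real chips can push individual pools below the 500× gate even
when the chip-level average is high.

## Numerical conventions

Coordinates are 1-based inclusive on the amplicon target (the region
between, and excluding, the primers).  EXPECTED-mode rounding is numpy's
half-even `rint`.  σ values below 10⁻¹² are treated as exactly zero.  All
randomness flows from explicit integer seeds; the pipeline spawns
per-stage child seeds from the single top-level seed, so a config + seed
pair reproduces every output byte-for-byte (paths and timestamps aside).
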