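# Methods

This note documents the models, estimators, and numerical choices behind
`catmap`, in the spirit of a statistical-software methods appendix: what is
assumed, what the tunable parameters mean, what the simulators do and do
not emulate, and where the design was genuinely open.

## Synthetic data

### Genomes

`simulate_genome` draws lognormal scaffold sizes (shape 0.7) normalised to
the requested total and tiles each scaffold with an alternating renewal
process whose block types (intergenic / genic / repeat) are chosen with
probabilities equal to the requested base fractions and whose block lengths
are exponential (mean 300 bp).  Realised fractions therefore converge to
the request on megabase-scale genomes (±2% at 1 Mb).  Repeat intervals are
filled with low-complexity sequence (homopolymer or dinucleotide motifs) so
the flank-complexity and flank-uniqueness filters downstream act on real
signal.  The model does not emulate GC isochores, gene structure
(exon/intron), or realistic repeat families.

### Variant pools

`simulate_variant_pool` places SNPs as a Poisson process (default
1 per kb), and draws per-population alternate-allele frequencies
hierarchically: each SNP receives a latent category — channel-specific,
blue-specific, fixed interspecific difference, or shared — with weights
proportional to the published array composition, and channel strains are
correlated through a species-level Beta draw (concentration 8).  A
configurable share of channel-specific SNPs is private to one strain or to
the wild population.  Pools only emit SNPs whose pooled minor allele
frequency is ≥ 0.05, mirroring the variant-calling thresholds applied
upstream of array design.  Configurable fractions of tri-allelic SNPs and
of SNP pairs closer than 35 bp guarantee that every hard filter has work
to do.  Linkage disequilibrium between candidate SNPs is not modelled.

### Probe-quality scores

Each SNP gets independent forward and reverse conversion-quality scores
from Beta(92.4, 42.0).  These defaults were solved so that the *retained*
probe (the better of the two) has mean 0.71 with 97% above 0.65 — the two
summaries the retained array is expected to reproduce.  The score is an
opaque stand-in for a proprietary conversion model; no sequence features
feed into it.

### Families

`simulate_families` draws founder haplotypes i.i.d. per marker (allele
frequency 0.5, no founder LD), then simulates meioses as an
interference-free Markov chain along each chromosome: between adjacent
markers a gamete switches haplotype with probability equal to the inverse
Kosambi transform of the sex-specific cM gap.  Marker positions are given
on the base (male) map; the female map is the base map scaled by
`female_scale` (default 1.4, the typical genome-wide female:male map ratio
in channel catfish), optionally overridden per chromosome to mimic the
observed 0.96–2.06 spread.  Because distances are later re-estimated with
the Kosambi function, this construction makes parameter recovery exact in
expectation.  Genotyping error replaces a call with one of the other two
genotypes uniformly at rate `genotyping_error_rate`; missingness is
uniform at `missing_rate`; parents are recorded without error (their
genotypes anchor cross-type determination).  The full ground truth —
founder haplotypes, every crossover, true positions — is returned for
oracle tests.  Offspring counts default to 120/119/120/119 with the first
two families sharing a sire (478 offspring total; the published study
reports only the total, so the split is a choice, configurable).

Passing tests on these simulations demonstrates correct estimation under
the stated error model; real array data add features the generator omits
(intensity-driven miscalls that are marker-specific rather than uniform,
founder LD, segregation distortion from real biology, null alleles).

## Array design

The filter cascade computes all applicable reason codes per SNP without
short-circuiting, so hard-filter application is order-independent by
construction.  Hard codes: multi-locus flank (exact 71-mer occurrence
count on both strands, not alignment — reproducible at desk scale),
adjacent SNP within 35 bp, low-complexity run (homopolymer or dinucleotide
run ≥ 8 bp; the published criterion names only "simple sequence repeats",
so the threshold is exposed), non-bi-allelic, flank GC outside 30–70%.
Soft codes (A/T–C/G allele pair, pooled MAF ≤ 0.1) demote a SNP to tier 2
of the spacing selection rather than excluding it: tier-2 SNPs are
admitted only inside holes where the tier-1 selection left more than twice
the stage gap.  This renders the published "preferentially selected" /
"unless absolutely needed" language deterministic.  Greedy spacing scans
left to right by position (ties: higher MAF, then id) with gaps enforced
within each stage (genic 200 bp, intergenic 350 bp, then
species/strain-diagnostic additions); SNPs from unmapped sources are
exempt.  Dual-probe tiling targets SNPs whose full flank is unique but
whose 35 bp arm recurs ("less unique" flanks — the published rule is not
quantified, so this is our operationalisation); such SNPs keep both probes
even when neither passes the conversion threshold (default τ = 0.6, a
config knob calibrated so retained probes average ≈ 0.71).

## Genotype QC

Sample QC applies strict inequalities (DQC > 0.85, call rate > 0.95 for
evaluation; 0.82/0.97 for mapping — both exposed, no attempt to reconcile
the two published pairs).  DQC has no computable definition without raw
intensities and is treated as an opaque per-sample scalar supplied by the
simulator.  Conversion classes derive from call composition: all three
genotypes → PolyHighResolution; heterozygote plus one homozygote →
NoMinorHom; a single cluster → MonoHighResolution; call rate below
threshold → CallRateBelowThreshold.  Two homozygote clusters without
heterozygotes are classified PolyHighResolution (both alleles detected).
OTV and Other require intensity-space clusters and are assigned only via
explicit simulation flags.

## Pedigree checking

IBS distance is `1 − (mean shared alleles)/2` over pairwise-complete
markers with a minimum-overlap guard (default 50).  Clustering is
complete-linkage agglomeration (scipy); the projection is classical
(Torgerson) scaling — double-centred squared distances, top eigenvectors.
The outlier statistic is the standard score of each sample's
nearest-neighbour distance (the most outlier-sensitive neighbour
statistic); the published analysis does not define its Z construction, so
ours is documented rather than asserted, with default cut Z > 4.

## Linkage mapping

### Two-point engine

Informative meioses are transmissions from heterozygous parents.  With no
grandparents, parental phase is a per-family nuisance maximised over (at
most four configurations; equivalently, each parent's fraction ranges over
[0, 1] and folds onto [0, 0.5]).  `estimate_two_point` maximises the exact
two-locus cell likelihood (sixteen parental gamete combinations) over
(r_female, r_male) jointly across families, via a coarse grid plus local
refinement — the phase maximisation makes the surface multimodal, so a
pure local search is unreliable.  The scalable all-pairs engine counts
discordant deducible transmissions with phase resolved per family-parent
(minority class = recombinant).  Two deducibility levels are kept: the
*strict* level (co-parent homozygous) yields unbiased counts; the *full*
level adds homozygous offspring of double-heterozygous crosses, which
conditions on the co-parent's gamete and shrinks the apparent fraction for
linked pairs while remaining exact under the null — ideal for LOD
screening, where sensitivity matters and the null calibration is what the
threshold means.

### Genotyping-error model

A uniform misclassification channel (a call becomes one of the other two
genotypes with probability e) is folded into the two-locus cell
probabilities.  The rate e is estimated from Mendelian-impossible calls:
in het × hom crosses the co-parent's opposite homozygote occurs with
probability e/2 per call, in hom × hom crosses any unexpected class with
probability e.  Pooled over all markers and families this gives a precise
global estimate (relative error well under 25% at e = 0.005–0.02 in
validation).  Without the channel, each error mimics a double crossover
and every interval inflates by roughly e — at 200 markers per chromosome
that triples the map length.

### Ordering

Marker order is obtained by spectral seriation: the Fiedler vector of the
graph Laplacian of a Gaussian similarity kernel over the pairwise
two-point distance matrix (kernel scale = the 10th percentile of
off-diagonal distances).  This was a deliberate departure from the more
familiar greedy-extension + 2-opt optimisers: at realistic densities the
sum-of-adjacent-distances objective is noise-dominated, and full 2-opt
*reduces* order quality even on error-free data (measured: Kendall τ 0.97
from seriation falls to 0.63–0.92 after 2-opt) because orders chaining
noise-deflated pairwise estimates beat the true order on that objective.
Spectral seriation instead uses all pairwise distances simultaneously.
Groups of ≤ 8 markers are ordered by exhaustive search, where the
objective is exact.  A second round contracts co-located stacks and
re-runs the seriation, mirroring the two-round practice for dense maps.

### Placement and distances

Final positions come from a banded multipoint placement: sex-specific ML
fractions are fitted for every pair within a sliding window of 8 order
positions, Kosambi-transformed, and the markers are placed on the line by
weighted least squares (the sign pattern fixed by the current order turns
the absolute-value objective into a graph-Laplacian linear system, solved
exactly; a few outer iterations update the signs).  The placement may
locally refine the order; two fit-embed rounds are run.  A gross-
misplacement repair then splits the order at junctions whose adjacent
fitted distance exceeds max(12 cM, 5 × median), and re-assembles the
segments (with orientation) by exhaustive search over endpoint ML
distances, accepting only decisive improvements (> 10 cM) — this catches
the rare seriation "fold" of a chromosome end into the interior.

Plain accumulation of adjacent-interval estimates is deliberately not the
default (it remains available as `method="adjacent"`): adjacent fractions
sit at the resolution limit of the cross, and summing hundreds of noisy,
zero-truncated intervals along a jittered order inflates the total — the
classic map-expansion problem the published study also fought by filtering
stacked markers.

Total map lengths are measured by crossover-event counting: each meiosis's
deducible transmission sequence is phased along the group (aligning each
marker with a persistent per-offspring reference so that recombinants are
the minority class), single-marker haplotype blips and discordant end
markers are attributed to genotyping error, and the remaining haplotype
switches are counted.  Lengths are 100 × crossovers per effective meiosis
(coverage-weighted), which approaches the Poisson sampling bound of the
realised crossover process.  The embedded coordinates are
isotonic-projected onto the shared order (pool-adjacent-violators, so
positions are monotone) and rescaled to the counted totals.  Sex-average
fractions are the meiosis-count-weighted mean of the sex fractions.

### Sex-dimorphism test

The per-group female–male contrast is a likelihood-ratio G-test
(G = 2 Σ O ln(O/E), df 1) on a 2×2 table of recombinant vs non-recombinant
meiosis-interval trials by sex.  The recombinant cells are the crossover
counts implied by the fitted lengths and meiosis counts: raw
deducible-transmission counts carry sex-symmetric error flips that dominate
the table and mask the contrast at realistic error rates.  Because the
inferred counts carry estimation noise beyond Poisson, the test is a
screen, mildly anticonservative under exact equality; at a true
genome-wide scale of 1.4 with ≈ 950 meioses it rejects at p < 0.01 with
large margin.  The published construction of this test is not described;
ours is documented, not asserted as theirs.

### Defaults

LOD limit 35 with minimum group size 10 (group formation); joining LOD 10
with margin 3; per-family missing ≤ 12 and minor-allele *count* ≥ 6 (the
published "MAF less than 6 (about 5%)" reads as a count in ~120-offspring
families); ≥ 2 informative families; distortion χ² at p < 0.005 (summed
over informative families, df summed); duplicate missing tolerance 5%;
pair-graph sparsification floor LOD 3 (far below the 35 threshold, so it
cannot affect group membership).

## Genome integration

Scaffold placement is by majority marker vote; orientation by the Spearman
correlation between bp and cM over unique genetic positions (|ρ| ≥ 0.5,
else unknown; at least 3 unique positions).  Stacked markers are
uninformative for within-scaffold order, so monotonicity analysis uses
unique positions only.  Misassembly calls: runs of ≥ 3 unique-position
markers stepping against the dominant orientation → inverted segment
(interval = first to last marker of the run); markers voting for another
group, or runs displaced > 10 cM from a Theil–Sen physical–genetic trend →
translocated segment; a clean scaffold whose orientation contradicts a
supplied prior → whole reversal.  The 10 cM displacement default sits far
above the ~0.1 cM local noise of a dense map.  The detector is validated
by plant-and-recover only — no quantitative calling rule is published for
the motivating cases — achieving recall 1.0 at false-call rate 0.0 on the
packaged replicate generator (100 replicates, 3 planted events each).

## Problem sizes

The packaged study conditions — 3 chromosomes of 80–120 cM with 200
markers each, four families of ~120 offspring, 1% genotyping error, 2%
missingness, female scale 1.4 — are a deliberate desk-scale stand-in for
the published 253,087-marker map, which is not reproducible without the
original genotype data.  At these conditions the pipeline recovers 3
groups at membership purity 1.0, per-group order concordance τ ≥ 0.97,
sex-average lengths within ±10% of truth, and a genome-wide female:male
ratio within [1.30, 1.50] across tested seeds.

## Known limitations

- Two-point only: no multipoint HMM likelihood; ordering resolution near
  stacked markers is bounded by pairwise information.
- The error channel is uniform per call; intensity-driven, marker-specific
  error structure is not modelled (and OTV detection is out of scope).
- Sex-specific lengths rely on crossover counting with blip removal, which
  slightly undercounts tight double crossovers and end-interval events
  (net bias ≈ −5% at the packaged study scale).
- Founders are drawn without LD and at allele frequency 0.5; informative-
  meiosis patterns in real pedigrees will be less favourable.
- Flank uniqueness is exact k-mer matching; a near-match (≤ 2 mismatches)
  mode would be needed to emulate hybridisation-level cross-reactivity.
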