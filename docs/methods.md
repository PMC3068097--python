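# Methods

`paleospruce` couples two lines of evidence about the Holocene history of
a Norway spruce (*Picea abies*) population at a South Carpathian mountain
lake: chloroplast haplotypes typed from ancient pollen and macrofossils
compared against the extant stand, and a pollen-accumulation-rate (PAR)
record from the same sediment core used as a population-size proxy. This
note documents the models, conventions and numerical choices, and what the
synthetic-data generators do and do not emulate.

## Sequence data model

Eight short cpDNA amplicons (CK, MD, B, D, TL, Li, LF, K2i; 124–251 bp)
are the typing panel; cpDNA is paternally inherited and non-recombining in
spruce, so each individual carries one haplotype per fragment and the
concatenation over fragments is itself a haplotype. Coordinates are
1-based and inclusive in two frames: fragment-local, and a fixed
concatenated frame laid out in panel order. Fragment B contains a
mononucleotide microsatellite reported in run-length notation
(`12A + 5G`); because its alleles vary in length (16–20 bp), the
concatenated frame reserves the maximal 20-column width for the block, and
the flanks of B contribute 196 invariant bp (derived from the printed
per-sample lengths, which the concatenation reproduces exactly for every
consistent row). One printed concatenated coordinate (TL position 168) is
inconsistent with the cumulative offsets implied by every other TL
coordinate; the package uses the internally consistent frame.

Repeat-block alleles sharing the canonical A-run + G-run structure are
aligned *left-flush within each homopolymer run*: every A-run is padded to
the widest A-run before the G-runs start. A single-repeat contraction then
costs exactly one gapped column. The one rearranged allele
(`12A + 4G + 3A + G`) cannot fit that zoning and is laid out literally.
This convention is a package choice — the original alignment was manual
and unpublished — and it is configurable in spirit: the network module
offers a stepwise-distance mode scoring |run-length difference| instead.
The published mean-pairwise-differences value for the ancient B sample
(2.6667) is not reproducible under this or any simple convention we
implemented (ours gives 15/6 = 2.5); it is therefore not asserted
anywhere, while all four published ancient haplotype-diversity values are
reproduced exactly.

A sample enters a locus's analysis only if it types **all** variable
positions of that locus. This inclusion rule is not stated in the source
table but is the only rule consistent with its per-locus haplotype counts.

### The packaged haplotype fixture

The extant table (9 haplotypes, n = 58) stores the printed relative
frequencies; integer counts reconstructed as round(p·58) sum to 56, and
the two untyped individuals are surfaced in `metadata`, not patched over.
Three more reconstructions are flagged in metadata rather than silently
applied: the cone's Li typing (needed for the three-sequence ancient Li
sample) is inferred from the reported sample size and a cone-vs-seed
transversion at Li 157; pollen sample P13's TL states are stored as
*observed* (A at 168 and 206, the two sites later attributed to damage),
which is what reproduces the published mean pairwise differences k =
72/91 = 0.7912; and the 211-bp printed length of the two replicate seeds
disagrees by 2 bp with their 12A+5G allele. Because no invariant sequence
is published, fragment backbones are seeded synthetic placeholders; every
statistic in the package depends only on the states at variable positions
and on the invariant-site *count*, never on backbone content.

## Damage screening

Post-mortem cytosine deamination produces apparent C→T (and, on the
complementary strand, G→A) transitions in ancient templates. The filter
compares each ancient read, site by site, against a per-locus reference
defined as the majority state of the extant panel (ties broken toward the
modal haplotype). Transitions in ancient reads are flagged as putative
damage and reverted/masked/kept by policy; transversions and gap events
are never altered. The rule is deliberately blunt: it cannot distinguish
an authentic transition polymorphism from a lesion. Rather than hide this,
flagged sites whose observed state segregates in the reference panel are
marked `panel-segregating` and reported as candidate authentic variants.
Default policy is `revert` (matching the haplotype counts of the
published per-locus table); `keep` reproduces the uncorrected statistics.

Taxon assignment of short anchored amplicons (spruce vs pine vs fir
contamination) uses plain Hamming distance after end-trimming, with a
0.10 mismatch-fraction ceiling and a tie→unassigned rule; the fragments
are ≤251 bp and primer-anchored, so alignment-free methods would add
nothing.

## Population-genetic statistics

Gaps are fifth-state characters by default: a gap differs from any base,
two gaps in the same column match, and `N` sites are excluded pairwise.

- Haplotype diversity: Nei's unbiased Hd = n(1 − Σp²)/(n − 1).
- k: mean pairwise differences over all unordered pairs; π = k/L with L
  the compared alignment length.
- Differentiation: Ks = w·K1 + (1−w)·K2 with w = n1/(n1+n2); Kt = mean
  pairwise differences of the pooled sample; Kst = 1 − Ks/Kt (defined 0
  when Kt = 0). Fst = 1 − Hw/Hb with *unweighted* Hw — the two statistics
  differ only in their population-size weighting. Negative estimates are
  reported as computed (a display-only clip to 0 is available).
- Significance: population labels are permuted preserving n1/n2;
  p = (1 + #extreme)/(1 + n_perm) (add-one estimator, never exactly 0).
  "Extreme" is directional toward differentiation — permuted Kst/Fst ≥
  observed but permuted Ks ≤ observed, since *low* within-group diversity
  relative to the pool signals structure. Stars: ns / * (p<0.05) /
  ** (p<0.01).

A subtlety worth recording: for two populations that are literal copies of
one polymorphic sample, Kst is slightly *negative*, not zero — pooled
pairs include cross-copy self-matches, so Kt < Ks at finite n. The
meaningful null property, which the tests verify by Monte Carlo, is that
Kst has zero expectation under label permutation, and that the
permutation test's type-I error is calibrated (rejection rate at α = 0.05
within [0.03, 0.07] under a panmictic null).

## Median-joining networks

Haplotype relationships are summarised by a Bandelt-style median-joining
network: starting from the ε-relaxed minimum spanning network (an edge is
feasible when its weight is within ε of the MST bottleneck distance of
its endpoints), quasi-medians of connected triples — site-wise majority,
ties expanding to all variants, integer run-length coordinates taking the
middle value — are inserted greedily while they shorten the minimum
spanning structure, then obsolete medians are pruned. ε defaults to 0 (the
original analysis did not report one). Tie-breaking is lexicographic
throughout, so output is deterministic for a fixed input set; the classic
desktop implementation may differ cosmetically. With ε = 0 and no
beneficial Steiner point the network provably equals a minimum spanning
tree, which the tests check against a brute-force Steiner enumeration on
≤4-site instances. Sequences are truncated to their common anchored
length before network building when inputs span different amplicon
versions (the fragment-B analysis truncates to 112 bp).

## PAR palaeodemography

The age–depth model is piecewise-linear through calibrated control points
(calibration of radiocarbon dates is upstream of this package);
sedimentation rate is the reciprocal slope of the containing segment, and
extrapolation beyond the dated interval is refused. Concentration uses the
standard exotic-marker estimate count × (spike_added/spike_count)/volume;
PAR = concentration × sedimentation rate (grains·cm⁻²·yr⁻¹). Smoothing is
a centred running mean (default 3 terms, shrinking at the ends).

PAR→stem-density calibration is a pluggable power law trees/ha = a·PAR^b.
The regional transfer function used in the original study is not printed
anywhere; the default is fitted through its two printed anchor pairs
(PAR 200 → 9, PAR 7000 → 101 trees/ha), which also lands the reported
sparse-population average (PAR 120 → 6.4 trees/ha) on the top of its
printed range. The published density figures are mutually inconsistent
under any single power law, so densities always travel with a provenance
note and the third reported pair is not fitted.

Event detection is a two-state ratio scan over the smoothed series, oldest
to youngest. An *expansion* is confirmed when the series rises to ≥
`rise_threshold` (default 2.0×) above its running minimum; it is dated at
the last sample attaining that minimum and ends at the subsequent peak. A
*bottleneck* begins at a local maximum followed by a decline to ≤
`fall_threshold` (default 0.5×) that stays below threshold for ≥
`min_duration` (default 200 yr); flat plateaus are dated at their
departure point, and after each emitted bottleneck the reference maximum
re-arms so stepped declines count separately. Thresholds are ratios, so
detection is invariant under uniform rescaling; the defaults are package
choices (the source identifies events narratively) and all are
configurable.

## Synthetic-data generators

The Wright–Fisher simulator is forward-time and haploid — exact for
uniparental cpDNA — with point mutations at rate μ_snp per site per
generation split transition:transversion by κ (default 2), and a
single-step microsatellite model mutating one homopolymer run by ±1
repeat with probability μ_ms per individual per generation (default
10⁻³, a typical chloroplast microsatellite scale; μ_snp defaults to 10⁻⁶
— over a few hundred generations sequence mutation is nearly negligible,
so observed diversity is standing variation, which is why the default
founder pool is the packaged nine-haplotype table at its published
frequencies). Generation time defaults to 25 yr for mapping calendar ages
to generations. N(t) can be derived from a PAR trajectory via the density
calibration times a forest area (default 2 ha, chosen so the extant
population is ~70 and the early Holocene ancient population ~1/5 of it,
the reported order of magnitude).

The sediment simulator inverts the PAR computation: counts are Poisson
with mean concentration × volume × effort and spike counts Poisson with
mean spike_added × effort, so the estimation path is unbiased up to the
O(1/E[spike]) ratio-estimator term (<0.5% at the default effort; the
round-trip bias test bounds it at 2%).

The bundled scenario encodes the narrative chronology as a deterministic
PAR trajectory (Lateglacial background ~120, interstadial plateau ~155, a
Younger Dryas dip, expansion from ~11,100 cal yr BP to an early Holocene
maximum averaging ~4900, bottleneck onsets at 9180, 7200 and 2200 cal yr
BP, a second expansion from ~3900) sampled at 50-yr resolution, plus
eleven synthetic age–depth control points anchored so the cone horizon
(545 cm) dates to 11,000 and the pollen horizon (533 cm) to 10,700 cal yr
BP. Ancient samples (n = 6 and 10) are drawn at those two ages and an
extant sample (n = 58) at present; ancient reads receive deamination
lesions at δ = 0.02 per C/G site with a truth ledger.

What the generators do *not* emulate: taphonomic loss and PCR failure
(ancient sample sizes are set, not modelled), pollen source-area and
productivity effects on PAR (the density calibration is taken as exact in
simulation), heterogeneous deamination along fragments (δ is uniform),
selection, and migration. Passing tests therefore demonstrate that the
estimators recover truth under their own model assumptions at realistic
sizes and noise levels — not that those assumptions hold for any
particular lake.

## Problem sizes and determinism

Every stochastic component takes an integer seed and is bit-reproducible.
The test suite sizes its Monte-Carlo checks for a desk run: permutation
calibration uses 1000 trials × 99 permutations on 6+6 samples (stat
evaluation from a precomputed distance matrix), drift decay 500 replicates
of N = 30 over 20 generations, PAR round-trip 200 replicates on a 200-yr
grid, and the full scenario simulates ~630 generations at N ≈ 10–160 in
under a second. Expansion onsets on noisy series are asserted within broad
windows because a flat pre-expansion trough dates its minimum diffusely
under noise; bottleneck onsets are asserted within 400 yr (150 yr on
noise-free series, the smoothing shift).

## Known limitations

- The fifth-state treatment double-counts a two-column repeat-length
  change relative to the stepwise model; the two modes answer different
  questions and both are exposed.
- Hd on the extant side uses the 56 reconstructible individuals; per-locus
  extant sample sizes in the source are unknowable (printed Hd values
  imply n varies by locus), so extant diversities differ from the printed
  ones in the third decimal.
- The median-joining implementation targets dozens of haplotypes (it
  refuses >10,000); its median-insertion step recomputes spanning trees
  naively.
- PAR-derived densities are indicative only; the calibration is a
  two-point fit with a provenance warning, not a validated transfer
  function.
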