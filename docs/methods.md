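# Methods

## Study design emulated

The package analyses a panel of ten focal inbred lines plus two distant
outgroup lines, all effectively homozygous (selfed for many generations),
resequenced with short paired-end reads against a reference assembly
built from one of the focal lines.  One haplotype therefore represents
each line, the minor-allele frequency of any biallelic variant takes
values 0.1–0.5 in steps of 0.1, and the outgroups define ancestral
states.  Only deletions relative to the reference are discoverable by the
long-insert signal; insertions relative to the reference appear as
derived *insertion* alleles once polarized.

## Discordant-pair calling

A pair is discordant when both mates map with MAPQ ≥ 29 and the geometry
is abnormal: orientation other than inner-facing (+,−), insert span
(outer distance, |TLEN|) ≥ 1,000 bp, or mates on different sequences.
The orientation-to-class table is the standard paired-end signature set:
long-insert (+,−) → deletion; (+,+)/(−,−) → inversion; outward-facing
(−,+) and inter-chromosomal pairs → transposition.  Pooled pairs are
single-linkage clustered: two pairs link when their left-anchor starts
*and* right-anchor starts each differ by ≤ 225 bp (window chosen from
the smallest library insert); chains are accepted.  Clusters need ≥ 3
supporting pairs.  A deletion's predicted interval is the inner edges of
the two anchor groups — [max left end, min right start) — with no
insert-size correction; on synthetic data this lands within one insert
length of the true breakpoints, and candidates with non-positive size
are rejected.  Insert span is interpreted as the *outer* distance
(275.8 bp mean); the alternative inner-gap reading would only shift the
deletion-size estimate by a constant ~150 bp and no result here depends
on it.

## Filter cascade

Filters run in a fixed order (reference-accession → minimum size →
type-specific depth → discordant density); order affects only which
filter gets blamed in the verdict table, never the retained set, and the
cascade is idempotent.  "Genome-wide depth distribution" is implemented
as the per-accession distribution of mean depths over non-overlapping
1 kb tiles; an interval's depth statistic is the mean over tiles fully
contained in it (partially overlapping boundary tiles would leak
flanking coverage into short intervals).  The discordant-density
background is the count of pooled discordant anchors per non-overlapping
5 kb tile; a candidate fails when either 5 kb endpoint window, after
discounting the candidate's own pairs, exceeds the 90th percentile of
that background.  If any supporting accession fails a test the candidate
is rejected outright.

## SNP calling

Homozygous base calls require 3× ≤ depth ≤ 25× (a per-line maximum of
40× is available for high-coverage lines) and a strict majority: more
than 75 % of reads showing one base, ties at exactly 75 % staying
uncalled.  Population SNPs are sites callable in *all* focal lines and
polymorphic among them; multi-allelic sites are kept, flagged, and their
minor count pools all non-major alleles.  Coding effects recompute the
codon under the longest transcript's frame, strand-aware; CDS lengths
not divisible by three are skipped with a warning.

## Neutral null machinery

Genealogies follow the standard Kingman coalescent (time in 2N_e
generations, rate k(k−1)/2 for k lineages); exactly S mutations are
placed multinomially in proportion to branch length (infinite sites).
Because S is fixed, all envelope outputs are invariant to branch-length
rescaling — the time-unit choice is documentation, not a parameter.

The envelope design is n = 10, S = 100, 10,000 replicates.  Tajima's D
uses all ten chromosomes.  For normalized H, each replicate assigns
k ~ Uniform{1..5} chromosomes as outgroup and polarizes the remaining
m = 10 − k by strict outgroup consensus.  Sites that remain polymorphic
in the ingroup but cannot be oriented (mixed outgroup) are **excluded
from θ_L only**, while π, S and the variance use every
ingroup-segregating site.  This mixed treatment — the natural behaviour
of an implementation that skips unoriented sites when accumulating the
derived-count-weighted estimator — reproduces the reference 95 %
interval (−1.88, +5.70) for H; excluding such sites from the statistic
entirely (available as `drop_unoriented="all"`) yields a markedly
narrower interval of about (−2.2, +1.6).  The D interval is
(−1.72, +1.59) either way.  The selection scan uses the same H estimator
so scan scores and envelope bounds are commensurable.

The mean MAF reported by the envelope (~0.223) is the fixed-S value:
conditioning every genealogy on the same number of sites weights short
trees more than θ-conditioned simulation would, so it sits below the
analytic folded expectation Σ (i/n)·p_i = 0.2282 with
p_i ∝ 1/i + 1/(n−i).  Tests of the mutation placer therefore reweight
replicates by total tree length, which recovers the analytic spectrum.

The allele-frequency sampling-error simulation draws a true frequency
p ~ U(0,1) and an observed count k ~ Binomial(10, p), then censors the
observed frequency into [0.1, 0.9] by clamping — a variant can only be
ascertained if its minor allele is seen at least once, so monomorphic
draws are recorded at the boundary.  The mean |k/10 − p| over 50,000
replicates is ≈ 0.096.  Discard-and-redraw censoring is available as an
option and gives ≈ 0.104.

## Allele age and selection strength

Intra-allelic diversity π_A is the mean pairwise difference among
carriers of a focal allele over a 500 bp haplotype centred on it
(singletons have no pairs and are skipped; only sites callable in all
carriers count, normalized by window length).  Dividing a class's mean
π_A by the grand-mean synonymous π_A — diversity accrued over the mean
neutral coalescent time of 2N_e generations — converts it to a mean
allele age T.

The age-to-selection inversion uses the Wright–Fisher diffusion with
infinitesimal variance x(1−x) and drift γ·x(1−x) (γ = N_e·s, additive
selection, constant population size, no dominance, time in 2N_e
generations).  The age of an allele that entered at frequency ~0 and is
observed at x is distributed as the loss time of the diffusion started
at x conditioned on loss; its expectation is computed from the
conditioned sojourn-time (Green's-function) densities by adaptive
quadrature, with all exponentials arranged to have non-positive
arguments so the integrand is stable to γ of several hundred.  In the
neutral limit this reduces to the Kimura–Ohta closed form
A(x) = −2x ln x/(1−x), which the integrator matches to < 1e-4; expected
age is symmetric in ±γ (verified numerically), strictly decreasing in
|γ|, and γ-recovery (invert the forward map on a grid) holds to 1e-4
relative error.  `nes_from_age` root-finds A(x; γ) = T by Brent's
method; ages above the neutral expectation clamp to γ = 0 with a
warning.  With this scaling the printed anchors follow directly:
T = 0.36 at x = 0.2 gives γ = 5.39, T = 0.54 gives 2.74, T = 0.63 gives
1.95 — i.e. the conventional one-decimal values 5.4 / 2.7 / 1.9 (the
1.95 → "1.9" case reflects the rounded inputs: the unrounded age
0.0055/0.0087 gives 1.94).

## Synthetic data generator

The generator emulates the study's detection signal directly at the
alignment level; reads are never simulated as sequences.  Defaults are
the study conditions where stated — 10 focal + 2 outgroup lines, insert
275.8 ± 28.8 bp, 2 × 75 bp reads — and desk-scale choices elsewhere:

* genome: one 4 Mb chromosome of uniform random sequence; 300 genes
  (5′UTR, three exons, two introns, 3′UTR) and 800 TEs from eight
  families placed without mutual overlap;
* deletions: 30 non-overlapping intervals with truncated-Pareto sizes
  (tail index 0.74 over [1 kb, 200 kb], median ≈ 2.5 kb, matching the
  strongly right-skewed size distribution of real large indels and
  keeping each line's deleted fraction near the realistic ~2–3 % so
  depth percentiles stay meaningful); minor-allele counts follow a
  neutral-like law p(m) ∝ 1/m over 1..5; carriers are drawn from the
  nine non-reference lines; for a 25 % fraction the deletion is the
  ancestral state (outgroups deleted too), so the reference allele is a
  derived insertion — the class the selection scan targets;
* SNPs: density 0.01/bp, derived counts ∝ 1/i over the focal lines,
  outgroups always ancestral;
* pairs: per line, fragments are placed uniformly on the line's genome
  (reference minus carried deletions) and mapped back to reference
  coordinates; fragments spanning a deletion junction acquire insert ≈
  fragment + deletion length, reads straddling a junction are dropped as
  unmappable; chimera noise rewires 0.1 % of right anchors (20× inside
  five 20 kb repeat-like hotspots), and 5 % of pairs get one mate's MAPQ
  below 29; per-line depth profiles count read bp per 1 kb tile;
* the reference line is simulated against its own genome, so its
  discordant pairs are pure noise — exactly what the reference-accession
  filter removes.

What the generator does **not** emulate: base-call errors and quality
scores, alignment ambiguity beyond the hotspot chimera model, diploid
heterozygosity, recombination within the sampled histories, linkage
between SNPs and indel haplotypes (SNP carriers are drawn independently
per site), and real TE sequence homology.  Passing tests therefore show
the pipeline's logic is correct under its stated signal model, not that
the thresholds are optimal for any particular real dataset.  Planted
deletions adjacent to a hotspot can legitimately fail the
discordant-density filter; across seeds the default configuration
recovers planted deletions with precision 1.0 and recall 0.83–1.0
(recall 1.0 with the default seed, and exactly 1.0 whenever noise is
switched off).

## Problem sizes and determinism

Default analyses run on one CPU in minutes: the 4 Mb, 12-line simulation
produces ~2.6 M read-pair records; the envelope uses 10,000 replicates
(~3 s) and the sampling-error simulation 50,000.  All randomness flows
from explicit seeds (`numpy.random.default_rng` with derived streams per
line and stage), so every stage is bit-reproducible; clustering sorts
its input canonically so results are independent of input order.

## Known limitations

* Breakpoints are anchor-edge estimates (± ~1 insert length); no
  split-read or assembly refinement.
* Inversions and transpositions are called and filtered but not analysed
  further.
* The paper-style χ² on base-pair composition treats every base as an
  independent trial; with indels arriving in kb-size blocks it is
  anti-conservative, so effect sizes (shares, folds) matter more than
  its p-value.
* The diffusion inversion assumes additive selection, constant N_e and
  no recombination within the 500 bp π_A window; violations bias |N_e s|
  in ways the method cannot detect.
* π_A-based ages for classes observed at one frequency in ten lines
  inherit the ±0.1 sampling granularity of that frequency.
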