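# Methods

`ndjmap` analyses recombination in progeny of spontaneous meiotic
nondisjunction (NDJ) mapped by pooled backcross sequencing, and ships a
synthetic twin of the experimental design so every stage can be tested
against known truth.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## The experimental design being modelled

A doubly heterozygous female (haplotypes `P1` and `P2`, e.g. *w1118* x
*Oregon R*) undergoes NDJ of a metacentric autosome.  Disomic sons carrying
both maternal chromosome copies are backcrossed to `P1` testers and their
offspring sequenced as one pool per son.  Each offspring carries one of the
father's two copies plus a maternal `P1` copy, so at a biallelic marker the
pooled alternate (`P2`) allele frequency reflects the father's genotype:

| father's P2 copies | pooled alt frequency |
|---|---|
| 0 (HOM_P1) | 0 |
| 1 (HET)    | 0.25 |
| 2 (HOM_P2) | 0.5 |

Crossovers in the NDJ-producing oocyte appear as persistent switches
between these three frequency states along the chromosome; the state across
the centromere identifies the erroneous division (heterozygous = meiosis I,
homozygous = meiosis II).

## Chromosome model

Arms are dm6-style contigs with 0-based half-open coordinates (VCF/BED
conversions at the I/O boundary).  A metacentric chromosome is two arms in
canonical orientation (first telomere->centromere, second
centromere->telomere) separated by an unassembled satellite gap; a
telocentric chromosome is a single arm.  Heterochromatin blocks come from a
BED file (H3K9me3-like domains); genetic-map anchors from a TSV, with
centimorgan positions interpolated piecewise-linearly and clamped beyond
the terminal anchors.  `arm_fraction` measures telomere-anchored position
along an arm, used by the distal/pericentric zone rules; the bundled
`dm6_chr2()`/`dm6_chrX()` models use real dm6 assembly lengths with
approximate heterochromatin boundaries and standard-map-scale anchors, and
are intended for simulation and testing rather than lift-over-grade
annotation.

## The meiosis simulator

A bivalent is four chromatids (two sisters per homolog).  Per arm, a
crossover count is drawn from a configurable distribution (default
`{0: 0.12, 1: 0.78, 2: 0.10}`, matching the ~8-16% per-arm zero-crossover
rates reported for these genotypes and leaving doubles uncommon); positions
are uniform over euchromatin (optionally weighted by a density table, or
allowed into heterochromatin for caller stress-tests).  Interference is a
hard minimum intra-arm spacing (default 2 Mb, the smallest double-crossover
spacing seen in normal meioses of these stocks) enforced by resampling - a
deliberate simplification of gamma-model interference that reproduces the
qualitative behaviour.  There is no chromatid interference: the chromatid
pair for each crossover is drawn uniformly.

Exchanges are applied distal-first and swap everything telomere-ward of the
breakpoint between the two involved chromatids (the strand-path model).
This keeps centromere identity fixed, and matters: proximal-first
application mis-assigns the products of 3-strand double crossovers.

Segregation: a normal gamete is one chromatid; MI NDJ yields one chromatid
from each homolog; MII NDJ yields both sisters of one homolog.  A
consequence worth noting: in an MII gamete a 3-strand double crossover can
place the same breakpoint on both inherited sisters, whose pooled
frequencies then cancel - "MII reveals every crossover" is exact for single
crossovers but only parity-wise in general.

Sequencing of the pool: per-marker depth is Poisson(`mean_depth`, default
30); alternate reads are Binomial(depth, f') where f' blends the ideal
state frequency with a symmetric per-read error (`seq_error`, default 0.01,
Nanopore-scale).  The pool is treated as effectively infinite (fly
backcrosses yield large progeny counts); an optional `n_pool_offspring`
adds the shared composition noise of a small pool, in which case observed
heterozygous-site frequencies shift coherently away from 0.25.  Default
marker spacing is 5 kb - far denser than any biological length scale in
the analysis while keeping cohort simulation interactive; the real SNP
panel (~170 bp mean spacing) can be emulated by configuration.

What the simulator does *not* model: read-level artefacts (mapping bias,
indels, error non-uniformity), unassembled-satellite markers, segregation
distortion, and viability effects.  Passing recovery tests therefore
demonstrate the caller's statistical behaviour under the declared noise
model, not robustness to alignment pathology.

## Panel filters

Markers are sites where the two parental stocks are homozygous for
different single-nucleotide alleles (multi-allelic sites dropped outright;
on designated chromosomes, sites present in a third "exclusion" stock VCF
are disregarded).  Two filters run in a fixed order: (1) per individual, a
marker with total depth < 8 is masked; (2) panel-wide, a marker whose
alternate-frequency variance across the remaining unmasked individuals is
< 0.01 is dropped (population variance, ddof=0; fewer than two usable
observations also drops the marker).  Both cuts are strict `<`.  The order
matters because masking changes the observed variance; depth-first is the
declared convention.  Note the variance filter presumes a cohort of mixed
genotypes - in a cohort where every individual shares a state at a site,
that site is (correctly, per the filter's purpose) discarded as
uninformative.

## Crossover calling

"Persistent change in allele frequency" is operationalised as the exact
maximum a posteriori state path under per-marker binomial emissions
(`alt ~ Binomial(depth, f(1-eps) + (1-f)eps)`, `eps = 0.01`) with a fixed
log-penalty `ln 1e-6` per adjacent-marker state switch, computed by dynamic
programming with ties broken toward fewer segments, then lower state index.
Segments with fewer than `min_segment_markers = 10` markers are merged into
their larger neighbour.  Terminal segments are exempted down to
`min_terminal_markers = 2`: a distal crossover near a telomere has only one
flanking boundary, and a 10-marker terminal requirement would silently
erase exactly the distal-crossover class the cause analysis needs.  The
switch penalty already makes short spurious terminal segments expensive
(a two-marker terminal segment must carry ~14 nats of emission evidence).

A call is reported as the interval between flanking SNPs, never a point.
The bounds are chosen conservatively: walking outward from the state
boundary, the interval ends at the first marker whose cumulative emission
log-odds for its segment's state reaches `ln 1e6`.  At modest depth the
single marker adjacent to a true breakpoint is ambiguous a few percent of
the time, so the raw boundary-adjacent marker pair would frequently exclude
the true breakpoint; the cumulative-evidence bound keeps the interval a
genuine credible bound at the cost of a few extra flanking markers.

Boundaries are annotated with heterochromatin/pericentric-zone overlap,
double-crossover membership with bp and cM separations (flagged
`within_normal_range` when >= 2 Mb and >= 10 cM apart, the smallest
spacings seen among normal-meiosis doubles), and a centromere-gap check: if
the two arms' centromere-proximal states disagree, a crossover must be
hiding in the unassembled satellite and a `gap_shift` call spanning the gap
is emitted.

## Division classification and monosomy rescue

The call uses the state of the centromere-proximal terminal segment within
a 1 Mb pericentric window on each arm (>= 10 markers required, else
`ambiguous`): HET/HET = MI, matching homozygous states = MII.  Conflicting
states (different homozygous classes, or a HET/HOM mix) return `ambiguous`
rather than a forced call - those patterns are exactly what a pericentric
exchange produces, and silently binning them would corrupt the downstream
spectra.  A chromosome homozygous end-to-end is compatible with monosomy
rescue; it is labelled `rescue_suspect` only when a direct
HOM_P1 <-> HOM_P2 switch proves a duplicated recombinant chromatid, and
otherwise stays MII with an "indistinguishable" flag, since no meiotic
disomy can produce the switch but a non-recombinant rescue is
indistinguishable from MII.

## Detection model and the MII adjustment

Detectability is enumerated exactly (rational arithmetic) over the equally
likely inheritance outcomes of each mode: for a single crossover the
recombinant chromatid is inherited with probability 1/2 in a normal
meiosis; MI NDJ gives 1/2 one-recombinant (detectable), 1/4 reciprocal
recombinants and 1/4 non-recombinants (both fully heterozygous, hence
invisible in pooled frequencies); MII NDJ always shows a single crossover.
When comparing crossover spectra across modes, the MII single-crossover
fraction is therefore halved; doubles are left unadjusted (rare, and no
principled correction exists without a model of the pre-detection
distribution, which is deliberately out of scope).  Observed per-arm
crossover counts are segmentation boundaries, so an MII reciprocal pair
counts as two - the spectrum reports what the data can show.

## Cause categorisation

Rules fire in strict order: (1) no calls -> `no_crossover`; (2) all calls
within the distal 24% of their arm -> `distal_crossover`; (3) any call in
the pericentric zone (heterochromatin plus the proximal 15% of each arm's
euchromatin) -> `pericentric_crossover`; (4) otherwise `unrelated`.  The
24%/15% thresholds were calibrated on a telocentric chromosome's genetic
map intervals; on a metacentric they are applied per arm (each arm treated
as a telomere-anchored unit, both arms' zones active), which is the
configurable default - whether the original distal fraction should instead
be measured chromosome-wide is not stated anywhere authoritative, and per
arm is the reading consistent with treating each arm as an independent
failure domain.  Call positions are interval midpoints; intervals
straddling a zone edge are decided by midpoint and flagged.

## Statistics

The one-tailed two-proportion Z-test uses the pooled-variance formula with
no continuity correction by default (the common R convenience function
applies a Yates correction silently; both variants are exposed because the
original setting is unknowable, and printed p-values are reproducible only
when counts and correction match).  Mann-Whitney tests delegate to scipy:
exact enumeration for tie-free pooled samples of <= 20, otherwise the
normal approximation with midrank tie correction.  Landscape summaries bin
call midpoints into 1 Mb windows as per-event exchange rates.

## Numerical and degenerate-input conventions

Tracks shorter than the internal support threshold fall back to a single
segment with a warning.  Empty frequency tracks warn and return empty.
Depth-zero markers are uninformative to the emission model and are masked
by the depth filter anyway.  Enumeration probabilities are
`fractions.Fraction` end to end and sum to exactly 1.  All simulator
randomness flows through one seeded NumPy generator; cohort outputs are
byte-identical under a fixed seed.

## Test-suite problem sizes

Oracle equivalence for the segmentation is checked exhaustively (all 3^n
state paths) for tracks up to 10 markers and against an independent
memoized recursion at 30 markers; full exhaustive enumeration at 30 markers
(3^30 paths) is not computable and the two-pronged check covers the same
property.  The recovery suite simulates 1,300 individuals at 50 kb marker
spacing, mean depth 20 and 2% read error - 1,000 single-crossover-per-arm
events (~1,500 detectable breakpoints) plus 300 crossover-free chromosomes -
and requires >= 99% breakpoint containment, < 1% spurious-call rate and
perfect MI/MII classification.  Monte-Carlo checks of the detection model
use 100,000 simulated meioses per mode, within three binomial standard
errors of the exact values.

## Known limitations

* The caller assumes the three-state autosomal disomy design; X-chromosome
  pools (whose state vector depends on offspring sex composition) are
  supported only through a user-supplied expected-frequency vector.
* Gene-conversion tracts, mitotic recombination and per-read phasing are
  out of scope.
* Crossovers within ~2 markers of a track end are below any support
  threshold and are missed; at the default simulated density this is a
  sub-0.5% effect concentrated at telomeres.
* The genetic-map anchors bundled with the dm6-like models are approximate;
  centimorgan annotations inherit that approximation.
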