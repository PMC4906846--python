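# Methods

## Measurement model

A ddPCR well partitions a diluted aliquot into `N` droplets (default 20,000,
droplet volume 0.85 nL — QX200-typical, both configurable). Each target
molecule lands in a uniformly random droplet; a droplet is positive if it
received at least one molecule. The per-droplet occupancy is therefore
binomial(M, 1/N), which at these sizes is indistinguishable from Poisson,
and the occupancy is estimated from the negative fraction,
`λ = −ln((N−P)/N)`. The estimator's relative bias from the
binomial/Poisson distinction is of order `1/(2N)` (~2.5e-5 at N = 20,000)
and is ignored. At the working cap of 10,000 molecules per well
(occupancy ≤ 0.5) the correction over naive positive counting is ≤ ~22 %;
the full correction is always applied, so the estimator remains valid up to
occupancies of ~2 where wells approach saturation. A fully positive well
carries no finite estimate and is flagged `saturated`; one saturated
replicate taints its replicate set.

Confidence intervals are Wilson score intervals on the positive fraction,
chosen because they behave at 0 and near saturation, transformed through
the (monotone) occupancy and volume formulas. Replicates (triplicate by
default) are pooled by summing positives and droplets — the maximum-
likelihood combination — and then rescaled to a single well so that
"copies per reaction" keeps its meaning; the replicate spread is reported
as the sample standard deviation (ddof = 1) of the per-replicate absolute
counts. False-positive/negative droplet classification is assumed perfect
(rates 0); the droplet reader's amplitude thresholding is out of scope.

## Protocol model

Molecules are classed by amplicon (A214/B397/C568, lengths 214/397/568 bp),
length and end-state, ordered
`sheared → end_repaired → a_tailed → adaptor_ligated → p5p7_flanked`.
Every step carries a physical retention in [0,1] applied to all species
and, for chemical steps, a conversion efficiency in [0,1] applied to the
species at the step's source state; unconverted molecules stay in place.
This separation is the modelling counterpart of the assay's overall/
stepwise deconvolution. Cleanup retention may be a logistic curve in
fragment length (configurable midpoint/steepness/floor/ceiling) to emulate
preferential short-fragment loss; no mechanistic bead-chemistry model is
attempted, and sequence-driven bias is not modelled at all (the assay
itself cannot separate the two sources).

PCR multiplies the adaptor-ligated pool by `(1+e)^c` (default e = 0.95,
c = 6 cycles; one source reports 10 cycles for the same experiment, so the
cycle count is configurable) capped at a total capacity (default unbounded
in the library; 4e12 molecules in the study generator). The cap is the
simplest mechanism that reproduces the observed anticorrelation between
ligation efficiency and PCR fold: efficient ligation feeds the PCR more
substrate, which saturates and amplifies less per molecule. Non-amplifiable
species pass through unamplified. In stochastic mode every retention and
conversion is a seeded binomial draw with the matching expectation; the PCR
fold is applied deterministically (rounded), since amplification noise is
negligible at these molecule numbers.

The nine built-in kit workflows encode the published step structure; each
listed step counts as 1, a combined end-repair/A-tailing mix is one step,
"PCR & bead cleanup" is represented as two steps, and the enzymatic
fragmentation + end-prep reaction of KAPA HyperPlus is one step that takes
input DNA straight to the A-tailed state. Ambiguous rows (the exact cleanup
positions of the Truseq kits, the 4 + 4 decomposition of Accel-NGS 2S, the
Accel single-strand chemistry mapped onto generic sequential conversions)
are assumptions; they affect only step placement, not the step totals or
the yield algebra. Kit presets ship with neutral (1.0) efficiency
placeholders that callers must set.

## Yields

`overall = measured/input` and `stepwise = converted/total-same-step` are
molecule-count ratios (ddPCR counts molecules; mass enters only once, when
the input is converted at 650 g/mol/bp — 660 is accepted and configurable).
Yields are never clamped; post-PCR overall yields above 1 are meaningful.
The ligation stepwise yield is documented as a ligation-*chain* yield
(end repair and A-tailing failures are indistinguishable from ligation
failures in this design). Ratio uncertainties use the first-order delta
method assuming independent numerator and denominator — exact here, since
the two channels are measured in separate wells. Whether the post-PCR
"total" channel includes unamplified non-ligated fragments is ambiguous in
the source design; the report computes the total channel as measured
(which, in the simulator, does include pass-through molecules) alongside
the P5/P7 channel, and flags rather than fails on anything unmeasured.

## Dilution planning

Input mass → molecules via `m·1e-9/(650·L̄)·N_A` with L̄ the molar-fraction-
weighted mean length. The planner picks the smallest dilution composed of
serial stages of a fixed base (default 10; exact continuous mode available)
such that `molecules/µL × template volume / factor ≤ cap` (cap 10,000).
Default volumes — 50 µL sample, 1 µL template per well — are documented
defaults, not measured values. Plans scale proportionally for other input
masses (100 ng → factor/5, 20 ng → factor/25 of a 500 ng plan), which
leaves the per-well load unchanged; factors below 1 clamp to 1 with a
warning. The 1e5–1e7 range quoted for 500 ng libraries is treated as the
*total* factor, not a per-stage value.

## Error rates

Per mapped read, mismatches come from the MD tag (or a reference FASTA
when MD is absent), insertion/deletion bases from CIGAR I/D operations.
The denominator is the aligned (M/X/=) base count — deleted bases excluded,
soft/hard clips excluded everywhere; including deletions in the denominator
and counting indel events instead of bases are options. Rates are pooled
(class totals over the summed denominator) rather than averaged per read;
base-weighted per-read averaging gives identical numbers. Mates are counted
independently and duplicates are not removed.

## Synthetic study generator

`generate_study` emulates the study design: three synthetic amplicons with
the assay's published primer/probe sites embedded (true genomic coordinates
are not modelled — the references are labelled synthetic), an equimolar
500 ng input, nine kits with true ligation-chain efficiencies spanning the
reported range (0.035 … 1.0; the Accel kits get 0.20 purely to drive the
simulation, since their truth was unmeasurable), 0.9 bead-cleanup retention
shaped by a logistic length curve (floor 0.55, midpoint 180 bp — short-
fragment loss), a stringent 0.25-retention double size selection for the
PCR-free kit (matching its reported >80 % pre-ligation loss), and a
capacity-limited PCR (e = 0.95, 6 cycles, 4e12 molecules). Measurements are
triplicate 20,000-droplet wells at planner-chosen dilutions on the three
channels; reads are 150-base proper pairs with mismatch 1e-3, insertion
2e-4, deletion 0, emitted as aligned SAM with MD/NM tags (validated
byte-for-byte against `samtools calmd`) to avoid an aligner dependency.

All randomness derives from one seed through spawned substreams; a fixed
config reproduces every output byte-identically. What passing tests show:
the estimators are unbiased and correctly calibrated *under the generative
model* — uniform partitioning, perfect droplet classification, binomial
losses, independent wells. Real data add pipetting error, droplet-size
variation, rain (intermediate amplitudes), PCR inhibitors and operator
effects that the generator deliberately omits.

## Numerical and design choices

* Occupancy uses `log1p` for accuracy at low positive fractions; zero
  positives give exactly 0 copies with a finite Wilson upper bound.
* Expected-mode propagation is pure floating arithmetic; conversion-free
  chains compose to the product of retentions to ~1e-12 relative error.
* Stepwise yields are reported as missing-with-flag (never NaN-silent, never
  raised) when a channel is unmeasured (Accel adaptor channel) or a
  denominator is zero; report writers emit empty cells plus a flag column.
* Study problem sizes (20,000 droplets × 3 replicates; a few thousand read
  pairs per sample) were chosen so that 3-SE recovery tests are sharp while
  the whole suite stays fast.

## Known limitations

Single-molecule droplet loading is assumed resolvable by the Poisson
correction only; amplitude thresholding, duplex assays and rain are out of
scope. The PCR capacity model is a one-parameter cap, not an enzyme/dNTP
kinetics model — it reproduces the anticorrelation qualitatively, not
measured fold values. Library complexity is not estimated. Accel-kit
chemistry is represented only as generic sequential conversions.
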