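# Methods

This note records the model behind `replichrom`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish about real data.

## Lagging-strand model

The simulator is a 1-D discrete-event model of one lagging strand of length
`strand_length` (default 200 kb). Time is normalized to fork travel:
`fork_speed = 1` bp per time unit, so every rate reads as events per bp of
fork progression.

**Priming and synthesis.** Primer spacings are
`primer_spacing_min + Exponential(primer_spacing_mean − primer_spacing_min)`
(defaults 50 and 150 bp, giving a mean initiation interval of 150 bp).
Fragment synthesis and nick translation are treated as instantaneous
relative to fork travel: at its priming time, a fragment extends back to the
preceding primer and then displaces the preceding fragment's 5′ DNA until
its 3′ end reaches the first nucleosome edge on that DNA, or until
`max_displacement` (1000 bp) of strand displacement, whichever comes first.
The stop position is the ligation junction. If a fragment's stop coincides
with the previous junction, the preceding fragment was displaced entirely
and the two merge (the displaced primer is discarded). Consecutive junctions
delimit the final ligated fragments, which tile the strand exactly; the
first fragment runs to the strand start and the final stretch terminates
against the last chromatinized edge without loading a clamp of its own.
Fragment length is therefore set by the spacing of *occupied* nucleosome
edges: a regular array yields lengths at one repeat, inter-edge intervals
that receive no primer yield two repeats, and missing nucleosomes yield long
fragments.

**Nucleosome deposition.** Deposition attempts arrive at rate
`deposition_rate` (default 2.0 per unit — effectively instantaneous, since
one nucleosome per ~180 bp of fork travel suffices). Each attempt targets
`last_dyad + repeat + Normal(0, deposition_jitter_sd)` where
`repeat = footprint + linker = 147 + 33 = 180` bp and the jitter default is
10 bp (typical in-vivo positioning noise; it also prevents the lattice from
being artificially crystalline). The target is clamped to maintain the
147-bp footprint spacing, slid rightward past any position whose footprint
widened by `pcna_block_halfwidth` (15 bp) covers a resident clamp, and
deposited only if the footprint fits on already-synthesized DNA; otherwise
the attempt is dropped and, by Poisson memorylessness, the process resumes
exactly at the next state change. Skipped ground is never backfilled — the
model's chromatin defects are persistent at the timescale of one S phase.

**PCNA.** One clamp loads per primer. Its unloading clock starts at its
fragment's ligation and rings after `Exponential(1 / (k_elg1 + k_spont))`:
the ligation-gated Elg1-RLC pathway plus spontaneous (trimer-instability)
dissociation. The obstacle is a point at the clamp's *load position* (the
primer). Sliding is not modeled, so a static location had to be chosen, and
this is the one deliberate departure from the obvious alternative (the
ligation junction): junctions coincide with nucleosome edges of the very
lattice the deposition rule extends, so a junction-resident clamp always
sits one linker plus half a footprint (~106 bp) left of the next candidate
dyad and can never intersect its exclusion window — under that geometry the
obstruction pathway is dead code and delayed unloading has no phenotype.
The load position is random with respect to the emerging lattice, which is
what lets retained clamps actually collide with deposition. Measured
consequence (ten 100–200-kb strands): junction-placed clamps give
mutant ≈ wild type (mean 220 vs 221 bp); primer-placed clamps give the
expected emergent phenotypes (mean ~342 vs ~218 bp, mono-fraction fold ~6,
near-zero KS distance for the disassembly-prone rescue).

**Presets** (YAML package data): `wt` (`k_elg1 = 1.0`, `k_spont = 0.001`):
clamps unload within ~1 bp of fork travel, long before the deposition
frontier (which trails by roughly half a footprint plus the deposition
wait) reaches them. `elg1d` (`k_elg1 = 0`): mean clamp residence of 1000
time units, so ~93% of clamps are still resident when deposition arrives.
`pol30-r14e` / `pol30-d150e` (`k_elg1 = 0`, `k_spont` 1.0 / 0.5):
disassembly-prone clamps that rescue retention. `cac` (`deposition_rate`
0.008): the deposition frontier advances at 0.008 × 180 ≈ 1.4 bp per bp of
fork travel, marginally above the fork, producing the mild fragment
lengthening of a chaperone-deficient condition; at rates ≥ 0.02 the lag is
negligible.

**MNase readout.** At a sample time (default 60% of strand completion),
nucleosomes deposited so far protect their footprints; each naked stretch of
length L is cut with probability `1 − exp(−cut_coeff · L)` at a uniform
point (at most one cut per stretch — a deliberately coarse digestion model).
Protected fragments are classified by dyad count (0/1/2/more) and reported
as bp-mass fractions of the synthesized DNA. The default
`cut_coeff = 0.01`/bp cuts a 33-bp linker with probability 0.28:
sub-saturating digestion, chosen so that differences in linker length
between conditions remain visible rather than being flattened at either
digestion extreme.

## Metaprofiles

Fragment midpoints (floor((start+end)/2)) are the protection measure;
full-fragment pileup is available via `mode="coverage"` but midpoints give
the sharper phasing signal. Per-bp midpoint depth is summed over
anchor-centred windows, minus-strand windows reversed first, and divided by
`n_anchors × (total midpoints / genome length)` — the normalization scope is
genome-wide and per sample, because per-window normalization would erase
occupancy differences between conditions. Anchors within one flank of a
chromosome end are dropped and counted, not zero-padded. Smoothing is a
centered moving average (default 50 bp; even widths are incremented to odd),
truncating at the edges. Under uniform coverage the normalized profile is 1
up to counting noise (the flat-coverage check uses 2 M fragments over 50 kb
and 40 anchors so that the per-offset standard error is ~0.03).

The nucleosome repeat is estimated as the lag maximizing the unbiased
autocorrelation of the mean-subtracted profile within a search range, ties
to the smaller lag; a flat or aperiodic profile (no positive peak) returns
`None` rather than a number. Recovery is reliable to ±5 bp on well-phased
fixtures (jitter ≲ 10 bp); at jitter ≳ 20 bp the autocorrelation peak
broadens and drifts, which is a property of the statistic, not a bug. The
organization score is the RMS deviation of the profile from its mean —
zero iff flat, and strictly decreasing in generator jitter on the synthetic
suite (0/20/40/80 bp). That monotonicity is what a "clear defect in
organization" claim needs operationally.

## Gel densitometry

Migration position is modeled and fitted as linear in log10(size).
Calibration is a least-squares fit through the ladder (≥ 2 points, strictly
monotone in either orientation). The baseline under a lane is the pointwise
maximum of a rolling minimum (window 10% of the trace) and a rolling median
(twice that window) of a lightly pre-smoothed copy: the minimum tracks
drifting offsets, the median tracks the floor of zero-clipped scanner noise,
and the doubled median window keeps bands occupying up to half of it from
lifting the estimate. The *signed* residual is integrated (trapezoid) over
size windows mapped through the calibration — symmetric noise then cancels
instead of inflating areas. Bands must be narrow relative to half the
baseline window or their mass is eaten; the synthetic fixtures use 8-bp band
widths accordingly. Default windows: mono 120–220 bp, di 280–420 bp, total
50–1000 bp — conventions, configurable, and fold changes on real scans are
window-sensitive, so only constructed-fixture behaviour is asserted
(3:1 mixture → 0.75 ± 0.02; 80%-mono titration lane → 0.80 ± 0.02; noisy
round-trip within 10% at a noise SD of one tenth the band peak).

## SILAC enrichment

Per-protein ratio is the median of peptide heavy/light ratios — robust to
single-peptide outliers, and the mean would be biased upward under the
lognormal noise the generator (and instrument reality) produce. Records
with non-positive intensities are dropped and counted; proteins under
`min_peptides` are excluded and listed. Classification is a plain ratio
threshold with deterministic ranking (ratio, then summed intensity, then
id); no multiple-testing machinery, since the underlying presentation is a
ratio-vs-intensity scatter, not hypothesis tests. At 20% multiplicative
noise and 8 peptides the median relative error over proteins is ≲ 6%.

## Synthetic data: what it does and does not show

The generators emulate the *observable layers* — phased dyad arrays with
tunable jitter, mono/di/free fragment mixtures, Gaussian gel bands in
log-size coordinate with a ladder, lognormal peptide tables — with known
ground truth and bit-reproducible seeding (one integer seed per generator,
fixed sub-stream offsets). They deliberately omit sequence-level realism:
no GC or mappability bias, no digestion sequence preference, no fragment
length/occupancy coupling, no chromatin heterogeneity between loci, no
replication-timing structure. Passing tests therefore establish that the
estimators recover known generative parameters under clean conditions
(repeat to ±5 bp, class weights to multinomial noise, band areas to 1–2%,
ratios to ~10%) and that the simulator's condition contrasts point in the
biologically observed directions; they do not certify effect sizes on real
sequencing or densitometry data, where the omitted biases dominate the
error budget.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere; BED is read at face value.
Histogram modes are reported as bin centers; a plateau counts as one peak,
snapped to its highest raw bin with ties to the left, and a mode must hold
at least `min_fraction` (default 1%) of the mass in its bin. Dyad
collisions in the generator are resolved by dropping the later-placed dyad.
Zero-length strands, empty fragment sets, empty band lists and empty
peptide tables all return empty results rather than raising; infeasible
anchor packings, invalid windows, non-monotone ladders, mixed-sample
profiling and out-of-range searches raise typed errors that the CLI maps to
exit codes 2 (input) and 3 (infeasible).

## Problem sizes

The shipped analyses and tests use ten replicate 200-kb strands per
simulated condition (~9 × 10³ pooled fragments for wild type), 30–40
anchors with 6-nucleosome arrays per side for profile fixtures, and
2 × 10⁶ uniform fragments for the flat-coverage check. These sizes put
Monte-Carlo error comfortably inside every stated tolerance while keeping
the full suite under a minute of compute on one core; all scale linearly
if larger runs are wanted.

## Known limitations

No leading-strand or whole-genome replication program; a single fork, no
converging forks except as the strand-end boundary condition. Ligase
depletion (the experimental trick that makes Okazaki fragments visible) is
not modeled — lengths are read at termination. Whether clamp retention also
delays ligation is unknown and not modeled (only deposition is coupled).
The one-cut-per-stretch MNase model understates internal fragmentation of
long naked gaps. PCNA is a point; clamp crowding, sliding and encounters
with nick-translating polymerase are not represented.
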