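# Methods

## The model

Transcription elongation is modelled as a totally asymmetric exclusion
process of extended particles with pausing. A gene is a 1-D lattice of
`L` nucleotide sites (1-based; site 1 is the transcription start). Each
elongation complex (EC, an RNAP with its nascent transcript) is a
stochastic stepper whose *active site* sits on one lattice site and whose
footprint covers `d` consecutive sites `[x, x+d-1]`; hard-core exclusion
keeps active-site positions of any two ECs at least `d` apart.

Dynamics, per fixed timestep `dt`, applied to ECs in downstream-to-
upstream order:

* a **stalled** EC is rescued to the active state at the same position
  with probability `dt/τ` (backtracked/arrested complexes are abstracted
  into a single stalled state with exponential lifetime `τ`);
* an **active** EC whose active site is on a pause site first stalls with
  probability `f·dt`, otherwise attempts a +1 step with probability
  `ε·dt`;
* an active EC elsewhere attempts a +1 step with probability `ε·dt`;
  steps that would violate exclusion are rejected;
* an EC whose active site passes `L` terminates and is removed;
* last, if the promoter region `[1, d]` is free, a new EC enters at
  site 1 with probability `α·dt`.

Pause sites are a fixed, seeded random subset of interior sites
`[2, L-1]` — a property of the gene shared by every run, mimicking
sequence-encoded pausing. A stalled EC keeps its footprint and blocks all
traffic behind it; queues of ECs packed at spacing exactly `d` behind a
stalled EC are the model's "traffic jams" and the mechanistic heart of
its predictions.

The Gre transcript-cleavage factor enters only through pause kinetics.
Its loss is modelled by one single-parameter change ("scenario"):
multiply pause duration `τ`, multiply pause frequency `f`, or divide the
stepping rate `ε`.

### Assumptions and non-goals

No explicit backtracking displacement, no premature termination or
drop-off, no ribosome coupling, no sequence-dependent pause strength, no
transcript degradation. Rescue returns the EC to the active state at the
same position.

## Numerical scheme

Fixed-increment kinetic Monte Carlo with per-event probabilities
`rate·dt`. A validity guard refuses runs when
`dt·max(α, ε, f, 1/τ) > 0.2`, keeping discretisation bias at the percent
level; convergence is tested by halving `dt` (mean single-complex transit
changes by <1%). Stall-before-step within one timestep at a pause site
induces an O(dt) bias only.

The within-step update order is downstream-first, which avoids same-step
convoying artifacts (an EC moving into a gap its predecessor vacated in
the same step); a random-order mode is available for sensitivity checks
and is exercised by the invariant tests. One seeded Mersenne-Twister
stream drives each run; replicate `r` of a batch uses `seed + r`, so all
outputs are bit-reproducible from `(inputs, seed)`.

Two analytic oracles check the engine: the exact mean single-complex
transit time `(L + n_pause·f·τ)/ε`, and the maximal current
`ε/(1+√d)²` of the extended-particle exclusion process (`ε/4` at `d=1`).
Note the discrete-time downstream-first update carries a small *positive*
throughput bias of order `ε·dt` relative to the continuous-time limit
(ordered-sequential updates transport slightly more current per unit
time), so saturation tests run at `ε·dt = 0.025` and allow the measured
rate to sit up to ~4% above the continuous bound.

## Parameters, units and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `α` | initiation attempt rate (1/s) | 0.2 | mid expression range; well below the saturation current ~0.6/s for `ε`=62, `d`=35 |
| `ε` | stepping rate (nt/s) | 62 | the wild-type in vivo elongation velocity measured by the two-probe assay |
| `f` | stall rate on a pause site (1/s) | 0.2 | with `ε`=62, ~4.5% of complexes stall somewhere on the 2700-nt reporter per transit |
| `τ` | mean stall duration (s) | 1 | wild type: pauses resolve quickly; pausing costs <0.1 s per transit |
| `d` | EC footprint (nt) | 35 | heritage of the rRNA-transcription lattice framework this model extends; configurable |
| `dt` | timestep (s) | 0.01 (`KineticParams`), 0.002 in all shipped presets | 0.01 s is the classic choice but violates the `rate·dt ≤ 0.2` guard at `ε`≈62; presets use 0.002 s |
| pause density | pause sites per nt | 0.005 | 14 sites on the 2700-nt reporter |
| reporter | `L`, probe windows | 2700; early `[1,500]`, late `[2201,2700]` | the ~2700-bp two-probe reporter geometry; probe distance 2200 nt between 3' ends |

The kinetic parameter values behind the original simulations are not
published; all defaults above are package choices, fixed once after an
exploratory calibration and used unchanged by every test and script.

### Scenario presets

* `nogre_pause_duration` — τ×100 (dead-end pauses on the induction
  timescale). The default no-Gre hypothesis.
* `nogre_pause_frequency` — f×5, paired with its own wild-type baseline
  of very rare but very long pauses (`f`=0.04/s, `τ`=100 s). With the
  primary short-pause baseline, multiplying `f` cannot reduce the
  late-probe slope: the mutant's pauses would remain too brief to strand
  complexes within the assay window. Reproducing the observed pattern
  under this hypothesis *requires* rare-long pauses in the wild type —
  which is precisely why the pause-duration hypothesis is preferred, the
  rare-long wild-type baseline having no independent support.
* `nogre_stepping_rate` — ε÷2. Delays the late signal but preserves the
  late/early slope ratio, which is how the induction assay rejects it.

## Virtual experiments

**Induction (two-probe) assay.** Each run starts from an empty lattice
("induction at t=0"); the early/late signals are run-averaged cumulative
counts of transcripts whose active site has passed the respective probe
window's 3' end — an RNA hybridises to a probe only once it contains the
full probe target. Default: 1000 runs, 150 s window, 0.25 s sampling.

**Velocity estimator.** The onset of each probe signal is the x-intercept
of a straight line fitted to the signal's rising phase — samples between
10% and 50% of its value at the end of the fitting window. Velocity =
distance between the probes' 3' ends / (late onset − early onset). The
rise-fit is robust to the curvature of run-averaged signals near the
onset; a cruder threshold-crossing alternative sits behind a flag and
carries a known bias when the window truncates the two signals unequally.
On pause-free simulations the estimator recovers `ε` within 5% at a few
hundred runs; at the default wild type it returns ~61.6 nt/s for the
configured 62 nt/s.

**Scenario discrimination.** The late/early tail-slope ratio (linear fits
over the last 30% of the window) separates the hypotheses: ~0.98 (wild
type), ~0.82 (both pause scenarios), ~0.99 (stepping-rate scenario).

**Steady state.** Rate = completions after a burn-in (default 10%)
divided by post-burn-in time. Runs sized by `suggest_n_steps`, which
targets ≥200 completions *and* ≥40 stall lifetimes `τ` — without the
latter, long-`τ` conditions are sampled far from steady state. Zero
completions raise an error; <100 expected completions warn. Sweeps run
replicate batches (paired seeds across conditions) and bootstrap the
WT/scenario fold change (200 resamples) for CIs. Fold change is defined
wild-type/scenario, so >1 means expression lost without the Gre factor;
both linear and log2 are reported.

### Expression-level and gene-length sweeps

With dead-end pauses (τ×100) the fold change rises from ~1.05 at
`α`=0.02/s to ~1.8–2.0 at `α`=2/s on a 600-nt gene: weakly expressed
genes are initiation-limited and indifferent to pausing; highly expressed
genes are limited by the average elongation velocity, and queuing behind
stalls erodes exactly that.

Length dependence deserves care. With dead-end pauses the model predicts
fold changes that *grow* roughly linearly with `L` at fixed pause
density: queues park active complexes on pause sites, where they stall
secondarily, a cascade whose burden scales with the number of pause
sites. Observed expression data show no correlation between gene length
and Gre dependence, which within this model constrains the steady-state
pause burden to the weak-perturbation regime (`J·n·f·τ/ε ≪ 1`). The
shipped length sweep therefore runs a milder long-stall scenario (τ×5) in
which the fold change is visible yet approximately flat (~1.00/1.03/1.13
across L = 300/1000/3000, 13% variation); the dead-end variant is also
exported by `analysis/03_steady_state_sweeps.py` for comparison. The
flux relation (rate ≈ occupancy × mean on-gene velocity / L) makes the
mean velocity the binding constraint for highly expressed genes.

## Synthetic sequencing data and the fidelity pipeline

The generator emulates an error-counting RNA-seq experiment on a small
random reference (≥1 kb, configurable GC): 135-nt reads drawn uniformly
from both strands, three independent Bernoulli substitution channels
applied in molecular order (transcription → reverse transcription →
sequencing; each hit becomes one of the three other bases), phred
qualities from a 38-plateau profile decaying to 30 at the 3' end, plus
0.5%/base low-quality (phred 10) injections to exercise the quality
filter. A manifest records every read's origin, strand and per-channel
error positions. All draws are fixed-shape arrays from one seeded
generator, so conditions sharing a seed are coupled: raising one
channel's rate yields a superset of errors, making paired-seed ordering
comparisons essentially noise-free.

It does **not** emulate realistic Illumina error spectra, indels,
duplicates, adapter contamination, coverage bias or RNA secondary
structure effects — passing tests show the pipeline's accounting is
correct against known truth, not that real libraries behave this way.

Pipeline order (homopolymer filter on raw reads → trim 20/20 to 95 nt →
quality filter mean ≥25, min ≥15 → map → tally). The mapper is
exhaustive and ungapped: every placement on both strands is scored by
mismatch count (via a sliding-window comparison), and a read is reported
only for a unique best placement with ≤6 mismatches; ties are discarded
as ambiguous. `N` bases are wildcards for scoring and excluded from both
numerator and denominator of the per-base rate. The headline metric is
the per-base mismatch percentage; the per-read mean and the fraction of
reads with ≥1 mismatch are reported alongside because figure-legend and
text conventions for such metrics differ.

Error-model presets (per-base): sequencing 0.0012 for all conditions;
reverse transcription 0.0033 (M-MLV) vs 0.0006 (AccuScript, ~5-fold
higher fidelity); transcription 0.0004 (wild type) vs 0.0008 (mutant).
Combined rates then fall in the 0.22–0.53% range with the
RT channel dominating the low-fidelity enzyme, the regime reported for
such experiments; only the transcription channel differs between
genotypes, as in the real design where the same RNA is split across
enzymes.

## Degenerate inputs and tie-breaks

* `build_gene` draws `round(density·L)` pause sites without replacement
  from `[2, L-1]`; density 0 means none; requesting more sites than
  interior positions is an error.
* Probe windows must lie in `[1, L]` with the early window ending before
  the late one.
* `estimate_velocity` raises `NoOnsetError` for flat signals, fewer than
  two samples in the rising phase, or a late onset not after the early
  onset.
* `steady_state_rate` raises `UndefinedRateError` (with the offending
  parameters) on zero completions rather than returning 0.
* Empty trajectories give all-zero queue statistics; queue sizes count
  the complexes packed behind a stalled leader, excluding the leader.
* Trimmed reads shorter than one base are dropped and counted; trimmed
  lengths differing from the expected 95 nt warn.

## Limitations

* The discrete-time update's positive throughput bias (O(`ε·dt`)) means
  absolute saturation currents sit slightly above continuous-time theory;
  all preset regimes run well below saturation where the bias is
  negligible.
* The exhaustive mapper is O(reference × reads) and intended for
  synthetic references up to ~100 kb, not genomes.
* Mismatch rates conflate the three error channels by construction; like
  the real experiment, the pipeline cannot attribute individual
  mismatches to transcription, and only paired-design comparisons are
  meaningful.
* All conclusions about scenario discrimination are conditional on the
  package's calibrated defaults; the original kinetic values are
  unpublished.
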