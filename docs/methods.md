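# Methods

`cupore` analyses single-channel current recordings from a
copper(II)-functionalized MspA (N91H) nanopore that senses free amino
acids. This note documents the generative model behind the synthetic
recordings, the detection and inference procedures, the numerical choices,
and what the package's tests do and do not demonstrate about real data.

## Signal model

A recording is a uniformly sampled current trace (pA). Three current
levels matter:

* **I\*** — the open-pore current, observed when no copper ion occupies
  the constriction ("state \*");
* **I0** — the copper-bound baseline ("state 0"), the reference level for
  all blockade measurements;
* **I1** — the level while one amino acid is coordinated by the
  copper–histidine complex ("state 1").

An event is characterised by its fractional **blockade**
`(I0 − I1) / I0`, its **dwell time** Δt (ms), the standard deviation of
its in-event current, and a 1,000-point **density feature vector**: the
kernel density of the I0-standardized in-event samples evaluated at
0.001, 0.002, …, 1.000 (features `X0001`–`X1000`). Occasional events show
a second, deeper sub-level ("state 2"), treated phenomenologically (the
physical origin — a second bound molecule or noise — is not modelled).

## Synthetic recordings (`cupore.simulate`)

The simulator emulates the statistical structure of the recordings, not
the electrochemistry:

* Baseline `I0` with i.i.d. Gaussian noise (`noise_sd`, default 1 pA on a
  100 pA baseline).
* Copper occupancy: two-state alternation between I0 and I\* with
  exponential residence times tuned so the long-run state-0 fraction
  equals `copper_occupancy` (default 0.878). Only the occupancy fraction
  is constrained by measurement; the exponential kinetics and the mean
  open-pore residence (50 ms) are package choices.
* Binding events: arrivals are a homogeneous Poisson process with
  per-class rate `capture_rate × concentration` (min⁻¹); blockade is drawn
  per event from the class Gaussian; dwell is exponential with the class
  half-life; within-event samples carry the same Gaussian noise.
  Overlapping arrivals are rejected and counted; a request whose rejection
  fraction exceeds 50% fails loudly. Copper excursions are placed in the
  gaps between events, so the nominal event rate is realised exactly and
  the occupancy target is exact on blank traces (on busy traces the
  state-0 fraction is correspondingly reduced by event time).
* State-2 events: with probability `state2_prob` (default 0.05) the middle
  third of an event drops a further 0.08 fractional blockade.
* Blank controls: sparse artifacts (Poisson, `artifact_rate`/min) whose
  samples are uniform over a wide blockade band — a broad, *flat*
  amplitude density, unlike the sharply peaked density of a binding event.
  This is the designed contrast that the KNN background filter exploits.
* The 2 kHz four-pole Bessel filter of the recording hardware is
  approximated, optionally, by a moving-average smoother (off by default).

**Parameter table.** Five numbers in the packaged table are calibrated to
published measurements: the blockade means/s.d. of S (0.132 ± 0.0033),
P-S (0.295 ± 0.0093), K (0.171 ± 0.0026), Ac-K (0.233 ± 0.0071) and the
His1 dwell half-life (42.7 ms). Histidine appears as two classes (His1,
His2) reflecting its two binding populations. All other entries are
synthetic placeholders (flagged `calibrated=False`) spread over the
plausible blockade range 0.10–0.36, with dwell half-lives of 1.5–8 ms and
capture rates of 0.05–1.2 events·min⁻¹·µM⁻¹ (proline rarest, polar side
chains more frequent than non-polar). Consequences: any analysis whose
outcome depends on the *relative geometry* of non-calibrated classes
(e.g. how confusable N and L are) reflects these choices, not the pore.

**Sampling rate.** The default is the instrument rate, 100 kHz. Tests and
the acceptance script use the reduced-rate mode (`TraceConfig.fast()`,
2 kHz — the analogue filter bandwidth, so little information is lost)
to keep desk-scale runs fast. At 2 kHz the shortest segmentable event is
2.5 ms (5 samples); dwell-time and detection-efficiency statements below
that scale are rate-dependent.

**Hydrolysis.** Exopeptidase digestion is a sequential-cleavage model:
residues are removed one at a time from the enzyme's terminus
(C for carboxypeptidase A1, N for leucyl aminopeptidase) at
`cleavage_rate` per minute, so the m-th residue from the terminus is
released with probability `P(N ≥ m)`, `N ~ Poisson(rate × time)`.
Carboxypeptidase A1 cannot release R, K or P: when one becomes terminal,
hydrolysis halts permanently and all deeper residues stay at zero. The
model ignores residue-specific rate constants beyond the stop rule.

## Detection (`cupore.signals`)

1. **Change points.** Penalized exact search (PELT) under the Gaussian
   mean+variance cost `n·log(σ̂²)` per segment. The penalty defaults to
   `5·log(n)` per change point — large enough that homogeneous noise is
   not split (spurious likelihood-ratio gains grow like `2·log n`), small
   enough that a 5-sample event 13 pA deep in 1 pA noise is isolated with
   a wide margin. Segment variance is floored at `10⁻⁶ × var(trace)` so
   noiseless step traces stay finite; minimum segment length is 5
   samples. Traces longer than 200,000 samples are segmented chunk by
   chunk; chunk boundaries are emitted as breaks, which downstream event
   extraction merges across, so only the bookkeeping — not the event
   set — depends on the chunking. On short traces the search is exact and
   is verified against exhaustive enumeration in the tests.
2. **Polish.** Each segment is replaced by its arithmetic mean.
3. **Baseline.** I0 is the duration-weighted mode of segment levels (the
   tightest 2%-wide cluster carrying the most time), re-estimated in
   30-second windows for drift. Events sit far below the mode and copper
   excursions above it, so neither biases it. If no cluster covers 20% of
   the recording, there is no stable baseline and the estimate fails
   loudly.
4. **Events.** Maximal runs of segments at least `min_blockade = 0.1`
   below I0; I1 is the duration-weighted mean over the run; runs shorter
   than `min_dwell_ms = 0.5` are dropped; segments *above* baseline
   (copper excursions) are never events. Sub-segments differing by more
   than 5% of I0 are counted as sub-levels; events with more than one
   sub-level are flagged (state 2) and excluded from classifier training
   but kept in event tables.
5. **Features.** Gaussian KDE (Silverman bandwidth) of the raw
   (not polished) standardized in-event samples on the fixed grid; raw
   samples are the default because polishing collapses within-event
   structure the classifier may use. Standardized samples outside
   [−0.5, 1.5] mark a corrupt event and raise.

**Fits.** Dwell half-lives come from a least-squares fit of
`exp(−t·ln2/t½)` to the empirical survival function (reported s.e. is the
larger of the curve-fit s.e. and the parametric `t½/√n`). Blockade
distributions are Gaussian fits to the blockade histogram; a point mass
short-circuits to (value, 0). Both require ≥ 30 events and fail loudly on
degenerate input.

## Background filtering (`cupore.background`)

Signals are pooled with an equally sized seeded random subsample of
blank-control events; all 1,003 features are z-scored across the pool
(unscaled distances would be dominated by dwell); a signal is removed when
any of its k = 10 nearest pool neighbours (self excluded, ties broken by
pool index) is a blank. The removal decision is reproduced by brute-force
enumeration in the tests.

## Classification (`cupore.classify`)

One whole experiment per class is held out for validation; 80% of the
remaining events (per class) train, the rest test; training classes are
resampled to exactly 1,000 rows (upsampling with replacement below,
downsampling without replacement above — plain row resampling, no
jitter). Six scikit-learn families are wrapped (RF, Gaussian NB, a
single-hidden-layer MLP of ~√1003 ≈ 32 units, KNN, bagged trees,
AdaBoost) behind one interface with stratified k-fold cross-validation
(default tenfold). Multi-class AUC is macro-averaged one-vs-rest.
The accuracy/recovery trade-off keeps events whose maximum class
probability meets a threshold and reports retained fraction and accuracy;
no monotonicity is asserted, it is an empirical curve.

## Quantification (`cupore.quantify`)

Signal frequency is count/duration (per minute, total recording time —
the copper-unbound fraction is *not* excluded). Calibration is OLS of
frequency on concentration with Pearson R, p, and adjusted R²; inversion
propagates the joint slope/intercept covariance by the delta method. The
limit-of-detection criterion is strict: a class is detectable iff some
continuous 10-minute window (slid at 1 s) contains **more than five**
(≥ 6) confident calls.

## Hydrolysate inference (`cupore.hydrolysate`)

Confident calls (max probability strictly > 0.95) are counted per class
and converted to molar percentages by dividing by per-class rates and
renormalising to 100%. The rate table is the caller's choice; the
recommended normaliser is the **measured** confident-call frequency of
single-class standards run through the identical pipeline, because it
cancels class-dependent detection and probability-threshold retention —
normalising by the generative capture rate alone leaves those
efficiencies in and can distort abundances when classes with adjacent
blockades lose more calls to the threshold.

The positional trend is Spearman's ρ between abundance and proximity to
the cleavage terminus (positive = more abundant nearer the terminus),
with an exact permutation p-value for up to 8 positions. The reference
sequence supplies the positional axis and may differ from the digested
peptide: correlating two same-composition hydrolysates against one common
axis is what makes a reversed sequence show the opposite sign. Repeated
residues share their class abundance at every occurrence (mid-ranked
ties); stop residues are excluded from the axis.

Peptide profiles pool all standardized in-event samples of one peptide
into a single 1,000-point density; peptides are compared by Euclidean
distance and embedded with classical (Torgerson) MDS — double-centred
Gram matrix, top positive eigenpairs — which reproduces
Euclidean-embeddable distances exactly and warns when the negative
spectral mass exceeds 5%.

## What the tests show — and what they cannot

The acceptance suite regenerates every quantity from scratch at desk
scale: ~5,000 simulated events per class for the blockade and dwell
recoveries, a 4-class / ~4,000-row training matrix for the classifier
checks, 8-minute traces per point for the calibration series, 20-minute
traces per peptide for the digestion trends, and a 10-minute blank for
the occupancy estimate, all at 2 kHz. Passing shows the pipeline is
self-consistent and unbiased under the stated generative model. It does
not validate the model against real pores: real recordings have 1/f and
50/60 Hz noise, baseline drift beyond the simulated step kinetics,
concentration-dependent capture, and 20-class confusability determined by
the true blockade geometry rather than the synthetic placeholder table.
Published 20-class accuracies and per-class limits of detection depend on
those real calibrations and are out of scope by design.

## Degenerate inputs and tie-breaks

Constant traces segment to nothing; a constant dwell or abundance vector
raises rather than returning NaN; a point-mass blockade sample returns
s.d. 0 without fitting; KDE of a near-degenerate sample falls back to a
narrow fixed bandwidth (5×10⁻⁴) so the density is a sharp peak at the
value; KNN distance ties break by pool index; MDS axes with non-positive
eigenvalues are zeroed. Sample indices are 0-based and event intervals
half-open `[start, end)`.
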