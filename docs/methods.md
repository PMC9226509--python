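# Methods

`vfret` simulates and analyzes single-molecule FRET experiments in which a
telomeric G-quadruplex (G4) overhang folds *vectorially* — while an enzyme
releases the G-rich strand one nucleotide at a time — and contrasts the
outcome with conventional *post-folding* (pf), where the whole strand is
free at once. This note documents the generative model, the measurement
model, the analysis estimators, and the choices made where the design was
genuinely open.

## Kinetic model

Each molecule is an independent continuous-time state machine:

```
DUPLEX --(enzyme arrival)--> UNWINDING(1..L nt) --> UNFOLDED_SS
     --(Exp(k_fold))--> [INTERMEDIATE --(Exp(k_int))-->] FOLDED(conformer)
     --(Exp(k_on·[ligand]), gated)--> BOUND (absorbing)
```

* **Strand release.** After the enzyme arrives, each of the `L` overhang
  nucleotides is released after an independent exponential waiting time at
  the per-nucleotide rate `k_nt`. For the helicase (Rep-X) mode `k_nt`
  follows a Hill-type ATP dependence
  `k_nt = k_cat·S^2/(K^2+S^2)` with `K = 2 mM`, `k_cat = 1601 s^-1`,
  anchored at two observations: 50 µM ATP slows unwinding to exactly
  1 nt/s (the telomerase-speed condition), while saturating ATP (1 mM,
  ~320 nt/s) releases a 24-nt overhang well inside one 100 ms camera
  frame, so the duplex-to-high-FRET transition looks instantaneous. A
  simple Michaelis–Menten law cannot satisfy both anchors (its dynamic
  range between 50 µM and 1 mM is at most ~20×), which is why a Hill
  coefficient of 2 — plausible for a helicase hydrolyzing multiple ATP per
  step — is used. The exonuclease mode digests at a constant,
  ATP-independent 12 nt/s (typical λ-exonuclease processivity).
* **Enzyme arrival.** Nominally 10 s after flow start, plus a per-molecule
  uniform jitter of 0–4.2 s. Arrivals in a real flow cell are not
  perfectly synchronous; the jitter width is chosen as roughly one
  excitation cycle so that folding events decorrelate from the
  alternating-laser phase (a perfectly synchronized cohort would place
  every fast release inside the same excitation gap, a sampling artifact
  no real experiment has).
* **Folding.** Once the last nucleotide is free, the strand folds after an
  `Exp(k_fold)` wait with `k_fold = 1/0.41 s^-1` for every construct — the
  one-step dwell shared by G2–G4 and c-Myc. With probability
  `p_multistep` (G3 0.27, G4 0.33, exonuclease mode 0.02, G2/c-Myc 0) the
  molecule instead visits a single intermediate level before completing,
  leaving it at rate `k_int = 0.2 s^-1` (mean 5 s — seconds-scale, as
  two-step traces show, but not so long that photobleaching censors most
  of them; the paper-free choice is documented below).
* **Conformers.** The folded level is drawn from the preset's conformer
  weights. The multi-step (presumably 5′-initiated) pathway terminates in
  the high-FRET conformer; this coupling is both physically motivated (a
  distinct pathway can reach a distinct fold) and necessary for
  classifiability — with the duplex at 0.5 and conformers at 0.65–0.70, no
  intermediate level could otherwise sit ≥0.07 away from all of its
  neighbours. Slow vf→pf conformer relaxation is a re-draw from the pf
  weights at `k_relax = 1/(3 h)`.
* **Ligand capture.** A per-molecule Bernoulli gate with probability
  `accessible_fraction` decides whether capture is possible at all; gated
  molecules bind irreversibly after an `Exp(k_on·c)` wait once folded.
  C2 (250 nM) and POT1 (500 nM) both use `k_on·c = 0.05 s^-1`
  (plateau within ~2–3 minutes). The gate reproduces plateaus below 100 %
  without invoking exchange dynamics; whether the real sub-populations are
  static is unresolved, and the gate is one admissible reading.

### FRET levels

Duplex 0.50 everywhere. Conformer levels follow the reported histogram
peaks: G2 0.75/0.90, G3 0.65/0.80, G4 0.70/0.85, c-Myc 0.90 (single),
poly-T 0.35, bound state 0.30. The single-strand (ramp-end) level and the
intermediate level are free choices, spaced so that every level along one
molecule's path is separable at the classifier's ±0.07 band: G2 ss 0.60;
c-Myc ss 0.65; G4 ss 0.58 with the intermediate midway to the multi-step
terminal conformer (0.715); G3 ss 0.40 (below the duplex — a
construct-specific dye geometry choice forced by the narrow 0.50–0.65
corridor) with the intermediate at 0.60. During unwinding the true FRET
interpolates linearly in released-nucleotide count from duplex to ss.

## Measurement model

Frame-integrated intensities at 100 ms: the true level is time-averaged
over each frame, donor and acceptor signals partition `I_tot = 1000`
counts as `(1−E, E)`, donor leakage `l = 0.07` adds to the measured
acceptor, and Gaussian noise (sd 60 counts) is added per channel.
Excitation alternates cyclically; two patterns are used, mirroring real
practice:

* **histogram movies** — 10 green / 1 dark / 10 red frames, the dense red
  interleave the donor-only filter was designed around;
* **kinetics movies** — 40 green / 1 dark / 2 red. Real-time folding and
  binding assays need near-continuous green excitation (a 0.41 s dwell
  cannot survive a 48 %-blind duty cycle), while the sparse red probe still
  flags dark acceptors and acceptor photobleaching.

Donor and acceptor bleach independently (both mean 200 s). A donor-only
sub-population (default 10 %) is rendered with the acceptor dark from the
start. PIFE (exonuclease mode only) multiplies the donor by 1.5 while the
enzyme is in contact, which lowers apparent FRET during digestion.

## Analysis estimators

* **Preprocessing.** `E = I_A/(I_D+I_A)` (uncorrected proximity ratio; no
  gamma correction). Donor-only molecules are flagged from the first two
  red blocks and excluded; dataset leakage is estimated from their mean
  apparent FRET (`l = E0/(1−E0)`) and removed at intensity level. Donor
  bleach truncates at a sustained collapse of total intensity (<25 % of the
  initial median for ≥5 frames); acceptor bleach truncates one full cycle
  before the first dark red block, and frames after the last red block
  (unverifiable) are dropped.
* **Idealization.** Penalized least-squares segmentation
  (optimal-partitioning dynamic program, L2 cost, penalty
  `3·σ̂²·ln n`, minimum segment 2 frames, robust σ̂ from median absolute
  first differences). Interior segment boundaries are reported midway
  between the adjacent samples, which keeps event times unbiased when a
  transition falls inside an excitation gap.
* **Classification.** Segment means are matched to preset levels with a
  ±0.07 band. The final level is the last conformer-band segment (the
  intermediate level competes as a decoy so a trace truncated mid-
  intermediate is not called folded; a persistent bound-band tail overrides
  the decoy because irreversible capture proves the fold completed).
  Fold entry and ramp completion are refined by matched two-level step
  fits with the levels held fixed — immune to the level-merging ambiguity
  of free-mean segmentation and able to resolve single-frame plateaus.
  Near-ties break toward the latest boundary with a margin of
  1.5·(level gap)·σ̂, cancelling the early-boundary drift that noise
  induces (validated against simulator ground truth: the mean dwell is
  recovered within ~2 % under default noise). Intermediate runs must hold
  ≥2 frames near the intermediate level; a fixed-level chain fit
  (duplex→ss→intermediate→final, acceptance threshold 15·σ̂²) rescues
  short intermediates that segmentation smooths over, at a measured false-
  positive rate below 0.2 %.
* **Dwell kinetics.** The folding dwell runs from ramp completion to
  folded-band entry; sub-resolution dwells enter as 0 rather than being
  dropped (survivor bias would otherwise inflate the 0.41 s mean). The
  rate is the exponential MLE `1/mean` (binned least-squares decay
  available for parity with histogram fitting).
* **Folding-fraction curve.** Cumulative folded fraction versus time since
  mean enzyme arrival (nominal + half the jitter), fitted with
  `A(1−e^{−kt})`. The amplitude is anchored at the observed plateau: a
  two-parameter fit of a lagged sigmoid with an exponential is ill-posed
  and can collapse into a small-k/large-A minimum.
* **Accessibility.** Per-molecule irreversible capture times (first
  post-fold entry into the bound band, E < 0.45, with no later return and
  ≥1 s of persistence) feed a Kaplan–Meier estimate of the cumulative
  bound fraction — censored molecules are retained, not discarded — fitted
  with `A(1−e^{−kt})`; with ≥30 events the amplitude is anchored at the
  KM plateau.
* **Histograms.** First 21 green frames per molecule inside the analysis
  window, binned on [−0.1, 1.2], unit area. Mixtures are fitted to the
  binned density by least squares with unconstrained means (5 seeded
  starts), sd floor 0.01, and BIC selection; a higher K wins only when its
  components are separated by at least twice the broader width and carry
  ≥2 % mass each, which stops noise-splitting of single peaks.

## What the simulation does and does not capture

The generator reproduces the features that drive the analysis: directional
release with an ATP-tunable ramp, abrupt folding with exponential dwells,
two competing pathways, conformer-specific levels, donor-only molecules,
leakage, photobleaching, ALEX gaps, PIFE, and gated irreversible capture.
It does **not** model photon-level statistics (Gaussian, not Poisson,
noise), dye blinking, spectral crosstalk beyond a single leakage constant,
flow or diffusion physics (arrival is a configured time plus jitter),
enzyme pausing or slippage, or any structural identity of the conformers —
"conformer" here is only a FRET level with a weight. Passing tests
therefore demonstrate that the estimators recover the parameters of this
generative class at realistic noise, not that they would be artifact-free
on real movies (baseline drift, stage drift and blinking are the usual
extra failure modes).

Quantities measured from classified ensembles carry the same censoring a
real experiment has: molecules that bleach before folding (or mid-
intermediate) are excluded, which depletes the slower multi-step pathway
by a few percentage points relative to its generative probability — the
measured multi-step fraction for G3 centers near 23 % for a generative
27 % at these bleach rates. This is a property of the measurement, not an
estimator defect, and the same censoring acted on the real data the
target fractions come from.

## Problem sizes and numerical choices

Analysis cohorts use n = 300 molecules (n = 500 for dwell statistics),
40–60 s kinetics movies, and 240 s binding movies — enough that binomial
error on a fraction is ~±2.7 points and the dwell mean is determined to
~5 %. Degenerate inputs are defined: zero-noise traces segment exactly
(penalty floor), zero-total-intensity frames yield NaN FRET samples that
are dropped, all-censored binding sets report amplitude 0 with a
`plateau_reached=False` flag, and all-identical dwell sets raise.
Reproducibility: every cohort derives per-molecule seeds from the master
seed via `numpy.random.SeedSequence.spawn`, so cohorts are bit-identical
across runs and independent of iteration order.
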