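# Methods

## The analysis problem

A raised line of orientation θ ∈ {−10, −5, +5, +10}° (relative to the axis
perpendicular to the scan direction) embossed on a rotating drum (diameter
59 mm, 20 lines ≥ 8 mm apart, 5 copies per orientation) sweeps across the
receptive field of one first-order tactile afferent at a constant speed
v ∈ {15, 20, 30, 45, 60, 90, 120, 180} mm/s; three drum rotations give 15
trials per orientation × speed. The question the package answers is how well
an ideal observer can identify θ from that single neuron's spikes — within
one speed, and across speeds — and at what spatial scale the orientation
signal lives.

## Trial segmentation and the spatial domain

Spike times are converted to drum positions by linear interpolation of the
encoder trace. Each line passage is cut to an 8 mm response window (the
minimum spacing between lines). The registration of the window to the line is
a free choice; we centre it, per neuron and physical line, on the centre of
mass of the pooled response to that line (all speeds and rotations, ≥ 10
spikes required; nominal line position otherwise, flagged). This registration
is deterministic and identical across speeds, which matters because the
across-speed analyses correlate signals on a shared position grid. Windows
are closed intervals: a spike exactly on a boundary belongs to the window.
Windows that would protrude past the recorded trace are clamped inside it and
flagged.

## Response measures

* Peak rate: reciprocal of the shortest inter-spike interval in the window;
  trials with < 2 spikes return 0 Hz and are flagged (frequent at
  120–180 mm/s, where counts are low).
* Mean rate: spike count ÷ the *measured* traversal time of the window.
* Rate profile: piecewise-constant instantaneous frequency — the value 1/ISI
  held over each inter-spike interval (left-closed, right-open), zero outside
  the response. Temporal grids default to 1 ms; spatial grids to 10 µm
  (~3× the 3 µm encoder resolution). Under a constant-speed trace the two
  domains are exact reparametrizations (x = v t).

## Ideal-observer decoding

All decoders are leave-one-trial-out and strict: the held-out trial is
assigned the orientation whose reference it matches strictly best, and ties
count as errors (they arise only for degenerate, e.g. spikeless, signals).
Within a speed, the reference for every candidate orientation is built from
14 trials — the same-orientation mean excludes the held-out trial, and the
other orientations drop the trial with the same rotation/presentation index —
so all references have equal sample size and the held-out trial never
informs any reference. Across speeds, each core-speed trial is compared with
the full 15-trial references at every other speed. Intensity decoders use
absolute distance to the reference mean; profile decoders use the mean
zero-lag Pearson correlation (windows are registered by drum position, so a
lag search would be redundant; zero-variance signals correlate 0 with
everything).

Temporal-domain cross-speed comparisons start-align profiles on an absolute
time grid and zero-pad to the longer window duration. Zero-padding (rather
than truncating to the shorter window) avoids reducing slow-speed trials to
empty segments when compared against fast-speed references, while still never
rescaling time — rescaling would covertly re-create the spatial domain and
void the temporal/spatial contrast.

The speed-normalization control divides every intensity by a linear
population fit of mean intensity on speed (OLS per neuron type). When the
fitted line is not positive over the speed range — which happens for measures
that *decrease* with speed, such as the synthetic SA-1 peak rate — the
normalized variant is skipped with an explicit log line rather than dividing
by a non-positive rate.

In the confusion matrix (and only there) strict-rule ties split their
assignment mass uniformly over the tied orientations, so that every
4-column block of every row sums to exactly 1.

## Spatial precision (best kernel)

Spatial spike trains are deposited on a grid (linear cloud-in-cell weights)
and convolved with unit-mass Gaussian kernels, SD σ on a doubling grid
5–1280 µm, kernel support truncated at ±5σ, grid step = max(2 µm, min σ / 2)
(the step must satisfy step ≤ σ/2). For each σ and core speed the mean
squared Pearson correlation over cross-speed trial pairs (within-speed pairs
excluded, equal weight per pair) is averaged separately for same- and
different-orientation pairs; the difference is an inverted U in log σ whose
argmax σ* (ties → smaller σ; flat curves → flagged and excluded) is the
per-speed best kernel, and a neuron is summarised by the mean of σ* across
speeds. An optional log-parabolic interpolation through the peak and its two
neighbours refines interior maxima — without it the estimate is quantized to
the doubling grid, which matters when comparing nearby precision levels.
Plain r instead of R² is available by flag.

The equivalent sinusoidal period P of a Gaussian SD σ minimises
∫ (exp(−x²/2σ²) − (1+cos 2πx/P)/2)² dx over one period; by scale invariance
P = cσ with c ≈ 4.9215, computed once at run time by bounded minimisation of
an adaptive-quadrature integral and cross-checked in the tests against an
independent Gauss–Legendre/golden-section oracle.

## The synthetic afferent model

Each model neuron has n Gaussian subfields (FA-1: n uniform 10–24; SA-1:
5–12 — about half, mirroring the innervation anatomy) at uniform positions in
an ellipse (semi-axes 2500 µm along the scan direction × 1500 µm across it),
with amplitudes 0.3–1.0 and SDs σ_sub 40–90 µm. The drive of an edge with
scan-axis intercept x is Σᵢ aᵢ exp(−dᵢ²/2σᵢ²) with dᵢ the perpendicular
distance from subfield i to the (zero-width, infinite) line; the 0.5 mm
physical line width is not modelled, as edge responses are dominated by the
leading edge.

Spiking is a *frozen-pattern* scheme. Once per neuron, each subfield draws a
Poisson number of burst events (mean ∝ gain × aᵢσᵢ at a 10 mm/s reference
speed) at Gaussian offsets around its centre, and a single recruitment
strength uᵢ ~ U(0,1). A trial at speed v expresses the bursts of the
subfields with uᵢ < (v/10 mm/s)^(β−1) (capped at 1), each spike independently
with probability 0.9, shifts all positions by the trial's jitter
δ ~ N(0, j²), adds a Poisson background (2 Hz), and applies absolute
refractory thinning (1 ms default, 0.5 ms floor). Marginally each trial is an
inhomogeneous Poisson process with rate g (v/v₀)^β × drive + background
(v₀ = 30 mm/s; β = 0.6 for FA-1, 0.2 for SA-1; gains 200–350 / 130–230 Hz),
expected count ∝ v^(β−1), and the same orientation geometry as the drive.
The departures from trial-independent Poisson sampling are deliberate:

* real afferents repeat their spike patterns closely across passes of the
  same stimulus, and the spatial-precision estimator *measures* that
  repeatability — with independent Poisson draws per trial, spike placement
  noise inside the subfield envelope imposes a ~40–90 µm floor on the
  recovered best kernel that no realistic firing rate removes, and the jitter
  knob j becomes unrecoverable;
* recruiting whole subfields (rather than individual spikes) as speed falls
  keeps cross-speed spike sets nested at burst granularity, so shared bursts
  match exactly up to jitter.

Costs of these choices, stated plainly: per-neuron spike counts step discretely
when a subfield crosses its recruitment threshold, so the rising-rate /
falling-count trends hold in expectation and at the population level rather
than trial-by-trial for every neuron; and the observed *peak* rate
(an order statistic ∝ v^(2β−1) under these dynamics) rises with speed only
for β > 0.5, i.e. for the FA-1 default and not the SA-1 default. No fingertip
continuum mechanics (viscoelasticity, anisotropy, ridge-level deformation) is
modelled.

What a green synthetic test establishes, therefore, is that the *analysis*
behaves correctly on data with the assumed statistical structure —
speed-invariant spatial patterning, controllable jitter, speed-dependent
intensity — not that the generator reproduces fingertip biomechanics.

## Reference experiments and their design

* Chance calibration shuffles orientation labels within each neuron × speed
  (one shared permutation across decoding schemes) and checks every decoder
  against its chance level. The calibration cohort uses β = 0.8 so that even
  180 mm/s trials keep enough spikes: the documented tie→incorrect rule
  scores spikeless trials wrong deterministically, which would bias any null
  containing degenerate trials below chance (that convention is tested
  separately on constructed degenerate inputs).
* The spatial/temporal contrast uses j = 20 µm, β = 0.5, all 8 speeds.
* Jitter recovery fixes one frozen FA-type layout for all 30 records
  (6 replicates × j ∈ {10, 20, 40, 80, 160} µm) and uses dense punctate
  spiking (gain 800–1200 Hz, σ_sub 10–25 µm, minor axis 900 µm, 0.5 ms
  refractory) with peak interpolation. Receptive-field geometry is a nuisance
  variable for an estimator-recovery experiment — the best kernel also
  reflects each neuron's orientation-shift scale |c_y·Δtanθ| — so it is held
  fixed, as one would calibrate an instrument on a known phantom.

## Numerical and degenerate-input conventions

* Ties in any strict argmax/argmin: incorrect (confusion matrix: mass split).
* Zero-variance signals: Pearson correlation defined as 0.
* Trials with < 2 spikes: peak rate 0 Hz, all-zero profile, flagged.
* Best-kernel ties: smaller σ; flat difference curves: NaN, neuron flagged.
* Canonical CSVs are written with `%.17g` and read with round-trip float
  parsing, so save→load is bit-exact and same-seed runs are byte-identical.
* Statistical testing is limited to one-tailed one-sample t-tests with
  Bonferroni correction across speeds (zero-variance groups decided by sign
  and flagged); repeated-measures ANOVA belongs to external tools, and the
  tidy per-neuron tables are shaped for them.
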