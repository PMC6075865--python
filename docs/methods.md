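# Methods

This note documents the models, conventions and numerical choices behind
`exophys`, and what the synthetic-data generators do and do not emulate.

## Flash-evoked capacitance decomposition (`capfit`)

**Model.** After Ca²⁺ uncaging, the membrane capacitance rises as

    CM(t) = A0 + A1·(1 − exp(−t'/τ1)) + A2·(1 − exp(−t'/τ2)) + k·t'

with `t' = t − t0` the time since the burst onset `t0`. A1/τ1 describe the
readily releasable pool (RRP), A2/τ2 the slowly releasable pool (SRP), k the
sustained component, A0 the pre-flash cell capacitance. Components are zero
for `t < t0` and the baseline continues, so the trace is continuous at the
onset.

**Secretory delay.** The classical definition — the interval between the
flash and the intersection of the back-extrapolated fast exponential with the
baseline — is realized by fitting `t0` as a free parameter. For an
exponential rising from the baseline these constructions coincide, and a
free onset is numerically better behaved than a post-hoc geometric
intersection of two fitted curves. The delay is `t0 − t_flash`, bounded to
[0, 50] ms by default.

**Optimization.** Damped least squares (trust-region reflective) restarted
from a grid of time-constant guesses (τ1 ∈ {10, 30} ms, τ2 ∈ {150, 400} ms),
amplitude guesses from trace quantiles; the lowest-residual solution wins,
ties broken toward the smaller τ1. Bounds bracket the physiological range:
τ1 ∈ [1, 100] ms, τ2 ∈ [50, 2000] ms, amplitudes ≥ 0. The sustained rate k
is deliberately unconstrained so a negative fitted slope is reported rather
than hidden (whether it should be clamped at zero is a modelling choice the
caller can make downstream). RRP/SRP labels are assigned by τ ordering after
the fit, never by parameter position, so optimizer paths cannot swap pools.
On noiseless generator traces all five parameters and the delay are
recovered to better than 1e-6 relative (see the test suite), which is the
designed oracle-equivalence property of the generator/fitter pair.

**Tonic rate and ΔCM.** The tonic (premature) secretion rate is the
least-squares slope of CM over a pre-flash window, in fF/s. Total ΔCM over
an interval uses median-smoothed endpoints (1 s window by default,
configurable to 0 for exact endpoints) to suppress sampling noise.

## Amperometric analysis (`ampero`)

**Detection.** The baseline is a running median over 200 ms — robust to the
sparse, strongly skewed events — and the noise SD is estimated from the MAD
of the residual (the MAD of a noiseless trace is zero; the estimator then
degenerates gracefully instead of inflating the threshold with event power).
Events are threshold crossings at baseline + 4·SD that persist ≥ 0.2 ms,
with hysteresis down to +2·SD and boundaries at the surrounding baseline
re-crossings. The printed cuts — amplitude > 4 pA with charge in
10–5000 fC (frequency analysis) and amplitude > 7 pA (kinetics) — are
applied as *eligibility flags after* detection, not as detection thresholds.

**Kinetics.** Amplitude is peak minus baseline; charge the trapezoid
integral of baseline-subtracted current over the event (1 fC = 1 pA·ms);
rise time from the 50% to the 90% crossing on the rising limb; half-width
at 50% of peak, all with linear interpolation between samples. Events whose
50%-level profile shows more than one peak are flagged as overlaps and
their kinetics omitted — overlapping events are superposed, never
deconvolved.

**Foot.** The prespike foot runs from the first sustained rise above
baseline + 3·SD to the main-spike takeoff. The takeoff is the maximum of
the second derivative on the upstroke; the search is anchored at the last
sample below 30% of the peak (±0.8 ms) so curvature at the foot-onset ramp
or at injected flickers cannot masquerade as the takeoff. Feet shorter than
2 ms are reported but flagged not analyzable, and flicker analysis refuses
them. With the log-normal spike template this takeoff criterion sits
~0.3 ms into the visible upstroke, a constant small bias shared by any
curvature-based takeoff definition.

**Flickers.** Within an analyzable foot the current derivative is low-pass
filtered at 1.2 kHz; each contiguous run beyond ±6 pA/ms counts as one
fluctuation (polarities counted separately, then summed), and a run that
reaches the end of the foot is the spike upstroke itself and is excluded.
The flicker frequency is count/duration (1/ms). The threshold is the fixed
printed value by default; an adaptive 4·SD-of-derivative mode can be had by
passing a different threshold. The rms foot noise — a threshold-independent
companion measure — is computed after removing a 3rd-order polynomial trend
(the slow foot ramp) from the foot current.

**Aggregation.** Per cell, the median of each parameter over that cell's
events; across cells, the unweighted mean ± SEM of the medians, so every
cell counts equally regardless of how many events it fired. Cells with ≤ 20
events are excluded from the across-cell mean by default (flagged, not
dropped from the table).

## SNARE assembly kinetics (`snarekin`)

The integrated second-order law for A + B → P with equal initial
concentrations,

    SC(t) = SC0 + (SC∞ − SC0) · A0·k·t / (A0·k·t + 1),

is fitted by least squares in (SC0, SC∞, log k); k is parameterized on the
log scale for positivity and conditioning. A0 and k are not separately
identifiable from one curve, so A0 is fixed at the limiting reactant
concentration (3 µM by default, per the assay design). Times are entered in
minutes and converted to seconds so k carries its conventional 1/(M·s)
units. Flat data collapse SC∞ − SC0 to zero and leave k unidentified; such
fits are flagged rather than reported as converged. Normalization to the
value at a reference time (240 min by default) uses the nearest sample
within a tolerance; fitting before or after normalizing gives the same k on
noiseless data.

Group comparison: Kruskal-Wallis across groups, Dunn's rank post test
against the control (z on pooled mean ranks with tie correction; Bonferroni
adjustment over the comparisons made, switchable to none), and rates
reported as percent of the control mean with SEM by first-order error
propagation. Because replicates are not paired across groups, the relative
rate is a ratio of group means, not a mean of per-replicate ratios.

## Mimicry scoring (`helixmim`)

**Similarity.** A position is *similar* when its BLOSUM62 entry is strictly
positive, identities included — the convention of classical global-alignment
tools, and the one that reproduces the published 18-residue fractions (9/18,
5/18, 7/18, 3/18) for the CpxII-CTD/SNARE comparisons. Equal-length
segments are compared gaplessly; unequal lengths are globally aligned with
affine gaps (open 10, extend 0.5), and the percentage is taken over aligned
columns. For all four bundled segment pairs the optimal global alignment is
gap-free, so both modes agree there.

**Hydrophobic moment.** µH = (1/N)·|Σ H_n·e^(i·n·δ)| with the Eisenberg
normalized consensus scale and δ = 100°/residue; the scale is a named,
swappable table. µH is invariant to the phase origin and bounded by the
largest per-residue hydrophobicity.

**Segments.** The bundled comparison windows are the 18-residue
hydrophobic-layer (+2…+7) regions of the mouse proteins: CpxII 117–134
(the last 18 residues of the CTD peptide), SNAP25a SN1 60–77, SNAP25a SN2
181–198, SybII 63–80 and Syntaxin-1a 233–250. Note the SN1 window is
specific to the SNAP25a splice variant; the SNAP25b window at the same
coordinates differs at several exon-5 positions and gives visibly different
similarity and moment values.

## Synthetic data (`synthio`)

All generators draw every random number from one integer seed per call and
return bitwise-identical output for identical parameters.

* **Flash traces**: the closed-form response above plus an optional tonic
  pre-flash ramp and additive white Gaussian noise (5 fF SD default, 2 kHz
  sampling, flash at 0.5 s into a 5.5 s sweep; burst defaults 150 fF/20 ms
  and 200 fF/250 ms with 15 fF/s sustained — typical chromaffin values).
  The flash-locked component starts at the back-extrapolated baseline value
  at flash + delay, so delay recovery is well-posed by construction.
* **Amperometric traces**: Poisson-placed events at 25 kHz, low-pass
  filtered at 2 kHz with a Gaussian FIR whose −3 dB point sits at the
  cutoff (σ_t = √(ln 2)/(2π·f_c); family and cutoff recorded in trace
  metadata). The main spike is a log-normal pulse parameterized by
  amplitude (log-normal across events, median 35 pA), 50–90% rise time
  (0.3 ms) and half-width (2.5 ms), so its kinetics are analytically
  controllable and its charge has a closed form. Feet are ramp-to-plateau
  precursors (ramp slope 4 pA/ms, below the flicker threshold); flickers
  are derivative pulses — a fast rise at a settable slope (12 pA/ms
  default, exercisable from both sides of the 6 pA/ms threshold) followed
  by a 6× slower sub-threshold return. Flicker onsets are spaced
  (≥ duration + 0.6 ms) so each injected pulse keeps its own
  suprathreshold derivative run after filtering; the truth table records
  the count actually placed, so at densities beyond this separation
  capacity the realized count falls below the nominal Poisson draw. The
  stated baseline noise SD refers to the *filtered* trace (white noise is
  pre-scaled by the filter's variance reduction). Overlapping events
  superpose.
* **Assembly time courses**: the second-order law evaluated at the assay's
  sampling times (0–240 min) with multiplicative Gaussian noise
  (cv = 0.1 default, matching densitometry variability; k default
  140 M⁻¹s⁻¹ places half-saturation near 40 min at 3 µM).

**What the generators do not emulate**: calcium indicator signals,
kiss-and-run fusion modes, electrode drift, correlated (1/f) noise, cell-to-
cell parameter heterogeneity beyond the event-size distributions, and
overlapping-event waveform distortion beyond linear superposition. Passing
recovery tests on this synthetic material therefore validates the numerics
and conventions of the analysis chain, not its robustness to every artifact
of real recordings.

## Statistics (`groupstats`)

One-way ANOVA with the Tukey-Kramer studentized-range post test (unequal n
supported, via statsmodels); two-sided Mann-Whitney U, exact for both
n ≤ 8 without ties and normal-approximated with tie correction otherwise
(identical samples return p = 1); right-continuous ECDFs; significance
stars at 0.05/0.01/0.001. Kruskal-Wallis + Dunn lives in `snarekin`, its
only consumer; Dunn's test is implemented here because no installed package
provides it.

## Problem sizes used in the test suite

Monte-Carlo suites use 50 seeds for flash-fit and amperometric recovery,
200 fits for assembly-rate bias, 1000 simulations for rank-test
calibration, and 200 seeds for Poisson event-count checks — sizes at which
the binomial/standard-error bands in the assertions are meaningful while
the whole suite stays fast.
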