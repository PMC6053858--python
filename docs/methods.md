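# Methods

This note documents the model, the numerical choices, and the design
decisions behind the package, and states what the simulated-listener
experiments do and do not show.

## Hearing model

The engine reasons about a single cochlear place: the auditory filter
centred at the dead-region edge frequency f_e. When the probe tone lies
above f_e (inside the dead region) its excitation peaks at f_e and so
does the signal-to-masker excitation ratio, so the likelihood of each
response only needs the excitation levels evaluated there. This is what
makes a two-parameter model — θ = (f_e, OHCL(f_e)) — sufficient.

The filter is a rounded-exponential weighting W(g) = (1 + p|g|)e^(−p|g|)
with separate lower/upper slopes. Concretely:

* upper skirt fixed at the normal sharpness p51 = 4·cf/ERB_N(cf);
* lower skirt p_lower = max(0.2·p51, p51·max(0.2, 1 − ohcl/65)
  − 0.35·(p51/p51(1 kHz))·max(0, L − 51)), where L is the masker's
  overall level (the dominant component of the stimulus context).

These coefficients reproduce the qualitative behaviour the procedure
relies on — tuning broadens with level above 51 dB and with
outer-hair-cell loss, tuning curves flatten at high OHCL — and, because
the simulated listener answers from exactly the same model, every
recovery experiment in this package is internally consistent by
construction. The 65-dB OHCL cap reflects the saturation of filter
broadening; beyond it slopes would degenerate. Which level sets the
level-dependent slope (signal, masker, or their sum) is genuinely open;
the masker level is used because it dominates in the relevant regime,
and the model-mismatch switch (±25% on the lower-skirt slope) exists to
probe sensitivity to exactly this kind of choice.

Masker excitation integrates W over the noise band (bandwidth
max(1 ERB_N, 200 Hz), flat spectrum, truncated at a 20-Hz floor with
the total power renormalised into the surviving band). The band integral
uses the exact antiderivative of (1 + pg)e^(−pg); numerical quadrature
serves as the independent oracle in the tests. A broadband
threshold-equalising background noise at 35 dB HL/ERB_N — physically
present in every trial to mask distortion products — is added in
intensity; it only matters at very low masker levels. All levels are in
dB HL, so the excitation of the noise is directly comparable with the
audiometric threshold, and the effective masker level is
max(E_noise, HL_total(f_e)).

The detection likelihood is a Gaussian CDF of E_sig − E_noise with
σ = 3 dB, scaled into [0.01, 0.99]: the 1% floor/ceiling is a lapse rate
that lets the posterior recover from occasional wrong button presses.
At E_sig = E_noise the hit probability is exactly 0.5, which is also the
defining equation of the predicted tuning curve (solved by bisection
per masker frequency within 20–90 dB HL).

## Inference grid

f_e bins are 0.1 Cam wide and span the eight Cams below the probe
frequency, additionally clipped to the audiogram's tabulated range (the
interpolator deliberately refuses to extrapolate). OHCL bins are 2.5 dB
wide over [0, 65]; the joint grid is a few thousand cells, which keeps
one update far below the ~2-s intertrial budget of a live session. The
prior is uniform over admissible cells; admissibility encodes
OHCL ≤ HL_total(f_e), f_e < f_sig, and audibility of the 10-dB-SL probe
in quiet. Likelihood products are accumulated in log space with one
normalisation per update, so a hundred trials of 0.01-probability
responses cannot underflow. The OHCL discretisation and its uniform
prior are package choices (only the f_e bin width is prescribed by the
protocol).

## Stimulus selection and session

Candidate maskers form a lattice of 0.25 Cams × 2 dB over the eight Cams
below f_sig and 20–90 dB HL (≈1200 candidates; the level cap is a
comfort/safety bound). Because the lattice and the grid are fixed for a
session, the full (cell × candidate) hit-probability matrix is
precomputed once; each trial's information scores then reduce to two
matrix-vector products, and a 124-trial session takes well under a
second on one CPU.

Selection is stochastic — probability proportional to the
mutual-information score times a Gaussian weight (σ = 1.5 Cams) around
the current f̂_e — rather than greedy argmax, to keep exploring and to
avoid locking onto an early wrong estimate. Candidates within 2 Cams of
the immediately preceding masker (only the last one, per the protocol's
singular phrasing) are excluded. If every weight is zero the selector
falls back to a uniform draw over the non-excluded candidates and flags
the trial. The Gaussian weighting is an efficiency device, not a
correctness device: the tests verify recovery still succeeds with the
weighting disabled (σ → ∞).

A session presents 4 practice trials (fixed easy pairs 3 Cams below the
probe at L_sig − 30 and L_sig + 10, excluded from inference — the
protocol only calls for "easy" examples, so the exact stimuli are a
package choice), then 120 trials of which 20 are catch trials at
positions drawn once up front. Catch trials present the most recent
masker without the signal and never touch the posterior; they feed only
the false-alarm diagnostic. The 16-trial familiarisation grid *is*
inference data. One counting RNG stream drives selection and the
simulated responder, so a (config, seed, responder) triple reproduces a
session bit for bit and any single draw can be re-derived from the
logged call counter.

With the adaptive-slope option, σ starts at 3 dB and is re-estimated
every 5 active trials from trial 10 onward (the cadence is a package
choice; the strategy itself — floor at 2 dB, recommend a restart above
20 dB — follows the protocol). Early stopping, off by default, requires
three consecutive trials querying less than 0.1 bit, so one lucky quiet
trial cannot end a run.

## Slope estimation

The psychometric-function slope is fitted to responses against masker
level relative to the predicted tuning curve of the MAP parameters. The
latent model is linear in level with a Gaussian-CDF link; it is fitted
by MAP probit regression with a weak Gaussian prior (scale 100) on the
coefficients. The prior's only practical role is to keep perfectly
separated data well posed (such data are additionally flagged
`separable`); it is weak enough that the fit is scale-consistent within
a few percent. Outlier rejection discards yes responses more than 3
current-σ above the curve and no responses more than 3σ below, starting
from σ = 3 dB, and refits until the discarded set stabilises (≤ 10
iterations). A full marginal-likelihood optimisation of the latent
hyperparameters would give the same predictive family; the MAP fit was
chosen because it is simpler to verify and every contract (recovery of
a 3-dB slope, > 20 dB for level-blind responders, separability
flagging) is met without it.

## Simulated listeners

The cohort generator emulates ears with sloping high-frequency losses:
logistic HL_total on the Cam axis with low-frequency plateau 10–40 dB,
high-frequency plateau 80–110 dB, slope at the 65-dB-HL point sampled
log-uniformly in 14–145 dB/octave, true f_e sampled uniformly in Cams
between 0.5 and 3.3 kHz, OHCL uniform in [10 dB, HL_total(f_e)].
Psychometric σ is 3 dB except for designated ~10-dB outliers, and
false-alarm rates are 1% except for two tinnitus-like profiles at 10%
and 17%. Draws are rejected unless the probe the screening cascade would
select is clearly audible in quiet at the ear's edge place — the same
entry condition a live protocol enforces by asking the subject — for
every tier the stochastic 20-trial cascade might plausibly pick.

What passing these simulations shows: the inference, selection and
scoring machinery is correct and efficient *under the model*, including
under ±25% misspecification of the filter-broadening coefficient. What
it does not show: robustness to everything real listeners add —
criterion drift, attention lapses over time, losing track of the probe,
off-model tuning-curve shapes. The diagnostics (false-alarm rate, slope
estimate, convergence curves) exist precisely because those effects
cannot be ruled out in live data.

## Numerical conventions and edge cases

* Cam scale: Cam(F) = 21.4·log10(4.37F + 1) (F in kHz),
  ERB_N(F) = 24.7·(4.37F + 1) Hz; round trips are exact to 1e−6
  relative over the audiometric range.
* Audiogram interpolation is linear on the (Cam, dB HL) plane; threshold
  crossings are solved on that plane and the lowest-frequency crossing
  wins (the screening targets the low edge of a high-frequency loss).
* Ties in the MAP estimate break toward the lowest f_e bin.
* Roex slopes must be positive and p_lower ≤ p_upper; OHCL above 65 dB
  is clipped with a warning; noise bands below 20 Hz are truncated and
  renormalised.
* Tuning-curve points with no 50% level inside 20–90 dB HL are
  undefined (NaN); an ear whose probe is inaudible in quiet under θ has
  no tuning curve at all and is flagged.
* Result JSON rounds floats to 12 significant digits for byte-stable
  output across platforms; trial logs store shortest exact float
  representations so the round trip is lossless.

## Problem sizes used in the shipped experiments

Recovery experiments run 50 seeded 124-trial sessions per standard
cohort profile (nine profiles); slope recovery uses 50 replicates of 100
probit trials; selection-frequency checks use 1e5 draws; exhaustive
oracles run on ≤ 6-cell grids with 5 trials. These sizes give stable
pass/fail statistics while keeping the full suite at a couple of minutes
on a single CPU.

## Known limitations

* Excitation is evaluated only at f_e; the model cannot represent ears
  whose detection place shifts with masker configuration.
* The likelihood has no criterion/bias parameter: a listener with a high
  false-alarm rate (tinnitus-like profiles) violates the model, which is
  detected post hoc rather than modelled.
* The exact roex broadening coefficients are internal conventions; only
  their qualitative shape is constrained by the behaviour the procedure
  needs.
* The TEN cascade models excitation levels only; no noise waveform or
  calibration chain is represented.
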