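# smartdrt

Bayesian active-learning estimation of cochlear dead-region edge
frequencies from yes/no tone-in-noise trials.

## The problem

A cochlear *dead region* (DR) is a stretch of the cochlea with no or very
few functioning inner hair cells or neurons. A pure tone whose frequency
falls inside a basal DR is detected, if at all, by *off-place listening*
at the place with characteristic frequency f_e — the edge of the dead
region. Knowing f_e matters clinically: hearing-aid amplification is
usually limited to frequencies below about 1.7 f_e. Classical estimates
of f_e come from psychophysical tuning curves (PTCs), whose minimum sits
near f_e, but measuring a whole PTC is slow.

This package implements a model-based adaptive test that estimates f_e
(and the outer-hair-cell loss at it, OHCL(f_e)) *without* measuring the
whole tuning curve, by choosing each trial's masker to be maximally
informative about the model parameters. It is aimed at computational
audiologists and psychophysicists: everything runs against a simulated
listener, so procedures and analysis can be validated end to end without
human subjects. Audiograms and trial logs are plain CSV, so recorded
human sessions can be re-analysed with the same engine.

## The model

Detection of a probe tone (f_sig, L_sig, fixed at 10 dB SL) in a
narrowband masker (f_mask, L_mask; bandwidth max(1 ERB_N, 200 Hz)) is
evaluated at the single place f_e with a rounded-exponential (roex)
auditory filter W(g) = (1 + p|g|)e^(−p|g|), g = (f − f_e)/f_e. The upper
skirt keeps the normal sharpness p51 = 4 f_e / ERB_N(f_e); the lower
skirt broadens with stimulus level above 51 dB and with OHCL(f_e).
Excitation levels E_sig and E_noise are computed from the filter, the
effective masker excitation is max(E_noise, HL_total(f_e)) (the absolute
threshold can limit audibility), and the probability of a *yes* is

    p(y = 1 | x, θ) = 0.01 + 0.98 · Φ((E_sig − E_noise) / σ),   σ = 3 dB

with θ = (f_e, OHCL(f_e)) and x = (f_mask, L_mask). Inference is exact
Bayes on a discrete grid (0.1-Cam f_e bins, 2.5-dB OHCL bins) with a
uniform prior constrained by OHCL ≤ HL_total(f_e), f_e < f_sig, and
audibility of the probe in quiet. Each trial's stimulus is drawn with
probability proportional to

    I(y*; θ | x*) · N(cam(f_mask); f̂_e, 1.5²)

where I is the mutual information between the next response and θ (the
BALD decomposition, at most 1 bit) and candidates within 2 Cams of the
previous masker are excluded. A session comprises 4 practice trials, a
fixed 16-trial familiarisation grid, and information-selected trials up
to 100 inference trials, with 20 signal-absent catch trials mixed in.
The probe tone itself is fixed beforehand by a quick
threshold-equalising-noise (TEN) screening cascade at the frequencies
where the audiogram reaches 65, 70 and 75 dB HL (block criterion:
hits + correct rejections ≥ 15 of 20).

Post-hoc consistency checks: the catch-trial false-alarm rate, the slope
of the psychometric function (probit fit on masker levels normalised to
the predicted tuning curve, with iterative 3-σ outlier rejection), and
three convergence diagnostics (mean negative log predictive probability,
folded estimate ratio, queried information per trial).

## Worked example

Generate a synthetic test ear, screen it, and run a full adaptive
session:

```python
import smartdrt as s
s.generate_cohort(7)[0].to_json("prof.json")
```

```
$ smartdr ten-test --profile prof.json --seed 1
tier 65 dB HL: 4 hits, 10 correct rejections -> FAIL (dead region)
outcome: dr_detected
chosen signal: 3064.2 Hz at 75.0 dB HL (tier 65)

$ smartdr simulate-run --profile prof.json --seed 2 --quiet
final f_e estimate: 23.9 Cams (2760 Hz)
true f_e:           23.9 Cams (2772 Hz)
false-alarm rate on catch trials: 0.0%
```

The screening block scored 14 of 20 (below the 15-correct criterion), so
a dead region is indicated at the 65-dB-HL frequency and the probe is
placed there at 10 dB SL. The 124-trial adaptive session (4 practice +
100 inference + 20 catch) then recovers the simulated ear's true edge
frequency to within 0.1 Cam — about half a percent in frequency. The
same engine is available as a scikit-learn-style estimator
(`EdgeFrequencyEstimator.fit(X, y)` on arrays of maskers and responses),
and `smartdr estimate --log ...` re-derives the posterior from a saved
trial log.

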