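# Methods

## Problem and model

`echopress` estimates the acoustic impedance of the anterior and posterior
corneal surface from pulse-echo ultrasound amplitudes and correlates those
impedances with intraocular pressure (IOP). Acoustic impedance — density
times longitudinal sound speed, reported in MRayl — governs the
pressure-amplitude reflection at an interface, so the echo amplitude from a
surface carries the impedance contrast across it. Because corneal stiffness
rises with IOP and impedance tracks stiffness, the impedance of a
pressurized eye is expected to rise approximately linearly with IOP, making
a calibrated echo amplitude a candidate for noncontact IOP readout.

The eye immersed in saline is treated as a layered medium at normal
incidence:

    saline (Z0) | anterior cornea (Z1) | posterior cornea (Z2) | aqueous humor (Z3)

Anterior surface (single interface):

    A1 / A0 = (Z1 − Z0) / (Z1 + Z0)

Posterior surface (three-layer, two-way transmission through the anterior
interface plus reflection at the posterior one):

    Ar / A0 = T01 · R23 · T10 · g,
    T01 = 2 Z1 / (Z1 + Z0),  T10 = 2 Z0 / (Z1 + Z0),
    R23 = (Z3 − Z2) / (Z3 + Z2)

`A0` is the incident amplitude, obtained in practice from the echo of a
quartz plate of known density and speed (a near-perfect reflector), and `g`
is a scalar geometric gain that absorbs the curvature/defocus loss of the
non-planar posterior interface. Both relations invert in closed form:

    Z1 = Z0 (A0 + A1) / (A0 − A1),
    R23 = −Ar / (A0 · T01 T10 · g),  Z2 = Z3 (1 − R23) / (1 + R23).

Measured amplitudes are envelope magnitudes, so the sign of `R23` must be
assumed: the default (`posterior_sign="auto"`) takes Z2 > Z3 (corneal
stroma denser than aqueous humor), consistent with every measured value in
the study conditions; an explicit override and, for the anterior surface, a
polarity flag from the feature extractor select the mirror branches.

One modelling note: the two-way posterior chain requires the product
T01·R23·T10; the per-interface identity T01·T10 = 1 − R01² (pressure-
amplitude conservation) is enforced as a property test at 1e-12.

## Signal processing

Echo amplitude and time of flight (TOF) are taken from the signal
envelope, computed as the magnitude of the analytic signal (Hilbert
transform) — chosen over rectify-and-smooth because it has no tuning
parameters. Two echo windows are located with a peak finder constrained to
a minimum separation (default 0.2 µs; peaks below 10% of the record
maximum are ignored as noise). Within each window, a least-squares
parabola is fitted to the contiguous samples at or above 70% of the local
maximum — always including the maximum and its two neighbours, so at
least three points enter the fit — and the vertex gives a sub-sample TOF
and the peak amplitude, with an R² diagnostic. Ties and degenerate cases:
a maximum on a window edge or an upward-opening fit raise a `FitError`
rather than returning a value.

Fitting a parabola to a Gaussian-shaped peak over the 70% window
underestimates the peak by ≈0.4–0.5% (the Gaussian's quartic term); this
is the dominant systematic of the pipeline. Propagated through the
inversions the bias is scaled by the small reflection coefficients
(|R| ≈ 0.01–0.02) and amounts to ≲4·10⁻⁴ MRayl — an order of magnitude
below the 0.003 MRayl recovery criterion — so it is accepted rather than
corrected.

Aggregation pools the A-lines within each repeat, then averages repeats
with equal weight (identical to a grand mean for the balanced default
design of 3 repeats × 10 A-lines); dispersions are standard deviations over
all A-lines. The anterior–posterior TOF difference equals 2·d/c for
corneal thickness d and sound speed c.

## Synthetic data generator

No raw RF data from the study is public, so validation uses a synthetic
generator that emulates the acquisition: a Gaussian-enveloped cosine pulse
at 47 MHz whose −6 dB spectral full width equals 62% of the centre
frequency (the pulse model is the minimal one matching the stated centre
frequency and fractional bandwidth), sampled at 1 GHz into 4096-sample
records; the anterior echo is centred at 25% of the record and the
posterior echo 2·d/c later with the signed model amplitudes (the posterior
echo is phase-inverted when Z2 > Z3); additive white Gaussian noise per
sample, default standard deviation 1% of the anterior amplitude — chosen
to reproduce the order of the relative scatter of the measured anterior
amplitudes (0.0011/1.63 ≈ 0.07% to 0.0234/2.15 ≈ 1%). Per-record RNG
streams are spawned from a single seed, so datasets regenerate bit for bit.

Ground-truth impedances vary linearly with IOP between the study's
endpoint means (anterior 1.5399 → 1.5519 MRayl, posterior
1.5393 → 1.5698 MRayl over 10 → 50 mmHg). The remaining constants are
solved so the forward model is self-consistent with the measured endpoint
amplitudes rather than taken from textbooks:

- **Z0** solves R(Z0, Z1_high)/R(Z0, Z1_low) = 2.1454/1.6347 by Brent
  root finding in (0, Z1_low); the solution is 1.50212 MRayl, a plausible
  saline value.
- **A0** = 1.6347 / R(Z0, Z1_low) = 131.61 (arbitrary units; whether the
  measured amplitudes are volts is unknown, so units are carried through
  unchanged).
- **g** (posterior gain) = 0.3591, set so the three-layer model with
  Z3 = Z0 reproduces the posterior amplitude 0.5778 at 10 mmHg. The
  curvature correction of the original measurement is not published, so a
  single scalar on the posterior path is used; the anterior path needs
  none because the anterior calibration absorbs any constant factor.
- **Z3 = Z0**: aqueous humor and balanced salt solution are both dilute
  aqueous media; no separate measurement exists.
- Corneal thickness 0.8 mm and speed 1580 m/s (typical porcine values),
  fixed across IOP — the impedance method is insensitive to thickness, and
  the TOF-vs-IOP behaviour is deliberately not modelled beyond this
  constant. Attenuation inside the cornea is omitted (the amplitude model
  contains none).

This calibration leaves one measured number unused: the posterior
amplitude at 50 mmHg (1.0382). The forward model predicts 1.0412 for it —
a 0.3% consistency check computed by `scripts/acceptance.py` (target t8),
not an input.

What the generator does **not** emulate: beam diffraction and focusing,
speckle from stromal microstructure, eye-to-eye biological variability,
alignment/curvature drift with inflation, frequency-dependent attenuation,
and any nonlinearity of the impedance–IOP relation. Passing tests
therefore demonstrate that the estimation chain is unbiased and precise
under the stated acoustic model and noise — not that the linear model is
the correct physiology.

## Statistics

Per-IOP means of each quantity (n = 5 levels by default) are correlated
with pressure by the Pearson product-moment coefficient; significance uses
the exact transform t = r√((n−2)/(1−r²)) with n−2 degrees of freedom,
two-sided — verified against direct numerical integration of the Student-t
density to 1e-10. This reproduces the reported P values for the printed
(r, P) pairs at n = 5 (e.g. r = 0.9849 → P = 0.0022, r = 0.8651 →
P = 0.0581), with one known anomaly: the reported anterior-impedance pair
(R = 0.7378, P = 0.0025) is not consistent with any n ≤ 30 under this (or
any standard) test; it is documented here and excluded from checks. Trend
lines are ordinary least squares of value on IOP. No multiple-testing
correction is applied (a handful of pre-specified correlations, reported
as-is). The Laplace thin-shell stress σ = P·R/(2t) is provided as a
utility (1 mmHg = 133.322 Pa) for relating IOP to corneal wall stress.

The measured correlation coefficients themselves (e.g. R = 0.9849) are not
reproducible from a simulation: they depend on the unpublished five-point
noise realization. The testable property is that under the calibrated
linear map with 1% noise, the posterior-impedance correlation exceeds
r = 0.98 for every seed in a 20-seed sweep.

## Numerical choices and problem sizes

- Brent root finding for Z0 at xtol 1e-15; calibration self-consistency is
  asserted at 1e-9 relative.
- Parabola fits are solved on window-centred abscissae for conditioning.
- Envelope ripple of the wideband (62%) pulse from negative-frequency
  leakage is ≈0.1% of the peak; the noiseless extraction bound of 0.5%
  covers ripple plus the parabola bias.
- Default test and acceptance runs use the study design exactly
  (5 levels × 3 repeats × 10 A-lines = 150 records of 4096 samples); a full
  pipeline run takes well under a second, and the 20-seed sweeps a few
  seconds.
- The acquisition's vertical scan step is treated as perfect alignment;
  motorized-scan geometry is out of scope.

## Limitations

The posterior gain is constant across pressure, so any real change of
corneal curvature with inflation — which would modulate the posterior
amplitude independently of impedance — is absorbed into the impedance
estimate. The sign conventions assume a cornea denser than both saline and
aqueous humor. Correlations at n = 5 have wide confidence bands; the exact
t test is valid under bivariate normality of level means.
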