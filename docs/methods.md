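# Methods

## Scope and model

The package implements a complete high-wavenumber (HWN) Raman analysis for
brain-tissue classification at the needle-biopsy scale: a generative model of
the measurement, the four-stage preprocessing chain, univariate band
statistics, and a cross-validated binary classifier. The clinical contrast is
*dense cancer* (cancer-cell fraction > 60%, diagnostically collectable)
against *non-diagnostic* tissue (normal brain plus infiltrated tissue at
≤ 60% cancer cells).

## Synthetic measurement model

A measured frame at channel $\nu$ is modeled as

$$F(\nu) = \mathrm{clip}\big(R(\nu)\,[S(\nu) + L(\nu)] + d + \varepsilon(\nu),\; 0,\; \mathrm{adc\_max}\big)$$

with $S$ the tissue Raman component, $L$ a smooth autofluorescence baseline,
$R$ the multiplicative instrument response, $d$ the dark level, and
$\varepsilon$ zero-mean Gaussian noise with variance
$\sigma^2(\nu) = \texttt{noise\_scale}^2\,(\mathbb E[F(\nu)] + 0.1)$, a
shot-noise approximation for a CCD with a small read-noise floor. The
laser-off background frame carries only $d + \varepsilon$.

**Raman component.** $S$ is a sum of Gaussian bands (Lorentzian available)
parameterized by center, peak amplitude, and FWHM. The classes share centers
and widths and differ only in amplitude:

| band | center (cm⁻¹) | FWHM (cm⁻¹) | normal amp | dense-cancer amp |
|---|---|---|---|---|
| lipid CH₂ sym | 2845 | 35 | 1.00 | 0.55 |
| lipid CH₂ asym | 2885 | 40 | 0.70 | 0.50 |
| protein CH₃ | 2930 | 45 | 0.75 | 0.95 |
| water OH | 3450 | 160 | 0.45 | 0.55 |
| sapphire (optional) | 3240 | 25 | 0.30 | 0.30 |

Amplitudes are in arbitrary detector units; no published absolute
intensities or SNR exist for this measurement, so the defaults are chosen to
place the noiseless 2930/2845 ratio below 1 for normal tissue (0.74) and
above 1 for dense cancer (1.66), the qualitative direction the biochemistry
dictates (protein up, lipid down with cancer-cell density). The sapphire
band is a toggle: present for a lensed handheld probe, absent for a lensless
needle.

**Mixing.** A site with cancer fraction $f$ has Raman component
$(1-f)\,S_\text{normal} + f\,S_\text{cancer}$. Because the numerator band
grows and the denominator band shrinks linearly in $f$, the 2930/2845 ratio
is strictly increasing in $f$ — the generator's key monotone invariant.
Infiltrated fractions are drawn uniformly on (0, 0.60], dense on (0.60, 1].

**Biological variability.** Per acquisition, band amplitudes receive
independent lognormal jitter (σ = 0.10), the overall intensity a lognormal
factor (σ = 0.20), and the baseline coefficients a common lognormal factor
(σ = 0.10). These defaults make neighboring fractions across the 60%
boundary genuinely confusable, so classification performance is high but not
perfect — the regime the analysis is meant for.

**Baseline and response.** The fluorescence baseline is an order-3
polynomial in the scaled coordinate $t = (\nu - \bar\nu)/\text{half-span} \in
[-1, 1]$, positive over the window, with dense cancer slightly brighter. The
instrument response is a smooth positive unit-mean curve
$1 + s\cos(\pi(t + 0.3))$ with $s = 0.15$.

**Cohort defaults** reproduce the reference clinical composition: 280 sites
(105 normal, 51 infiltrated, 124 dense cancer) over 19 patients in blocks of
14–15 sites each, labels shuffled across patients. Artifact probabilities
(`p_saturation`, `p_spike`) default to 0 — the default cohort represents
retained, analysis-ready measurements; artifacts are opt-in to exercise QC.
A `separation` dial (0–1) scales the cancer-vs-normal amplitude contrast;
`separation=0` produces pure-noise cohorts for null experiments.

**Randomness.** One top-level seed; per-acquisition child streams are spawned
deterministically (`numpy.random.SeedSequence`), so equal seeds give
bitwise-equal cohorts regardless of how many acquisitions are drawn.

## Preprocessing

Stage order is fixed: averaging/background subtraction → response division →
fluorescence removal → SNV. Averaging before or after subtracting the single
shared background frame is equivalent; the averaged form is implemented.

**Instrument response** is `measured/certified` white-light, rescaled to unit
mean (the scale is arbitrary; SNV later removes it anyway). If response and
spectrum axes differ, linear interpolation is applied; extrapolation is an
error.

**Fluorescence removal** is a modified iterative polynomial fit: fit order-p
polynomial, replace every point above the fit by the fit, refit; stop when
the fit changes by less than `tol × range(input)` or after `max_iter`
rounds. Defaults: order 5, tol 1e-6, max_iter 100; the fit uses the
mean-centered, range-scaled wavenumber coordinate for conditioning.
Non-convergence sets a provenance flag rather than raising — the fit at the
iteration cap is already within a fraction of a percent of the converged
curve in every case measured. Accuracy depends on band width: for a
polynomial baseline plus a single Gaussian band, the off-peak (beyond
3×FWHM) baseline error is under 5% of the band amplitude at FWHM 20 cm⁻¹
and under 15% at FWHM 35 cm⁻¹; broad bands (the 160 cm⁻¹ water band)
partially absorb into the baseline. This is the known cost of polynomial
baseline methods and the reason recovery tests against ground truth use the
generator's known baseline (`known_baseline=` injection) when exactness is
required. Degree-≤p peak-free polynomials are recovered with residual at
numerical zero.

**SNV** uses the sample (n−1) standard deviation — the conventional
chemometrics definition; the choice only rescales all spectra identically
and is stated here because alternatives exist.

**Quality control.** Saturation: any signal-frame channel at or above
`adc_max`. Spikes: residual against a 7-channel rolling median exceeding 8×
the robust (MAD) scale over a run of ≤ 5 channels; the scale is floored at
1% of the signal range so smooth band curvature on near-noiseless spectra
cannot trip the detector, and genuine Raman bands (tens of cm⁻¹ ≈ 10–25
channels) are too wide to register. Metadata-driven exclusions — partitioned
biopsy samples and off-target tissue identified on histology — are honored
from the sidecar, never inferred from spectra, and are counted in the
partitioned-rejection bucket of the QC report. Flagged acquisitions are
dropped, not repaired. Rejection precedence: metadata > saturation > spike.

## Band statistics

Band intensity is the mean over |ν − center| ≤ half-width (default 5 cm⁻¹ ≈
3 channels; 0 reads the nearest channel). The protein/lipid ratio is
computed on the baseline-removed, **pre-SNV** spectrum: SNV output is
mean-centered, so its values can be negative at 2845 cm⁻¹ and the ratio
loses its scale-free meaning; computing on SNV spectra is possible but
explicitly opt-in. Per-peak tests are two-sided two-sample t-tests, Welch by
default (pooled available). Boxplot summaries use type-7 (linear
interpolation) quantiles and Tukey 1.5×IQR whiskers clipped to the most
extreme inlier.

## Classification

Channels are screened by the two-sided p-value of the point-biserial
correlation with the binary label, computed via its exact pooled-t
transform; constant channels get p = 1 by convention. The k smallest
p-values are kept (default k = 141; ties break toward the lower channel
index via a stable sort). The classifier is an SVM (default linear kernel,
C = 1, solver tolerance 1e-8 so scores are row-order invariant); features
are standardized with training-fold statistics.

LOOCV scores every spectrum with a model trained on the rest. Selection and
standardization run **inside** each fold by default; the global-selection
variant (screen once on all data) is provided because published procedures
are often ambiguous on this point, and the two modes are distinguished in
provenance. On pure-noise cohorts in-fold selection shows no optimistic
bias, while global selection scores measurably higher — the leakage contrast
is itself under test. A training fold reduced to a single class (possible
only when a class has one member) falls back to the majority sign and is
flagged.

Note a related finite-sample effect: leave-one-out accuracy of a
near-interpolating classifier on *uninformative* data runs systematically
below the majority-class rate (removing the held-out sample tilts the
boundary against its class). Measured here: ≈ −0.10 at n = 45–90 with the
default SVM. Tests therefore bound optimism tightly (one-sided) and apply
only a coarse two-sided sanity band.

ROC thresholds sit at midpoints between distinct sorted scores plus ±∞
sentinels, so each achievable (FPR, TPR) appears once and the trapezoid AUC
equals the Mann–Whitney concordance probability with ties counted ½ (exact
identity, tested to 1e-12). The operating point minimizes
$\sqrt{\mathrm{FPR}^2 + (1-\mathrm{TPR})^2}$, ties broken by higher TPR then
lower FPR. Dense cancer is the positive class; prediction is score ≥
threshold. Proportions are kept at full precision internally and rounded
only for presentation. No class reweighting and no probability calibration
are applied.

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
class-dependent band amplitudes with a monotone ratio, smooth removable
baseline, multiplicative response, heteroscedastic noise, replicate framing,
QC-able artifacts, patient grouping — with full ground truth. It does not
emulate: absolute intensities or the clinical SNR (unpublished), patient-level
spectral correlation beyond grouping tags, wavelength-calibration error,
fiber-background drift, or fingerprint-region information. Passing tests
therefore demonstrate correctness of the pipeline's mechanics and its
statistical discipline (no leakage, exact metric identities, monotone
responses), not field performance on clinical tissue; classification metrics
on synthetic cohorts characterize the simulation, not the instrument.

## Numerical and design choices

- Axis length is `floor((stop − start)/spacing) + 1` with a 1e-12 guard
  against floating-point undershoot at exact multiples.
- Polynomial fits use `numpy.polynomial` on scaled coordinates; no raw
  Vandermonde on wavenumbers.
- The acceptance script sizes its problems to run in seconds: the full
  default 280-spectrum cohort for the clinical-style run; 100 random
  instances for the AUC identity; 21 sites for the exclusion bookkeeping.
  Statistical tests in the suite use 45–60-spectrum cohorts with 3–10
  replicates, sizes at which the asserted effects are decisively resolved.
- Known limitations: broad-band baseline leakage (above); LOOCV pessimism on
  noise (above); per-spectrum (not per-patient) folds by default, matching
  the stated validation procedure — a leave-one-patient-out mode would be the
  natural extension for deployment-grade claims.
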