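"""Spectral preprocessing chain for raw Raman acquisitions.

Turns a raw acquisition (replicate CCD frames + laser-off background) into an
analysis-ready spectrum through four stages, in this fixed order:

1. replicate averaging and background subtraction;
2. division by the instrument response (measured against a certified
   white-light source, stored as a unit-mean multiplicative curve);
3. removal of tissue autofluorescence by a modified iterative polynomial fit
   (fit a low-order polynomial, clamp the spectrum to the fit from above,
   refit until the fit stabilizes);
4. standard normal variate (SNV) normalization, i.e. per-spectrum centering
   and scaling to unit sample standard deviation.

Quality control runs alongside: acquisitions whose frames hit the ADC ceiling
(CCD saturation), show narrow spike artifacts (cosmic rays), or carry a
metadata rejection flag (e.g. a partitioned biopsy sample or off-target
tissue on histology) are dropped rather than repaired, with counts balanced
in a :class:`QCReport`.

Note on stage 1: averaging the replicate frames before or after subtracting
the single shared background frame gives the same net spectrum; the averaged
form is implemented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .axis import WavenumberAxis

__all__ = [
    "RawAcquisition",
    "InstrumentResponse",
    "ProcessedSpectrum",
    "QCReport",
    "QCFlag",
    "PreprocessingParams",
    "average_and_subtract",
    "derive_response",
    "correct_response",
    "remove_fluorescence",
    "snv_normalize",
    "qc_flags",
    "preprocess_acquisition",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class RawAcquisition:
    """One measurement site: replicate signal frames + laser-off background."""

    axis: WavenumberAxis
    frames: list[np.ndarray]
    background: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.axis)
        if len(self.frames) < 1:
            raise ValueError("acquisition needs at least one signal frame")
        for f in self.frames:
            if np.asarray(f).shape != (n,):
                raise ValueError("signal frame length does not match axis")
        if np.asarray(self.background).shape != (n,):
            raise ValueError("background frame length does not match axis")


@dataclass(frozen=True)
class InstrumentResponse:
    """Unit-mean positive multiplicative response of the optical chain."""

    axis: WavenumberAxis
    factors: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.shape != (len(self.axis),):
            raise ValueError("response length does not match axis")
        if np.any(f <= 0):
            raise ValueError("response factors must be positive")
        object.__setattr__(self, "factors", f)

    def interpolated_to(self, axis: WavenumberAxis) -> np.ndarray:
        """Factors on ``axis``; linear interpolation, extrapolation is an error."""
        if axis.values[0] < self.axis.values[0] - 1e-9 or axis.values[-1] > self.axis.values[-1] + 1e-9:
            raise ValueError("target axis extends beyond the response axis (no extrapolation)")
        if len(axis) == len(self.axis) and np.allclose(axis.values, self.axis.values):
            return self.factors
        return np.interp(axis.values, self.axis.values, self.factors)


class QCFlag(str, enum.Enum):
    SATURATED = "saturated"
    SPIKE_ARTIFACT = "spike_artifact"
    PARTITIONED_SAMPLE = "partitioned_sample"


@dataclass(frozen=True)
class ProcessedSpectrum:
    """A preprocessed, SNV-normalized spectrum with provenance."""

    axis: WavenumberAxis
    intensities: np.ndarray
    baseline: np.ndarray
    pre_snv: np.ndarray
    qc_flags: frozenset[QCFlag]
    provenance: tuple[str, ...]
    meta: dict = field(default_factory=dict)


@dataclass
class QCReport:
    """Bookkeeping of acquisition rejection; counts always balance."""

    n_input: int = 0
    n_rejected_saturation: int = 0
    n_rejected_artifact: int = 0
    n_rejected_partitioned: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_rejected_saturation
            - self.n_rejected_artifact
            - self.n_rejected_partitioned
        )


@dataclass(frozen=True)
class PreprocessingParams:
    """Tunables of the processing chain.

    The polynomial order, convergence tolerance and iteration cap of the
    fluorescence-removal stage are package choices (order 5, relative
    tolerance 1e-6, 100 iterations). The spike detector is a rolling-median
    deviation test (window 7 channels, threshold 8x the robust scale of the
    residual) and can be disabled.
    """

    poly_order: int = 5
    poly_tol: float = 1e-6
    poly_max_iter: int = 100
    spike_window: int = 7
    spike_threshold: float = 8.0
    spike_max_width: int = 5
    detect_spikes: bool = True
    adc_max: float | None = 50.0
    exclude_meta_key: str = "exclude"
    partitioned_meta_key: str = "partitioned"


def average_and_subtract(acq: RawAcquisition) -> np.ndarray:
    """Stage 1: elementwise mean of the signal frames minus the background."""
    return np.mean(np.asarray(acq.frames, dtype=float), axis=0) - np.asarray(
        acq.background, dtype=float
    )


def derive_response(measured_white: np.ndarray, certified_white: np.ndarray,
                    axis: WavenumberAxis | None = None) -> InstrumentResponse:
    """Stage 2 calibration: response = measured/certified, rescaled to unit mean.

    ``measured_white`` is the instrument's reading of a calibrated white-light
    source whose certified emission is ``certified_white``.
    """
    measured = np.asarray(measured_white, dtype=float)
    certified = np.asarray(certified_white, dtype=float)
    if measured.shape != certified.shape:
        raise ValueError("measured and certified spectra must have equal length")
    if np.any(certified <= 0):
        raise ValueError("certified white-light values must be positive")
    if np.any(measured <= 0):
        raise ValueError("measured white-light values must be positive")
    factors = measured / certified
    factors = factors / factors.mean()
    if axis is None:
        axis = WavenumberAxis(np.arange(measured.size, dtype=float))
    return InstrumentResponse(axis=axis, factors=factors)


def correct_response(spectrum: np.ndarray, response: InstrumentResponse,
                     axis: WavenumberAxis | None = None) -> np.ndarray:
    """Stage 2: divide out the instrument response."""
    spectrum = np.asarray(spectrum, dtype=float)
    factors = response.factors if axis is None else response.interpolated_to(axis)
    if spectrum.shape != factors.shape:
        raise ValueError("spectrum and response length mismatch")
    if np.any(factors == 0):
        raise ValueError("response factor of zero")
    return spectrum / factors


def remove_fluorescence(
    spectrum: np.ndarray,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    axis: WavenumberAxis | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stage 3: modified iterative polynomial baseline removal.

    Fits an order-``order`` polynomial to the spectrum, replaces every point
    lying above the fit by the fit value, and refits; iterates until the
    maximum absolute change of the fit falls below ``tol`` times the input
    range, or ``max_iter`` is reached. Peaks are progressively excluded from
    the fit, so the converged polynomial tracks the smooth autofluorescence
    under them.

    Returns ``(raman, baseline, converged)`` with ``raman = spectrum -
    baseline``. Non-convergence is reported via the flag, not an exception.
    The fit runs on a mean-centered, range-scaled coordinate for numerical
    conditioning.
    """
    y = np.asarray(spectrum, dtype=float)
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    if y.size <= order + 1:
        raise ValueError("spectrum too short for the requested polynomial order")
    if axis is not None:
        x = axis.values
    else:
        x = np.arange(y.size, dtype=float)
    t = (x - x.mean()) / (0.5 * (x[-1] - x[0]))

    scale = float(np.ptp(y))
    if scale == 0.0:
        return np.zeros_like(y), y.copy(), True

    work = y.copy()
    fit = np.polynomial.polynomial.polyval(t, np.polynomial.polynomial.polyfit(t, work, order))
    converged = False
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyfit(t, work, order)
        )
        if np.max(np.abs(new_fit - fit)) < tol * scale:
            fit = new_fit
            converged = True
            break
        fit = new_fit
    baseline = fit
    return y - baseline, baseline, converged


def snv_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Stage 4: standard normal variate normalization.

    Subtracts the spectrum mean and divides by the sample (n-1 denominator)
    standard deviation, the conventional chemometrics definition.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least two channels")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (x - x.mean()) / sd


def qc_flags(
    acq: RawAcquisition,
    adc_max: float | None = 50.0,
    params: PreprocessingParams | None = None,
) -> frozenset[QCFlag]:
    """Detect saturation and spike artifacts in a raw acquisition.

    Saturation: any signal-frame channel at or above the ADC ceiling. Spike:
    any net-spectrum channel deviating from a rolling median (window 7) by
    more than 8x the robust scale of the residual, over a run narrower than
    ``spike_max_width`` channels — narrow enough that a genuine Raman band
    (tens of cm^-1 wide) never trips it. Metadata-driven flags (partitioned
    sample) are honored from ``acq.meta``, never inferred from the spectrum.
    """
    params = params or PreprocessingParams()
    flags: set[QCFlag] = set()

    if adc_max is not None:
        if any(np.any(np.asarray(f) >= adc_max) for f in acq.frames):
            flags.add(QCFlag.SATURATED)

    if params.detect_spikes:
        net = average_and_subtract(acq)
        window = params.spike_window if params.spike_window % 2 == 1 else params.spike_window + 1
        smooth = median_filter(net, size=window, mode="nearest")
        resid = net - smooth
        mad = float(np.median(np.abs(resid - np.median(resid))))
        # floor the scale at 1% of the signal range so the smooth curvature
        # residual of genuine (tens of cm^-1 wide) bands never trips the test
        # on near-noiseless spectra
        robust_scale = max(1.4826 * mad, 0.01 * float(np.ptp(net)), 1e-12)
        outliers = np.abs(resid) > params.spike_threshold * robust_scale
        if np.any(outliers):
            # spike = short run of outliers, not a broad band-shaped excursion
            runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], outliers.view(np.int8), [0])))).reshape(-1, 2), axis=1)
            if np.any(runs <= params.spike_max_width):
                flags.add(QCFlag.SPIKE_ARTIFACT)

    if acq.meta.get(params.partitioned_meta_key, False):
        flags.add(QCFlag.PARTITIONED_SAMPLE)
    return frozenset(flags)


def preprocess_acquisition(
    acq: RawAcquisition,
    response: InstrumentResponse | None,
    params: PreprocessingParams | None = None,
    known_baseline: np.ndarray | None = None,
) -> ProcessedSpectrum:
    """Run the four-stage chain on one acquisition (no QC rejection).

    ``known_baseline`` replaces the iterative polynomial estimate with a given
    fluorescence curve (e.g. the generator's ground truth in recovery tests,
    or an independently measured blank); it is subtracted directly.
    """
    params = params or PreprocessingParams()
    provenance = ["average_and_subtract"]
    net = average_and_subtract(acq)
    if response is not None:
        net = correct_response(net, response, axis=acq.axis)
        provenance.append("correct_response")
    if known_baseline is not None:
        baseline = np.asarray(known_baseline, dtype=float)
        if baseline.shape != (len(acq.axis),):
            raise ValueError("known_baseline length does not match axis")
        raman = net - baseline
        provenance.append("subtract_known_baseline")
    else:
        raman, baseline, converged = remove_fluorescence(
            net, order=params.poly_order, max_iter=params.poly_max_iter,
            tol=params.poly_tol, axis=acq.axis,
        )
        provenance.append("remove_fluorescence")
        if not converged:
            provenance.append("remove_fluorescence:not_converged")
    normalized = snv_normalize(raman)
    provenance.append("snv_normalize")
    return ProcessedSpectrum(
        axis=acq.axis,
        intensities=normalized,
        baseline=baseline,
        pre_snv=raman,
        qc_flags=qc_flags(acq, adc_max=params.adc_max, params=params),
        provenance=tuple(provenance),
        meta=dict(acq.meta),
    )


def preprocess_cohort(
    acquisitions: list[RawAcquisition],
    response: InstrumentResponse | None = None,
    params: PreprocessingParams | None = None,
) -> tuple[list[ProcessedSpectrum], QCReport]:
    """Preprocess a cohort, rejecting flagged or metadata-excluded acquisitions.

    Rejection precedence when an acquisition trips several rules: metadata
    exclusion (partitioned sample / off-target tissue) > saturation > spike.
    The returned report's counts satisfy
    ``n_input == n_retained + sum(rejections)``.
    """
    params = params or PreprocessingParams()
    report = QCReport(n_input=len(acquisitions))
    retained: list[ProcessedSpectrum] = []
    for acq in acquisitions:
        acq_id = acq.meta.get("acquisition_id", "?")
        excluded_meta = bool(acq.meta.get(params.exclude_meta_key, False))
        flags = qc_flags(acq, adc_max=params.adc_max, params=params)
        if excluded_meta or QCFlag.PARTITIONED_SAMPLE in flags:
            report.n_rejected_partitioned += 1
            continue
        if QCFlag.SATURATED in flags:
            report.n_rejected_saturation += 1
            continue
        if QCFlag.SPIKE_ARTIFACT in flags:
            report.n_rejected_artifact += 1
            continue
        try:
            retained.append(preprocess_acquisition(acq, response, params))
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for acquisition {acq_id}: {exc}") from exc
    return retained, report
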