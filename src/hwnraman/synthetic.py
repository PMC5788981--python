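"""Synthetic high-wavenumber Raman cohort generator.

Emulates the measurement process of a fiber-optic Raman biopsy probe in brain
tissue: each measurement site yields a few replicate CCD frames (laser on) and
one laser-off background frame. The underlying "true" Raman component is a sum
of CH-stretch lipid bands (2845, 2885 cm^-1), the protein CH3 band
(2930 cm^-1), the broad water OH band (~3450 cm^-1) and, optionally, a
sapphire lens artifact at 3240 cm^-1. On top of it sit a smooth tissue
autofluorescence baseline (low-order polynomial), a multiplicative instrument
response, an additive dark level, and heteroscedastic shot-like noise.

Tissue classes follow the cancer-cell-fraction taxonomy used in brain-biopsy
histopathology: *normal* (fraction 0), *infiltrated* (0 < fraction <= 0.60)
and *dense cancer* (fraction > 0.60). Infiltrated and dense spectra are linear
mixtures of the two pure-class spectra weighted by the cancer fraction, so the
protein/lipid 2930/2845 band ratio rises monotonically with cancer content.

Every stochastic quantity derives from a single top-level seed through
deterministically spawned child streams, so equal seeds give bitwise-equal
cohorts. Full ground truth (fraction, noiseless ratio, baseline and response
curves) is returned for parameter-recovery tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .axis import WavenumberAxis, make_axis
from .preprocessing import RawAcquisition

__all__ = [
    "LineShape",
    "TissueLabel",
    "BandSpec",
    "TissueClassParams",
    "AcquisitionConfig",
    "CohortSpec",
    "GroundTruth",
    "CohortRecord",
    "pure_class_spectrum",
    "mixture_spectrum",
    "label_from_fraction",
    "simulate_acquisition",
    "simulate_cohort",
    "default_normal_params",
    "default_cancer_params",
    "evaluate_baseline",
    "instrument_response_curve",
]


class LineShape(str, enum.Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


class TissueLabel(str, enum.Enum):
    NORMAL = "normal"
    INFILTRATED = "infiltrated"
    DENSE_CANCER = "dense_cancer"


# Dense-cancer fractions exceed this; infiltrated tissue is at or below it.
DENSE_FRACTION_THRESHOLD = 0.60

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center (cm^-1), peak amplitude, FWHM width, line shape."""

    center: float
    amplitude: float
    width: float
    shape: LineShape = LineShape.GAUSSIAN

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-peak line shape times amplitude on the given grid."""
        d = np.asarray(wavenumbers, dtype=float) - self.center
        if self.shape is LineShape.GAUSSIAN:
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)
        hw = self.width / 2.0
        return self.amplitude * hw**2 / (d**2 + hw**2)


@dataclass(frozen=True)
class TissueClassParams:
    """Pure-class spectral model: band set + fluorescence polynomial coefficients.

    ``fluorescence_coeffs`` are in increasing powers of the scaled coordinate
    t = (nu - mid) / half_span in [-1, 1] (numerically conditioned form).
    """

    band_set: tuple[BandSpec, ...]
    fluorescence_coeffs: tuple[float, ...]
    label_name: TissueLabel

    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.band_set])

    def with_amplitudes(self, amplitudes: Sequence[float]) -> "TissueClassParams":
        if len(amplitudes) != len(self.band_set):
            raise ValueError("amplitude count must match band count")
        bands = tuple(
            replace(b, amplitude=float(a)) for b, a in zip(self.band_set, amplitudes)
        )
        return replace(self, band_set=bands)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Detector/acquisition model parameters (arbitrary detector units)."""

    n_replicates: int = 3
    integration_time: float = 0.5
    response_smoothness: float = 0.15
    dark_level: float = 0.2
    noise_scale: float = 0.05
    adc_max: float = 50.0
    p_saturation: float = 0.0
    p_spike: float = 0.0
    include_sapphire_band: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate frame")
        for name in ("p_saturation", "p_spike"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.adc_max <= self.dark_level:
            raise ValueError("adc_max must exceed dark_level")


@dataclass(frozen=True)
class GroundTruth:
    """Generation-time truth for one acquisition, for recovery tests."""

    cancer_fraction: float
    true_ratio_2930_2845: float
    baseline_curve: np.ndarray = field(repr=False)
    response_curve: np.ndarray = field(repr=False)
    true_raman: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CohortRecord:
    acquisition: RawAcquisition
    label: TissueLabel
    truth: GroundTruth


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and biological-variability settings.

    Default per-class counts reproduce the clinical study composition
    (105 normal, 51 infiltrated, 124 dense cancer over 19 patients).
    ``separation`` scales the cancer-vs-normal amplitude contrast: 0 makes the
    classes spectrally identical (pure-noise cohorts), 1 is the full default
    contrast.
    """

    n_normal: int = 105
    n_infiltrated: int = 51
    n_dense: int = 124
    n_patients: int = 19
    separation: float = 1.0
    amplitude_jitter: float = 0.10
    intensity_jitter: float = 0.20
    baseline_jitter: float = 0.10

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_infiltrated, self.n_dense) < 0:
            raise ValueError("per-class counts must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_infiltrated + self.n_dense


_SAPPHIRE_BAND = BandSpec(center=3240.0, amplitude=0.30, width=25.0)

# Shared centers/widths; the classes differ only in amplitude, with the
# protein band (2930) up and the lipid bands (2845/2885) down in dense cancer.
_BAND_CENTERS_WIDTHS = ((2845.0, 35.0), (2885.0, 40.0), (2930.0, 45.0), (3450.0, 160.0))
_NORMAL_AMPLITUDES = (1.00, 0.70, 0.75, 0.45)
_CANCER_AMPLITUDES = (0.55, 0.50, 0.95, 0.55)
_NORMAL_FLUOR = (4.0, -1.2, 0.5, -0.2)
_CANCER_FLUOR = (4.8, -1.0, 0.4, -0.3)


def _bands(amplitudes: Sequence[float], shape: LineShape) -> tuple[BandSpec, ...]:
    return tuple(
        BandSpec(center=c, amplitude=a, width=w, shape=shape)
        for (c, w), a in zip(_BAND_CENTERS_WIDTHS, amplitudes)
    )


def default_normal_params(shape: LineShape = LineShape.GAUSSIAN) -> TissueClassParams:
    """Lipid-dominated normal-brain spectral model (2930/2845 ratio < 1)."""
    return TissueClassParams(_bands(_NORMAL_AMPLITUDES, shape), _NORMAL_FLUOR, TissueLabel.NORMAL)


def default_cancer_params(
    separation: float = 1.0, shape: LineShape = LineShape.GAUSSIAN
) -> TissueClassParams:
    """Protein-dominated dense-cancer model, contrast scaled by ``separation``.

    ``separation=1`` gives the full default contrast (2930/2845 ratio > 1);
    ``separation=0`` collapses onto the normal-brain model.
    """
    a_n = np.array(_NORMAL_AMPLITUDES)
    a_c = np.array(_CANCER_AMPLITUDES)
    amps = a_n + separation * (a_c - a_n)
    coeffs = tuple(
        n + separation * (c - n) for n, c in zip(_NORMAL_FLUOR, _CANCER_FLUOR)
    )
    return TissueClassParams(_bands(amps, shape), coeffs, TissueLabel.DENSE_CANCER)


def _scaled_coord(axis: WavenumberAxis) -> np.ndarray:
    mid = 0.5 * (axis.start + axis.stop)
    half = 0.5 * (axis.stop - axis.start)
    return (axis.values - mid) / half


def evaluate_baseline(coeffs: Sequence[float], axis: WavenumberAxis) -> np.ndarray:
    """Polynomial autofluorescence baseline on the axis (coeffs in t-powers)."""
    t = _scaled_coord(axis)
    return np.polynomial.polynomial.polyval(t, np.asarray(coeffs, dtype=float))


def instrument_response_curve(axis: WavenumberAxis, smoothness: float = 0.15) -> np.ndarray:
    """Smooth positive unit-mean multiplicative response of the optical chain."""
    t = _scaled_coord(axis)
    factors = 1.0 + smoothness * np.cos(np.pi * (t + 0.3))
    if np.any(factors <= 0):
        raise ValueError("response_smoothness too large: response must stay positive")
    return factors / factors.mean()


def pure_class_spectrum(params: TissueClassParams, axis: WavenumberAxis) -> np.ndarray:
    """Noiseless Raman component of a pure tissue class: sum of its bands."""
    for band in params.band_set:
        if not axis.contains(band.center):
            raise ValueError(f"band center {band.center} cm^-1 outside axis range")
    out = np.zeros(len(axis))
    for band in params.band_set:
        out += band.evaluate(axis.values)
    return out


def mixture_spectrum(
    cancer_fraction: float,
    normal_params: TissueClassParams,
    cancer_params: TissueClassParams,
    axis: WavenumberAxis,
) -> np.ndarray:
    """Linear mixture (1-f)*normal + f*cancer of the pure-class spectra."""
    if not 0.0 <= cancer_fraction <= 1.0:
        raise ValueError("cancer_fraction must lie in [0, 1]")
    f = float(cancer_fraction)
    return (1.0 - f) * pure_class_spectrum(normal_params, axis) + f * pure_class_spectrum(
        cancer_params, axis
    )


def label_from_fraction(cancer_fraction: float) -> TissueLabel:
    """Histology label from cancer-cell fraction: 0 -> normal, (0, 0.60] ->
    infiltrated, (0.60, 1] -> dense cancer."""
    if not 0.0 <= cancer_fraction <= 1.0:
        raise ValueError("cancer_fraction must lie in [0, 1]")
    if cancer_fraction == 0.0:
        return TissueLabel.NORMAL
    if cancer_fraction <= DENSE_FRACTION_THRESHOLD:
        return TissueLabel.INFILTRATED
    return TissueLabel.DENSE_CANCER


def _band_window_mean(spectrum: np.ndarray, axis: WavenumberAxis, center: float,
                      half_width: float = 5.0) -> float:
    mask = axis.window_mask(center, half_width)
    return float(spectrum[mask].mean())


def noiseless_ratio(spectrum: np.ndarray, axis: WavenumberAxis) -> float:
    """2930/2845 band ratio of a noiseless Raman component (5 cm^-1 half-window)."""
    return _band_window_mean(spectrum, axis, 2930.0) / _band_window_mean(spectrum, axis, 2845.0)


def simulate_acquisition(
    true_raman: np.ndarray,
    baseline_curve: np.ndarray,
    response_curve: np.ndarray,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    *,
    axis: WavenumberAxis,
    cancer_fraction: float = 0.0,
    meta: dict | None = None,
) -> tuple[RawAcquisition, GroundTruth]:
    """Simulate one measurement site: replicate signal frames + background frame.

    Each signal frame is ``clip(response * (raman + baseline) + dark + noise,
    0, adc_max)``; the laser-off background frame carries only dark level and
    noise. Noise is heteroscedastic Gaussian with variance proportional to the
    expected counts plus a floor (shot-noise approximation for a CCD). With
    probability ``p_spike`` one replicate gains a narrow high spike (cosmic-ray
    artifact); with probability ``p_saturation`` the frames are scaled to hit
    the ADC ceiling. Identical generator state gives identical output.
    """
    true_raman = np.asarray(true_raman, dtype=float)
    n = len(axis)
    for name, vec in (("true_raman", true_raman), ("baseline_curve", baseline_curve),
                      ("response_curve", response_curve)):
        if np.asarray(vec).shape != (n,):
            raise ValueError(f"{name} length does not match axis length {n}")

    expected = response_curve * (true_raman + baseline_curve) + config.dark_level
    sd = config.noise_scale * np.sqrt(np.maximum(expected, 0.0) + 0.1)
    frames = [
        expected + sd * rng.standard_normal(n) for _ in range(config.n_replicates)
    ]

    if config.p_spike > 0 and rng.random() < config.p_spike:
        i_frame = int(rng.integers(config.n_replicates))
        i_chan = int(rng.integers(1, n - 1))
        width = int(rng.integers(1, 3))
        # a cosmic-ray spike dwarfs the signal but stays below the ADC
        # ceiling, so it is an artifact distinct from saturation
        spike_amp = 30.0 * max(float(np.max(expected)), 1.0)
        headroom = 0.95 * config.adc_max - float(np.max(frames[i_frame][i_chan : i_chan + width]))
        frames[i_frame][i_chan : i_chan + width] += min(spike_amp, max(headroom, 0.0))

    if config.p_saturation > 0 and rng.random() < config.p_saturation:
        peak = max(float(np.max(f)) for f in frames)
        if peak > 0:
            scale = 1.05 * config.adc_max / peak
            frames = [f * scale for f in frames]

    frames = [np.clip(f, 0.0, config.adc_max) for f in frames]
    bg_sd = config.noise_scale * np.sqrt(config.dark_level + 0.1)
    background = np.clip(
        config.dark_level + bg_sd * rng.standard_normal(n), 0.0, config.adc_max
    )

    acq = RawAcquisition(axis=axis, frames=frames, background=background,
                         meta=dict(meta or {}))
    truth = GroundTruth(
        cancer_fraction=float(cancer_fraction),
        true_ratio_2930_2845=noiseless_ratio(true_raman, axis),
        baseline_curve=np.asarray(baseline_curve, dtype=float),
        response_curve=np.asarray(response_curve, dtype=float),
        true_raman=true_raman,
    )
    return acq, truth


def _patient_sizes(n_total: int, n_patients: int) -> list[int]:
    base, rem = divmod(n_total, n_patients)
    return [base + 1] * rem + [base] * (n_patients - rem)


def _draw_fraction(label: TissueLabel, rng: np.random.Generator) -> float:
    if label is TissueLabel.NORMAL:
        return 0.0
    if label is TissueLabel.INFILTRATED:
        u = rng.random()
        while u == 0.0:  # open at 0: fraction 0 means normal tissue
            u = rng.random()
        return DENSE_FRACTION_THRESHOLD * u
    u = rng.random()
    return DENSE_FRACTION_THRESHOLD + (1.0 - DENSE_FRACTION_THRESHOLD) * (1.0 - u)


def simulate_cohort(
    spec: CohortSpec | None = None,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
    axis: WavenumberAxis | None = None,
    normal_params: TissueClassParams | None = None,
    cancer_params: TissueClassParams | None = None,
) -> list[CohortRecord]:
    """Generate a labeled cohort of raw acquisitions with full ground truth.

    Class counts follow ``spec`` (defaults reproduce the 280-spectrum clinical
    composition). Infiltrated cancer fractions are uniform on (0, 0.60], dense
    fractions uniform on (0.60, 1]. Acquisitions are distributed over
    ``n_patients`` patients in near-equal blocks (14-15 sites per patient at
    the defaults) with class labels shuffled across patients. Per-acquisition
    biological variability: lognormal jitter on band amplitudes, overall
    intensity, and fluorescence coefficients.
    """
    spec = spec or CohortSpec()
    config = config or AcquisitionConfig()
    axis = axis or make_axis()
    if seed is None:
        seed = config.seed
    normal_params = normal_params or default_normal_params()
    cancer_params = cancer_params or default_cancer_params(spec.separation)

    if config.include_sapphire_band:
        normal_params = replace(
            normal_params, band_set=normal_params.band_set + (_SAPPHIRE_BAND,)
        )
        cancer_params = replace(
            cancer_params, band_set=cancer_params.band_set + (_SAPPHIRE_BAND,)
        )

    root = np.random.SeedSequence(seed)
    top_rng = np.random.default_rng(root.spawn(1)[0])
    labels = (
        [TissueLabel.NORMAL] * spec.n_normal
        + [TissueLabel.INFILTRATED] * spec.n_infiltrated
        + [TissueLabel.DENSE_CANCER] * spec.n_dense
    )
    order = top_rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    patient_ids: list[int] = []
    for pid, size in enumerate(_patient_sizes(len(labels), spec.n_patients)):
        patient_ids.extend([pid] * size)

    response = instrument_response_curve(axis, config.response_smoothness)
    a_n = normal_params.amplitudes()
    a_c = cancer_params.amplitudes()
    c_n = np.array(normal_params.fluorescence_coeffs)
    c_c = np.array(cancer_params.fluorescence_coeffs)

    records: list[CohortRecord] = []
    child_seeds = root.spawn(len(labels))
    for i, (label, child) in enumerate(zip(labels, child_seeds)):
        rng = np.random.default_rng(child)
        f = _draw_fraction(label, rng)
        amps = (1.0 - f) * a_n + f * a_c
        if spec.amplitude_jitter > 0:
            amps = amps * np.exp(spec.amplitude_jitter * rng.standard_normal(len(amps)))
        if spec.intensity_jitter > 0:
            amps = amps * np.exp(spec.intensity_jitter * rng.standard_normal())
        params_i = normal_params.with_amplitudes(amps)
        raman = pure_class_spectrum(params_i, axis)

        coeffs = (1.0 - f) * c_n + f * c_c
        if spec.baseline_jitter > 0:
            coeffs = coeffs * np.exp(spec.baseline_jitter * rng.standard_normal())
        baseline = evaluate_baseline(coeffs, axis)

        meta = {
            "acquisition_id": f"acq{i:04d}",
            "patient_id": f"P{patient_ids[i]:02d}",
            "label": label.value,
            "cancer_fraction": f,
            "integration_time": config.integration_time,
        }
        acq, truth = simulate_acquisition(
            raman, baseline, response, config, rng,
            axis=axis, cancer_fraction=f, meta=meta,
        )
        records.append(CohortRecord(acquisition=acq, label=label, truth=truth))
    return records
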