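"""Univariate band statistics on processed high-wavenumber Raman spectra.

The biochemical readouts: band intensities at the named CH/OH-stretch peaks,
the protein/lipid ratio (intensity at 2930 cm^-1 over 2845 cm^-1 — CH3
stretch dominated by proteins vs CH2 stretch dominated by lipids), per-class
mean spectra, two-sided two-sample t-tests per peak, and Tukey five-number
summaries of per-spectrum ratios for boxplots.

Band intensities are window means over |wavenumber - center| <= half_width
(default 5 cm^-1, about 3 channels on the default grid); half_width 0 reads
the single nearest channel. The ratio is computed on the baseline-removed,
pre-SNV spectrum by default: SNV-normalized values are mean-centered and can
be negative at 2845 cm^-1, so their ratio is not scale-free in the intended
sense. Ratios of SNV spectra are permitted but flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .axis import WavenumberAxis
from .dataset import LabeledDataset

__all__ = [
    "PeakDefinition",
    "DEFAULT_PEAKS",
    "RatioSummary",
    "PeakTestResult",
    "band_intensity",
    "protein_lipid_ratio",
    "class_mean_spectrum",
    "peak_ttest",
    "ratio_boxplot_summary",
    "peak_tests_by_class",
]

DEFAULT_HALF_WIDTH = 5.0


@dataclass(frozen=True)
class PeakDefinition:
    """A named band: center wavenumber and intensity-extraction half-width."""

    name: str
    center: float
    half_width: float = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be nonnegative")


#: The five prominent high-wavenumber peaks: CH2 symmetric / asymmetric
#: lipid-protein stretches (2845, 2885), protein CH3 stretch (2930), sapphire
#: lens artifact (3240, probe-dependent), water OH stretch (3450).
DEFAULT_PEAKS = (
    PeakDefinition("lipid_CH2_sym", 2845.0),
    PeakDefinition("lipid_CH2_asym", 2885.0),
    PeakDefinition("protein_CH3", 2930.0),
    PeakDefinition("sapphire", 3240.0),
    PeakDefinition("water_OH", 3450.0),
)

PROTEIN_PEAK = DEFAULT_PEAKS[2]
LIPID_PEAK = DEFAULT_PEAKS[0]


@dataclass(frozen=True)
class RatioSummary:
    """Tukey five-number summary of per-spectrum ratios within one class."""

    label: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass(frozen=True)
class PeakTestResult:
    peak: PeakDefinition
    t_statistic: float
    p_value: float
    group_means: tuple[float, float]


def band_intensity(
    spectrum: np.ndarray, peak: PeakDefinition, axis: WavenumberAxis
) -> float:
    """Mean intensity over the peak window; nearest channel if half_width is 0."""
    if not axis.contains(peak.center):
        raise ValueError(f"peak {peak.name} at {peak.center} cm^-1 outside axis")
    spectrum = np.asarray(spectrum, dtype=float)
    if peak.half_width == 0.0:
        return float(spectrum[axis.nearest_index(peak.center)])
    mask = axis.window_mask(peak.center, peak.half_width)
    if not mask.any():
        raise ValueError(f"empty band window for peak {peak.name}")
    return float(spectrum[mask].mean())


def protein_lipid_ratio(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> float:
    """2930/2845 band-intensity ratio, the protein/lipid metric."""
    num = band_intensity(spectrum, PeakDefinition("protein_CH3", 2930.0, half_width), axis)
    den = band_intensity(spectrum, PeakDefinition("lipid_CH2_sym", 2845.0, half_width), axis)
    if den == 0.0:
        raise ValueError("zero 2845 cm^-1 band intensity: ratio undefined")
    return num / den


def class_mean_spectrum(dataset: LabeledDataset, label: str, *, use_snv: bool = True) -> np.ndarray:
    """Channelwise arithmetic mean over all spectra with the given label."""
    mask = dataset.class_mask(label)
    if not mask.any():
        raise ValueError(f"no spectra with label {label!r}")
    X = dataset.snv if use_snv else dataset.pre_snv
    return X[mask].mean(axis=0)


def peak_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    peak: PeakDefinition | None = None,
    *,
    equal_var: bool = False,
) -> PeakTestResult:
    """Two-sided two-sample t-test on per-spectrum band intensities.

    Welch (unequal variance) by default; ``equal_var=True`` for the pooled
    Student variant. Identical groups give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return PeakTestResult(
        peak=peak or PeakDefinition("unnamed", np.nan, 0.0),
        t_statistic=float(t),
        p_value=float(p),
        group_means=(float(a.mean()), float(b.mean())),
    )


def peak_tests_by_class(
    dataset: LabeledDataset,
    label_a: str,
    label_b: str,
    peaks: tuple[PeakDefinition, ...] = DEFAULT_PEAKS,
    *,
    use_snv: bool = False,
) -> list[PeakTestResult]:
    """Per-peak two-sided t-tests between two tissue classes."""
    mask_a = dataset.class_mask(label_a)
    mask_b = dataset.class_mask(label_b)
    X = dataset.snv if use_snv else dataset.pre_snv
    results = []
    for peak in peaks:
        if not dataset.axis.contains(peak.center):
            continue
        vals = np.array([band_intensity(row, peak, dataset.axis) for row in X])
        results.append(peak_ttest(vals[mask_a], vals[mask_b], peak))
    return results


def _five_number(values: np.ndarray) -> tuple[float, float, float, float, float]:
    # type-7 (linear interpolation) quantiles; Tukey 1.5*IQR whiskers clipped
    # to the most extreme observation inside the fence
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return float(inside.min()), float(q1), float(med), float(q3), float(inside.max())


def ratio_boxplot_summary(
    dataset: LabeledDataset,
    half_width: float = DEFAULT_HALF_WIDTH,
    *,
    use_snv: bool = False,
) -> dict[str, RatioSummary]:
    """Per-class five-number summaries of the 2930/2845 ratio.

    Computed on the pre-SNV spectra by default (see module docstring).
    """
    X = dataset.snv if use_snv else dataset.pre_snv
    summaries: dict[str, RatioSummary] = {}
    for label in dict.fromkeys(dataset.labels):  # preserve first-seen order
        mask = dataset.class_mask(label)
        if not mask.any():
            raise ValueError(f"empty class {label!r}")
        ratios = np.array(
            [protein_lipid_ratio(row, dataset.axis, half_width) for row in X[mask]]
        )
        lo, q1, med, q3, hi = _five_number(ratios)
        summaries[label] = RatioSummary(
            label=label, n=int(mask.sum()), median=med, q1=q1, q3=q3,
            whisker_low=lo, whisker_high=hi,
        )
    return summaries
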