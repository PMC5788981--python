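"""Labeled collections of processed spectra shared by the stats and
classification stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import WavenumberAxis
from .preprocessing import ProcessedSpectrum

__all__ = ["LabeledDataset"]


@dataclass(frozen=True)
class LabeledDataset:
    """Processed spectra paired with tissue labels.

    ``snv`` holds the SNV-normalized spectra (one row per spectrum); ``pre_snv``
    the baseline-removed spectra before normalization, on which band-ratio
    statistics are computed by default. ``cancer_fractions`` may carry NaN for
    real data whose histology reports only the label.
    """

    axis: WavenumberAxis
    snv: np.ndarray = field(repr=False)
    pre_snv: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    cancer_fractions: np.ndarray = field(repr=False)
    patient_ids: tuple[str, ...] = ()
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n, p = self.snv.shape
        if self.pre_snv.shape != (n, p) or p != len(self.axis):
            raise ValueError("spectra matrices must be n_spectra x n_channels")
        if len(self.labels) != n or self.cancer_fractions.shape != (n,):
            raise ValueError("labels/fractions must match the number of spectra")

    def __len__(self) -> int:
        return self.snv.shape[0]

    @classmethod
    def from_processed(
        cls,
        spectra: list[ProcessedSpectrum],
        labels: list[str] | None = None,
    ) -> "LabeledDataset":
        if not spectra:
            raise ValueError("empty spectra list")
        axis = spectra[0].axis
        if labels is None:
            labels = [s.meta.get("label", "unknown") for s in spectra]
        fractions = np.array(
            [float(s.meta.get("cancer_fraction", np.nan)) for s in spectra]
        )
        return cls(
            axis=axis,
            snv=np.vstack([s.intensities for s in spectra]),
            pre_snv=np.vstack([s.pre_snv for s in spectra]),
            labels=tuple(labels),
            cancer_fractions=fractions,
            patient_ids=tuple(str(s.meta.get("patient_id", "")) for s in spectra),
            ids=tuple(str(s.meta.get("acquisition_id", i)) for i, s in enumerate(spectra)),
        )

    def class_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])
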