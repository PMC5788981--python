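"""Protein/lipid band-ratio statistics on a preprocessed synthetic cohort.

Computes the per-class 2930/2845 cm^-1 ratio (protein CH3 over lipid CH2
stretch) and a two-sided t-test of the protein band between dense cancer and
normal brain. Dense cancer shows the higher ratio: proteins up, lipids down.
"""

from hwnraman import (
    CohortSpec,
    InstrumentResponse,
    LabeledDataset,
    preprocess_cohort,
    ratio_boxplot_summary,
    simulate_cohort,
)
from hwnraman.spectral_stats import peak_tests_by_class
from hwnraman.synthetic import instrument_response_curve

records = simulate_cohort(
    CohortSpec(n_normal=25, n_infiltrated=12, n_dense=25, n_patients=6), seed=11
)
axis = records[0].acquisition.axis
response = InstrumentResponse(axis, instrument_response_curve(axis))
processed, qc = preprocess_cohort([r.acquisition for r in records], response)
dataset = LabeledDataset.from_processed(processed)
print(f"retained {qc.n_retained}/{qc.n_input} spectra after QC")

for label, s in ratio_boxplot_summary(dataset).items():
    print(f"{label:13s} n={s.n:3d}  ratio median {s.median:.3f}  IQR [{s.q1:.3f}, {s.q3:.3f}]")

print("\nper-peak two-sided t-tests, dense cancer vs normal:")
for r in peak_tests_by_class(dataset, "dense_cancer", "normal"):
    print(f"  {r.peak.name:14s} {r.peak.center:6.0f} cm^-1  t={r.t_statistic:7.2f}  p={r.p_value:.2e}")
# Expect a large positive t at 2930 (protein up in dense cancer) and a large
# negative t at 2845 (lipid down); the ratio separates the classes even
# before any multivariate model is fit.
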