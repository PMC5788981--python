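"""File formats and pipeline orchestration.

Spectra travel as plain delimited text for auditability: a wide spectra table
(first column the wavenumber axis, one column per CCD frame, frame ids in the
header) plus a metadata sidecar (one row per frame: acquisition id, frame
role signal/background, patient id, tissue label, cancer fraction). A
ground-truth table accompanies synthetic cohorts. Delimiter is auto-detected
among comma and tab.

:func:`run_pipeline` chains the stages (simulate -> preprocess -> stats ->
classify) into a reproducible run: deterministic given the seed, every
artifact hashed into a manifest alongside a config snapshot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .axis import WavenumberAxis
from .classification import SvmParams, binarize, evaluate
from .dataset import LabeledDataset
from .preprocessing import (
    InstrumentResponse,
    PreprocessingParams,
    RawAcquisition,
    preprocess_cohort,
)
from .spectral_stats import peak_tests_by_class, ratio_boxplot_summary
from .synthetic import AcquisitionConfig, CohortRecord, CohortSpec, simulate_cohort

__all__ = [
    "RunConfig",
    "read_spectra_table",
    "write_spectra_table",
    "write_cohort",
    "read_cohort",
    "run_pipeline",
]


class SpectraFormatError(ValueError):
    """Malformed spectra table (ragged rows, bad axis, duplicate ids)."""


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_spectra_table(path: str | Path) -> tuple[WavenumberAxis, np.ndarray, list[str]]:
    """Read a wide spectra table: (axis, frames[n_channels, n_frames], frame ids)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    header = path.read_text().splitlines()[0].split(delim)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise SpectraFormatError(f"{path}: duplicate frame ids {dupes}")
    try:
        df = pd.read_csv(path, sep=delim)
    except pd.errors.ParserError as exc:
        raise SpectraFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a wavenumber column plus >=1 frame column")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise SpectraFormatError(f"{path}: ragged/missing values in column {bad!r}")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wn) <= 0):
        row = int(np.argmax(np.diff(wn) <= 0)) + 1
        raise SpectraFormatError(f"{path}: wavenumber axis not strictly increasing at row {row}")
    ids = [str(c) for c in df.columns[1:]]
    frames = df.iloc[:, 1:].to_numpy(dtype=float)
    return WavenumberAxis(wn), frames, ids


def write_spectra_table(
    path: str | Path,
    axis: WavenumberAxis,
    frames: np.ndarray,
    ids: list[str],
    delimiter: str = "\t",
) -> None:
    frames = np.asarray(frames, dtype=float)
    if frames.shape != (len(axis), len(ids)):
        raise ValueError("frames must be n_channels x n_frames matching ids")
    df = pd.DataFrame(frames, columns=ids)
    df.insert(0, "wavenumber_cm1", axis.values)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.8g")


def write_cohort(records: list[CohortRecord], outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort: spectra table + metadata sidecar + ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not records:
        raise ValueError("empty cohort")
    axis = records[0].acquisition.axis

    frame_cols, ids, meta_rows, truth_rows = [], [], [], []
    for rec in records:
        acq = rec.acquisition
        aid = acq.meta["acquisition_id"]
        for j, frame in enumerate(acq.frames):
            fid = f"{aid}_s{j}"
            ids.append(fid)
            frame_cols.append(frame)
            meta_rows.append({**_meta_row(acq), "frame_id": fid, "role": "signal"})
        fid = f"{aid}_bg"
        ids.append(fid)
        frame_cols.append(acq.background)
        meta_rows.append({**_meta_row(acq), "frame_id": fid, "role": "background"})
        truth_rows.append(
            {
                "acquisition_id": aid,
                "cancer_fraction": rec.truth.cancer_fraction,
                "true_ratio_2930_2845": rec.truth.true_ratio_2930_2845,
            }
        )

    paths = {
        "spectra": outdir / "spectra.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_spectra_table(paths["spectra"], axis, np.column_stack(frame_cols), ids)
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def _meta_row(acq: RawAcquisition) -> dict:
    m = acq.meta
    return {
        "acquisition_id": m.get("acquisition_id", ""),
        "patient_id": m.get("patient_id", ""),
        "label": m.get("label", ""),
        "cancer_fraction": m.get("cancer_fraction", np.nan),
    }


def read_cohort(spectra_path: str | Path, metadata_path: str | Path) -> list[RawAcquisition]:
    """Reassemble raw acquisitions from a spectra table + metadata sidecar."""
    axis, frames, ids = read_spectra_table(spectra_path)
    meta = pd.read_csv(Path(metadata_path), sep=_sniff_delimiter(Path(metadata_path)))
    missing = set(meta["frame_id"]) - set(ids)
    if missing:
        raise SpectraFormatError(f"metadata frame ids missing from spectra table: {sorted(missing)[:3]}")
    col_of = {fid: i for i, fid in enumerate(ids)}
    acqs = []
    for aid, grp in meta.groupby("acquisition_id", sort=False):
        sig = grp[grp["role"] == "signal"]
        bg = grp[grp["role"] == "background"]
        if sig.empty or bg.empty:
            raise SpectraFormatError(f"acquisition {aid}: needs signal and background frames")
        row0 = grp.iloc[0]
        acqs.append(
            RawAcquisition(
                axis=axis,
                frames=[frames[:, col_of[f]] for f in sig["frame_id"]],
                background=frames[:, col_of[bg["frame_id"].iloc[0]]],
                meta={
                    "acquisition_id": str(aid),
                    "patient_id": str(row0.get("patient_id", "")),
                    "label": str(row0.get("label", "")),
                    "cancer_fraction": float(row0.get("cancer_fraction", np.nan)),
                    "exclude": bool(row0.get("exclude", False)),
                    "partitioned": bool(row0.get("partitioned", False)),
                },
            )
        )
    return acqs


@dataclass
class RunConfig:
    """Settings for a reproducible pipeline run."""

    output_dir: str = "hwnraman_run"
    seed: int = 0
    spectra_path: str | None = None  # None -> simulate
    metadata_path: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    svm: SvmParams = field(default_factory=SvmParams)
    ratio_half_width: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, typ in (
            ("cohort", CohortSpec),
            ("acquisition", AcquisitionConfig),
            ("preprocessing", PreprocessingParams),
            ("svm", SvmParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig, stages: str = "all") -> dict:
    """Run the requested stages and return an artifact manifest.

    ``stages`` is one of ``simulate``, ``preprocess``, ``stats``,
    ``classify`` or ``all``; later stages pull their inputs from the output
    directory, so staged invocations compose. Every written artifact is
    content-hashed into ``manifest.json`` together with the seeded config
    snapshot, making reruns bit-checkable.
    """
    valid = {"simulate", "preprocess", "stats", "classify", "all"}
    if stages not in valid:
        raise ValueError(f"unknown stage {stages!r}; expected one of {sorted(valid)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    want = (
        ("simulate", "preprocess", "stats", "classify") if stages == "all" else (stages,)
    )

    if "simulate" in want:
        records = simulate_cohort(config.cohort, config.acquisition, seed=config.seed)
        artifacts.update(write_cohort(records, outdir))

    if any(s in want for s in ("preprocess", "stats", "classify")):
        spectra_path = Path(config.spectra_path) if config.spectra_path else outdir / "spectra.tsv"
        metadata_path = Path(config.metadata_path) if config.metadata_path else outdir / "metadata.tsv"
        for p, stage in ((spectra_path, "spectra table"), (metadata_path, "metadata sidecar")):
            if not p.exists():
                raise FileNotFoundError(
                    f"missing {stage} at {p}; run the simulate stage first or point "
                    f"spectra_path/metadata_path at an existing cohort"
                )
        acqs = read_cohort(spectra_path, metadata_path)
        response = InstrumentResponse(
            axis=acqs[0].axis,
            factors=_response_for_run(config, acqs[0].axis),
        )
        processed, qc = preprocess_cohort(acqs, response, config.preprocessing)
        if not processed:
            raise ValueError("no spectra survived quality control")
        _write_json(outdir / "qc_report.json", {
            "n_input": qc.n_input,
            "n_rejected_saturation": qc.n_rejected_saturation,
            "n_rejected_artifact": qc.n_rejected_artifact,
            "n_rejected_partitioned": qc.n_rejected_partitioned,
            "n_retained": qc.n_retained,
        })
        artifacts["qc_report"] = outdir / "qc_report.json"
        dataset = LabeledDataset.from_processed(processed)
        write_spectra_table(
            outdir / "processed.tsv", dataset.axis, dataset.snv.T, list(dataset.ids)
        )
        artifacts["processed"] = outdir / "processed.tsv"

        if "stats" in want:
            summaries = ratio_boxplot_summary(dataset, config.ratio_half_width)
            tests = []
            if all(dataset.class_mask(c).sum() >= 2 for c in ("normal", "dense_cancer")):
                tests = peak_tests_by_class(dataset, "dense_cancer", "normal")
            _write_json(outdir / "stats.json", {
                "ratio_by_class": {k: dataclasses.asdict(v) for k, v in summaries.items()},
                "peak_ttests_dense_vs_normal": [
                    {
                        "peak": t.peak.name,
                        "center_cm1": t.peak.center,
                        "t_statistic": t.t_statistic,
                        "p_value": t.p_value,
                        "mean_dense": t.group_means[0],
                        "mean_normal": t.group_means[1],
                    }
                    for t in tests
                ],
            })
            artifacts["stats"] = outdir / "stats.json"

        if "classify" in want:
            y = binarize(dataset.labels)
            cv, roc, report = evaluate(dataset.snv, y, config.svm)
            pd.DataFrame(
                {"id": dataset.ids, "label": y, "score": cv.scores}
            ).to_csv(outdir / "scores.tsv", sep="\t", index=False)
            artifacts["scores"] = outdir / "scores.tsv"
            _write_json(outdir / "classification.json", {
                "auc": roc.auc,
                "threshold": report.threshold,
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "confusion": {"tp": report.tp, "fn": report.fn,
                              "tn": report.tn, "fp": report.fp},
                "provenance": list(cv.provenance),
            })
            artifacts["classification"] = outdir / "classification.json"

    manifest = {
        "seed": config.seed,
        "stages": list(want),
        "config": config.snapshot(),
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(artifacts.items())},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _response_for_run(config: RunConfig, axis: WavenumberAxis) -> np.ndarray:
    # the synthetic instrument's response is known in closed form; real runs
    # would derive it from a white-light calibration pair
    from .synthetic import instrument_response_curve

    return instrument_response_curve(axis, config.acquisition.response_smoothness)
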