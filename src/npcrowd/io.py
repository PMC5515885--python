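"""File formats: spectrum CSV, multichannel TIFF, manifests and reports.

Conventions: spectra are CSV with columns ``wavelength_nm,intensity``
(header required, one spectrum per file); batch manifests are CSV with
``file,label,concentration_mg_per_ml``; images are multichannel TIFF
with channel order (donor, acceptor[, chromosome marker]); label masks
are single-channel uint8 TIFF; everything structured is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .interphase import CellMeasurement, GroupSummary, TreatmentComparison
from .mitotic import TimelapseTrace
from .phantoms import PhantomManifest
from .spectra import CalibrationCurve, EmissionSpectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_manifest",
    "write_image",
    "read_image",
    "write_manifest",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_group_summary_csv",
    "write_comparison_json",
    "write_calibration_json",
    "read_calibration_json",
    "write_trace_csv",
    "write_half_times_json",
]


def read_spectrum_csv(path: str | Path, label: str = "") -> EmissionSpectrum:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: spectrum CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(float),
        df["intensity"].to_numpy(float),
        label=label or Path(path).stem,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectra_manifest(path: str | Path) -> list[tuple[Path, str, float]]:
    """Batch manifest rows: (spectrum file, label, concentration mg/mL)."""
    df = pd.read_csv(path)
    required = {"file", "label", "concentration_mg_per_ml"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: manifest needs columns {sorted(required)}"
        )
    base = Path(path).parent
    return [
        (base / row.file, str(row.label), float(row.concentration_mg_per_ml))
        for row in df.itertuples()
    ]


def write_image(path: str | Path, channels: Sequence[np.ndarray]) -> None:
    """Write channels (or a (T, C, H, W) stack) as multichannel TIFF."""
    arr = np.asarray(channels)
    tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_manifest(manifest: PhantomManifest, stem: str | Path) -> Path:
    """Write manifest JSON (+ label/mask TIFFs) next to ``stem``.

    Returns the JSON path.  Arrays go to ``<stem>.labels.tif`` /
    ``<stem>.masks.tif``; the JSON carries scalar ground truth.
    """
    stem = Path(stem)
    data = manifest.summary_dict()
    if manifest.labels is not None:
        lab_path = stem.with_suffix(".labels.tif")
        tifffile.imwrite(lab_path, manifest.labels.astype(np.uint8))
        data["labels_tiff"] = lab_path.name
    if manifest.chromosome_masks is not None:
        masks = np.stack(
            [manifest.chromosome_masks, manifest.rim_masks], axis=1
        ).astype(np.uint8)
        mask_path = stem.with_suffix(".masks.tif")
        tifffile.imwrite(mask_path, masks)
        data["masks_tiff"] = mask_path.name
    json_path = stem.with_suffix(".manifest.json")
    json_path.write_text(json.dumps(data, indent=2))
    return json_path


def write_measurements_csv(
    measurements: Sequence[CellMeasurement], path: str | Path
) -> None:
    pd.DataFrame([m.to_row() for m in measurements]).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> list[CellMeasurement]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        qc = getattr(row, "qc", "")
        out.append(
            CellMeasurement(
                probe_ne=row.probe_ne,
                probe_cyto=row.probe_cyto,
                relative_probe=row.relative_probe,
                localization_ne=row.localization_ne,
                localization_cyto=row.localization_cyto,
                cell_id=str(row.cell_id),
                qc_flags=[] if (not isinstance(qc, str) or not qc) else qc.split(";"),
            )
        )
    return out


def write_group_summary_csv(
    summaries: Sequence[GroupSummary], path: str | Path
) -> None:
    rows = [
        {
            "group": s.group,
            "n": s.n,
            "mean": s.mean,
            "sd": s.sd,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
            "n_outliers": len(s.outliers),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_comparison_json(comp: TreatmentComparison, path: str | Path) -> None:
    data = {
        "reference": {"group": comp.reference.group, "n": comp.reference.n,
                      "mean": comp.reference.mean, "sd": comp.reference.sd},
        "treated": {"group": comp.treated.group, "n": comp.treated.n,
                    "mean": comp.treated.mean, "sd": comp.treated.sd},
        "relative_mean": comp.relative_mean,
        "relative_values": comp.relative_values,
        "welch": {"t": comp.welch.t, "df": comp.welch.df, "p": comp.welch.p},
    }
    Path(path).write_text(json.dumps(data, indent=2))


def write_calibration_json(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2))


def read_calibration_json(path: str | Path) -> CalibrationCurve:
    data = json.loads(Path(path).read_text())
    return CalibrationCurve(
        slope=data["slope_per_mg_per_ml"],
        floor=data["floor"],
        ratio_at_zero=data["ratio_at_zero"],
        fitted_on=[tuple(p) for p in data.get("fitted_on", [])],
        residual_rms=data.get("residual_rms", 0.0),
        monotone_warning=data.get("monotone_warning", False),
        model=data.get("model", "linear-with-floor"),
    )


def write_trace_csv(trace: TimelapseTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_min": trace.times,
            "localization": trace.localization,
            "probe": trace.probe,
            "area": trace.area,
        }
    ).to_csv(path, index=False)


def write_half_times_json(trace: TimelapseTrace, path: str | Path) -> None:
    def ht(res):
        if res is None:
            return None
        return {
            "time_min": res.time,
            "recovered": res.recovered,
            "direction": res.direction,
            "level": res.level,
            "method": res.method,
        }

    data = {
        "anaphase_onset_frame": trace.anaphase_onset_frame,
        "half_max_localization": ht(trace.half_max_localization),
        "half_min_probe": ht(trace.half_min_probe),
        "qc": trace.qc_flags,
    }
    Path(path).write_text(json.dumps(data, indent=2))
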