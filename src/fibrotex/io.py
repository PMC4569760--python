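"""Reading and writing ROIs, cohorts, and manifests.

Real-use ROIs arrive either as DICOM (pixel spacing from the PixelSpacing
tag) or as PNG/TIFF with a JSON sidecar carrying ``pixel_spacing_mm`` and
optionally ``tilt_deg``.  Spacing is load-bearing — the standardization
chain resamples to a physical 0.5 mm grid — so a missing spacing is an
error, never a default.

Synthetic cohorts are written as a directory of float TIFF images plus a
CSV manifest (subject_id, roi_path, reader1..3, metavir_mean, collagen_pct,
true_severity) that the pipeline can re-ingest.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .standardize import ROIImage
from .synthetic import SubjectRecord

__all__ = [
    "read_roi",
    "write_roi",
    "write_stack",
    "write_cohort",
    "read_cohort_manifest",
]


def read_roi(
    path: str | Path,
    format: str | None = None,
    sidecar: str | Path | None = None,
) -> ROIImage:
    """Load an ROI from DICOM, PNG, or TIFF.

    For PNG/TIFF a JSON sidecar (default: same stem, ``.json``) must supply
    ``pixel_spacing_mm``; ``tilt_deg`` defaults to 0.  For DICOM the spacing
    comes from the PixelSpacing tag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        if "PixelSpacing" not in ds:
            raise ValueError(f"{path}: DICOM lacks PixelSpacing; spacing is required")
        spacing = float(ds.PixelSpacing[0])
        pixels = ds.pixel_array.astype(float)
        return ROIImage(pixels=pixels, pixel_spacing_mm=spacing, name=path.stem)
    if fmt in ("png", "tif", "tiff"):
        pixels = np.asarray(iio.imread(path), dtype=float)
        if pixels.ndim == 3:
            pixels = pixels.mean(axis=2)  # grayscale from RGB
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no sidecar {sidecar.name}; pixel_spacing_mm is required"
            )
        meta = json.loads(sidecar.read_text())
        if "pixel_spacing_mm" not in meta:
            raise ValueError(f"{sidecar}: sidecar lacks pixel_spacing_mm")
        return ROIImage(
            pixels=pixels,
            pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
            tilt_deg=float(meta.get("tilt_deg", 0.0)),
            name=path.stem,
        )
    raise ValueError(f"unsupported ROI format: {fmt}")


def write_roi(roi: ROIImage, path: str | Path) -> None:
    """Write an ROI as float32 TIFF plus a JSON sidecar with its geometry."""
    path = Path(path)
    tifffile.imwrite(path, roi.pixels.astype(np.float32))
    sidecar = {"pixel_spacing_mm": roi.pixel_spacing_mm, "tilt_deg": roi.tilt_deg}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def write_stack(stack, path_stem: str | Path) -> list[Path]:
    """Write a transform stack as a TIFF triplet (<stem>_{original,gradient,laplacian})."""
    paths = []
    for name in ("original", "gradient", "laplacian"):
        p = Path(f"{path_stem}_{name}.tiff")
        tifffile.imwrite(p, getattr(stack, name).astype(np.float32))
        paths.append(p)
    return paths


def write_cohort(records: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write a cohort as TIFF ROIs plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for j, roi in enumerate(rec.rois):
            roi_path = outdir / f"{rec.subject_id}_roi{j}.tiff"
            write_roi(roi, roi_path)
            row = {"subject_id": rec.subject_id, "roi_path": roi_path.name}
            for r, s in enumerate(rec.metavir_reader_scores, start=1):
                row[f"reader{r}"] = s
            row["metavir_mean"] = rec.metavir_mean
            row["collagen_pct"] = rec.collagen_pct
            row["true_severity"] = rec.true_severity
            rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(manifest: str | Path) -> list[SubjectRecord]:
    """Re-ingest a cohort written by :func:`write_cohort` (or hand-built)."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError(f"{manifest}: manifest is empty")
    reader_cols = sorted(c for c in df.columns if c.startswith("reader"))
    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        rois = [read_roi(manifest.parent / p) for p in grp["roi_path"]]
        first = grp.iloc[0]
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                rois=rois,
                metavir_reader_scores=[int(first[c]) for c in reader_cols],
                collagen_pct=float(first["collagen_pct"]),
                true_severity=float(first.get("true_severity", np.nan)),
            )
        )
    return records
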