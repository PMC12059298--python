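"""Reading and writing CT series and measurement results.

A *series* is one ordered stack of axial slices in Hounsfield units (HU).
Slices are read from single-frame DICOM files (stored values are rescaled to
HU with RescaleSlope/RescaleIntercept) and ordered along the patient axis.
This module also houses the packaged validation table: 50%/10% MTF values for
20 consecutive phantom slices measured by two independent single-image
methods, indexed by the tube current the automatic exposure control selected
for each slice.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .exceptions import SeriesReadError

__all__ = [
    "CTSlice",
    "CTSeries",
    "ValidationFixture",
    "read_series",
    "write_series",
    "slice_range",
    "load_table2_fixture",
    "write_results",
    "read_results",
]

_FIXTURE_RESOURCE = "table2_single_image_mtf.csv"


@dataclass(frozen=True)
class CTSlice:
    """One axial CT image in Hounsfield units.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        HU values; finite, rectangular, non-empty.
    pixel_spacing_mm : float
        Isotropic in-plane pixel spacing in mm.
    slice_index : int
        Position of the slice within its series (0-based, increasing).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.ndim != 2 or pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(pixels)):
            raise ValueError("pixels must be finite HU values")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        object.__setattr__(self, "pixels", pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CTSeries:
    """An ordered stack of slices with uniform geometry."""

    slices: tuple[CTSlice, ...]

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise ValueError("a series needs at least one slice")
        ref = slices[0]
        for s in slices[1:]:
            if s.shape != ref.shape:
                raise ValueError(
                    f"mixed slice dimensions: {s.shape} vs {ref.shape}"
                )
            if not np.isclose(s.pixel_spacing_mm, ref.pixel_spacing_mm):
                raise ValueError("mixed pixel spacing within a series")
        indices = [s.slice_index for s in slices]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("slice_index must be strictly increasing")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[CTSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> CTSlice:
        return self.slices[i]

    @property
    def pixel_spacing_mm(self) -> float:
        return self.slices[0].pixel_spacing_mm


@dataclass(frozen=True)
class ValidationFixture:
    """Packaged per-slice 50%/10% MTF comparison table (20 phantom slices).

    Columns: slice number, tube current (mA), then 50%MTF and 10%MTF in
    lp/cm for a reference QC program (IndoQCT) and for the single-image
    edge method.
    """

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        expected = [
            "number",
            "tube_current_ma",
            "indoqct_mtf50_lp_cm",
            "indoqct_mtf10_lp_cm",
            "single_mtf50_lp_cm",
            "single_mtf10_lp_cm",
        ]
        if list(self.rows.columns) != expected:
            raise ValueError(f"fixture columns must be {expected}")
        if len(self.rows) != 20:
            raise ValueError("fixture must contain exactly 20 rows")

    @property
    def dataframe(self) -> pd.DataFrame:
        return self.rows


def load_table2_fixture() -> ValidationFixture:
    """Load the packaged 20-row single-image MTF comparison table."""
    with resources.files("ctseqmtf.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        df = pd.read_csv(fh)
    return ValidationFixture(rows=df)


def _hu_from_dataset(ds: Dataset) -> np.ndarray:
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return ds.pixel_array.astype(np.float64) * slope + intercept


def _spacing_from_dataset(ds: Dataset, name: str) -> float:
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise SeriesReadError(f"{name}: missing PixelSpacing")
    row_mm, col_mm = float(spacing[0]), float(spacing[1])
    if not np.isclose(row_mm, col_mm, rtol=1e-6, atol=1e-9):
        raise SeriesReadError(
            f"{name}: anisotropic pixel spacing {row_mm} x {col_mm} mm "
            "is not supported (the edge-profile axis needs a single spacing)"
        )
    return row_mm


def read_series(path: str | Path) -> CTSeries:
    """Read a directory of single-frame DICOM files into a :class:`CTSeries`.

    Slices are ordered by the z component of ImagePositionPatient when every
    file carries it, otherwise by InstanceNumber.  Mixed dimensions, missing
    pixel spacing and non-monotonic positions are hard errors.
    """
    path = Path(path)
    if not path.is_dir():
        raise SeriesReadError(f"{path} is not a directory")
    entries = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        entries.append((f.name, ds))
    if not entries:
        raise SeriesReadError(f"no readable DICOM image files in {path}")

    use_position = all(
        getattr(ds, "ImagePositionPatient", None) is not None for _, ds in entries
    )
    if use_position:
        keyed = [(float(ds.ImagePositionPatient[2]), name, ds) for name, ds in entries]
    else:
        keyed = [(float(getattr(ds, "InstanceNumber", i)), name, ds)
                 for i, (name, ds) in enumerate(entries)]
    keyed.sort(key=lambda t: t[0])
    for (ka, _, _), (kb, name_b, _) in zip(keyed, keyed[1:]):
        if kb <= ka:
            raise SeriesReadError(
                f"non-monotonic slice ordering at file {name_b!r} "
                f"(position {kb} follows {ka})"
            )

    slices = []
    for idx, (_, name, ds) in enumerate(keyed):
        spacing = _spacing_from_dataset(ds, name)
        slices.append(
            CTSlice(pixels=_hu_from_dataset(ds), pixel_spacing_mm=spacing,
                    slice_index=idx)
        )
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise SeriesReadError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
    return CTSeries(slices=tuple(slices))


def write_series(series: CTSeries, path: str | Path,
                 slice_thickness_mm: float = 5.0) -> list[Path]:
    """Write a series as one minimal single-frame CT DICOM file per slice.

    HU are stored as signed 16-bit integers with RescaleSlope 1 and
    RescaleIntercept -1024, so integer-valued HU round-trip exactly.  All
    UIDs are derived deterministically from the pixel content, so identical
    series produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digest = str(abs(hash("ctseqmtf")))
    series_uid = generate_uid(entropy_srcs=["ctseqmtf-series", digest,
                                            str(len(series))])
    written = []
    for s in series:
        intercept = -1024.0
        stored = np.round(s.pixels - intercept).astype(np.int16)
        sop_uid = generate_uid(
            entropy_srcs=["ctseqmtf-slice", str(s.slice_index),
                          str(float(stored.sum())), str(s.pixel_spacing_mm)]
        )
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = generate_uid(entropy_srcs=["ctseqmtf-study", digest])
        ds.Modality = "CT"
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "ctseqmtf"
        ds.Rows, ds.Columns = s.shape
        ds.PixelSpacing = [s.pixel_spacing_mm, s.pixel_spacing_mm]
        ds.SliceThickness = slice_thickness_mm
        ds.InstanceNumber = s.slice_index + 1
        ds.ImagePositionPatient = [0.0, 0.0, s.slice_index * slice_thickness_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = stored.tobytes()
        out = path / f"slice_{s.slice_index:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


def slice_range(series: CTSeries, first: int, last: int) -> CTSeries:
    """Contiguous sub-series selected with 1-based inclusive indices.

    The 1-based convention matches how slices are counted on the console
    ("the 16th to the 35th image").
    """
    n = len(series)
    if not (1 <= first <= last <= n):
        raise ValueError(
            f"invalid slice range {first}:{last}; valid ranges satisfy "
            f"1 <= first <= last <= {n}"
        )
    return CTSeries(slices=series.slices[first - 1:last])


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, path: str | Path, config: dict | None = None) -> None:
    """Write measurement results as JSON.

    ``results`` may be a dataclass (e.g. a ResolutionResult or a sequence
    measurement) or a list of them.  Floats are serialized at full precision
    so re-reading reproduces values exactly.
    """
    record = {"config": _jsonable(config) if config is not None else None,
              "results": _jsonable(results)}
    path = Path(path)
    try:
        with path.open("w") as fh:
            json.dump(record, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> dict:
    """Read a JSON results record written by :func:`write_results`."""
    with Path(path).open() as fh:
        return json.load(fh)
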