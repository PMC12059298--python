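"""ESF -> LSF -> MTF chain for single slices and pooled sequences.

The edge spread function (ESF) of an ROI is the per-row mean HU profile
across the air/object boundary.  It is upsampled 5x with a cubic spline,
differentiated to the line spread function (LSF), and Fourier-transformed;
the magnitude spectrum normalized to 1 at zero frequency is the modulation
transfer function (MTF).  Spatial frequencies are reported in line pairs per
centimeter (1 cycle/mm = 10 lp/cm) and the curve is truncated at the Nyquist
frequency of the *original* pixel sampling, since interpolation adds no
information beyond it.

For a sequence, the per-slice ESF samples are pooled into one scatter and a
smoothing spline (generalized cross-validation by default) produces a single
sequence-level ESF, from which one sequence-level MTF follows.  A
four-parameter Gaussian-plus-Lorentzian model can be fitted to stabilize the
curve; resolution metrics are the frequencies of the first downward
crossings of 0.5 and 0.1 (the "50%MTF" and "10%MTF" values).

Interpolating and differentiating a coarsely sampled edge attenuates the
measured spectrum by a known, purely numerical amplitude response (the
cardinal cubic-spline reconstruction response times the central-difference
response).  The measurement pipeline divides this response out, a standard
compensation in MTF practice; the bare :func:`lsf_to_mtf` applies it only on
request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline, make_smoothing_spline
from scipy.optimize import curve_fit

from .exceptions import (
    CTSeqMTFError,
    DegenerateLSFError,
    MeasurementError,
    MTFFitError,
    ResolutionBeyondNyquistError,
)
from .edge_localization import EdgeROI, locate_edge_roi
from .series_io import CTSeries

__all__ = [
    "ESFCurve",
    "PooledESF",
    "LSFCurve",
    "MTFCurve",
    "MTFFitParams",
    "ResolutionResult",
    "MeasurementConfig",
    "SequenceMeasurement",
    "compute_esf",
    "upsample_esf",
    "pool_sequence_esf",
    "esf_to_lsf",
    "finalize_lsf",
    "sampling_response",
    "lsf_to_mtf",
    "fit_mtf_model",
    "resolution_metrics",
    "measure_sequence",
    "write_mtf_curve_csv",
]

logger = logging.getLogger(__name__)

_ZEROING_POINTS = 5  # leading (air-side) samples whose mean defines the LSF baseline


# ---------------------------------------------------------------------------
# curve containers

@dataclass
class ESFCurve:
    """Edge profile: position across the edge (mm) vs mean HU."""

    positions_mm: np.ndarray
    values_hu: np.ndarray
    source_slice: int | str = 0

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=np.float64)
        self.values_hu = np.asarray(self.values_hu, dtype=np.float64)
        if self.positions_mm.ndim != 1 or self.positions_mm.size < 2:
            raise ValueError("an ESF needs at least 2 samples")
        if self.positions_mm.shape != self.values_hu.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def spacing_mm(self) -> float:
        return float(self.positions_mm[1] - self.positions_mm[0])

    def __len__(self) -> int:
        return self.positions_mm.size


@dataclass
class PooledESF:
    """Per-slice ESF samples pooled into one smooth sequence-level curve."""

    scatter_positions_mm: np.ndarray
    scatter_values_hu: np.ndarray
    smooth_curve: ESFCurve
    smoothing_parameter: float | None  # csaps-style p in (0,1]; None = GCV
    degenerate: bool = False  # True when only one input curve was available


@dataclass
class LSFCurve:
    """Normalized line spread function on a uniform grid."""

    positions_mm: np.ndarray
    values: np.ndarray

    @property
    def spacing_mm(self) -> float:
        return float(self.positions_mm[1] - self.positions_mm[0])


@dataclass
class MTFFitParams:
    """Coefficients of the Gaussian-plus-Lorentzian MTF model.

    MTF_fit(f) = [c exp(-pi^2 f^2 / d) + a / (1 + 4 pi^2 f^2 b^2)] / (c + a)

    with f in lp/cm.  The model equals 1 at f = 0 by construction, and (a, c)
    are identifiable only through their ratio, so fits are normalized to
    a + c = 1.
    """

    a: float
    b: float
    c: float
    d: float

    def __call__(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=np.float64)
        gauss = self.c * np.exp(-np.pi**2 * f**2 / self.d)
        lorentz = self.a / (1.0 + 4.0 * np.pi**2 * f**2 * self.b**2)
        return (gauss + lorentz) / (self.c + self.a)


@dataclass
class MTFCurve:
    """Modulation vs spatial frequency (lp/cm), normalized to 1 at f = 0."""

    frequencies_lp_per_cm: np.ndarray
    modulation: np.ndarray
    nyquist_lp_per_cm: float
    fitted: MTFFitParams | None = None

    def __post_init__(self) -> None:
        self.frequencies_lp_per_cm = np.asarray(self.frequencies_lp_per_cm,
                                                dtype=np.float64)
        self.modulation = np.asarray(self.modulation, dtype=np.float64)
        if self.frequencies_lp_per_cm[0] != 0.0:
            raise ValueError("frequency axis must start at 0")
        if not np.isclose(self.modulation[0], 1.0):
            raise ValueError("modulation must be 1 at zero frequency")


@dataclass(frozen=True)
class ResolutionResult:
    """50%/10% MTF frequencies in lp/cm with provenance."""

    f50_lp_per_cm: float
    f10_lp_per_cm: float
    mode: Literal["per-slice", "pooled"]
    curve_source: Literal["raw", "fitted"]
    slice_index: int | str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f50_lp_per_cm < self.f10_lp_per_cm:
            raise ValueError("expected 0 < f50 < f10 on a decreasing MTF")


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunable parameters of the sequence measurement pipeline."""

    threshold_hu: float = -500.0
    roi_half_width: int = 20
    upsample_factor: int = 5
    smoothing: float | str = "auto"  # csaps-style p in (0,1], or "auto" for GCV
    fit_model: bool = True
    correct_sampling: bool = True
    fit_band_fraction: float = 0.6  # model fitted to f <= fraction * Nyquist

    def to_dict(self) -> dict:
        return {
            "threshold_hu": self.threshold_hu,
            "roi_half_width": self.roi_half_width,
            "upsample_factor": self.upsample_factor,
            "smoothing": self.smoothing,
            "fit_model": self.fit_model,
            "correct_sampling": self.correct_sampling,
            "fit_band_fraction": self.fit_band_fraction,
        }


@dataclass
class SequenceMeasurement:
    """Outcome of measuring one CT sequence."""

    pooled: ResolutionResult
    per_slice: dict[int, ResolutionResult]
    skipped: dict[int, str]
    pooled_mtf: MTFCurve
    pooled_esf: PooledESF
    config: dict


# ---------------------------------------------------------------------------
# single-curve operations

def compute_esf(roi: EdgeROI) -> ESFCurve:
    """Average the ROI across columns: ESF value i = mean of patch row i.

    Rows run from air (top) to object (bottom), so the profile rises from
    the background HU to the object HU; positions are row index times the
    pixel spacing.
    """
    values = roi.patch.mean(axis=1)
    positions = np.arange(roi.patch.shape[0]) * roi.pixel_spacing_mm
    return ESFCurve(positions_mm=positions, values_hu=values,
                    source_slice=0)


def upsample_esf(esf: ESFCurve, factor: int = 5) -> ESFCurve:
    """Cubic-spline resample onto a grid ``factor`` times finer.

    Inserting ``factor - 1`` interpolated points between neighbours gives
    ``factor * (n - 1) + 1`` samples; original samples are reproduced
    exactly.
    """
    if factor < 1:
        raise ValueError("upsample factor must be >= 1")
    if len(esf) < 4:
        raise ValueError("cubic spline upsampling needs >= 4 samples")
    step = np.diff(esf.positions_mm)
    if not np.allclose(step, step[0]):
        raise ValueError("ESF positions must be uniformly spaced")
    spline = CubicSpline(esf.positions_mm, esf.values_hu)
    n_out = factor * (len(esf) - 1) + 1
    grid = esf.positions_mm[0] + np.arange(n_out) * (step[0] / factor)
    return ESFCurve(positions_mm=grid, values_hu=spline(grid),
                    source_slice=esf.source_slice)


def pool_sequence_esf(esfs: Sequence[ESFCurve],
                      smoothing: float | str = "auto",
                      factor: int = 5) -> PooledESF:
    """Pool per-slice ESF samples and fit one smoothing spline.

    All curves must share the same position grid (the ROI placement centers
    every curve on its detected edge, so grids align).  With ``smoothing =
    "auto"`` the penalty is chosen by generalized cross-validation; a numeric
    ``smoothing`` is a csaps-style p in (0, 1] (1 = interpolation), mapped to
    the penalty lam = (1 - p) / p.  When the pooled scatter is exactly
    replicated (noiseless curves), GCV degenerates to interpolation and an
    interpolating cubic spline is used directly.
    """
    if len(esfs) == 0:
        raise ValueError("no ESF curves to pool")
    ref = esfs[0]
    for e in esfs[1:]:
        if len(e) != len(ref) or not np.allclose(e.positions_mm, ref.positions_mm):
            raise ValueError("ESF curves have mismatched position grids")
    if len(esfs) == 1:
        logger.warning("pooling a single ESF curve: returning it unchanged")
        smooth = upsample_esf(ref, factor)
        smooth.source_slice = "pooled"
        return PooledESF(scatter_positions_mm=ref.positions_mm.copy(),
                         scatter_values_hu=ref.values_hu.copy(),
                         smooth_curve=smooth, smoothing_parameter=1.0,
                         degenerate=True)

    positions = ref.positions_mm
    stack = np.vstack([e.values_hu for e in esfs])  # (n_slices, n_points)
    scatter_x = np.tile(positions, len(esfs))
    scatter_y = stack.ravel()
    ybar = stack.mean(axis=0)
    counts = np.full(positions.size, float(len(esfs)))

    p_eff: float | None
    if smoothing == "auto":
        if np.all(np.ptp(stack, axis=0) == 0.0):
            spline = make_interp_spline(positions, ybar, k=3)  # GCV limit
            p_eff = 1.0
        else:
            spline = make_smoothing_spline(positions, ybar, w=counts, lam=None)
            p_eff = None
    else:
        p = float(smoothing)
        if not 0 < p <= 1:
            raise ValueError("smoothing parameter must lie in (0, 1]")
        if p == 1.0:
            spline = make_interp_spline(positions, ybar, k=3)
        else:
            lam = (1.0 - p) / p
            spline = make_smoothing_spline(positions, ybar, w=counts, lam=lam)
        p_eff = p

    step = positions[1] - positions[0]
    n_out = factor * (positions.size - 1) + 1
    grid = positions[0] + np.arange(n_out) * (step / factor)
    smooth = ESFCurve(positions_mm=grid, values_hu=spline(grid),
                      source_slice="pooled")
    return PooledESF(scatter_positions_mm=scatter_x, scatter_values_hu=scatter_y,
                     smooth_curve=smooth, smoothing_parameter=p_eff,
                     degenerate=False)


def finalize_lsf(values: np.ndarray) -> np.ndarray:
    """Zero, orient and range-normalize a raw (differentiated) LSF.

    Subtracts the mean of the first five samples (the flat air-side tail),
    flips the sign if the dominant peak is negative, and divides by the
    max - min range.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < _ZEROING_POINTS:
        raise ValueError("LSF needs at least 5 samples for baseline zeroing")
    values = values - values[:_ZEROING_POINTS].mean()
    if abs(values.min()) > abs(values.max()):
        values = -values
    span = values.max() - values.min()
    if span <= 1e-12 * max(1.0, abs(values).max()) or span == 0.0:
        raise DegenerateLSFError("degenerate LSF: no edge in the profile")
    return values / span


def esf_to_lsf(esf: ESFCurve) -> LSFCurve:
    """Differentiate the ESF (central differences, one-sided at the ends)."""
    if len(esf) < _ZEROING_POINTS:
        raise ValueError("ESF too short to differentiate")
    step = np.diff(esf.positions_mm)
    if not np.allclose(step, step[0]):
        raise ValueError("ESF positions must be uniformly spaced")
    raw = np.gradient(esf.values_hu, step[0])
    return LSFCurve(positions_mm=esf.positions_mm.copy(), values=finalize_lsf(raw))


def sampling_response(frequencies_cycles_per_mm: np.ndarray,
                      pixel_spacing_mm: float,
                      factor: int) -> np.ndarray:
    """Amplitude response of the sample -> cubic spline -> gradient chain.

    Cardinal cubic-spline interpolation of samples spaced T attenuates a
    sinusoid of frequency f by sinc(fT)^4 * 6 / (4 + 2 cos(2 pi f T)); the
    central difference on the fine grid (spacing T / factor) contributes
    sin(2 pi f delta) / (2 pi f delta).  The product is the purely numerical
    attenuation the measurement chain imprints on the true MTF.
    """
    f = np.asarray(frequencies_cycles_per_mm, dtype=np.float64)
    T = float(pixel_spacing_mm)
    delta = T / factor
    H = np.sinc(f * T) ** 4 * 6.0 / (4.0 + 2.0 * np.cos(2.0 * np.pi * f * T))
    x = 2.0 * np.pi * f * delta
    with np.errstate(invalid="ignore", divide="ignore"):
        Hg = np.where(x > 0, np.sin(x) / np.where(x > 0, x, 1.0), 1.0)
    return H * Hg


def lsf_to_mtf(lsf: LSFCurve, pixel_spacing_mm: float, factor: int,
               correct_sampling: bool = False) -> MTFCurve:
    """Fourier-transform the LSF into an MTF in lp/cm.

    The magnitude of the DFT (no window, no zero padding) is divided by its
    zero-frequency value so that MTF(0) = 1, and the curve is truncated at
    the Nyquist frequency of the original pixel sampling.  With
    ``correct_sampling`` the numerical :func:`sampling_response` of the
    interpolation/differentiation chain is divided out.
    """
    n = lsf.values.size
    delta = lsf.spacing_mm
    if not np.isclose(delta, pixel_spacing_mm / factor, rtol=1e-6):
        raise ValueError("LSF grid spacing does not match pixel_spacing/factor")
    spectrum = np.abs(np.fft.rfft(lsf.values))
    if spectrum[0] == 0.0:
        raise DegenerateLSFError("all-zero LSF: DC component vanishes")
    freqs_cpm = np.fft.rfftfreq(n, delta)
    nyquist_cpm = 1.0 / (2.0 * pixel_spacing_mm)
    keep = freqs_cpm <= nyquist_cpm * (1.0 + 1e-12)
    modulation = spectrum[keep] / spectrum[0]
    freqs_cpm = freqs_cpm[keep]
    if correct_sampling:
        modulation = modulation / sampling_response(freqs_cpm, pixel_spacing_mm,
                                                    factor)
    return MTFCurve(frequencies_lp_per_cm=freqs_cpm * 10.0,
                    modulation=modulation,
                    nyquist_lp_per_cm=nyquist_cpm * 10.0)


# ---------------------------------------------------------------------------
# model fit and metrics

def _model(f, c, b, d):
    return c * np.exp(-np.pi**2 * f**2 / d) + (1.0 - c) / (1.0 + 4.0 * np.pi**2 * f**2 * b**2)


_FIT_STARTS = (
    (0.5, 1.0, 1.0),
    (0.9, 0.5, 2.0),
    (0.9, 0.1, 5.0),
    (0.5, 0.2, 10.0),
    (1.0, 0.05, 3.0),
)


def fit_mtf_model(curve: MTFCurve,
                  max_frequency_lp_per_cm: float | None = None) -> MTFFitParams:
    """Least-squares fit of the four-parameter MTF model.

    Fits (c, b, d) with a = 1 - c (the (a, c) pair is identifiable only up
    to a common scale) over frequencies up to ``max_frequency_lp_per_cm``
    (default: the whole retained band), restarting from several initial
    guesses; the best-residual fit wins.  The parameters are stored on
    ``curve.fitted`` and returned.
    """
    f = curve.frequencies_lp_per_cm
    m = curve.modulation
    if max_frequency_lp_per_cm is not None:
        band = f <= max_frequency_lp_per_cm
        f, m = f[band], m[band]
    if f.size < 8:
        raise MTFFitError("need at least 8 frequency samples to fit the model")
    best: tuple[np.ndarray, float] | None = None
    for p0 in _FIT_STARTS:
        try:
            popt, _ = curve_fit(_model, f, m, p0=p0,
                                bounds=([0.0, 1e-6, 1e-6], [1.0, 1e3, 1e4]),
                                maxfev=5000, method="trf")
        except RuntimeError:
            continue
        residual = float(np.sum((_model(f, *popt) - m) ** 2))
        if best is None or residual < best[1]:
            best = (popt, residual)
    if best is None:
        raise MTFFitError(
            "MTF model fit did not converge from any start; "
            "use raw-curve mode (fit_model=False)"
        )
    c, b, d = best[0]
    params = MTFFitParams(a=1.0 - c, b=float(b), c=float(c), d=float(d))
    curve.fitted = params
    return params


def _first_downward_crossing(freqs: np.ndarray, values: np.ndarray,
                             level: float) -> float | None:
    below = np.nonzero(values <= level)[0]
    below = below[below > 0]
    if below.size == 0:
        return None
    i = int(below[0])
    if values[i] == level:
        return float(freqs[i])
    f0, f1 = freqs[i - 1], freqs[i]
    v0, v1 = values[i - 1], values[i]
    return float(f0 + (f1 - f0) * (v0 - level) / (v0 - v1))


_FIT_GRID_STEP = 0.01  # lp/cm resolution for metrics read off the fitted model


def resolution_metrics(curve: MTFCurve, use_fit: bool = False,
                       mode: Literal["per-slice", "pooled"] = "per-slice",
                       slice_index: int | str | None = None) -> ResolutionResult:
    """50%/10% MTF frequencies: first downward crossings of 0.5 and 0.1.

    Raw curves are interpolated linearly between the bracketing samples and
    never extrapolated beyond the retained (Nyquist-limited) band.  With
    ``use_fit`` the fitted model is evaluated on a 0.01 lp/cm grid; the
    parametric form may be followed moderately beyond the Nyquist band
    (up to twice the band edge), which is what makes a 10% crossing beyond
    Nyquist readable at all.
    """
    if use_fit:
        if curve.fitted is None:
            raise MTFFitError("use_fit requested but the curve has no fitted model")
        fmax = 2.0 * curve.frequencies_lp_per_cm[-1]
        freqs = np.arange(0.0, fmax + _FIT_GRID_STEP, _FIT_GRID_STEP)
        values = curve.fitted(freqs)
        source = "fitted"
    else:
        freqs = curve.frequencies_lp_per_cm
        values = curve.modulation
        source = "raw"
    f50 = _first_downward_crossing(freqs, values, 0.5)
    f10 = _first_downward_crossing(freqs, values, 0.1)
    if f50 is None or f10 is None:
        missing = "50%" if f50 is None else "10%"
        raise ResolutionBeyondNyquistError(
            f"MTF does not fall below the {missing} level within the retained "
            "band: resolution beyond Nyquist"
        )
    return ResolutionResult(f50_lp_per_cm=f50, f10_lp_per_cm=f10, mode=mode,
                            curve_source=source, slice_index=slice_index)


# ---------------------------------------------------------------------------
# sequence pipeline

def _slice_esf(ct_slice, config: MeasurementConfig) -> ESFCurve:
    roi = locate_edge_roi(ct_slice, config.threshold_hu, config.roi_half_width)
    esf = compute_esf(roi)
    esf.source_slice = ct_slice.slice_index
    return esf


def measure_sequence(series: CTSeries,
                     config: MeasurementConfig | None = None
                     ) -> SequenceMeasurement:
    """Run the full per-slice and pooled-sequence measurement.

    Per slice: segment -> centroid -> top edge -> ROI -> ESF -> 5x spline
    upsample -> LSF -> MTF -> raw 50%/10% metrics.  Slices where any stage
    fails are skipped with a logged reason.  All successfully extracted ESFs
    are then pooled with a smoothing spline into one sequence-level ESF, and
    the sequence MTF (optionally stabilized by the four-parameter model fit)
    yields the pooled metrics.
    """
    if config is None:
        config = MeasurementConfig()
    spacing = series.pixel_spacing_mm
    factor = config.upsample_factor

    esfs: list[ESFCurve] = []
    per_slice: dict[int, ResolutionResult] = {}
    skipped: dict[int, str] = {}
    for ct_slice in series:
        idx = ct_slice.slice_index
        try:
            esf = _slice_esf(ct_slice, config)
        except CTSeqMTFError as exc:
            logger.warning("slice %d skipped: %s", idx, exc)
            skipped[idx] = str(exc)
            continue
        esfs.append(esf)
        try:
            lsf = esf_to_lsf(upsample_esf(esf, factor))
            mtf = lsf_to_mtf(lsf, spacing, factor,
                             correct_sampling=config.correct_sampling)
            per_slice[idx] = resolution_metrics(mtf, use_fit=False,
                                                mode="per-slice",
                                                slice_index=idx)
        except CTSeqMTFError as exc:
            logger.warning("slice %d: metrics unavailable (%s); "
                           "its ESF still enters the pooled fit", idx, exc)
            skipped[idx] = str(exc)

    if not esfs:
        summary = "; ".join(f"slice {i}: {r}" for i, r in skipped.items())
        raise MeasurementError(f"every slice failed edge localization ({summary})")

    pooled_esf = pool_sequence_esf(esfs, smoothing=config.smoothing, factor=factor)
    pooled_lsf = esf_to_lsf(pooled_esf.smooth_curve)
    pooled_mtf = lsf_to_mtf(pooled_lsf, spacing, factor,
                            correct_sampling=config.correct_sampling)
    if config.fit_model:
        fit_mtf_model(pooled_mtf,
                      max_frequency_lp_per_cm=config.fit_band_fraction
                      * pooled_mtf.nyquist_lp_per_cm)
    pooled = resolution_metrics(pooled_mtf, use_fit=config.fit_model,
                                mode="pooled", slice_index="pooled")
    return SequenceMeasurement(pooled=pooled, per_slice=per_slice,
                               skipped=skipped, pooled_mtf=pooled_mtf,
                               pooled_esf=pooled_esf, config=config.to_dict())


def write_mtf_curve_csv(curve: MTFCurve, path: str | Path) -> None:
    """Write an MTF curve as CSV: frequency_lp_per_cm, mtf_raw[, mtf_fitted]."""
    import pandas as pd

    data = {"frequency_lp_per_cm": curve.frequencies_lp_per_cm,
            "mtf_raw": curve.modulation}
    if curve.fitted is not None:
        data["mtf_fitted"] = curve.fitted(curve.frequencies_lp_per_cm)
    pd.DataFrame(data).to_csv(path, index=False)
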