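"""Time-series conditioning: detrending, nuisance regression, band-pass.

Regional BOLD series are conditioned in a fixed order — linear detrend,
nuisance regression, ideal band-pass — before correlation networks are
built. The band-pass is an ideal (rectangular) filter applied on discrete
Fourier coefficients: bins with low <= f <= high are kept unchanged, all
others are zeroed, and the DC bin is always removed when low > 0. This
matches the filtering convention of the REST/DPARSF resting-state
toolchain and makes the filter exactly idempotent and linear, which the
test suite exploits. A Butterworth alternative is available for
sensitivity analysis but is not the default.

Each operation appends its name to the set's provenance tuple so the
applied order is auditable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .bands import BandSpec, InvalidDesignError


class InsufficientDataError(ValueError):
    """Too few time points for the requested operation."""


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Per-subject T x N matrix of regional time series.

    ``region_ids`` are 1-based atlas indices in registry order;
    ``provenance`` records the conditioning steps applied so far.
    """

    subject_id: str
    values: np.ndarray            # shape (T, N), float
    tr_seconds: float
    region_ids: tuple[int, ...]
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if not np.isfinite(v).all():
            raise ValueError("values contain non-finite entries")
        if v.shape[1] != len(self.region_ids):
            raise ValueError(
                f"{v.shape[1]} columns but {len(self.region_ids)} region ids"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass(frozen=True)
class NuisanceSet:
    """T x M matrix of nuisance covariates (motion, global/WM/CSF signals)."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(self.names):
            raise ValueError("one name per covariate column required")
        object.__setattr__(self, "values", v)

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


def detrend_linear(ts: ROITimeSeriesSet) -> ROITimeSeriesSet:
    """Remove the least-squares linear trend (and mean) from every column."""
    if ts.n_timepoints < 3:
        raise InsufficientDataError(
            f"linear detrend needs T >= 3, got T={ts.n_timepoints}"
        )
    out = _signal.detrend(ts.values, axis=0, type="linear")
    return replace(ts, values=out, provenance=ts.provenance + ("detrend_linear",))


def regress_nuisance(ts: ROITimeSeriesSet, nuis: NuisanceSet) -> ROITimeSeriesSet:
    """Project out nuisance covariates (plus an intercept) from every column.

    Residuals are orthogonal to every covariate column and to the constant.
    A rank-deficient covariate matrix is fit by pseudo-inverse with a
    warning; M >= T is rejected.
    """
    T = ts.n_timepoints
    if nuis.n_covariates and nuis.values.shape[0] != T:
        raise ValueError(
            f"nuisance has {nuis.values.shape[0]} rows, series has {T}"
        )
    if nuis.n_covariates >= T:
        raise ValueError(
            f"cannot regress {nuis.n_covariates} covariates from T={T} points"
        )
    design = np.column_stack([np.ones(T), nuis.values]) if nuis.n_covariates \
        else np.ones((T, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient nuisance matrix; fitting by pseudo-inverse",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    out = ts.values - design @ beta
    return replace(ts, values=out, provenance=ts.provenance + ("regress_nuisance",))


def band_bin_mask(n_timepoints: int, tr_seconds: float, band: BandSpec) -> np.ndarray:
    """Boolean keep-mask over the rfft bins of a length-T series.

    A bin is kept iff low <= f <= high (inclusive edges); the DC bin is
    dropped whenever low > 0.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    eps = 1e-12
    keep = (freqs >= band.low - eps) & (freqs <= band.high + eps)
    if band.low > 0:
        keep &= freqs > 0
    return keep


def band_power_fraction(n_timepoints: int, tr_seconds: float, band: BandSpec) -> float:
    """Fraction of white-noise variance surviving the ideal band-pass.

    Counts real degrees of freedom per rfft bin: DC and (for even T) the
    Nyquist bin carry one each, every other bin carries two.
    """
    keep = band_bin_mask(n_timepoints, tr_seconds, band)
    T = n_timepoints
    dof = np.full(keep.shape, 2.0)
    dof[0] = 1.0
    if T % 2 == 0:
        dof[-1] = 1.0
    return float(dof[keep].sum() / T)


def bandpass_ideal(ts: ROITimeSeriesSet, band: BandSpec) -> ROITimeSeriesSet:
    """Ideal FFT-domain band-pass: zero all DFT bins outside [low, high]."""
    if ts.n_timepoints < 8:
        raise InsufficientDataError(
            f"band-pass needs T >= 8, got T={ts.n_timepoints}"
        )
    band.validate_nyquist(ts.tr_seconds)
    keep = band_bin_mask(ts.n_timepoints, ts.tr_seconds, band)
    if not keep.any():
        raise InvalidDesignError(
            f"band {band.name!r} [{band.low}, {band.high}] Hz contains no DFT "
            f"bin at T={ts.n_timepoints}, TR={ts.tr_seconds}s"
        )
    coeffs = np.fft.rfft(ts.values, axis=0)
    coeffs[~keep, :] = 0.0
    out = np.fft.irfft(coeffs, n=ts.n_timepoints, axis=0)
    return replace(
        ts, values=out, provenance=ts.provenance + (f"bandpass_ideal[{band.name}]",)
    )


def bandpass_butterworth(ts: ROITimeSeriesSet, band: BandSpec,
                         order: int = 4) -> ROITimeSeriesSet:
    """Zero-phase Butterworth band-pass (sensitivity-analysis alternative)."""
    band.validate_nyquist(ts.tr_seconds)
    nyq = ts.nyquist_hz
    if band.low > 0:
        sos = _signal.butter(order, [band.low / nyq, min(band.high / nyq, 0.999)],
                             btype="bandpass", output="sos")
    else:
        sos = _signal.butter(order, min(band.high / nyq, 0.999),
                             btype="lowpass", output="sos")
    out = _signal.sosfiltfilt(sos, ts.values, axis=0)
    return replace(
        ts, values=out,
        provenance=ts.provenance + (f"bandpass_butterworth[{band.name}]",),
    )


def condition(ts: ROITimeSeriesSet, band: BandSpec,
              nuis: NuisanceSet | None = None) -> ROITimeSeriesSet:
    """The shipped conditioning order: detrend -> nuisance -> band-pass."""
    out = detrend_linear(ts)
    if nuis is not None and nuis.n_covariates:
        out = regress_nuisance(out, nuis)
    return bandpass_ideal(out, band)
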