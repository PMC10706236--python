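"""Spectral pre-treatments and column normalizations.

Pre-treatments (row-local unless noted):

* cubic smoothing spline (instrument-noise removal),
* MSC — multiplicative scatter correction against a reference spectrum
  (the reference is fit on calibration data and reused at prediction time),
* SNV — standard normal variate,
* first/second derivative by central finite differences.

Column normalizations (mean-center, autoscale, Pareto, Poisson, MinMax to
[-1, +1]) are fit on calibration rows only and applied unchanged to
prediction rows.

Smoothing-spline convention: the classical penalized least-squares trade-off
with parameter p in (0, 1], minimizing ``p * sum (y - f)^2 +
(1 - p) * integral f''(x)^2 dx`` over natural cubic splines — i.e. roughness
weight lambda = (1 - p) / p.  p -> 1 recovers interpolation; p -> 0
approaches the least-squares straight line.
"""
from __future__ import annotations

import dataclasses
from typing import Literal, Optional

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .containers import SpectraSet

__all__ = [
    "PreTreatmentSpec",
    "NormalizationSpec",
    "smooth_spline",
    "msc",
    "snv",
    "derivative",
    "fit_pretreatment",
    "apply_pretreatment",
    "fit_normalizer",
    "apply_normalizer",
    "PreprocessChain",
]

PRETREATMENT_METHODS = ("msc", "snv", "d1", "d2")
NORMALIZATION_METHODS = ("mean_center", "autoscale", "pareto", "poisson", "minmax")


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------
def smooth_spline(spectra: SpectraSet, p: float = 0.01) -> SpectraSet:
    """Cubic smoothing-spline fit of each row over the wavenumber axis."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"smoothing parameter p must be in (0, 1], got {p}")
    if spectra.n_channels < 4:
        raise ValueError("smoothing spline needs at least 4 channels")
    lam = (1.0 - p) / p
    x = spectra.wavenumbers
    out = np.empty_like(spectra.absorbance)
    for i, row in enumerate(spectra.absorbance):
        out[i] = make_smoothing_spline(x, row, lam=lam)(x)
    return spectra.with_absorbance(out)


# ---------------------------------------------------------------------------
# scatter corrections
# ---------------------------------------------------------------------------
def msc(
    spectra: SpectraSet, reference: Optional[np.ndarray] = None
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction.

    Each row is regressed on the reference spectrum (OLS: row = a + b*ref)
    and corrected to ``(row - a) / b``.  When no reference is given the mean
    spectrum of the input rows is used and returned for reuse on prediction
    data.
    """
    if reference is None:
        if spectra.n_rows < 2:
            raise ValueError("MSC needs >= 2 rows to form a mean reference")
        reference = spectra.absorbance.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_channels,):
        raise ValueError("reference length must equal channel count")
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("zero-variance MSC reference spectrum")
    rows = spectra.absorbance
    b = (rows - rows.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = rows.mean(axis=1) - b * reference.mean()
    corrected = (rows - a[:, None]) / b[:, None]
    return spectra.with_absorbance(corrected), reference


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: center each row to mean 0, scale to SD 1.

    SD uses the n-1 divisor.  A constant row is an error.
    """
    rows = spectra.absorbance
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        i = zero[0]
        raise ValueError(
            f"constant spectrum at row {i} (sample {spectra.sample_ids[i]}): "
            "SNV undefined"
        )
    return spectra.with_absorbance((rows - mu) / sd)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------
def derivative(spectra: SpectraSet, order: Literal[1, 2]) -> SpectraSet:
    """Central finite-difference derivative along the wavenumber axis.

    Interior channels use central differences; the two endpoint channels use
    one-sided differences of the same order so the channel count is stable
    across pre-treatments.  The grid must be uniform.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if spectra.n_channels < 3:
        raise ValueError("derivative needs at least 3 channels")
    steps = np.diff(spectra.wavenumbers)
    h = steps[0]
    if not np.allclose(steps, h, rtol=1e-8, atol=0.0):
        raise ValueError("wavenumber grid is not uniform; derivative undefined")
    x = spectra.absorbance
    out = np.empty_like(x)
    if order == 1:
        out[:, 1:-1] = (x[:, 2:] - x[:, :-2]) / (2.0 * h)
        out[:, 0] = (x[:, 1] - x[:, 0]) / h
        out[:, -1] = (x[:, -1] - x[:, -2]) / h
    else:
        out[:, 1:-1] = (x[:, 2:] - 2.0 * x[:, 1:-1] + x[:, :-2]) / h**2
        out[:, 0] = (x[:, 2] - 2.0 * x[:, 1] + x[:, 0]) / h**2
        out[:, -1] = (x[:, -1] - 2.0 * x[:, -2] + x[:, -3]) / h**2
    return spectra.with_absorbance(out)


# ---------------------------------------------------------------------------
# pre-treatment dispatch
# ---------------------------------------------------------------------------
@dataclasses.dataclass
class PreTreatmentSpec:
    """Choice of scatter correction / derivative, with fitted MSC reference."""

    method: str
    smoothing_param: float = 0.01
    msc_reference: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.method not in PRETREATMENT_METHODS:
            raise ValueError(
                f"method must be one of {PRETREATMENT_METHODS}, got {self.method!r}"
            )
        if not 0.0 < self.smoothing_param <= 1.0:
            raise ValueError("smoothing_param must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "smoothing_param": self.smoothing_param,
            "msc_reference": (
                None if self.msc_reference is None else list(map(float, self.msc_reference))
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreTreatmentSpec":
        ref = d.get("msc_reference")
        return cls(
            method=d["method"],
            smoothing_param=d.get("smoothing_param", 0.01),
            msc_reference=None if ref is None else np.asarray(ref, dtype=float),
        )


def fit_pretreatment(spectra: SpectraSet, spec: PreTreatmentSpec) -> PreTreatmentSpec:
    """Fit any data-dependent state (the MSC reference) on calibration rows."""
    if spec.method == "msc" and spec.msc_reference is None:
        return dataclasses.replace(
            spec, msc_reference=spectra.absorbance.mean(axis=0).copy()
        )
    return spec


def apply_pretreatment(spectra: SpectraSet, spec: PreTreatmentSpec) -> SpectraSet:
    if spec.method == "msc":
        if spec.msc_reference is None:
            raise ValueError("MSC spec has no fitted reference; call fit_pretreatment")
        corrected, _ = msc(spectra, reference=spec.msc_reference)
        return corrected
    if spec.method == "snv":
        return snv(spectra)
    if spec.method == "d1":
        return derivative(spectra, 1)
    return derivative(spectra, 2)


# ---------------------------------------------------------------------------
# column normalizations
# ---------------------------------------------------------------------------
@dataclasses.dataclass
class NormalizationSpec:
    """Column-wise normalization with parameters frozen on calibration data."""

    method: str
    fitted_params: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(
                f"method must be one of {NORMALIZATION_METHODS}, got {self.method!r}"
            )

    def to_dict(self) -> dict:
        params = None
        if self.fitted_params is not None:
            params = {k: list(map(float, v)) for k, v in self.fitted_params.items()}
        return {"method": self.method, "fitted_params": params}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        params = d.get("fitted_params")
        if params is not None:
            params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        return cls(method=d["method"], fitted_params=params)


def _first_bad_column(mask: np.ndarray) -> int:
    return int(np.flatnonzero(mask)[0])


def fit_normalizer(X: np.ndarray, spec: NormalizationSpec | str) -> NormalizationSpec:
    """Capture per-column statistics on calibration rows only."""
    if isinstance(spec, str):
        spec = NormalizationSpec(method=spec)
    X = np.asarray(X, dtype=float)
    m = spec.method
    if m == "mean_center":
        params = {"mean": X.mean(axis=0)}
    elif m in ("autoscale", "pareto"):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(
                f"{m}: zero-variance column {_first_bad_column(sd == 0)}"
            )
        params = {"mean": mu, "sd": sd}
    elif m == "poisson":
        mu = X.mean(axis=0)
        if np.any(mu <= 0):
            raise ValueError(
                f"poisson scaling needs positive column means; column "
                f"{_first_bad_column(mu <= 0)} violates this"
            )
        params = {"mean": mu}
    else:  # minmax
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        if np.any(hi == lo):
            raise ValueError(
                f"minmax: zero-range column {_first_bad_column(hi == lo)}"
            )
        params = {"min": lo, "max": hi}
    return NormalizationSpec(method=m, fitted_params=params)


def apply_normalizer(X: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Apply frozen calibration statistics; no clipping outside fitted range."""
    if spec.fitted_params is None:
        raise ValueError("normalizer not fitted; call fit_normalizer first")
    X = np.asarray(X, dtype=float)
    p = spec.fitted_params
    m = spec.method
    if m == "mean_center":
        return X - p["mean"]
    if m == "autoscale":
        return (X - p["mean"]) / p["sd"]
    if m == "pareto":
        return (X - p["mean"]) / np.sqrt(p["sd"])
    if m == "poisson":
        return X / np.sqrt(p["mean"])
    return -1.0 + 2.0 * (X - p["min"]) / (p["max"] - p["min"])


# ---------------------------------------------------------------------------
# fitted chain: smooth -> scatter correction / derivative -> normalization
# ---------------------------------------------------------------------------
@dataclasses.dataclass
class PreprocessChain:
    """The full X transform, fit on calibration rows and frozen thereafter.

    Order is smooth -> pre-treatment -> normalization.  ``fit`` consumes the
    calibration :class:`SpectraSet`; ``transform`` accepts any raw
    :class:`SpectraSet` on the same channel grid.
    """

    pretreatment: PreTreatmentSpec
    normalization: NormalizationSpec
    smoothing_param: float = 0.01
    wavenumbers: Optional[np.ndarray] = None

    def fit(self, calibration: SpectraSet) -> "PreprocessChain":
        self.wavenumbers = calibration.wavenumbers.copy()
        smoothed = smooth_spline(calibration, self.smoothing_param)
        self.pretreatment = fit_pretreatment(smoothed, self.pretreatment)
        treated = apply_pretreatment(smoothed, self.pretreatment)
        self.normalization = fit_normalizer(treated.absorbance, self.normalization)
        return self

    def transform(self, spectra: SpectraSet) -> np.ndarray:
        if self.wavenumbers is None:
            raise ValueError("chain not fitted")
        if spectra.n_channels != self.wavenumbers.size:
            raise ValueError(
                f"channel mismatch: chain fitted on {self.wavenumbers.size} "
                f"channels, got {spectra.n_channels}"
            )
        smoothed = smooth_spline(spectra, self.smoothing_param)
        treated = apply_pretreatment(smoothed, self.pretreatment)
        return apply_normalizer(treated.absorbance, self.normalization)

    def fit_transform(self, calibration: SpectraSet) -> np.ndarray:
        return self.fit(calibration).transform(calibration)

    def to_dict(self) -> dict:
        return {
            "pretreatment": self.pretreatment.to_dict(),
            "normalization": self.normalization.to_dict(),
            "smoothing_param": self.smoothing_param,
            "wavenumbers": (
                None if self.wavenumbers is None else list(map(float, self.wavenumbers))
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessChain":
        wn = d.get("wavenumbers")
        return cls(
            pretreatment=PreTreatmentSpec.from_dict(d["pretreatment"]),
            normalization=NormalizationSpec.from_dict(d["normalization"]),
            smoothing_param=d.get("smoothing_param", 0.01),
            wavenumbers=None if wn is None else np.asarray(wn, dtype=float),
        )
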