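"""Receptor-based visual modeling of irradiance spectra.

Converts measured downwelling irradiance into the quantities consumed by the
downstream ecological analysis: quantum catch per photoreceptor class (UV, B,
LW), achromatic photon catch, and Michelson relative-catch contrasts.

Spectral sensitivities use the Govardovskii et al. (2000) A1 visual-pigment
alpha-band template (optional beta band), peaking at the trichromat's
lambda-max values (UV 340 nm, B 435 nm, LW 545 nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m / s

#: default lambda-max (nm) per channel
LAMBDA_MAX = {"UV": 340.0, "B": 435.0, "LW": 545.0}

#: default integration window (nm)
DEFAULT_RANGE = (310.0, 670.0)


class SpectrumError(ValueError):
    """Raised on malformed or inconsistent spectral data."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly increasing wavelengths with values.

    ``units`` is either ``"energy"`` (W m-2 nm-1) or ``"quantal"``
    (photons s-1 m-2 nm-1).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: str = "energy"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumError("non-finite wavelength or value")
        if np.any(vals < 0):
            raise SpectrumError("negative spectral values; clip raw readings first")
        if self.units not in ("energy", "quantal"):
            raise SpectrumError(f"unknown units flag {self.units!r}")

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of values onto ``grid`` (no extrapolation)."""
        if grid.min() < self.wavelengths_nm[0] or grid.max() > self.wavelengths_nm[-1]:
            raise SpectrumError("interpolation grid outside spectrum span")
        return np.interp(grid, self.wavelengths_nm, self.values)


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-wavelength multiplicative gain mapping device counts to irradiance."""

    wavelengths_nm: np.ndarray
    gain: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "gain", g)
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("calibration wavelengths must be strictly increasing")
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise SpectrumError("calibration gain must be finite and positive")


@dataclass(frozen=True)
class SensitivityTemplate:
    """Normalized photoreceptor spectral sensitivity S(lambda) on a 1-nm grid."""

    lambda_max_nm: float
    wavelengths_nm: np.ndarray
    curve: np.ndarray
    channel_label: str = ""

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths_nm, self.curve, left=0.0, right=0.0)


@dataclass(frozen=True)
class CatchSet:
    """Quantum catches for the three channels plus derived contrast measures."""

    q_uv: float
    q_b: float
    q_lw: float

    @property
    def photon_catch_lw(self) -> float:
        return self.q_lw

    @property
    def photon_catch_mean(self) -> float:
        return (self.q_uv + self.q_b + self.q_lw) / 3.0

    @property
    def rel_uv(self) -> float:
        return michelson_relative_catch(self.q_uv, self.q_b, self.q_lw)

    @property
    def rel_b(self) -> float:
        return michelson_relative_catch(self.q_b, self.q_uv, self.q_lw)

    @property
    def rel_lw(self) -> float:
        return michelson_relative_catch(self.q_lw, self.q_uv, self.q_b)

    def as_dict(self) -> dict:
        d = {
            "q_uv": self.q_uv,
            "q_b": self.q_b,
            "q_lw": self.q_lw,
            "photon_catch_lw": self.photon_catch_lw,
            "photon_catch_mean": self.photon_catch_mean,
            "rel_uv": self.rel_uv,
            "rel_b": self.rel_b,
            "rel_lw": self.rel_lw,
        }
        lw, mean = log10_photon_catch(self)
        d["log10_photon_catch_lw"] = lw
        d["log10_photon_catch_mean"] = mean
        return d


def load_spectrum(path: str | Path, units: str = "energy") -> Spectrum:
    """Read a two-column text spectrum (wavelength nm, value).

    Whitespace- or comma-separated; ``#`` starts a comment. Rows are sorted by
    wavelength; duplicated wavelengths are rejected. Negative readings are
    clipped to zero with a warning (sensor noise below the dark floor).
    """
    path = Path(path)
    wl, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumError(f"{path}:{lineno}: non-numeric row") from exc
            wl.append(w)
            vals.append(v)
    if len(wl) < 2:
        raise SpectrumError(f"{path}: fewer than two data rows")
    order = np.argsort(wl)
    wl_arr = np.asarray(wl)[order]
    vals_arr = np.asarray(vals)[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[np.where(np.diff(wl_arr) == 0)[0][0]]
        raise SpectrumError(f"{path}: duplicated wavelength {dup} nm")
    if np.any(vals_arr < 0):
        log.warning("%s: %d negative readings clipped to 0", path, int((vals_arr < 0).sum()))
        vals_arr = np.clip(vals_arr, 0.0, None)
    return Spectrum(wl_arr, vals_arr, units=units, meta={"source": str(path)})


def load_calibration(path: str | Path) -> CalibrationCurve:
    """Read a calibration curve in the same two-column dialect."""
    s = load_spectrum(path)
    return CalibrationCurve(s.wavelengths_nm, s.values)


def apply_calibration(raw: Spectrum, cal: CalibrationCurve) -> Spectrum:
    """Multiply a raw spectrum pointwise by the (interpolated) gain."""
    lo, hi = raw.wavelengths_nm[0], raw.wavelengths_nm[-1]
    if lo < cal.wavelengths_nm[0] or hi > cal.wavelengths_nm[-1]:
        raise SpectrumError(
            f"spectrum span [{lo}, {hi}] outside calibration span "
            f"[{cal.wavelengths_nm[0]}, {cal.wavelengths_nm[-1]}]"
        )
    gain = np.interp(raw.wavelengths_nm, cal.wavelengths_nm, cal.gain)
    return replace(raw, values=raw.values * gain, units="energy")


def to_quantal(s: Spectrum) -> Spectrum:
    """Convert energy irradiance (W m-2 nm-1) to photon flux (photons s-1 m-2 nm-1).

    E = h c / lambda per photon, so N(lambda) = E(lambda) * lambda / (h c).
    """
    if s.units != "energy":
        raise SpectrumError("spectrum already in quantal units")
    factor = s.wavelengths_nm * 1e-9 / (PLANCK_H * SPEED_OF_LIGHT)
    return replace(s, values=s.values * factor, units="quantal")


def receptor_sensitivity(
    lambda_max_nm: float,
    grid: tuple[float, float] = (300.0, 800.0),
    include_beta_band: bool = False,
    channel_label: str = "",
) -> SensitivityTemplate:
    """Govardovskii et al. (2000) A1 pigment template on a 1-nm grid.

    Alpha band only by default; the beta band can be switched on. The curve is
    renormalized to a maximum of exactly 1 (attained at the lambda-max grid
    point up to grid resolution).
    """
    if not 300.0 <= lambda_max_nm <= 650.0:
        raise ValueError(f"lambda_max {lambda_max_nm} nm outside supported [300, 650]")
    lo, hi = grid
    wl = np.arange(float(lo), float(hi) + 0.5, 1.0)
    curve = _govardovskii_alpha(wl, lambda_max_nm)
    if include_beta_band:
        curve = curve + _govardovskii_beta(wl, lambda_max_nm)
    curve = curve / curve.max()
    return SensitivityTemplate(lambda_max_nm, wl, curve, channel_label)


def _govardovskii_alpha(wl: np.ndarray, lmax: float) -> np.ndarray:
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    with np.errstate(over="ignore"):
        denom = np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
    return 1.0 / denom


def _govardovskii_beta(wl: np.ndarray, lmax: float) -> np.ndarray:
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    return 0.26 * np.exp(-(((wl - lmb) / bb) ** 2))


def default_templates(include_beta_band: bool = False) -> dict[str, SensitivityTemplate]:
    """The three receptor templates used throughout the analysis."""
    return {
        ch: receptor_sensitivity(lm, include_beta_band=include_beta_band, channel_label=ch)
        for ch, lm in LAMBDA_MAX.items()
    }


def quantum_catch(
    s: Spectrum,
    template: SensitivityTemplate,
    integration_range: tuple[float, float] = DEFAULT_RANGE,
    grid_step_nm: float = 0.02,
) -> float:
    """Q = integral of S(lambda) * I_q(lambda) over the integration range.

    Both curves are linearly interpolated onto a common fine grid and
    integrated by the trapezoid rule. The step is 0.02 nm (not the 1-nm
    sampling grid) because the product of two piecewise-linear curves is
    piecewise quadratic: the fine step keeps the quadrature error below 1e-6
    relative. The spectrum must be quantal.
    """
    if s.units != "quantal":
        raise SpectrumError("quantum_catch requires a quantal spectrum")
    lo = max(integration_range[0], s.wavelengths_nm[0], template.wavelengths_nm[0])
    hi = min(integration_range[1], s.wavelengths_nm[-1], template.wavelengths_nm[-1])
    if hi <= lo:
        raise SpectrumError("no overlap between spectrum, template and integration range")
    n = int(np.floor((hi - lo) / grid_step_nm))
    grid = lo + grid_step_nm * np.arange(n + 1)
    if grid.size < 2:
        raise SpectrumError("integration window narrower than the grid step")
    integrand = s.interp(grid) * template.interp(grid)
    return float(np.trapezoid(integrand, grid))


def catch_set(
    s: Spectrum,
    templates: Optional[dict[str, SensitivityTemplate]] = None,
    integration_range: tuple[float, float] = DEFAULT_RANGE,
) -> CatchSet:
    """Quantum catches for UV/B/LW plus contrasts; energy input is auto-converted."""
    if s.units == "energy":
        s = to_quantal(s)
    if templates is None:
        templates = default_templates()
    q = {ch: quantum_catch(s, t, integration_range) for ch, t in templates.items()}
    return CatchSet(q_uv=q["UV"], q_b=q["B"], q_lw=q["LW"])


def michelson_relative_catch(q_a: float, q_b: float, q_c: float) -> float:
    """(Q_a - M) / (Q_a + M) with M = (Q_b + Q_c) / 2; in [-1, 1]."""
    if q_a < 0 or q_b < 0 or q_c < 0:
        raise ValueError("quantum catches must be non-negative")
    m = (q_b + q_c) / 2.0
    denom = q_a + m
    if denom == 0:
        raise ZeroDivisionError("Michelson contrast undefined: all catches zero")
    return (q_a - m) / denom


def log10_photon_catch(c: CatchSet) -> tuple[float, float]:
    """log10 of the LW and mean photon catch."""
    if c.photon_catch_lw <= 0 or c.photon_catch_mean <= 0:
        raise ValueError("cannot log-transform a zero photon catch")
    return float(np.log10(c.photon_catch_lw)), float(np.log10(c.photon_catch_mean))
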