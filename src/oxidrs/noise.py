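"""Three-component measurement-noise model for white-calibrated DRS spectra.

A modeled spectrum is corrupted, per channel, by

1. additive spectrometer noise ``eta(lambda) * xi_w(lambda)`` with iid
   standard-normal ``xi_w`` — ``eta`` is the relative standard deviation of
   repeated white-reference measurements, so on the white-calibrated scale
   the additive noise has a fixed absolute magnitude and dark (high-melanin,
   high-blood) spectra are relatively noisier;
2. a multiplicative wavelength-dependent residual ``xi_res(lambda) ~
   N(m(lambda), s(lambda))`` encoding the small systematic mismatch between
   the tissue model and real skin spectra (generally below 1%);
3. a multiplicative color-calibration tilt: a straight line in wavelength
   with unit mean over the 475-750 nm band whose end-to-end relative
   difference is ``xi_slope - 1``, ``xi_slope ~ N(1, 0.05)``, one draw shared
   by both channels.

The application order (additive, then residual, then tilt) is fixed.
Negative intensities are permitted after noise; the data-exclusion rules
act on them downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from oxidrs.forward import SpectrumPair

__all__ = ["NoiseSpec", "estimate_eta", "apply_noise",
           "default_residual_mean", "default_residual_std"]

_BAND = (475.0, 750.0)
_RAMP_REF = 742.0  # wavelength anchoring the synthetic residual curves


def _ramp(lam):
    """Smooth 0->1 ramp over the band, equal to 1 at 742 nm."""
    lam = np.asarray(lam, float)
    return ((lam - _BAND[0]) / (_RAMP_REF - _BAND[0])) ** 2


def default_residual_mean(lam, channel: int):
    """Synthetic residual mean curve; 0.995 at 742 nm on the short channel.

    A smooth stand-in for instrument-derived residual statistics (which are
    hardware specific); deviation from unity stays below 1%.
    """
    depth = 0.005 if channel == 0 else 0.006
    return 1.0 - depth * np.clip(_ramp(lam), 0.0, 1.4)


def default_residual_std(lam, channel: int):
    """Synthetic residual std curve; 0.007 at 742 nm on the short channel."""
    if channel == 0:
        return 0.004 + 0.003 * np.clip(_ramp(lam), 0.0, 1.4)
    return 0.005 + 0.003 * np.clip(_ramp(lam), 0.0, 1.4)


@dataclass
class NoiseSpec:
    """Configuration of the three noise components.

    ``eta`` is either a scalar (flat curve) or a callable ``eta(lambda)``;
    ``residual_mean``/``residual_std`` are callables ``f(lambda, channel)``.
    ``tilt_form`` selects the linear tilt (default) or the geometric
    alternative ``xi_slope ** (x - 1/2)`` with ``x`` the normalized
    wavelength.
    """

    eta: float | Callable = 0.002
    slope_sd: float = 0.05
    residual_mean: Callable = default_residual_mean
    residual_std: Callable = default_residual_std
    measurement_enabled: bool = True
    residual_enabled: bool = True
    tilt_enabled: bool = True
    tilt_band: tuple[float, float] = _BAND
    tilt_form: str = "linear"
    per_channel_tilt: bool = False

    def __post_init__(self):
        if self.slope_sd < 0:
            raise ValueError("slope_sd must be >= 0")
        if self.tilt_form not in ("linear", "geometric"):
            raise ValueError(f"unknown tilt_form {self.tilt_form!r}")

    def eta_curve(self, lam) -> np.ndarray:
        lam = np.asarray(lam, float)
        e = self.eta(lam) if callable(self.eta) else np.full_like(lam, self.eta)
        e = np.asarray(e, float)
        if np.any(e < 0):
            raise ValueError("eta must be nonnegative")
        return e

    @classmethod
    def disabled(cls) -> "NoiseSpec":
        return cls(measurement_enabled=False, residual_enabled=False,
                   tilt_enabled=False)

    @classmethod
    def phantom(cls, eta: float | Callable = 0.002) -> "NoiseSpec":
        """Phantom-style noise: measurement and tilt on, residual model off."""
        return cls(eta=eta, residual_enabled=False)

    @classmethod
    def from_files(cls, eta_file=None, residual_mean_files=None,
                   residual_std_files=None, **kwargs) -> "NoiseSpec":
        """Build from two-column text tables (wavelength, value).

        ``residual_*_files`` are (short-channel, long-channel) path pairs.
        """
        if eta_file is not None:
            tab = np.loadtxt(eta_file, comments="#")
            kwargs["eta"] = lambda lam: np.interp(lam, tab[:, 0], tab[:, 1])
        if residual_mean_files is not None:
            tabs = [np.loadtxt(f, comments="#") for f in residual_mean_files]
            kwargs["residual_mean"] = (
                lambda lam, c: np.interp(lam, tabs[c][:, 0], tabs[c][:, 1]))
        if residual_std_files is not None:
            stabs = [np.loadtxt(f, comments="#") for f in residual_std_files]
            kwargs["residual_std"] = (
                lambda lam, c: np.interp(lam, stabs[c][:, 0], stabs[c][:, 1]))
        return cls(**kwargs)


def estimate_eta(white_repeats) -> np.ndarray:
    """Relative white-reference noise: per-wavelength sample std / mean.

    ``white_repeats``: (n_repeats, n_lambda) dark-subtracted white spectra,
    n_repeats >= 2 with strictly positive means.
    """
    w = np.asarray(white_repeats, float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a (n_repeats >= 2, n_lambda) matrix")
    mean = w.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("white-reference mean must be positive at all wavelengths")
    return w.std(axis=0, ddof=1) / mean


def _tilt(lam, xi_slope, band, form):
    x = (np.asarray(lam, float) - band[0]) / (band[1] - band[0])
    if form == "linear":
        return 1.0 + (xi_slope - 1.0) * (x - 0.5)
    return float(xi_slope) ** (x - 0.5)


def apply_noise(spectrum: SpectrumPair, spec: NoiseSpec,
                rng: np.random.Generator) -> SpectrumPair:
    """Apply the three noise components to a spectrum pair.

    Deterministic for a given generator state.  Draw order is fixed:
    additive noise (short channel then long), residual (short then long),
    then the tilt slope(s).
    """
    lam = spectrum.wavelength_nm
    out = [spectrum.i_short.copy(), spectrum.i_long.copy()]
    if spec.measurement_enabled:
        eta = spec.eta_curve(lam)
        for c in range(2):
            out[c] = out[c] + eta * rng.standard_normal(lam.size)
    if spec.residual_enabled:
        for c in range(2):
            m = np.broadcast_to(np.asarray(spec.residual_mean(lam, c), float),
                                lam.shape)
            s = np.broadcast_to(np.asarray(spec.residual_std(lam, c), float),
                                lam.shape)
            out[c] = out[c] * rng.normal(m, s)
    if spec.tilt_enabled:
        xi = rng.normal(1.0, spec.slope_sd)
        for c in range(2):
            if spec.per_channel_tilt and c > 0:
                xi = rng.normal(1.0, spec.slope_sd)
            out[c] = out[c] * _tilt(lam, xi, spec.tilt_band, spec.tilt_form)
    return SpectrumPair(lam.copy(), out[0], out[1])
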