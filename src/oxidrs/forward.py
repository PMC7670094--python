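"""Dual-channel spectrum synthesis and sampling-volume-weighted targets.

A tissue realization (:class:`~oxidrs.tissue_optics.TissueParams`) is turned
into a pair of diffuse reflectance spectra — one per source-detector
separation — by evaluating the layer absorption triplet and the reduced
scattering at every wavelength and applying Beer-Lambert weighting to the
white-MC path-length table.  The regression targets (oxygen saturation and
RBC tissue fraction "as seen" by the detected photons) are computed from the
per-layer shares of detected photon path length, so a shallow sampling volume
yields targets dominated by the upper dermis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from oxidrs.tissue_optics import (
    CONSTANTS,
    ChromophoreTable,
    TissueParams,
    dermis_mu_a,
    epidermis_mu_a,
    layer_blood_fractions,
    layer_saturations,
    reduced_scattering,
)
from oxidrs.montecarlo import PathLengthTable

__all__ = [
    "SpectrumPair",
    "TargetPair",
    "default_wavelength_grid",
    "white_reference",
    "model_spectrum",
    "sampling_weights",
    "target_values",
    "forward_record",
]


def default_wavelength_grid(n: int = 28, lo: float = 475.0,
                            hi: float = 750.0) -> np.ndarray:
    """The analysis wavelength grid: n points evenly spaced on [lo, hi] nm."""
    return np.linspace(lo, hi, n)


@dataclass
class SpectrumPair:
    """White-calibrated diffuse reflectance at the two fiber separations."""

    wavelength_nm: np.ndarray
    i_short: np.ndarray  # 0.4 mm channel
    i_long: np.ndarray   # 1.2 mm channel

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.i_short = np.asarray(self.i_short, float)
        self.i_long = np.asarray(self.i_long, float)
        if not (self.wavelength_nm.shape == self.i_short.shape
                == self.i_long.shape):
            raise ValueError("wavelength grid and both channels must share a shape")

    @property
    def channels(self) -> np.ndarray:
        return np.stack([self.i_short, self.i_long])

    def copy(self) -> "SpectrumPair":
        return SpectrumPair(self.wavelength_nm.copy(), self.i_short.copy(),
                            self.i_long.copy())


@dataclass
class TargetPair:
    """Sampling-volume-weighted regression targets for one tissue model.

    ``s_o2`` is the blood-weighted saturation of the probed dermal blood
    (NaN when the model contains no blood), ``f_rbc`` the RBC tissue fraction
    (hematocrit times the path-weighted blood fraction); both fractions.
    """

    s_o2: float
    f_rbc: float
    weights: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))

    @property
    def saturation_defined(self) -> bool:
        return np.isfinite(self.s_o2)


def _mua_triplets(params: TissueParams, grid, table: ChromophoreTable):
    """Layer absorption (n_lambda, 3) and reduced scattering (n_lambda,)."""
    grid = np.asarray(grid, float)
    mua = np.column_stack([
        np.broadcast_to(epidermis_mu_a(grid, params, table), grid.shape),
        np.broadcast_to(dermis_mu_a(grid, params, 1, table), grid.shape),
        np.broadcast_to(dermis_mu_a(grid, params, 2, table), grid.shape),
    ])
    musp = reduced_scattering(grid, params.alpha, params.beta, params.gamma)
    return mua, np.broadcast_to(np.asarray(musp, float), grid.shape)


def white_reference(table: PathLengthTable) -> np.ndarray:
    """Per-channel white-reference detected fraction defining intensity 1.

    The reference is the absorption-free detected fraction at the center of
    the lookup grid (mid epidermis thickness, geometric-mean mu_s'), so that
    typical tissue spectra land on an O(0.1-1) white-calibrated scale.
    """
    t_mid = 0.5 * (table.t_epi_grid[0] + table.t_epi_grid[-1])
    m_mid = float(np.exp(0.5 * (np.log(table.musp_grid[0])
                                + np.log(table.musp_grid[-1]))))
    return table.reflectance_at(t_mid, m_mid, (0.0, 0.0, 0.0))


def model_spectrum(params: TissueParams, table: PathLengthTable, grid,
                   chromo: ChromophoreTable,
                   white_ref: np.ndarray | None = None) -> SpectrumPair:
    """Synthesize the dual-channel spectrum for one tissue realization."""
    spec, _ = forward_record(params, table, grid, chromo, white_ref,
                             with_targets=False)
    return spec


def sampling_weights(params: TissueParams, table: PathLengthTable, grid,
                     chromo: ChromophoreTable,
                     absorption_weighted: bool = True,
                     pool_channels: bool = True,
                     pool_wavelengths: bool = True) -> np.ndarray:
    """Per-layer fractions of detected photon path length (3 values).

    Photons are weighted by their Beer-Lambert survival at each wavelength
    (switchable to geometric path length only); the per-(wavelength, channel)
    layer fractions are averaged with equal weight over both channels and the
    wavelength grid.  The result is nonnegative and sums to 1.
    """
    grid = np.asarray(grid, float)
    mua, musp = _mua_triplets(params, grid, chromo)
    if not absorption_weighted:
        mua = np.zeros_like(mua)
    _, paths = table.spectrum_sums(params.t_epi, musp, mua, with_paths=True)
    tot = paths.sum(axis=2, keepdims=True)  # (ch, lambda, 1)
    if np.any(tot <= 0):
        raise ValueError("no detected photon path length at some wavelength")
    frac = paths / tot
    axes = []
    if pool_channels:
        axes.append(0)
    if pool_wavelengths:
        axes.append(1)
    w = frac.mean(axis=tuple(axes)) if axes else frac
    return w


def target_values(params: TissueParams, weights) -> TargetPair:
    """Targets from model parameters and per-layer path weights.

    RBC tissue fraction: hematocrit times the path-weighted blood fraction
    (the epidermis carries no blood).  Saturation: blood-weighted mean of the
    two dermal layer saturations; NaN (undefined) without blood in the
    sampling volume.
    """
    w = np.asarray(weights, float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("weights must be 3 nonnegative values")
    ws = w.sum()
    if ws <= 0:
        raise ValueError("weights must not all be zero")
    f1, f2 = layer_blood_fractions(params.f_blood, params.r_blood)
    s1, s2 = layer_saturations(params.s_o2, params.delta_o2)
    f_rbc = CONSTANTS.hematocrit * (w[1] * f1 + w[2] * f2) / ws
    blood_w = w[1] * f1 + w[2] * f2
    s_o2 = (w[1] * f1 * s1 + w[2] * f2 * s2) / blood_w if blood_w > 0 else np.nan
    return TargetPair(s_o2=float(s_o2), f_rbc=float(f_rbc), weights=w / ws)


def forward_record(params: TissueParams, table: PathLengthTable, grid,
                   chromo: ChromophoreTable,
                   white_ref: np.ndarray | None = None,
                   with_targets: bool = True,
                   absorption_weighted: bool = True):
    """One pass of the forward model: spectrum pair plus (optionally) targets.

    Shares the Beer-Lambert interpolation between the spectrum and the
    sampling-volume weights, which halves the cost of dataset generation.
    """
    grid = np.asarray(grid, float)
    mua, musp = _mua_triplets(params, grid, chromo)
    if white_ref is None:
        white_ref = white_reference(table)
    intensity, paths = table.spectrum_sums(
        params.t_epi, musp, mua, with_paths=with_targets)
    spec = SpectrumPair(grid, intensity[0] / white_ref[0],
                        intensity[1] / white_ref[1])
    if not with_targets:
        return spec, None
    if not absorption_weighted:
        _, paths = table.spectrum_sums(params.t_epi, musp,
                                       np.zeros_like(mua), with_paths=True)
    tot = paths.sum(axis=2, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("no detected photon path length at some wavelength")
    w = (paths / tot).mean(axis=(0, 1))
    return spec, target_values(params, w)
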