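"""Chromophore spectra, scattering law and unit conversions for the
three-layer skin model.

The model describes skin as a bloodless pigmented epidermis of variable
thickness on top of two dermal layers (a 0.2 mm upper dermis and a
semi-infinite deep dermis), each perfused with whole blood of its own
tissue fraction, oxygen saturation and mean vessel diameter.  Fifteen free
parameters (:class:`TissueParams`) control the absorption and reduced
scattering spectra of the three layers.

All lengths are in mm, absorption and scattering coefficients in 1/mm, and
fractions are dimensionless in [0, 1]; percent appears only at I/O
boundaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "OpticalConstants",
    "CONSTANTS",
    "TissueParams",
    "ChromophoreTable",
    "melanin_mu_a",
    "epidermis_mu_a",
    "layer_saturations",
    "layer_blood_fractions",
    "blood_mu_a",
    "vessel_packing_factor",
    "layer_vessel_diameters",
    "dermis_mu_a",
    "reduced_scattering",
    "hb_concentration",
]


class ValidationError(ValueError):
    """A parameter combination violates a model invariant."""


@dataclass(frozen=True)
class OpticalConstants:
    """Physical constants of the tissue model (read-only).

    Attributes
    ----------
    k_mel : melanin absorption at the 550 nm reference wavelength (1/mm).
    lambda0_mel : melanin reference wavelength (nm).
    lambda0_scat : scattering reference wavelength (nm).
    hematocrit : RBC volume fraction of whole blood.
    c_hb_rbc : mean cell hemoglobin concentration (g Hb / L RBC).
    hb_per_blood : hemoglobin content of whole blood (g Hb / L blood).
    m_hb : molecular weight of hemoglobin (g / mole).
    g_aniso : Henyey-Greenstein anisotropy factor.
    t_layer2 : fixed thickness of the upper dermis (mm).
    """

    k_mel: float = 48.42
    lambda0_mel: float = 550.0
    lambda0_scat: float = 600.0
    hematocrit: float = 0.43
    c_hb_rbc: float = 345.0
    hb_per_blood: float = 145.0
    m_hb: float = 64500.0
    g_aniso: float = 0.8
    t_layer2: float = 0.2


CONSTANTS = OpticalConstants()


@dataclass
class TissueParams:
    """One realization of the 15-parameter three-layer skin model.

    Attributes
    ----------
    t_epi : epidermis thickness (mm).
    f_mel : melanin volume fraction in the epidermis.
    beta_mel : melanin spectral-slope exponent.
    f_bcaro : beta-carotene fraction in the epidermis.
    f_lyco : lycopene fraction in the epidermis.
    f_blood : average dermal blood tissue fraction.
    r_blood : inter-layer blood asymmetry, in [-1, 1].
    s_o2 : average oxygen saturation (fraction).
    delta_o2 : inter-layer saturation difference (fraction).
    f_met : met-hemoglobin fraction of total hemoglobin.
    d_avg : average vessel diameter (mm).
    r_d : inter-layer vessel-diameter asymmetry.
    alpha : reduced scattering magnitude at 600 nm (1/mm).
    beta : Mie slope exponent.
    gamma : Rayleigh fraction, in [0, 1].
    """

    t_epi: float
    f_mel: float
    beta_mel: float
    f_bcaro: float
    f_lyco: float
    f_blood: float
    r_blood: float
    s_o2: float
    delta_o2: float
    f_met: float
    d_avg: float
    r_d: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.t_epi > 0:
            raise ValidationError(f"t_epi must be > 0, got {self.t_epi}")
        if self.f_blood < 0:
            raise ValidationError(f"f_blood must be >= 0, got {self.f_blood}")
        if not self.d_avg > 0:
            raise ValidationError(f"d_avg must be > 0, got {self.d_avg}")
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError(f"gamma must be in [0,1], got {self.gamma}")
        if not 0.0 <= self.f_met <= 1.0:
            raise ValidationError(f"f_met must be in [0,1], got {self.f_met}")
        # Derived layer quantities must be physical; the dataset sampler
        # rejection-samples against these same checks.
        layer_saturations(self.s_o2, self.delta_o2)
        layer_blood_fractions(self.f_blood, self.r_blood)
        layer_vessel_diameters(self.d_avg, self.r_d)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], float)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_array(cls, values) -> "TissueParams":
        return cls(*(float(v) for v in values))


class ChromophoreTable:
    """Wavelength-gridded absorption curves of the model chromophores.

    Curves (all 1/mm, on a common wavelength grid in nm):

    * ``mu_a_sat`` -- fully oxygen-saturated whole blood at 145 g Hb/L;
    * ``mu_a_red`` -- reduced (deoxygenated) whole blood at 145 g Hb/L;
    * ``mu_a_met`` -- fully met-hemoglobin whole blood at 145 g Hb/L;
    * ``mu_a_bcaro``, ``mu_a_lyco`` -- epidermal carotenoids per unit
      fraction; negligible (<1% of peak) above 550 nm.

    Queries interpolate linearly and raise outside the grid.
    """

    _CURVES = ("mu_a_sat", "mu_a_red", "mu_a_met", "mu_a_bcaro", "mu_a_lyco")

    def __init__(self, wavelength_nm, mu_a_sat, mu_a_red, mu_a_met,
                 mu_a_bcaro, mu_a_lyco):
        lam = np.asarray(wavelength_nm, float)
        if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing 1-D")
        self.wavelength_nm = lam
        for name, curve in zip(self._CURVES,
                               (mu_a_sat, mu_a_red, mu_a_met, mu_a_bcaro, mu_a_lyco)):
            arr = np.asarray(curve, float)
            if arr.shape != lam.shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {lam.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative absorption values")
            setattr(self, name, arr)

    def _interp(self, curve_name: str, lam) -> np.ndarray:
        lam = np.asarray(lam, float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside table range [{lo}, {hi}] nm")
        return np.interp(lam, self.wavelength_nm, getattr(self, curve_name))

    def sat(self, lam):
        return self._interp("mu_a_sat", lam)

    def red(self, lam):
        return self._interp("mu_a_red", lam)

    def met(self, lam):
        return self._interp("mu_a_met", lam)

    def bcaro(self, lam):
        return self._interp("mu_a_bcaro", lam)

    def lyco(self, lam):
        return self._interp("mu_a_lyco", lam)

    @classmethod
    def from_files(cls, sat_file, red_file, met_file, bcaro_file, lyco_file):
        """Build a table from five two-column text files (nm, 1/mm).

        Files may carry ``#`` comment/header lines.  Curves are resampled by
        linear interpolation onto the wavelength grid of the saturated-blood
        file, restricted to the range common to all five files.
        """
        curves = [np.loadtxt(f, comments="#") for f in
                  (sat_file, red_file, met_file, bcaro_file, lyco_file)]
        lo = max(c[0, 0] for c in curves)
        hi = min(c[-1, 0] for c in curves)
        lam = curves[0][:, 0]
        lam = lam[(lam >= lo) & (lam <= hi)]
        resampled = [np.interp(lam, c[:, 0], c[:, 1]) for c in curves]
        return cls(lam, *resampled)

    @classmethod
    def default(cls) -> "ChromophoreTable":
        """The package's shipped chromophore fixtures (450-900 nm)."""
        root = importlib.resources.files("oxidrs") / "data"
        return cls.from_files(
            root / "blood_oxy_mu_a.tsv",
            root / "blood_deoxy_mu_a.tsv",
            root / "blood_met_mu_a.tsv",
            root / "betacarotene_mu_a.tsv",
            root / "lycopene_mu_a.tsv",
        )


def melanin_mu_a(lam, beta_mel, constants: OpticalConstants = CONSTANTS):
    """Melanin absorption coefficient (1/mm).

    A power law anchored at 550 nm: ``k * (lambda/550)**(-beta_mel)`` with
    ``k = 48.42 / mm``.  ``beta_mel`` encodes the eumelanin/pheomelanin
    balance through the spectral slope.
    """
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = constants.k_mel * (lam / constants.lambda0_mel) ** (-beta_mel)
    return out if out.ndim else float(out)


def epidermis_mu_a(lam, params: TissueParams, table: ChromophoreTable):
    """Epidermal absorption: melanin plus the two carotenoids (1/mm)."""
    mel = melanin_mu_a(lam, params.beta_mel)
    out = (params.f_mel * mel
           + params.f_bcaro * table.bcaro(lam)
           + params.f_lyco * table.lyco(lam))
    return out if np.ndim(out) else float(out)


def layer_saturations(s_o2: float, delta_o2: float) -> tuple[float, float]:
    """Oxygen saturation of upper and deep dermis: ``s_o2 +/- delta_o2/2``."""
    s1 = s_o2 + delta_o2 / 2.0
    s2 = s_o2 - delta_o2 / 2.0
    for s in (s1, s2):
        if not 0.0 <= s <= 1.0:
            raise ValidationError(
                f"layer saturation {s:.4g} outside [0,1] "
                f"(s_o2={s_o2}, delta_o2={delta_o2})")
    return s1, s2


def layer_blood_fractions(f_blood: float, r_blood: float) -> tuple[float, float]:
    """Blood tissue fraction of upper and deep dermis: ``f*(1 +/- r)``."""
    f1 = f_blood * (1.0 + r_blood)
    f2 = f_blood * (1.0 - r_blood)
    if f1 < 0 or f2 < 0:
        raise ValidationError(
            f"negative layer blood fraction (f_blood={f_blood}, r_blood={r_blood})")
    return f1, f2


def layer_vessel_diameters(d_avg: float, r_d: float) -> tuple[float, float]:
    """Mean vessel diameter of upper and deep dermis: ``D*(1 -/+ r_d)``.

    The sign convention makes deep-dermis vessels the larger ones for
    positive ``r_d``.
    """
    d1 = d_avg * (1.0 - r_d)
    d2 = d_avg * (1.0 + r_d)
    if d1 < 0 or d2 < 0:
        raise ValidationError(
            f"negative vessel diameter (d_avg={d_avg}, r_d={r_d})")
    return d1, d2


def blood_mu_a(lam, s_o2_n: float, f_met: float, table: ChromophoreTable):
    """Whole-blood absorption (1/mm) at saturation ``s_o2_n``.

    A convex combination of the saturated, reduced and met-hemoglobin
    whole-blood curves:
    ``(1-f_met)[s*mu_sat + (1-s)*mu_red] + f_met*mu_met``.
    """
    if not 0.0 <= s_o2_n <= 1.0:
        raise ValidationError(f"s_o2_n must be in [0,1], got {s_o2_n}")
    if not 0.0 <= f_met <= 1.0:
        raise ValidationError(f"f_met must be in [0,1], got {f_met}")
    out = ((1.0 - f_met) * (s_o2_n * table.sat(lam)
                            + (1.0 - s_o2_n) * table.red(lam))
           + f_met * table.met(lam))
    return out if np.ndim(out) else float(out)


def vessel_packing_factor(mu_a_blood, d_n):
    """Vessel-packaging correction factor ``(1 - exp(-D*mu_a)) / (D*mu_a)``.

    Hemoglobin confined to discrete vessels of diameter ``d_n`` absorbs less
    than the same amount distributed homogeneously; the factor lies in
    (0, 1], tends to 1 as ``D*mu_a -> 0`` and decreases monotonically.
    """
    mu = np.asarray(mu_a_blood, float)
    d = np.asarray(d_n, float)
    if np.any(mu < 0) or np.any(d < 0):
        raise ValueError("vessel_packing_factor requires nonnegative inputs")
    x = d * mu
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x < 1e-8, 1.0 - x / 2.0, -np.expm1(-x) / np.where(x == 0, 1.0, x))
    return out if out.ndim else float(out)


def dermis_mu_a(lam, params: TissueParams, layer_n: int, table: ChromophoreTable):
    """Absorption of dermis layer ``layer_n`` in {1, 2} (1/mm).

    Product of the layer blood fraction, the vessel-packaging factor for the
    layer's vessel diameter and the layer's whole-blood absorption.
    """
    if layer_n not in (1, 2):
        raise ValueError(f"layer_n must be 1 or 2, got {layer_n}")
    i = layer_n - 1
    f_n = layer_blood_fractions(params.f_blood, params.r_blood)[i]
    s_n = layer_saturations(params.s_o2, params.delta_o2)[i]
    d_n = layer_vessel_diameters(params.d_avg, params.r_d)[i]
    mu_blood = blood_mu_a(lam, s_n, params.f_met, table)
    out = f_n * vessel_packing_factor(mu_blood, d_n) * mu_blood
    return out if np.ndim(out) else float(out)


def reduced_scattering(lam, alpha: float, beta: float, gamma: float,
                       constants: OpticalConstants = CONSTANTS):
    """Reduced scattering coefficient (1/mm): a Mie power law plus a
    Rayleigh ``lambda**-4`` component, equal to ``alpha`` at 600 nm.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0,1], got {gamma}")
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    x = lam / constants.lambda0_scat
    out = alpha * ((1.0 - gamma) * x ** (-beta) + gamma * x ** (-4.0))
    return out if out.ndim else float(out)


def hb_concentration(f_rbc_percent, constants: OpticalConstants = CONSTANTS):
    """Convert RBC tissue fraction (percent) to hemoglobin concentration
    in uM (umole hemoglobin per liter of tissue).

    ``c_Hb = f_RBC/100 * c_Hb,RBC / M_Hb * 1e6``, i.e. about 53.5 uM per
    percent RBC tissue fraction.
    """
    f = np.asarray(f_rbc_percent, float)
    if np.any(f < 0):
        raise ValueError("RBC tissue fraction must be nonnegative")
    out = f * (1e4 * constants.c_hb_rbc / constants.m_hb)
    return out if out.ndim else float(out)
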