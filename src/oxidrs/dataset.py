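"""Tissue-parameter sampling, dataset generation and data-exclusion rules.

Training and evaluation sets are drawn iid from configurable marginal
distributions over the 15 model parameters, with rejection of combinations
whose derived layer quantities (saturations, blood fractions, vessel
diameters) leave their physical ranges.  Each record carries the clean and
the noise-corrupted spectrum pair, the sampling-volume-weighted targets, and
two exclusion flags:

* ``excl_noisy`` — the long-channel noisy spectrum has more than two
  adjacent-point pairs differing by over 50% (relative to the larger of the
  pair), marking spectra too noisy to evaluate;
* ``excl_weak_hb`` — the hemoglobin signature is too weak to carry oxygen
  saturation information, operationalized as a blood-contrast statistic on
  the clean long-channel spectrum falling below a calibrated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from oxidrs.tissue_optics import ChromophoreTable, TissueParams, ValidationError
from oxidrs.montecarlo import PathLengthTable
from oxidrs.forward import SpectrumPair, forward_record, white_reference, _mua_triplets
from oxidrs.noise import NoiseSpec, apply_noise

__all__ = [
    "ParameterDistributions",
    "LabeledDataset",
    "sample_parameters",
    "generate_dataset",
    "exclude_noisy",
    "blood_contrast",
    "exclude_weak_hb",
    "DEFAULT_WEAK_HB_THRESHOLD",
]

# Calibrated (scripts/calibrate_weak_hb.py) so that, under the default
# distributions and noise model, the fraction of records usable for the
# saturation task is near 86%.
DEFAULT_WEAK_HB_THRESHOLD = 0.055

_FAMILIES = ("uniform", "loguniform", "triangular", "constant")


@dataclass
class ParameterDistributions:
    """Marginal distribution per model parameter.

    Each entry maps a :class:`TissueParams` field name to a tuple
    ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``,
    ``("triangular", lo, mode, hi)`` or ``("constant", value)``.
    Joint physical constraints are enforced by rejection sampling.
    """

    specs: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        names = TissueParams.field_names()
        missing = set(names) - set(self.specs)
        extra = set(self.specs) - set(names)
        if missing or extra:
            raise ValueError(f"missing={sorted(missing)} extra={sorted(extra)}")
        for name, s in self.specs.items():
            if s[0] not in _FAMILIES:
                raise ValueError(f"{name}: unknown family {s[0]!r}")
            if s[0] == "loguniform" and s[1] <= 0:
                raise ValueError(f"{name}: log-uniform support must be positive")

    @classmethod
    def default(cls) -> "ParameterDistributions":
        """Shipped defaults: wide, physiologically plausible skin ranges.

        These are the package's own choices of realistic supports (saturation
        spanning the full [0, 1], scattering ranges exceeding fitted skin
        values); they are configuration, not ground truth.
        """
        return cls({
            "t_epi": ("uniform", 0.04, 0.16),
            "f_mel": ("loguniform", 0.005, 0.4),
            "beta_mel": ("uniform", 2.5, 4.5),
            "f_bcaro": ("uniform", 0.0, 0.01),
            "f_lyco": ("uniform", 0.0, 0.01),
            "f_blood": ("loguniform", 5e-4, 0.05),
            "r_blood": ("uniform", -0.8, 0.8),
            "s_o2": ("uniform", 0.0, 1.0),
            "delta_o2": ("uniform", -0.4, 0.4),
            "f_met": ("uniform", 0.0, 0.05),
            "d_avg": ("loguniform", 0.005, 0.15),
            "r_d": ("uniform", 0.0, 0.9),
            "alpha": ("loguniform", 0.75, 6.0),
            "beta": ("uniform", 0.5, 3.0),
            "gamma": ("uniform", 0.0, 0.5),
        })

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 15) array of marginal draws (no joint constraints yet)."""
        cols = []
        for name in TissueParams.field_names():
            s = self.specs[name]
            if s[0] == "uniform":
                cols.append(rng.uniform(s[1], s[2], n))
            elif s[0] == "loguniform":
                cols.append(np.exp(rng.uniform(np.log(s[1]), np.log(s[2]), n)))
            elif s[0] == "triangular":
                cols.append(rng.triangular(s[1], s[2], s[3], n))
            else:
                cols.append(np.full(n, float(s[1])))
        return np.column_stack(cols)

    def musp_support(self, wavelengths) -> tuple[float, float]:
        """Range of reduced scattering reachable over the given wavelengths."""
        lam = np.asarray(wavelengths, float)
        x = lam / 600.0

        def rng_of(name):
            s = self.specs[name]
            return (s[1], s[1]) if s[0] == "constant" else (s[1], s[-1])

        a_lo, a_hi = rng_of("alpha")
        b_lo, b_hi = rng_of("beta")
        g_lo, g_hi = rng_of("gamma")
        vals = []
        for b in (b_lo, b_hi):
            for g in (g_lo, g_hi):
                vals.append((1 - g) * x ** (-b) + g * x ** (-4.0))
        v = np.array(vals)
        return float(a_lo * v.min()), float(a_hi * v.max())


def sample_parameters(n: int, dists: ParameterDistributions,
                      seed: int) -> list[TissueParams]:
    """Draw ``n`` valid tissue realizations by rejection sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[TissueParams] = []
    attempts = 0
    while len(out) < n:
        batch = dists.draw(max(n - len(out), 64), rng)
        for row in batch:
            attempts += 1
            try:
                out.append(TissueParams.from_array(row))
            except ValidationError:
                continue
            if len(out) == n:
                break
        if attempts > 64 and len(out) / attempts < 0.01:
            raise ValueError(
                "rejection-sampling acceptance below 1%; check distributions")
    return out


def exclude_noisy(i_long) -> bool:
    """Noisy-spectrum exclusion on the long-separation channel.

    Adjacent points differing by more than 50% of the larger of the two, in
    more than two pairs, mark the spectrum as excluded.  Pairs whose larger
    value is not positive are degenerate and count as violating.
    """
    y = np.asarray(i_long, float)
    hi = np.maximum(y[:-1], y[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(y)) / hi
    violating = (hi <= 0) | (rel > 0.5)
    return int(violating.sum()) > 2


def blood_contrast(params: TissueParams, table: PathLengthTable, grid,
                   chromo: ChromophoreTable,
                   band: tuple[float, float] = (520.0, 590.0)) -> float:
    """Hemoglobin-signature strength of the clean long-channel spectrum.

    One minus the mean, over the hemoglobin band, of the ratio between the
    spectrum and the same model with ``f_blood = 0``; zero without blood and
    increasing with blood content.
    """
    grid = np.asarray(grid, float)
    mua, musp = _mua_triplets(params, grid, chromo)
    with_blood, _ = table.spectrum_sums(params.t_epi, musp, mua)
    mua0 = mua.copy()
    mua0[:, 1:] = 0.0
    without, _ = table.spectrum_sums(params.t_epi, musp, mua0)
    m = (grid >= band[0]) & (grid <= band[1])
    if not np.any(m):
        raise ValueError("wavelength grid does not cover the hemoglobin band")
    ratio = with_blood[1, m] / without[1, m]
    return float(1.0 - ratio.mean())


def exclude_weak_hb(params: TissueParams, table: PathLengthTable, grid,
                    chromo: ChromophoreTable,
                    threshold: float = DEFAULT_WEAK_HB_THRESHOLD) -> bool:
    """True when the hemoglobin signature is too weak for the saturation task."""
    return blood_contrast(params, table, grid, chromo) < threshold


@dataclass
class LabeledDataset:
    """Array-backed labeled dataset of tissue models and spectra.

    ``spectra_clean``/``spectra_noisy``: (n, 2, n_lambda) with channel 0 the
    0.4 mm separation.  Targets are fractions; NaN saturation marks models
    without blood.  Exclusion flags are reproducible from the stored seeds.
    """

    wavelength_nm: np.ndarray
    params: np.ndarray          # (n, 15)
    spectra_clean: np.ndarray   # (n, 2, n_lambda)
    spectra_noisy: np.ndarray
    s_o2: np.ndarray            # (n,) fraction, NaN if undefined
    f_rbc: np.ndarray           # (n,) fraction
    weights: np.ndarray         # (n, 3)
    blood_contrast: np.ndarray  # (n,) hemoglobin-signature statistic
    excl_noisy: np.ndarray      # (n,) bool, from the noisy spectra
    excl_weak_hb: np.ndarray    # (n,) bool
    noise_seeds: np.ndarray     # (n,) uint32
    master_seed: int = 0
    weak_hb_threshold: float = DEFAULT_WEAK_HB_THRESHOLD

    def set_weak_hb_threshold(self, threshold: float) -> None:
        """Re-derive the weak-hemoglobin flags from the stored statistic."""
        self.weak_hb_threshold = float(threshold)
        self.excl_weak_hb = self.blood_contrast < threshold

    def __len__(self) -> int:
        return self.params.shape[0]

    def spectrum_pair(self, i: int, noisy: bool = False) -> SpectrumPair:
        s = self.spectra_noisy if noisy else self.spectra_clean
        return SpectrumPair(self.wavelength_nm, s[i, 0], s[i, 1])

    def tissue_params(self, i: int) -> TissueParams:
        return TissueParams.from_array(self.params[i])

    def included_saturation(self) -> np.ndarray:
        """Records usable for the oxygen-saturation task."""
        return (~self.excl_noisy & ~self.excl_weak_hb
                & np.isfinite(self.s_o2))

    def included_rbc(self) -> np.ndarray:
        """Records usable for the RBC-tissue-fraction task."""
        return ~self.excl_noisy

    # -- persistence --------------------------------------------------------

    _ARRAYS = ("wavelength_nm", "params", "spectra_clean", "spectra_noisy",
               "s_o2", "f_rbc", "weights", "blood_contrast", "excl_noisy",
               "excl_weak_hb", "noise_seeds")

    def save(self, path):
        with h5py.File(path, "w") as f:
            for name in self._ARRAYS:
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["master_seed"] = self.master_seed
            f.attrs["weak_hb_threshold"] = self.weak_hb_threshold

    @classmethod
    def load(cls, path) -> "LabeledDataset":
        with h5py.File(path, "r") as f:
            kw = {name: f[name][()] for name in cls._ARRAYS}
            kw["excl_noisy"] = kw["excl_noisy"].astype(bool)
            kw["excl_weak_hb"] = kw["excl_weak_hb"].astype(bool)
            return cls(master_seed=int(f.attrs["master_seed"]),
                       weak_hb_threshold=float(f.attrs["weak_hb_threshold"]),
                       **kw)


def generate_dataset(n: int, dists: ParameterDistributions,
                     table: PathLengthTable, grid, noise_spec: NoiseSpec,
                     seed: int, chromo: ChromophoreTable | None = None,
                     weak_hb_threshold: float = DEFAULT_WEAK_HB_THRESHOLD,
                     progress: bool = False) -> LabeledDataset:
    """Sample -> forward model -> targets -> noise -> exclusion flags."""
    grid = np.asarray(grid, float)
    if chromo is None:
        chromo = ChromophoreTable.default()
    params_list = sample_parameters(n, dists, seed)
    # per-record noise streams derived from one master seed
    noise_seeds = np.random.SeedSequence(seed).generate_state(n)
    wref = white_reference(table)
    n_lam = grid.size
    clean = np.empty((n, 2, n_lam))
    noisy = np.empty((n, 2, n_lam))
    s_o2 = np.empty(n)
    f_rbc = np.empty(n)
    weights = np.empty((n, 3))
    contrast = np.empty(n)
    ex_noisy = np.zeros(n, bool)
    band = (grid >= 520.0) & (grid <= 590.0)
    for i, p in enumerate(params_list):
        spec, tgt = forward_record(p, table, grid, chromo, wref)
        clean[i] = spec.channels
        s_o2[i] = tgt.s_o2
        f_rbc[i] = tgt.f_rbc
        weights[i] = tgt.weights
        rng = np.random.default_rng(noise_seeds[i])
        nspec = apply_noise(spec, noise_spec, rng)
        noisy[i] = nspec.channels
        ex_noisy[i] = exclude_noisy(nspec.i_long)
        # blood contrast reuses the clean spectrum; only the bloodless
        # long-channel counterpart needs a fresh Beer-Lambert pass
        mua, musp = _mua_triplets(p, grid, chromo)
        mua0 = mua.copy()
        mua0[:, 1:] = 0.0
        bloodless, _ = table.spectrum_sums(p.t_epi, musp, mua0)
        ratio = (spec.i_long[band] * wref[1]) / bloodless[1, band]
        contrast[i] = 1.0 - ratio.mean()
        if progress and (i + 1) % 1000 == 0:
            print(f"generated {i + 1}/{n} records")
    return LabeledDataset(
        wavelength_nm=grid,
        params=np.array([p.as_array() for p in params_list]),
        spectra_clean=clean, spectra_noisy=noisy,
        s_o2=s_o2, f_rbc=f_rbc, weights=weights,
        blood_contrast=contrast,
        excl_noisy=ex_noisy, excl_weak_hb=contrast < weak_hb_threshold,
        noise_seeds=noise_seeds, master_seed=int(seed),
        weak_hb_threshold=float(weak_hb_threshold))
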