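"""Calibrate the weak-hemoglobin exclusion threshold.

Generates a dataset under the default distributions and noise model and
scans the blood-contrast threshold until the fraction of records usable for
the saturation task is near the intended 86%.  The resulting value is fixed
as DEFAULT_WEAK_HB_THRESHOLD in oxidrs.dataset.

Usage: python scripts/calibrate_weak_hb.py [n_records] [n_photons]
"""

import sys

import numpy as np

from oxidrs.dataset import ParameterDistributions, generate_dataset
from oxidrs.forward import default_wavelength_grid
from oxidrs.montecarlo import ProbeGeometry, build_table
from oxidrs.noise import NoiseSpec


def main(n_records=12_000, n_photons=200_000, target_inclusion=0.86):
    dists = ParameterDistributions.default()
    grid = default_wavelength_grid()
    m_lo, m_hi = dists.musp_support(grid)
    table = build_table(
        np.linspace(0.04, 0.16, 4),
        np.exp(np.linspace(np.log(m_lo * 0.95), np.log(m_hi * 1.05), 6)),
        ProbeGeometry(), n_photons, seed=11)
    ds = generate_dataset(n_records, dists, table, grid, NoiseSpec(),
                          seed=303)
    defined = np.isfinite(ds.s_o2)
    for thr in np.arange(0.0, 0.5, 0.005):
        incl = (~ds.excl_noisy & (ds.blood_contrast >= thr) & defined).mean()
        print(f"threshold {thr:.3f}: saturation-task inclusion {incl:.3f}")
        if incl <= target_inclusion:
            print(f"--> calibrated threshold: {thr:.3f}")
            return thr
    raise SystemExit("no threshold reached the target inclusion")


if __name__ == "__main__":
    args = [int(a) for a in sys.argv[1:3]]
    main(*args)
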