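"""Regenerate the synthetic chromophore fixture tables in src/oxidrs/data/.

The hemoglobin curves are monotone-cubic (PCHIP) interpolations through
approximate anchor values of widely used molar-extinction compilations for
oxy-, deoxy- and met-hemoglobin, converted to whole-blood absorption at
145 g Hb/L via mu_a[1/mm] = ln(10) * eps[1/cm/M] * (145/64500)[M] / 10.
The carotenoid curves are Gaussian band-shape approximations.  All five are
synthetic approximations, not literature digitizations; users can substitute
their own two-column files (see ChromophoreTable.from_files).
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = Path(__file__).resolve().parent.parent / "src" / "oxidrs" / "data"

LN10 = np.log(10.0)
C_MOLAR = 145.0 / 64500.0          # mole Hb / L blood
EPS_TO_MUA = LN10 * C_MOLAR / 10.0  # (1/cm/M) -> (1/mm) at 145 g/L

# Approximate anchors (wavelength nm, molar extinction 1/cm/M).
OXY = [
    (450, 62816), (460, 26629), (470, 16846), (480, 14822), (490, 16684),
    (500, 20932), (510, 27080), (520, 31154), (530, 39956), (540, 53236),
    (542, 53292), (545, 52076), (550, 49896), (555, 42096), (560, 32620),
    (565, 33500), (570, 44496), (576, 55540), (580, 50104), (584, 36000),
    (586, 26600), (590, 14400), (596, 5700), (600, 3200), (610, 1506),
    (620, 942), (630, 610), (640, 442), (650, 368), (660, 319),
    (680, 290), (700, 290), (720, 334), (740, 446), (750, 518),
    (780, 710), (800, 816), (850, 1058), (900, 1198),
]
DEOXY = [
    (450, 62000), (460, 42000), (470, 27000), (480, 21000), (490, 19500),
    (500, 20862), (510, 23200), (520, 25773), (530, 30000), (540, 40000),
    (550, 50000), (555, 53412), (560, 53788), (565, 50000), (570, 45072),
    (576, 34000), (580, 30000), (586, 25000), (590, 22000), (600, 14677),
    (610, 10000), (620, 7500), (630, 5149), (640, 4345), (650, 3750),
    (660, 3227), (670, 2846), (680, 2530), (690, 2130), (700, 1794),
    (710, 1600), (720, 1375), (730, 1102), (740, 1115), (750, 1405),
    (760, 1670), (770, 1520), (780, 1345), (800, 761), (820, 693),
    (850, 691), (900, 720),
]
MET = [
    (450, 24000), (470, 12000), (490, 9500), (500, 9300), (510, 8700),
    (520, 7900), (530, 7200), (540, 6600), (550, 5900), (560, 5200),
    (570, 4600), (580, 4100), (590, 3800), (600, 3600), (615, 3650),
    (630, 3900), (640, 3300), (650, 2200), (660, 1500), (680, 900),
    (700, 700), (720, 560), (750, 400), (800, 300), (850, 250), (900, 220),
]

# Carotenoid bands: (center nm, relative amplitude), common sigma 10 nm.
BCARO_BANDS = [(451, 1.00), (478, 0.87)]
LYCO_BANDS = [(446, 0.80), (472, 1.00), (503, 0.87)]
CARO_PEAK_MUA = 30.0   # 1/mm per unit fraction, relative scale
CARO_SIGMA = 10.0


def hb_curve(anchors, lam):
    a = np.array(anchors, float)
    eps = PchipInterpolator(a[:, 0], a[:, 1])(lam)
    return np.clip(eps, 0.0, None) * EPS_TO_MUA


def caro_curve(bands, lam):
    mu = np.zeros_like(lam)
    for c, amp in bands:
        mu += amp * np.exp(-0.5 * ((lam - c) / CARO_SIGMA) ** 2)
    mu *= CARO_PEAK_MUA
    mu[mu < 1e-12] = 0.0
    return mu


def write(name, lam, mu, description):
    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / name
    with open(path, "w") as fh:
        fh.write(f"# {description}\n")
        fh.write("# SYNTHETIC approximation; substitute your own table for "
                 "exact literature curves.\n")
        fh.write("# wavelength_nm\tmu_a_per_mm\n")
        for l, m in zip(lam, mu):
            fh.write(f"{l:.0f}\t{m:.6g}\n")
    print(f"wrote {path} ({path.stat().st_size} bytes)")


def main():
    lam = np.arange(450.0, 901.0, 2.0)
    write("blood_oxy_mu_a.tsv", lam, hb_curve(OXY, lam),
          "fully oxygen-saturated whole blood, 145 g Hb/L (1/mm)")
    write("blood_deoxy_mu_a.tsv", lam, hb_curve(DEOXY, lam),
          "reduced (deoxygenated) whole blood, 145 g Hb/L (1/mm)")
    write("blood_met_mu_a.tsv", lam, hb_curve(MET, lam),
          "met-hemoglobin whole blood, 145 g Hb/L (1/mm)")
    write("betacarotene_mu_a.tsv", lam, caro_curve(BCARO_BANDS, lam),
          "epidermal beta-carotene per unit fraction (1/mm), relative scale")
    write("lycopene_mu_a.tsv", lam, caro_curve(LYCO_BANDS, lam),
          "epidermal lycopene per unit fraction (1/mm), relative scale")


if __name__ == "__main__":
    main()
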