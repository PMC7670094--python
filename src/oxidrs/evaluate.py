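"""Evaluation metrics and the experiment driver for the noise/ablation grid.

Accuracy is reported as the absolute RMS deviation (percentage units), the
coefficient of determination R^2, and — for the RBC tissue fraction — the
relative RMS deviation after excluding the records with the lowest 5% of
true values, whose near-zero denominators would otherwise dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from oxidrs.ann import NetConfig, TrainedNet, normalize_features, train_with_restarts

__all__ = ["abs_rms", "rel_rms", "r_squared", "EvalReport", "Variant",
           "evaluate_net", "run_variant_grid", "DEFAULT_VARIANTS"]


def abs_rms(true, est) -> float:
    """Root-mean-square deviation; inputs in percent."""
    t = np.asarray(true, float)
    e = np.asarray(est, float)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def rel_rms(true, est, tail_fraction: float = 0.05) -> float:
    """Relative RMS deviation in %, dropping the lowest ``tail_fraction`` of
    true values (ties broken by record index)."""
    t = np.asarray(true, float)
    e = np.asarray(est, float)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    n_drop = int(np.floor(tail_fraction * t.size))
    keep = np.argsort(t, kind="stable")[n_drop:]
    tk, ek = t[keep], e[keep]
    if np.any(tk <= 0):
        raise ValueError("true values must be positive after tail exclusion")
    return float(np.sqrt(np.mean(((ek - tk) / tk) ** 2)) * 100.0)


def r_squared(true, est) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    t = np.asarray(true, float)
    e = np.asarray(est, float)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("true values have zero variance")
    return 1.0 - float(np.sum((e - t) ** 2)) / ss_tot


@dataclass
class EvalReport:
    """Metrics for one cell of the experiment grid."""

    variant: str
    target: str
    train_noise: bool
    eval_noise: bool
    input_mode: str
    n_included: int
    abs_rms: float
    r2: float
    rel_rms: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Variant:
    """One experiment cell: what to train on and what to evaluate on.

    ``extended`` cells use the extended-wavelength (475-850 nm) dataset pair
    and are skipped when none is supplied.
    """

    name: str
    target: str                  # "saturation" | "rbc_fraction"
    train_noise: bool = True
    eval_noise: bool = True
    input_mode: str = "dual"
    extended: bool = False


DEFAULT_VARIANTS = [
    # the 2x2 noise grid for both targets
    Variant("sat clean/clean", "saturation", False, False),
    Variant("sat noise/clean", "saturation", True, False),
    Variant("sat clean/noise", "saturation", False, True),
    Variant("sat noise/noise", "saturation", True, True),
    Variant("rbc clean/clean", "rbc_fraction", False, False),
    Variant("rbc noise/clean", "rbc_fraction", True, False),
    Variant("rbc clean/noise", "rbc_fraction", False, True),
    Variant("rbc noise/noise", "rbc_fraction", True, True),
    # ablations (trained and evaluated with noise)
    Variant("sat long-only", "saturation", True, True, input_mode="long"),
    Variant("rbc long-only", "rbc_fraction", True, True, input_mode="long"),
    Variant("sat absolute", "saturation", True, True, input_mode="absolute_dual"),
    Variant("rbc absolute", "rbc_fraction", True, True, input_mode="absolute_dual"),
    Variant("sat 475-850", "saturation", True, True, extended=True),
    Variant("rbc 475-850", "rbc_fraction", True, True, extended=True),
]


def evaluate_net(net: TrainedNet, eval_dataset, eval_noise: bool) -> EvalReport:
    """Apply a trained network to an evaluation dataset and score it.

    Inclusion follows the dataset's exclusion flags for the network's target;
    saturation nets additionally require a defined saturation target.
    """
    target = net.target
    if target == "saturation":
        keep = eval_dataset.included_saturation()
        truth = eval_dataset.s_o2 * 100.0
    else:
        keep = eval_dataset.included_rbc()
        truth = eval_dataset.f_rbc * 100.0
    spectra = (eval_dataset.spectra_noisy if eval_noise
               else eval_dataset.spectra_clean)
    X, ok = normalize_features(spectra, mode=net.input_mode)
    keep = keep & ok
    est = net(X[keep])
    t = truth[keep]
    rr = rel_rms(t, est) if target == "rbc_fraction" else None
    return EvalReport(
        variant="", target=target,
        train_noise=bool(net.metadata.get("use_noisy", True)),
        eval_noise=eval_noise, input_mode=net.input_mode,
        n_included=int(keep.sum()), abs_rms=abs_rms(t, est),
        r2=r_squared(t, est), rel_rms=rr)


def run_variant_grid(train_dataset, eval_dataset, cfg: NetConfig,
                     variants=None, nets: dict | None = None,
                     extended_datasets=None, progress: bool = False):
    """Train (or reuse) one network per variant and evaluate it.

    ``nets`` maps ``(target, train_noise, input_mode, extended)`` to
    pre-trained networks; cells without an entry are trained here with the
    multi-restart protocol.  ``extended_datasets`` is an optional
    (train, eval) pair on the 475-850 nm grid; extended cells are skipped
    with a log entry when it is absent.  Returns ``(reports, nets)``.
    """
    variants = DEFAULT_VARIANTS if variants is None else variants
    nets = {} if nets is None else dict(nets)
    reports = []
    for v in variants:
        if v.extended:
            if extended_datasets is None:
                print(f"skipping {v.name}: no extended-wavelength datasets")
                continue
            tr_ds, ev_ds = extended_datasets
        else:
            tr_ds, ev_ds = train_dataset, eval_dataset
        key = (v.target, v.train_noise, v.input_mode, v.extended)
        if key not in nets:
            if progress:
                print(f"training net for {key} ...")
            nets[key] = train_with_restarts(
                tr_ds, v.target, cfg, use_noisy=v.train_noise,
                input_mode=v.input_mode)
        rep = evaluate_net(nets[key], ev_ds, v.eval_noise)
        rep.variant = v.name
        reports.append(rep)
        if progress:
            print(f"{v.name}: N={rep.n_included} absRMS={rep.abs_rms:.2f} "
                  f"R2={rep.r2:.3f}"
                  + (f" relRMS={rep.rel_rms:.1f}%" if rep.rel_rms is not None
                     else ""))
    return reports, nets


def reports_to_frame(reports) -> pd.DataFrame:
    """Collect reports into a DataFrame (one row per cell) for CSV export."""
    return pd.DataFrame([r.as_dict() for r in reports])
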