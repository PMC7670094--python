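"""Inverse model: small tanh networks mapping spectra to tissue parameters.

A single fully connected hidden layer of 25 tanh nodes and a linear output
maps the mean-normalized dual-channel spectrum (56 features in the general
case) directly to oxygen saturation or RBC tissue fraction, in percent.
Training minimizes mean squared error with Levenberg-Marquardt (analytic
Jacobian, damped normal equations), stops early after six consecutive
validation failures, and repeats from at least ten random initializations
until the selection-split RMS of the three best candidates agrees to within
2.5% relative; the best candidate is kept.  Predictions are truncated to
[0, 100]% for saturation and [0, inf)% for RBC tissue fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from oxidrs.forward import SpectrumPair

__all__ = ["NetConfig", "TrainedNet", "FeatureError", "normalize_input",
           "normalize_features", "fit_lm", "train", "train_with_restarts",
           "predict"]


class FeatureError(ValueError):
    """A spectrum cannot be turned into a feature vector."""


@dataclass
class NetConfig:
    """Architecture and training protocol configuration."""

    hidden: int = 25
    splits: tuple[float, float, float] = (0.70, 0.15, 0.15)
    patience: int = 6
    restarts_min: int = 10
    restarts_max: int = 30
    spread_tol: float = 0.025
    max_iter: int = 1000
    lm_lambda0: float = 1e-3
    lm_lambda_max: float = 1e8
    lm_subsample: int | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1 or self.hidden < 1:
            raise ValueError("patience and hidden must be >= 1")


@dataclass
class TrainedNet:
    """Weights and conventions of one trained inverse network."""

    w1: np.ndarray            # (hidden, n_in)
    b1: np.ndarray            # (hidden,)
    w2: np.ndarray            # (hidden,)
    b2: float
    bounds: tuple[float, float]       # output truncation, percent
    input_mode: str                   # "dual" | "long" | "absolute_dual"
    target: str                       # "saturation" | "rbc_fraction"
    metadata: dict = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return self.w1.shape[1]

    def raw_output(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {X.shape[1]}")
        H = np.tanh(X @ self.w1.T + self.b1)
        return H @ self.w2 + self.b2

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.raw_output(X), self.bounds[0], self.bounds[1])

    # -- persistence (self-describing JSON) ---------------------------------

    def save(self, path):
        doc = {
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "bounds": list(self.bounds), "input_mode": self.input_mode,
            "target": self.target, "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TrainedNet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(w1=np.array(doc["w1"]), b1=np.array(doc["b1"]),
                   w2=np.array(doc["w2"]), b2=float(doc["b2"]),
                   bounds=tuple(doc["bounds"]), input_mode=doc["input_mode"],
                   target=doc["target"], metadata=doc.get("metadata", {}))


# ---------------------------------------------------------------------------
# features

def normalize_input(spectrum: SpectrumPair, mode: str = "dual") -> np.ndarray:
    """Feature vector for one spectrum pair.

    ``dual``: each channel divided by its own mean (removing inter-channel
    calibration), short-channel block first — 56 features on the default
    grid.  ``long``: the mean-normalized 1.2 mm channel only.
    ``absolute_dual``: raw white-calibrated intensities, no normalization.
    """
    X, ok = normalize_features(spectrum.channels[None, :, :], mode)
    if not ok[0]:
        raise FeatureError("channel mean is not positive; record unusable")
    return X[0]


def normalize_features(spectra: np.ndarray, mode: str = "dual"):
    """Batch feature matrix from (n, 2, n_lambda) spectra.

    Returns ``(X, ok)`` where rows with a nonpositive channel mean are
    flagged unusable (their features are NaN).
    """
    s = np.asarray(spectra, float)
    if s.ndim != 3 or s.shape[1] != 2:
        raise ValueError("expected spectra with shape (n, 2, n_lambda)")
    if mode == "absolute_dual":
        X = s.reshape(s.shape[0], -1)
        return X, np.isfinite(X).all(axis=1)
    if mode == "dual":
        chans = [0, 1]
    elif mode == "long":
        chans = [1]
    else:
        raise ValueError(f"unknown input mode {mode!r}")
    blocks = []
    ok = np.ones(s.shape[0], bool)
    for c in chans:
        m = s[:, c, :].mean(axis=1)
        ok &= m > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            blocks.append(s[:, c, :] / m[:, None])
    X = np.concatenate(blocks, axis=1)
    X[~ok] = np.nan
    return X, ok


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core

def _init_params(n_in, hidden, t_train, rng):
    a = np.sqrt(6.0 / (n_in + hidden))
    w1 = rng.uniform(-a, a, (hidden, n_in))
    b1 = rng.uniform(-1.0, 1.0, hidden)
    scale = max(float(np.std(t_train)), 1.0)
    w2 = rng.uniform(-1.0, 1.0, hidden) * scale / np.sqrt(hidden)
    b2 = float(np.mean(t_train))
    return _pack(w1, b1, w2, b2)


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, n_in, hidden):
    k = hidden * n_in
    w1 = theta[:k].reshape(hidden, n_in)
    b1 = theta[k:k + hidden]
    w2 = theta[k + hidden:k + 2 * hidden]
    b2 = float(theta[-1])
    return w1, b1, w2, b2


def _forward(theta, X, n_in, hidden):
    w1, b1, w2, b2 = _unpack(theta, n_in, hidden)
    H = np.tanh(X @ w1.T + b1)
    return H @ w2 + b2, H


def _normal_equations(theta, X, t, n_in, hidden, chunk=4096):
    """Accumulate J^T J and J^T r for the 1-hidden-layer net."""
    w1, b1, w2, b2 = _unpack(theta, n_in, hidden)
    p = theta.size
    A = np.zeros((p, p))
    g = np.zeros(p)
    sse = 0.0
    for lo in range(0, X.shape[0], chunk):
        Xc = X[lo:lo + chunk]
        tc = t[lo:lo + chunk]
        H = np.tanh(Xc @ w1.T + b1)
        r = H @ w2 + b2 - tc
        G = (1.0 - H * H) * w2  # (n, hidden)
        J = np.empty((Xc.shape[0], p))
        J[:, :hidden * n_in] = (G[:, :, None] * Xc[:, None, :]).reshape(
            Xc.shape[0], -1)
        J[:, hidden * n_in:hidden * n_in + hidden] = G
        J[:, hidden * n_in + hidden:-1] = H
        J[:, -1] = 1.0
        A += J.T @ J
        g += J.T @ r
        sse += float(r @ r)
    return A, g, sse


def fit_lm(X_train, t_train, X_val, t_val, cfg: NetConfig, seed: int):
    """Train one network by damped LM with validation-based early stopping.

    Returns the parameter vector of the best-validation iteration, plus a
    history dict (per-iteration train/validation MSE, stop reason).
    """
    n, n_in = X_train.shape
    hidden = cfg.hidden
    rng = np.random.default_rng(seed)
    theta = _init_params(n_in, hidden, t_train, rng)

    def mse(theta_, X_, t_):
        y, _ = _forward(theta_, X_, n_in, hidden)
        return float(np.mean((y - t_) ** 2))

    lam = cfg.lm_lambda0
    best_val = mse(theta, X_val, t_val)
    best_theta = theta.copy()
    fails = 0
    history = {"train_mse": [], "val_mse": [], "stop": "max_iter",
               "converged": True}
    for _ in range(cfg.max_iter):
        if cfg.lm_subsample is not None and cfg.lm_subsample < n:
            idx = rng.choice(n, cfg.lm_subsample, replace=False)
            Xs, ts = X_train[idx], t_train[idx]
        else:
            Xs, ts = X_train, t_train
        A, g, sse = _normal_equations(theta, Xs, ts, n_in, hidden)
        cur = sse / Xs.shape[0]
        d = np.diag(A).copy()
        d[d < 1e-12] = 1e-12
        accepted = False
        while lam <= cfg.lm_lambda_max:
            try:
                step = np.linalg.solve(A + lam * np.diag(d), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta + step
            if mse(trial, Xs, ts) < cur:
                theta = trial
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            history["stop"] = "lambda_max"
            break
        history["train_mse"].append(mse(theta, X_train, t_train))
        val = mse(theta, X_val, t_val)
        history["val_mse"].append(val)
        if val < best_val:
            best_val = val
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails >= cfg.patience:
                history["stop"] = "early_stop"
                break
    else:
        history["converged"] = False
    history["best_val_mse"] = best_val
    return best_theta, history


# ---------------------------------------------------------------------------
# public training API

_TARGETS = {
    "saturation": dict(bounds=(0.0, 100.0)),
    "rbc_fraction": dict(bounds=(0.0, np.inf)),
}


def _prepare(dataset, target: str, use_noisy: bool, input_mode: str):
    """Features, percent-scale labels and usable-record mask for a target."""
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {sorted(_TARGETS)}")
    spectra = dataset.spectra_noisy if use_noisy else dataset.spectra_clean
    X, ok = normalize_features(spectra, mode=input_mode)
    if target == "saturation":
        keep = dataset.included_saturation() & ok
        t = dataset.s_o2 * 100.0
    else:
        keep = dataset.included_rbc() & ok
        t = dataset.f_rbc * 100.0
    return X[keep], t[keep], keep


def _split(n, splits, rng):
    idx = rng.permutation(n)
    n_tr = int(round(splits[0] * n))
    n_va = int(round(splits[1] * n))
    return idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:]


def train(dataset, target: str, cfg: NetConfig, use_noisy: bool = True,
          input_mode: str = "dual", seed: int | None = None,
          _labels_override=None) -> TrainedNet:
    """Train one network (single initialization) on a labeled dataset."""
    X, t, _ = _prepare(dataset, target, use_noisy, input_mode)
    if _labels_override is not None:
        t = np.asarray(_labels_override, float)
        if t.shape != (X.shape[0],):
            raise ValueError("label override has wrong length")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    i_tr, i_va, i_se = _split(X.shape[0], cfg.splits, rng)
    theta, hist = fit_lm(X[i_tr], t[i_tr], X[i_va], t[i_va], cfg, seed)
    w1, b1, w2, b2 = _unpack(theta, X.shape[1], cfg.hidden)
    y_sel, _ = _forward(theta, X[i_se], X.shape[1], cfg.hidden)
    sel_rms = float(np.sqrt(np.mean((np.clip(
        y_sel, *_TARGETS[target]["bounds"]) - t[i_se]) ** 2)))
    return TrainedNet(
        w1=w1, b1=b1, w2=w2, b2=b2,
        bounds=_TARGETS[target]["bounds"], input_mode=input_mode,
        target=target,
        metadata={"seed": int(seed), "use_noisy": use_noisy,
                  "selection_rms": sel_rms,
                  "train_mse": hist["train_mse"][-1] if hist["train_mse"] else None,
                  "best_val_mse": hist["best_val_mse"],
                  "stop": hist["stop"], "n_records": int(X.shape[0]),
                  "config": asdict(cfg)})


def train_with_restarts(dataset, target: str, cfg: NetConfig,
                        use_noisy: bool = True, input_mode: str = "dual",
                        _labels_override=None) -> TrainedNet:
    """Multi-restart training with the best-three RMS convergence rule.

    Trains at least ``restarts_min`` networks from different seeded
    initializations, continuing (up to ``restarts_max``) until the
    selection-split RMS of the three best agrees within ``spread_tol``
    relative; returns the network with the lowest selection RMS.
    """
    candidates: list[TrainedNet] = []
    k = 0
    while True:
        net = train(dataset, target, cfg, use_noisy, input_mode,
                    seed=cfg.seed + 1000 * k, _labels_override=_labels_override)
        candidates.append(net)
        k += 1
        if k >= cfg.restarts_min:
            rms = sorted(c.metadata["selection_rms"] for c in candidates)[:3]
            if rms[0] > 0 and (rms[-1] - rms[0]) / rms[0] < cfg.spread_tol:
                break
            if k >= cfg.restarts_max:
                candidates.sort(key=lambda c: c.metadata["selection_rms"])
                best = candidates[0]
                best.metadata["restart_warning"] = (
                    "restart cap reached without best-three convergence")
                best.metadata["n_restarts"] = k
                return best
    candidates.sort(key=lambda c: c.metadata["selection_rms"])
    best = candidates[0]
    best.metadata["n_restarts"] = k
    best.metadata["best_three_rms"] = sorted(
        c.metadata["selection_rms"] for c in candidates)[:3]
    return best


def predict(net: TrainedNet, spectra) -> np.ndarray:
    """Estimates in percent for spectra (SpectrumPair, (2, n_lambda) or
    (n, 2, n_lambda)); truncated to the network's output bounds."""
    if isinstance(spectra, SpectrumPair):
        s = spectra.channels[None]
    else:
        s = np.asarray(spectra, float)
        if s.ndim == 2:
            s = s[None]
    mode = {"dual": "dual", "long": "long",
            "absolute_dual": "absolute_dual"}[net.input_mode]
    X, ok = normalize_features(s, mode=mode)
    if not ok.all():
        raise FeatureError("records with nonpositive channel mean cannot be "
                           "predicted")
    return net(X)
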