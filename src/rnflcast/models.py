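"""Predictive methods: forecast a future RNFL profile from two prior visits.

Five methods share one train/predict contract:

``lr``, ``svr``, ``gbr``
    Flat regressors on the 1536-element concatenation of the two input
    profiles (input1 first). Each output dimension (768 thickness samples or
    7 sector averages) is an independent single-output regression sharing
    the same features; ordinary least squares is fitted jointly since the
    multi-output solution coincides with per-output fits.
``cnn``
    A two-channel 1D convolutional network on the (2, 768) stack of the two
    input profiles: four convolution → ReLU → max-pool blocks, two hidden
    fully connected layers, and a linear head of size 768 or 7; trained with
    Adam (lr 0.001) on mean squared error for 100 epochs by default, with
    ±5-sample circular shift augmentation in vector mode.
``carry_forward``
    The clinical no-change comparator: the prediction is exactly the most
    recent input profile (or its sector averages).

Usage follows the model/results idiom::

    model = RNFLForecastModel(train_triplets, method="gbr", target_mode="vector768")
    res = model.fit(seed=0)
    yhat = res.predict_triplets(test_triplets)
    print(res.summary())

SVR and the CNN see inputs (and targets) divided by 100 for numeric
conditioning; the scaling is inverted at output. LR and GBR run on raw μm.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.svm import SVR

from . import _nn
from .profiles import N_SAMPLES, RNFLProfile, sector_means
from .triplets import Triplet

METHODS = ("lr", "svr", "gbr", "cnn", "carry_forward")
TARGET_MODES = ("vector768", "sector7")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "lr": {},
    "svr": {"C": 1.0, "epsilon": 0.01, "gamma": "scale", "scale": 100.0},
    "gbr": {
        "n_estimators": 300,
        "max_depth": 3,
        "learning_rate": 0.05,
        "max_features": None,
        "subsample": 1.0,
    },
    "cnn": {
        "conv_channels": (16, 32, 64, 64),
        "kernel_sizes": (7, 5, 5, 3),
        "fc_sizes": (768,),
        "pool_width": 2,
        "batch_size": 32,
        "learning_rate": 1e-3,
        "epochs": 100,
        "shift_max": 5,
        "scale": 100.0,
    },
    "carry_forward": {},
}


def target_dim(target_mode: str) -> int:
    if target_mode == "vector768":
        return N_SAMPLES
    if target_mode == "sector7":
        return 7
    raise ValueError(f"unknown target_mode {target_mode!r}")


def _require_preprocessed(profile: RNFLProfile, what: str) -> np.ndarray:
    if not profile.is_preprocessed:
        raise ValueError(f"{what} must be preprocessed before modelling")
    return profile.values


def featurize_flat(triplet: Triplet, target_mode: str = "vector768") -> tuple[np.ndarray, np.ndarray]:
    """One triplet -> (1536-element feature row, target vector).

    The row is input1's 768 samples followed by input2's; the target is the
    target scan's full profile or its 7 sector averages.
    """
    x1 = _require_preprocessed(triplet.input1.profile, "input1 profile")
    x2 = _require_preprocessed(triplet.input2.profile, "input2 profile")
    y = _require_preprocessed(triplet.target.profile, "target profile")
    row = np.concatenate([x1, x2])
    if target_mode == "sector7":
        y = sector_means(triplet.target.profile).as_array()
    elif target_mode != "vector768":
        raise ValueError(f"unknown target_mode {target_mode!r}")
    return row, y


def triplets_to_arrays(
    triplets: Sequence[Triplet], target_mode: str = "vector768"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack triplets into (X1, X2, Y) arrays of shape (n, 768) / (n, d)."""
    if not triplets:
        raise ValueError("need at least one triplet")
    x1 = np.stack([_require_preprocessed(t.input1.profile, "input1 profile") for t in triplets])
    x2 = np.stack([_require_preprocessed(t.input2.profile, "input2 profile") for t in triplets])
    if target_mode == "sector7":
        y = np.stack([sector_means(t.target.profile).as_array() for t in triplets])
    else:
        y = np.stack([_require_preprocessed(t.target.profile, "target profile") for t in triplets])
    return x1, x2, y


def _fingerprint(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.round(a, 6)).tobytes())
    return h.hexdigest()[:16]


def _rbf_gram(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    sq = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * (a @ b.T)
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


def _circular_shift_batch(x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Roll each sample of a (B, ..., L) batch by its own shift along the ring."""
    L = x.shape[-1]
    idx = (np.arange(L)[None, :] - shifts[:, None]) % L
    if x.ndim == 3:
        return np.take_along_axis(x, idx[:, None, :], axis=2)
    return np.take_along_axis(x, idx, axis=1)


class CnnDivergenceError(RuntimeError):
    """Raised when the CNN training loss becomes non-finite."""


class RNFLForecastModel:
    """Forecasting model specification: triplets + method + target mode.

    Parameters
    ----------
    triplets : training triplets (preprocessed scans). May be empty only for
        the carry_forward comparator, which has nothing to fit.
    method : one of ``lr``, ``svr``, ``gbr``, ``cnn``, ``carry_forward``.
    target_mode : ``vector768`` (full profile) or ``sector7`` (G, T, TS, TI,
        N, NS, NI averages).
    hyperparams : overrides merged over the method's declared defaults.
    """

    def __init__(
        self,
        triplets: Sequence[Triplet],
        method: str,
        target_mode: str = "vector768",
        hyperparams: dict | None = None,
    ):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if target_mode not in TARGET_MODES:
            raise ValueError(f"unknown target_mode {target_mode!r}")
        if method != "carry_forward" and len(triplets) < 1:
            raise ValueError(f"method {method!r} needs at least one training triplet")
        self.triplets = list(triplets)
        self.method = method
        self.target_mode = target_mode
        self.hyperparams = {**DEFAULT_HYPERPARAMS[method], **(hyperparams or {})}

    def fit(self, seed: int = 0, verbose: bool = False) -> "RNFLForecastResults":
        t0 = time.perf_counter()
        state: dict = {}
        diagnostics: dict = {}
        fingerprint = ""
        if self.method != "carry_forward":
            x1, x2, y = triplets_to_arrays(self.triplets, self.target_mode)
            fingerprint = _fingerprint(x1, x2, y)
        if self.method == "lr":
            X = np.hstack([x1, x2])
            est = LinearRegression()
            est.fit(X, y)
            state["lr"] = est
        elif self.method == "svr":
            state.update(self._fit_svr(x1, x2, y, diagnostics))
        elif self.method == "gbr":
            state["gbr"] = self._fit_gbr(x1, x2, y, seed)
        elif self.method == "cnn":
            net, history = self._fit_cnn(x1, x2, y, seed, verbose)
            state["cnn"] = net
            diagnostics["loss_history"] = history
            diagnostics["final_loss"] = history[-1]
            diagnostics["best_loss"] = min(history)
        diagnostics["fit_seconds"] = time.perf_counter() - t0
        manifest = {
            "method": self.method,
            "target_mode": self.target_mode,
            "hyperparams": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.hyperparams.items()},
            "seed": seed,
            "n_triplets": len(self.triplets),
            "data_fingerprint": fingerprint,
        }
        return RNFLForecastResults(self, state, manifest, diagnostics)

    # -- per-method fitting -------------------------------------------------

    def _fit_svr(self, x1, x2, y, diagnostics) -> dict:
        hp = self.hyperparams
        scale = hp["scale"]
        X = np.hstack([x1, x2]) / scale
        ys = y / scale
        if np.all(X == X[0]):
            import warnings

            warnings.warn("SVR fitted on all-identical feature rows; predictions are constant")
        if float(X.var()) == 0.0:
            gamma = 1.0
        elif hp["gamma"] == "scale":
            gamma = 1.0 / (X.shape[1] * X.var())
        else:
            gamma = float(hp["gamma"])
        gram = _rbf_gram(X, X, gamma)
        ests = []
        for j in range(ys.shape[1]):
            est = SVR(kernel="precomputed", C=hp["C"], epsilon=hp["epsilon"])
            est.fit(gram, ys[:, j])
            ests.append(est)
        return {"svr": ests, "svr_train": X, "svr_gamma": gamma}

    def _fit_gbr(self, x1, x2, y, seed) -> list:
        hp = self.hyperparams
        X = np.hstack([x1, x2])
        ests = []
        for j in range(y.shape[1]):
            est = GradientBoostingRegressor(
                n_estimators=hp["n_estimators"],
                max_depth=hp["max_depth"],
                learning_rate=hp["learning_rate"],
                max_features=hp["max_features"],
                subsample=hp["subsample"],
                random_state=seed + j,
            )
            est.fit(X, y[:, j])
            ests.append(est)
        return ests

    def _fit_cnn(self, x1, x2, y, seed, verbose) -> tuple[_nn.Sequential, list[float]]:
        hp = self.hyperparams
        scale = hp["scale"]
        X = np.stack([x1, x2], axis=1) / scale  # (N, 2, 768)
        if X.shape[1:] != (2, N_SAMPLES):
            raise ValueError(f"CNN input must have shape (2, {N_SAMPLES})")
        Y = y / scale
        rng = np.random.default_rng(seed)
        net = _nn.build_cnn(
            in_channels=2,
            in_length=N_SAMPLES,
            out_dim=target_dim(self.target_mode),
            conv_channels=tuple(hp["conv_channels"]),
            kernel_sizes=tuple(hp["kernel_sizes"]),
            fc_sizes=tuple(hp["fc_sizes"]),
            rng=rng,
            pool_width=hp["pool_width"],
        )
        opt = _nn.Adam(net, lr=hp["learning_rate"])
        n = X.shape[0]
        bs = min(hp["batch_size"], n)
        # sector targets are not equivariant under ring shifts, so augmentation
        # is restricted to the vector mode where the target can shift along
        shift_max = hp["shift_max"] if self.target_mode == "vector768" else 0
        history: list[float] = []
        for epoch in range(hp["epochs"]):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                xb, yb = X[sel], Y[sel]
                if shift_max > 0:
                    shifts = rng.integers(-shift_max, shift_max + 1, size=len(sel))
                    xb = _circular_shift_batch(xb, shifts)
                    yb = _circular_shift_batch(yb, shifts)
                pred = net.forward(xb)
                loss, dloss = _nn.mse_loss(pred, yb)
                if not np.isfinite(loss):
                    raise CnnDivergenceError(
                        f"non-finite training loss at epoch {epoch}; lower the learning rate"
                    )
                net.backward(dloss)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / n_batches)
            if verbose:
                print(f"epoch {epoch + 1}/{hp['epochs']}: loss {history[-1]:.6f}")
        return net, history


@dataclass
class RNFLForecastResults:
    """Fitted forecaster: parameters, training manifest and prediction API."""

    model: RNFLForecastModel
    _state: dict
    manifest: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def method(self) -> str:
        return self.model.method

    @property
    def target_mode(self) -> str:
        return self.model.target_mode

    def predict_batch(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Predict targets for stacked input profiles (n, 768) + (n, 768)."""
        x1 = np.atleast_2d(np.asarray(x1, dtype=float))
        x2 = np.atleast_2d(np.asarray(x2, dtype=float))
        if x1.shape[1] != N_SAMPLES or x2.shape[1] != N_SAMPLES or x1.shape[0] != x2.shape[0]:
            raise ValueError(f"inputs must be (n, {N_SAMPLES}) arrays of equal length")
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise ValueError("inputs must be finite (preprocess profiles first)")
        m = self.method
        if m == "carry_forward":
            if self.target_mode == "sector7":
                return np.stack([sector_means(RNFLProfile(values=row)).as_array() for row in x2])
            return x2.copy()
        if m == "lr":
            return np.atleast_2d(self._state["lr"].predict(np.hstack([x1, x2])))
        if m == "svr":
            scale = self.model.hyperparams["scale"]
            X = np.hstack([x1, x2]) / scale
            gram = _rbf_gram(X, self._state["svr_train"], self._state["svr_gamma"])
            preds = np.column_stack([est.predict(gram) for est in self._state["svr"]])
            return preds * scale
        if m == "gbr":
            X = np.hstack([x1, x2])
            return np.column_stack([est.predict(X) for est in self._state["gbr"]])
        # cnn
        scale = self.model.hyperparams["scale"]
        X = np.stack([x1, x2], axis=1) / scale
        return self._state["cnn"].forward(X) * scale

    def predict(self, input1: RNFLProfile | np.ndarray, input2: RNFLProfile | np.ndarray) -> np.ndarray:
        """Predict one future profile (768,) or sector vector (7,)."""
        v1 = input1.values if isinstance(input1, RNFLProfile) else np.asarray(input1, float)
        v2 = input2.values if isinstance(input2, RNFLProfile) else np.asarray(input2, float)
        if isinstance(input1, RNFLProfile):
            _require_preprocessed(input1, "input1")
        if isinstance(input2, RNFLProfile):
            _require_preprocessed(input2, "input2")
        return self.predict_batch(v1[None, :], v2[None, :])[0]

    def predict_triplets(self, triplets: Sequence[Triplet]) -> np.ndarray:
        x1, x2, _ = triplets_to_arrays(triplets, self.target_mode)
        return self.predict_batch(x1, x2)

    def summary(self) -> str:
        """Plain-text summary of the fitted model and its training run."""
        lines = [
            "RNFL Forecast Results",
            "=" * 53,
            f"method:            {self.method}",
            f"target mode:       {self.target_mode} ({target_dim(self.target_mode)} outputs)",
            f"training triplets: {self.manifest['n_triplets']}",
            f"seed:              {self.manifest['seed']}",
            f"data fingerprint:  {self.manifest['data_fingerprint'] or '-'}",
            f"fit time:          {self.diagnostics.get('fit_seconds', 0.0):.2f} s",
        ]
        hp = self.manifest["hyperparams"]
        if hp:
            lines.append("hyperparameters:")
            for k, v in hp.items():
                lines.append(f"  {k:<16} {v}")
        if "final_loss" in self.diagnostics:
            lines.append(f"final train MSE (scaled): {self.diagnostics['final_loss']:.6f}")
            lines.append(f"best train MSE (scaled):  {self.diagnostics['best_loss']:.6f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write manifest JSON plus a parameter blob into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        if self.method == "cnn":
            np.savez(directory / "params.npz", **self._state["cnn"].state_dict())
        elif self.method in ("lr", "svr", "gbr"):
            import pickle

            with open(directory / "params.pkl", "wb") as fh:
                pickle.dump(self._state, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "RNFLForecastResults":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        model = object.__new__(RNFLForecastModel)
        model.triplets = []
        model.method = manifest["method"]
        model.target_mode = manifest["target_mode"]
        model.hyperparams = {**DEFAULT_HYPERPARAMS[manifest["method"]], **manifest["hyperparams"]}
        state: dict = {}
        if manifest["method"] == "cnn":
            hp = model.hyperparams
            rng = np.random.default_rng(0)
            net = _nn.build_cnn(
                2, N_SAMPLES, target_dim(manifest["target_mode"]),
                tuple(hp["conv_channels"]), tuple(hp["kernel_sizes"]),
                tuple(hp["fc_sizes"]), rng, hp["pool_width"],
            )
            with np.load(directory / "params.npz") as blob:
                net.load_state_dict(dict(blob))
            state["cnn"] = net
        elif manifest["method"] in ("lr", "svr", "gbr"):
            import pickle

            with open(directory / "params.pkl", "rb") as fh:
                state = pickle.load(fh)
        return cls(model, state, manifest, {})
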