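"""Stepwise neural-network "time to exacerbation" risk model.

A small single-hidden-layer network (sigmoid hidden units, linear
output) regresses the time to the next exacerbation (capped at 200
days) on temporal biomarker features.  By default the target is
fitted on the log1p scale — times far in the future are inherently
unpredictable from a 14-day biomarker window, and a raw-day loss
lets their variance drown the signal from imminent events — while
predictions are always returned in days.  Inputs are chosen by forward
stepwise selection: at each step every unused candidate feature is
tried in a network trained on the training split with early stopping
on the validation split and scored on the unseen test split,
averaged over Monte Carlo 60:20:20 splits stratified by patient.
The final model is tuned over a grid of hidden-node counts and can
be exported as an explicit closed-form formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureDatabase

__all__ = [
    "ANNConfig",
    "ANNModel",
    "SelectionStep",
    "SelectionTrace",
    "stepwise_select",
    "train_final",
    "predict_risk",
    "evaluate_regression",
    "monte_carlo_splits",
]


@dataclass(frozen=True)
class ANNConfig:
    max_steps: int = 20
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_mc_splits: int = 3
    hidden_nodes_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 8, 10)
    selection_hidden: int = 3      # hidden nodes used during selection
    epochs: int = 500
    learning_rate: float = 0.05
    momentum: float = 0.9
    patience: int = 80             # early-stopping patience (epochs)
    target_transform: str = "log1p"   # "log1p" or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.target_transform not in ("log1p", "none"):
            raise ValueError("target_transform must be 'log1p' or 'none'")


@dataclass
class ANNModel:
    """Trained network with its standardization constants.

    Prediction: g(y_mean + y_sd * (w2 . sigmoid(W1 z + b1) + b2))
    with z = (x - x_mean) / x_sd and g the inverse target transform
    (expm1 when the target was fitted on the log1p scale), so the
    risk score is always in days.
    """

    selected_inputs: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    W1: np.ndarray   # (n_inputs, hidden)
    b1: np.ndarray   # (hidden,)
    w2: np.ndarray   # (hidden,)
    b2: float
    hidden: int
    target_transform: str = "log1p"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X - self.x_mean) / self.x_sd
        h = 1.0 / (1.0 + np.exp(-(z @ self.W1 + self.b1)))
        out = self.y_mean + self.y_sd * (h @ self.w2 + self.b2)
        if self.target_transform == "log1p":
            return np.expm1(np.clip(out, None, 30.0))
        return out

    def to_json(self) -> str:
        payload = {
            "selected_inputs": self.selected_inputs,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "hidden": self.hidden,
            "target_transform": self.target_transform,
            "formula": self.formula(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        d = json.loads(text)
        return cls(
            selected_inputs=list(d["selected_inputs"]),
            x_mean=np.array(d["x_mean"]), x_sd=np.array(d["x_sd"]),
            y_mean=float(d["y_mean"]), y_sd=float(d["y_sd"]),
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=float(d["b2"]),
            hidden=int(d["hidden"]),
            target_transform=str(d.get("target_transform", "log1p")),
        )

    def formula(self) -> str:
        """Human-readable closed-form of the risk score."""
        zs = [
            f"z{i} = ({name} - {self.x_mean[i]:.17g}) / {self.x_sd[i]:.17g}"
            for i, name in enumerate(self.selected_inputs)
        ]
        hs = []
        for j in range(self.hidden):
            terms = " + ".join(
                f"{self.W1[i, j]:.17g}*z{i}" for i in range(len(self.selected_inputs))
            )
            hs.append(f"h{j} = 1/(1 + exp(-({terms} + {self.b1[j]:.17g})))")
        out_terms = " + ".join(f"{self.w2[j]:.17g}*h{j}" for j in range(self.hidden))
        eta = (f"eta = {self.y_mean:.17g} + {self.y_sd:.17g} * "
               f"({out_terms} + {self.b2:.17g})")
        risk = ("risk = exp(eta) - 1" if self.target_transform == "log1p"
                else "risk = eta")
        return "\n".join(zs + hs + [eta, risk])


@dataclass
class SelectionStep:
    step: int
    candidate_errors: dict[str, float]   # mean unseen-test MSE per candidate
    chosen: str
    chosen_error: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    selected_inputs: list[str] = field(default_factory=list)
    marker_tally: dict[str, int] = field(default_factory=dict)

    @property
    def panel(self) -> list[str]:
        """Distinct markers contributing selected features."""
        seen = []
        for f in self.selected_inputs:
            mk = f.split("|")[0]
            if mk not in seen:
                seen.append(mk)
        return seen


# ---------------------------------------------------------------------------
# network training (full-batch gradient descent with momentum)
# ---------------------------------------------------------------------------


def _train_mlp(Xtr, ytr, Xval, yval, hidden, epochs, lr, momentum, patience, rng):
    """Train one network; returns (W1, b1, w2, b2) at the best
    validation epoch.  Inputs must already be standardized."""
    n_in = Xtr.shape[1]
    W1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden)
    b2 = 0.0
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2); vb2 = 0.0
    best = (W1.copy(), b1.copy(), w2.copy(), b2)
    best_val = np.inf
    since_best = 0
    n = len(ytr)
    for _ in range(epochs):
        h = 1.0 / (1.0 + np.exp(-(Xtr @ W1 + b1)))
        pred = h @ w2 + b2
        err = pred - ytr
        if not np.all(np.isfinite(err)):
            raise RuntimeError("training diverged: non-finite loss")
        gout = 2.0 * err / n
        gw2 = h.T @ gout
        gb2 = gout.sum()
        gh = np.outer(gout, w2) * h * (1 - h)
        gW1 = Xtr.T @ gh
        gb1 = gh.sum(axis=0)
        vW1 = momentum * vW1 - lr * gW1
        vb1 = momentum * vb1 - lr * gb1
        vw2 = momentum * vw2 - lr * gw2
        vb2 = momentum * vb2 - lr * gb2
        W1 += vW1; b1 += vb1; w2 += vw2; b2 += vb2
        hv = 1.0 / (1.0 + np.exp(-(Xval @ W1 + b1)))
        val_mse = float(np.mean((hv @ w2 + b2 - yval) ** 2))
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best = (W1.copy(), b1.copy(), w2.copy(), b2)
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return best, best_val


def _standardize(Xtr, other):
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (Xtr - mean) / sd, [(X - mean) / sd for X in other], mean, sd


def monte_carlo_splits(patient_ids: np.ndarray, ratios, n_splits: int, seed: int):
    """Patient-stratified 60:20:20 index splits.

    All windows of a patient land in one split so that held-out error
    is measured on unseen patients.
    """
    patients = np.array(sorted(pd.unique(patient_ids)))
    out = []
    for k in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, k]))
        order = rng.permutation(patients)
        n = len(order)
        n_tr = max(int(round(ratios[0] * n)), 1)
        n_val = max(int(round(ratios[1] * n)), 1)
        n_tr = min(n_tr, n - 2) if n >= 3 else n_tr
        tr_p = set(order[:n_tr])
        val_p = set(order[n_tr:n_tr + n_val])
        te_p = set(order[n_tr + n_val:]) or set(order[-1:])
        idx = np.arange(len(patient_ids))
        out.append((
            idx[[p in tr_p for p in patient_ids]],
            idx[[p in val_p for p in patient_ids]],
            idx[[p in te_p for p in patient_ids]],
        ))
    return out


def _fit_on_split(X, y, tr, val, te, hidden, cfg: ANNConfig, rng):
    Xtr, (Xval, Xte), _, _ = _standardize(X[tr], [X[val], X[te]])
    y_mean, y_sd = y[tr].mean(), max(y[tr].std(), 1e-9)
    ytr = (y[tr] - y_mean) / y_sd
    yval = (y[val] - y_mean) / y_sd
    (W1, b1, w2, b2), _ = _train_mlp(
        Xtr, ytr, Xval, yval, hidden,
        cfg.epochs, cfg.learning_rate, cfg.momentum, cfg.patience, rng,
    )
    h = 1.0 / (1.0 + np.exp(-(Xte @ W1 + b1)))
    pred = y_mean + y_sd * (h @ w2 + b2)
    return float(np.mean((pred - y[te]) ** 2))


def stepwise_select(db: FeatureDatabase, config: ANNConfig,
                    candidates: list[str] | None = None) -> SelectionTrace:
    """Forward stepwise input selection scored on unseen test splits.

    At each step every unused candidate is added to the current input
    set, a network is trained per Monte Carlo split, and the
    candidate with the lowest mean test-set MSE is kept.  All
    ``max_steps`` steps are explored; the returned input set is the
    step prefix with the lowest mean unseen-test error, so steps that
    fail to improve are recorded but not selected.  Candidates within
    a step share the same splits and weight-initialisation streams so
    their errors are compared under common random numbers.
    """
    dev = db.development
    if dev.empty:
        raise ValueError("development set is empty")
    cols = candidates if candidates is not None else db.feature_columns
    y = dev["tte"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: all time-to-exacerbation equal")
    if config.target_transform == "log1p":
        y = np.log1p(y)
    X_all = dev[cols].to_numpy(dtype=float)
    splits = monte_carlo_splits(dev["patient_id"].to_numpy(),
                                config.split_ratios, config.n_mc_splits,
                                config.seed)
    trace = SelectionTrace()
    current: list[int] = []
    path: list[str] = []
    path_errors: list[float] = []
    for step in range(min(config.max_steps, len(cols))):
        errors: dict[str, float] = {}
        for ci, name in enumerate(cols):
            if ci in current:
                continue
            trial = current + [ci]
            errs = []
            for k, (tr, val, te) in enumerate(splits):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 11, step, k]))
                errs.append(_fit_on_split(X_all[:, trial], y, tr, val, te,
                                          config.selection_hidden, config, rng))
            errors[name] = float(np.mean(errs))
        chosen = min(errors, key=lambda k: (errors[k], k))
        current.append(cols.index(chosen))
        path.append(chosen)
        path_errors.append(errors[chosen])
        trace.steps.append(SelectionStep(step, errors, chosen, errors[chosen]))
    best_len = int(np.argmin(path_errors)) + 1
    trace.selected_inputs = path[:best_len]
    for f in trace.selected_inputs:
        mk = f.split("|")[0]
        trace.marker_tally[mk] = trace.marker_tally.get(mk, 0) + 1
    return trace


def train_final(db: FeatureDatabase, inputs: list[str],
                config: ANNConfig) -> ANNModel:
    """Tune hidden-node count on unseen test error and train the
    final network on the selected inputs."""
    dev = db.development
    y = dev["tte"].to_numpy(dtype=float)
    if config.target_transform == "log1p":
        y = np.log1p(y)
    X = dev[inputs].to_numpy(dtype=float)
    tr, val, te = monte_carlo_splits(dev["patient_id"].to_numpy(),
                                     config.split_ratios, 1, config.seed)[0]
    Xtr_s, (Xval_s, Xte_s), x_mean, x_sd = _standardize(X[tr], [X[val], X[te]])
    y_mean, y_sd = float(y[tr].mean()), float(max(y[tr].std(), 1e-9))
    ytr = (y[tr] - y_mean) / y_sd
    yval = (y[val] - y_mean) / y_sd

    best_model = None
    best_err = np.inf
    for hi, hidden in enumerate(config.hidden_nodes_grid):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, hi]))
        (W1, b1, w2, b2), _ = _train_mlp(
            Xtr_s, ytr, Xval_s, yval, hidden,
            config.epochs, config.learning_rate, config.momentum,
            config.patience, rng,
        )
        h = 1.0 / (1.0 + np.exp(-(Xte_s @ W1 + b1)))
        pred = y_mean + y_sd * (h @ w2 + b2)
        err = float(np.mean((pred - y[te]) ** 2))
        if err < best_err:
            best_err = err
            best_model = ANNModel(list(inputs), x_mean, x_sd, y_mean, y_sd,
                                  W1, b1, w2, float(b2), hidden,
                                  config.target_transform)
    if best_model is None:
        raise RuntimeError("no model trained; empty hidden_nodes_grid?")
    return best_model


def predict_risk(model: ANNModel, features) -> np.ndarray:
    """Risk score (predicted days to exacerbation) for feature rows.

    ``features`` may be a DataFrame containing the selected input
    columns or an array already ordered like ``selected_inputs``.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.selected_inputs if c not in features.columns]
        if missing:
            raise ValueError(f"missing model inputs: {missing}")
        X = features[model.selected_inputs].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(model.selected_inputs):
            raise ValueError(
                f"expected {len(model.selected_inputs)} inputs, got {X.shape[1]}")
    return model.predict(X)


def evaluate_regression(predictions, actual, split_labels=None) -> dict[str, float]:
    """Squared Pearson correlation (r^2) per split."""
    predictions = np.asarray(predictions, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if split_labels is None:
        split_labels = np.zeros(len(actual), dtype=int)
    split_labels = np.asarray(split_labels)
    out: dict[str, float] = {}
    for lab in pd.unique(split_labels):
        sel = split_labels == lab
        if sel.sum() < 3:
            raise ValueError("need >= 3 points per split")
        p, a = predictions[sel], actual[sel]
        if p.std() == 0 or a.std() == 0:
            import warnings
            warnings.warn("zero-variance predictions; r^2 reported as 0",
                          stacklevel=2)
            out[str(lab)] = 0.0
        else:
            r = np.corrcoef(p, a)[0, 1]
            out[str(lab)] = float(r * r)
    return out
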