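"""Multistep MIMO forecasting from the low/high-frequency components.

Both models forecast all tau horizons jointly from one regressor matrix
``z`` whose rows hold, for each usable time index n, the P most recent
values of c_L followed by the P most recent values of c_H (2P columns).
Targets are the observed series at n+1 .. n+tau.  The MIMO strategy avoids
the error accumulation of recursive single-step forecasting.

* MIMO-AR: ``x_hat = z @ beta.T`` with the tau x 2P coefficient matrix
  ``beta`` fitted by minimum-norm least squares (Moore-Penrose
  pseudoinverse).
* MIMO-ANN: a three-layer perceptron, logistic-sigmoid hidden layer of Q
  units and linear outputs (no bias terms), trained full-batch with
  Levenberg-Marquardt over several random restarts; the hidden width
  follows Q = round(log2(N_train)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressorSet",
    "MimoArModel",
    "MlpModel",
    "SplitSpec",
    "TrainingReport",
    "build_regressors",
    "split_rows",
    "fit_mimo_ar",
    "predict_mimo_ar",
    "init_mlp",
    "train_mlp_lm",
    "predict_mlp",
    "sigmoid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressorSet:
    """Lagged design matrix, multi-horizon targets and their time indices.

    ``row_index_map[r]`` is the 1-based time index n of row r: the row's
    regressors end at x_n and its targets are x_{n+1} .. x_{n+tau}.
    """

    z: np.ndarray         # rows x 2P
    targets: np.ndarray   # rows x tau
    row_index_map: np.ndarray
    P: int
    tau: int

    @property
    def n_rows(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class MimoArModel:
    beta: np.ndarray  # tau x 2P (plus one column if bias)
    P: int
    tau: int
    bias: bool = False


@dataclass(frozen=True)
class MlpModel:
    """Three-layer sigmoid MLP: hidden Y = f(z W), output x_hat = Y B.

    Training-set standardization statistics (inputs per column; targets
    centered per horizon with one common scale) travel with the model and
    are re-applied transparently at prediction time.
    """

    input_weights: np.ndarray   # 2P x Q
    output_weights: np.ndarray  # Q x tau
    Q: int
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    target_mean: np.ndarray | None = None   # per horizon
    target_scale: float | None = None       # common scale


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TrainingReport:
    run_errors: tuple[np.ndarray, ...]  # accepted-step MSE curve per run
    best_run: int
    final_mse: float


def sigmoid(u: np.ndarray) -> np.ndarray:
    """Logistic transfer function f(u) = 1 / (1 + exp(-u))."""
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def build_regressors(c_L, c_H, x, P: int, tau: int) -> RegressorSet:
    """Unroll the two components into the lagged MIMO design.

    Rows run over n = P .. N - tau (1-based); row n is
    ``[c_L(n) .. c_L(n-P+1), c_H(n) .. c_H(n-P+1)]`` with targets
    ``[x(n+1) .. x(n+tau)]``, giving N - P - tau + 1 rows.
    """
    c_L = np.asarray(c_L, dtype=float)
    c_H = np.asarray(c_H, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (c_L.shape == c_H.shape == x.shape) or x.ndim != 1:
        raise ValueError("c_L, c_H and x must be one-dimensional with equal length")
    N = x.size
    if P < 1 or tau < 1:
        raise ValueError("P and tau must be >= 1")
    if N < P + tau:
        raise ValueError(
            f"series too short: need N >= P + tau = {P + tau}, got {N}"
        )
    n_rows = N - P - tau + 1
    rows = np.arange(n_rows)
    # 0-based current time t = P-1 .. N-tau-1; lag columns t, t-1, ..., t-P+1
    t = rows + P - 1
    lag_idx = t[:, None] - np.arange(P)[None, :]
    z = np.hstack([c_L[lag_idx], c_H[lag_idx]])
    horizon_idx = t[:, None] + 1 + np.arange(tau)[None, :]
    targets = x[horizon_idx]
    return RegressorSet(
        z=z, targets=targets, row_index_map=t + 1, P=P, tau=tau
    )


def split_rows(reg: RegressorSet, spec: SplitSpec = SplitSpec()) -> tuple[RegressorSet, RegressorSet]:
    """Chronological split: first floor(fraction * rows) rows train, rest test."""
    if reg.n_rows < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(spec.train_fraction * reg.n_rows))
    if n_train == 0 or n_train == reg.n_rows:
        raise ValueError("split leaves an empty subset; adjust train_fraction")
    def _slice(a, b):
        return RegressorSet(
            z=reg.z[a:b], targets=reg.targets[a:b],
            row_index_map=reg.row_index_map[a:b], P=reg.P, tau=reg.tau,
        )
    return _slice(0, n_train), _slice(n_train, reg.n_rows)


def fit_mimo_ar(reg: RegressorSet, bias: bool = False) -> MimoArModel:
    """Least-squares MIMO-AR fit via the Moore-Penrose pseudoinverse.

    Returns the minimum-norm solution of ``targets ~ z @ beta.T``; the
    optional bias appends a ones column (off by default, matching the
    bias-free model form).
    """
    if reg.n_rows < 1:
        raise ValueError("empty regressor set")
    z = reg.z
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(reg.targets)):
        raise ValueError("regressors and targets must be finite")
    if bias:
        z = np.hstack([z, np.ones((z.shape[0], 1))])
    beta = (np.linalg.pinv(z) @ reg.targets).T
    return MimoArModel(beta=beta, P=reg.P, tau=reg.tau, bias=bias)


def predict_mimo_ar(model: MimoArModel, z: np.ndarray) -> np.ndarray:
    """Forecast all horizons at once: rows x tau matrix ``z @ beta.T``."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    expected = model.beta.shape[1] - (1 if model.bias else 0)
    if z.shape[1] != expected:
        raise ValueError(
            f"regressor width {z.shape[1]} does not match model's 2P = {expected}"
        )
    if model.bias:
        z = np.hstack([z, np.ones((z.shape[0], 1))])
    return z @ model.beta.T


# ---------------------------------------------------------------------------
# MIMO-ANN: three-layer sigmoid MLP trained with Levenberg-Marquardt
# ---------------------------------------------------------------------------

def hidden_width(n_train: int) -> int:
    """Hidden layer size rule Q = round(log2(N_train))."""
    if n_train < 2:
        raise ValueError("need at least 2 training rows")
    return max(1, round(float(np.log2(n_train))))


def init_mlp(P: int, n_train: int, tau: int, seed: int, Q: int | None = None) -> MlpModel:
    """Seeded small symmetric-uniform weight initialization.

    Weights are drawn uniformly from +-0.5 scaled by 1/sqrt(fan-in), which
    keeps the hidden units in the near-linear region of the sigmoid at the
    start of training.
    """
    if Q is None:
        Q = hidden_width(n_train)
    rng = np.random.default_rng(seed)
    n_in = 2 * P
    w = rng.uniform(-0.5, 0.5, size=(n_in, Q)) / np.sqrt(n_in)
    b = rng.uniform(-0.5, 0.5, size=(Q, tau)) / np.sqrt(Q)
    return MlpModel(input_weights=w, output_weights=b, Q=Q)


def _forward(z: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = sigmoid(z @ w)
    return y, y @ b


def _lm_run(
    z: np.ndarray,
    targets: np.ndarray,
    w0: np.ndarray,
    b0: np.ndarray,
    epochs: int,
    damping0: float,
    damping_up: float,
    damping_down: float,
    damping_max: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Levenberg-Marquardt run; returns (w, b, accepted-step MSE curve).

    Full-batch Gauss-Newton with adaptive damping on the sum-of-squares
    error over all tau outputs: the analytic Jacobian of the residuals is
    rebuilt after every accepted step; a rejected step only re-solves the
    damped normal equations with a larger damping factor.
    """
    n_in, Q = w0.shape
    tau = b0.shape[1]
    rows = z.shape[0]
    w, b = w0.copy(), b0.copy()
    lam = damping0
    y, pred = _forward(z, w, b)
    resid = pred - targets
    sse = float(np.sum(resid**2))
    curve = [sse / resid.size]
    n_w = n_in * Q

    accepted = 0
    while accepted < epochs and sse > 1e-24:
        # Jacobian of residuals wrt (w, b), residual order = C-flatten (row, horizon)
        yd = y * (1.0 - y)
        # d resid[n,h] / d w[i,j] = b[j,h] * yd[n,j] * z[n,i]
        Jw = np.einsum("nj,jh,ni->nhij", yd, b, z).reshape(rows * tau, n_w)
        Jb = np.zeros((rows, tau, Q, tau))
        for h in range(tau):
            Jb[:, h, :, h] = y
        J = np.hstack([Jw, Jb.reshape(rows * tau, Q * tau)])
        r = resid.reshape(-1)
        JtJ = J.T @ J
        g = J.T @ r
        if not np.all(np.isfinite(JtJ)) or not np.all(np.isfinite(g)):
            logger.warning("non-finite quantities during LM training; aborting run")
            break

        stepped = False
        while lam <= damping_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= damping_up
                continue
            w_new = w + delta[:n_w].reshape(n_in, Q)
            b_new = b + delta[n_w:].reshape(Q, tau)
            y_new, pred_new = _forward(z, w_new, b_new)
            resid_new = pred_new - targets
            sse_new = float(np.sum(resid_new**2))
            if np.isfinite(sse_new) and sse_new <= sse:
                w, b, y, resid, sse = w_new, b_new, y_new, resid_new, sse_new
                lam = max(lam * damping_down, 1e-15)
                accepted += 1
                curve.append(sse / resid.size)
                stepped = True
                break
            lam *= damping_up
        if not stepped:  # damping exhausted: local minimum reached
            break
    return w, b, np.asarray(curve)


def train_mlp_lm(
    model: MlpModel,
    reg: RegressorSet,
    epochs: int = 500,
    runs: int = 10,
    seed: int = 0,
    standardize: bool = True,
    damping0: float = 1e-3,
    damping_up: float = 10.0,
    damping_down: float = 0.1,
    damping_max: float = 1e10,
) -> tuple[MlpModel, TrainingReport]:
    """Train the MLP with Levenberg-Marquardt over ``runs`` random restarts.

    Restart k re-initializes the weights with seed ``seed + k`` (keeping the
    given model's architecture); the model with the lowest final training
    MSE is returned together with the per-run accepted-step error curves
    (MSE in the original target units).
    Standardization (on by default) rescales the inputs per column and the
    targets per horizon with a single common scale, using training-set
    statistics only; this keeps the sigmoid layer out of saturation and the
    Gauss-Newton residuals O(1), and because the target scale is common the
    optimized objective stays proportional to the raw sum of squares.  The
    statistics travel with the model and are undone at prediction time; pass
    ``standardize=False`` for fully raw training.
    """
    if epochs < 1 or runs < 1:
        raise ValueError("epochs and runs must be >= 1")
    z = reg.z
    if standardize:
        mean = z.mean(axis=0)
        scale = z.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        zs = (z - mean) / scale
        t_mean = reg.targets.mean(axis=0)
        t_scale = float(reg.targets.std()) or 1.0
        targets = (reg.targets - t_mean) / t_scale
    else:
        mean = scale = t_mean = t_scale = None
        zs = z
        targets = reg.targets

    n_in = z.shape[1]
    unit = t_scale**2 if standardize else 1.0  # curve reported in raw units
    curves: list[np.ndarray] = []
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    best_run = 0
    for k in range(runs):
        fresh = init_mlp(n_in // 2, max(reg.n_rows, 2), reg.tau, seed + k, Q=model.Q)
        w, b, curve = _lm_run(
            zs, targets, fresh.input_weights, fresh.output_weights,
            epochs, damping0, damping_up, damping_down, damping_max,
        )
        curves.append(curve * unit)
        final = float(curve[-1] * unit)
        if best is None or final < best[0]:
            best = (final, w, b)
            best_run = k
    assert best is not None
    trained = MlpModel(
        input_weights=best[1], output_weights=best[2], Q=model.Q,
        input_mean=mean, input_scale=scale,
        target_mean=t_mean, target_scale=t_scale,
    )
    report = TrainingReport(
        run_errors=tuple(curves), best_run=best_run, final_mse=best[0]
    )
    return trained, report


def predict_mlp(model: MlpModel, z: np.ndarray) -> np.ndarray:
    """Deterministic forward pass x_hat = f(z W) B (rows x tau)."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    if z.shape[1] != model.input_weights.shape[0]:
        raise ValueError(
            f"regressor width {z.shape[1]} does not match model input "
            f"width {model.input_weights.shape[0]}"
        )
    if model.input_mean is not None:
        z = (z - model.input_mean) / model.input_scale
    _, pred = _forward(z, model.input_weights, model.output_weights)
    if model.target_mean is not None:
        pred = pred * model.target_scale + model.target_mean
    return pred
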