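"""Multi-output time-delay neural network linking microstate and BOLD series.

A single shared tanh hidden layer maps a tapped delay line of r input
series (the last tau TRs) to all o output series at once, so the network
learns one joint representation of the cross-modal relationship:

    z = act(W [x_{t-1}; ...; x_{t-tau}] + b),    y_t = W~ z + b~

Training minimizes mean squared error with an L2 weight penalty (a fixed
ridge standing in for Bayesian-regularized backpropagation), solved by
L-BFGS with analytic gradients; initialization is seeded, so training is
deterministic.  Hyperparameters (hidden units, delays) come from a grid
search on the first 30 TRs; generalization is measured by expanding-window
chronological cross-validation from 31 TRs, predicting 1 and 2 TRs ahead
(2-step predictions use a directly trained 2-step model, never the true
t+1 value).  Four experiments probe both directions: microstate dynamics
(AT+TS, r=20) -> 7-network BOLD, direct time courses (DT, r=4) -> BOLD,
and the two reverse mappings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "TDNNModel",
    "CVResult",
    "build_delay_matrix",
    "train_mtdnn",
    "predict",
    "grid_search",
    "expanding_window_cv",
    "run_four_experiments",
    "compare_experiments_wilcoxon",
]

NEURON_GRID = (5, 10, 20, 40)
DELAY_GRID = (1, 2, 3, 4, 5)
GRID_WINDOW = 30
CV_INITIAL = 31
DEFAULT_EPOCHS = 100
DEFAULT_REG = 1e-2
EXPERIMENTS = ("a", "b", "c", "d")


@dataclass
class TDNNModel:
    W: np.ndarray  # m x (r * tau)
    b: np.ndarray  # m
    W_out: np.ndarray  # o x m
    b_out: np.ndarray  # o
    n_hidden: int
    max_delay: int
    n_inputs: int
    n_outputs: int
    horizon: int = 1
    activation: str = "tanh"
    reg: float = DEFAULT_REG
    seed: int = 0
    epochs: int = DEFAULT_EPOCHS
    final_loss: float = float("nan")
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)


@dataclass
class CVResult:
    """Expanding-window CV outcome for one experiment on one subject."""

    experiment: str
    output_names: list[str]
    r_h1: np.ndarray  # per-output Pearson r, 1 TR ahead
    r_h2: np.ndarray  # per-output Pearson r, 2 TRs ahead
    n_test_h1: int
    n_test_h2: int
    n_skipped: int = 0
    n_hidden: int = 0
    max_delay: int = 0

    def mean_r(self, horizon: int) -> float:
        r = self.r_h1 if horizon == 1 else self.r_h2
        return float(np.nanmean(r))


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------

def build_delay_matrix(
    inputs: np.ndarray, max_delay: int, horizon: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Tapped delay line: rows stack x_{t-h}, ..., x_{t-h-tau+1} per target t.

    ``inputs`` is time x r (a single series may be 1-D).  Returns
    ``(X, target_idx)`` where row q of X predicts time ``target_idx[q]``
    using only samples at least ``horizon`` steps in the past — no
    current-time leakage.
    """
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, r = x.shape
    if max_delay < 1:
        raise ValueError("max_delay must be >= 1")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    first = max_delay + horizon - 1  # earliest predictable target index
    if n < first + 2:
        raise ValueError(
            f"series of length {n} too short for max_delay={max_delay}, horizon={horizon}"
        )
    targets = np.arange(first, n)
    lag_blocks = [x[targets - horizon - q] for q in range(max_delay)]
    return np.hstack(lag_blocks), targets


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward(params, shapes, X, activation):
    W, b, W_out, b_out = _unpack(params, shapes)
    pre = X @ W.T + b
    Z = np.tanh(pre) if activation == "tanh" else pre
    return Z @ W_out.T + b_out, Z, pre


def _unpack(params, shapes):
    (m, d), (o, _) = shapes
    i = 0
    W = params[i : i + m * d].reshape(m, d); i += m * d
    b = params[i : i + m]; i += m
    W_out = params[i : i + o * m].reshape(o, m); i += o * m
    b_out = params[i : i + o]
    return W, b, W_out, b_out


def _loss_grad(params, shapes, X, Y, reg, activation, use_bias):
    W, b, W_out, b_out = _unpack(params, shapes)
    n = X.shape[0]
    pre = X @ W.T + b
    Z = np.tanh(pre) if activation == "tanh" else pre
    Yhat = Z @ W_out.T + b_out
    err = Yhat - Y
    loss = 0.5 * np.mean(err**2) + 0.5 * reg * (np.sum(W**2) + np.sum(W_out**2))
    scale = 1.0 / (n * Y.shape[1])
    gY = err * scale
    gW_out = gY.T @ Z + reg * W_out
    gb_out = gY.sum(axis=0) if use_bias else np.zeros_like(b_out)
    gZ = gY @ W_out
    gpre = gZ * (1.0 - Z**2) if activation == "tanh" else gZ
    gW = gpre.T @ X + reg * W
    gb = gpre.sum(axis=0) if use_bias else np.zeros_like(b)
    grad = np.concatenate([gW.ravel(), gb, gW_out.ravel(), gb_out])
    return loss, grad


def train_mtdnn(
    X: np.ndarray,
    Y: np.ndarray,
    n_hidden: int,
    reg: float = DEFAULT_REG,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    activation: str = "tanh",
    bias: bool = True,
    horizon: int = 1,
    input_names: list[str] | None = None,
    output_names: list[str] | None = None,
) -> TDNNModel:
    """Fit the shared-hidden-layer network by L-BFGS on MSE + L2.

    ``epochs`` bounds the number of full-batch optimizer iterations.
    Deterministic given ``seed`` (seeded initialization, deterministic
    optimizer).  Targets may be 1-D (single output).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in training data")
    m, d, o = n_hidden, X.shape[1], Y.shape[1]
    rng = np.random.default_rng(seed)
    w0 = np.concatenate(
        [
            rng.normal(0.0, 1.0 / np.sqrt(d), size=m * d),
            np.zeros(m),
            rng.normal(0.0, 1.0 / np.sqrt(m), size=o * m),
            np.zeros(o),
        ]
    )
    shapes = ((m, d), (o, m))
    res = scipy.optimize.minimize(
        _loss_grad,
        w0,
        args=(shapes, X, Y, reg, activation, bias),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": epochs, "maxls": 50},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"training diverged: loss={res.fun!r}, message={res.message}")
    W, b, W_out, b_out = _unpack(res.x, shapes)
    return TDNNModel(
        W=W, b=b, W_out=W_out, b_out=b_out,
        n_hidden=m, max_delay=d, n_inputs=d, n_outputs=o,
        horizon=horizon, activation=activation, reg=reg, seed=seed, epochs=epochs,
        final_loss=float(res.fun),
        input_names=list(input_names or []), output_names=list(output_names or []),
    )


def predict(model: TDNNModel, X: np.ndarray, horizon: int | None = None) -> np.ndarray:
    """Forward pass on delay-matrix rows.

    When ``horizon`` is given it must match the horizon the model was
    trained for (2-step predictions come from a directly trained 2-step
    model, not from recursing on 1-step output).
    """
    if horizon is not None:
        if horizon not in (1, 2):
            raise ValueError("horizon must be 1 or 2")
        if horizon != model.horizon:
            raise ValueError(
                f"model was trained for horizon {model.horizon}, not {horizon}"
            )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out, _, _ = _forward(
        np.concatenate([model.W.ravel(), model.b, model.W_out.ravel(), model.b_out]),
        ((model.n_hidden, model.W.shape[1]), (model.n_outputs, model.n_hidden)),
        X,
        model.activation,
    )
    return out


# ---------------------------------------------------------------------------
# model selection and cross-validation
# ---------------------------------------------------------------------------

def _pearson_per_output(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    out = np.full(true.shape[1], np.nan)
    for j in range(true.shape[1]):
        if true[:, j].std() > 0 and pred[:, j].std() > 0:
            out[j] = np.corrcoef(true[:, j], pred[:, j])[0, 1]
    return out


def grid_search(
    inputs: np.ndarray,
    outputs: np.ndarray,
    neuron_grid=NEURON_GRID,
    delay_grid=DELAY_GRID,
    window: int = GRID_WINDOW,
    reg: float = DEFAULT_REG,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
) -> tuple[int, int]:
    """Pick (hidden units, delays) on the first ``window`` TRs.

    Each grid cell is fit on a chronological 80/20 split of the window and
    scored by the average Pearson correlation between true and predicted
    outputs on the held-out 20%.  Degenerate grids (no finite score) fall
    back to the smallest cell with a warning.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float).T).T
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float).T).T
    if inputs.shape[0] < window:
        raise ValueError(f"need at least {window} TRs for the grid search")
    xin, yout = inputs[:window], outputs[:window]
    best, best_score = None, -np.inf
    for m in neuron_grid:
        for tau in delay_grid:
            try:
                X, targets = build_delay_matrix(xin, tau)
            except ValueError:
                continue
            Y = yout[targets]
            split = int(round(0.8 * X.shape[0]))
            if split < 2 or X.shape[0] - split < 2:
                continue
            model = train_mtdnn(
                X[:split], Y[:split], m, reg=reg, seed=seed, epochs=epochs
            )
            r = _pearson_per_output(Y[split:], predict(model, X[split:]))
            score = np.nanmean(r)
            if np.isfinite(score) and score > best_score:
                best, best_score = (m, tau), score
    if best is None:
        warnings.warn("grid search degenerate; falling back to smallest architecture")
        best = (neuron_grid[0], delay_grid[0])
    return best


def expanding_window_cv(
    inputs: np.ndarray,
    outputs: np.ndarray,
    n_hidden: int,
    max_delay: int,
    initial: int = CV_INITIAL,
    reg: float = DEFAULT_REG,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    censor: np.ndarray | None = None,
    experiment: str = "",
    output_names: list[str] | None = None,
) -> CVResult:
    """Expanding-window chronological CV with 1- and 2-TR-ahead horizons.

    Fold k trains on TRs 1..k (1-based) and tests the prediction of TR k+1
    (horizon 1) and TR k+2 (horizon 2, from a directly trained 2-step
    model); k runs from ``initial`` until the last TR has been tested.
    Per-output Pearson r is pooled over all test points, separately per
    horizon.  Censored test TRs are skipped and counted.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float).T).T
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float).T).T
    n = inputs.shape[0]
    if n < initial + 3:
        raise ValueError(f"need at least initial+3={initial + 3} TRs, got {n}")
    if censor is None:
        censor = np.zeros(n, dtype=bool)

    collected: dict[int, tuple[list[np.ndarray], list[np.ndarray]]] = {
        1: ([], []),
        2: ([], []),
    }
    n_skipped = 0
    designs = {h: build_delay_matrix(inputs, max_delay, horizon=h) for h in (1, 2)}
    for k in range(initial, n - 1):  # k = training length; 0-based test idx = k, k+1
        for h in (1, 2):
            test_idx = k + h - 1
            if test_idx >= n:
                continue
            if censor[test_idx]:
                n_skipped += 1
                continue
            X_all, targets = designs[h]
            train_rows = (targets <= k - 1) & ~censor[targets]
            test_rows = targets == test_idx
            if train_rows.sum() < 3 or not test_rows.any():
                continue
            model = train_mtdnn(
                X_all[train_rows],
                outputs[targets[train_rows]],
                n_hidden,
                reg=reg,
                seed=seed,
                epochs=epochs,
                horizon=h,
            )
            pred = predict(model, X_all[test_rows], horizon=h)
            collected[h][0].append(outputs[test_idx])
            collected[h][1].append(pred[0])

    r = {}
    counts = {}
    for h in (1, 2):
        true_list, pred_list = collected[h]
        counts[h] = len(true_list)
        if len(true_list) >= 3:
            r[h] = _pearson_per_output(np.array(true_list), np.array(pred_list))
        else:
            r[h] = np.full(outputs.shape[1], np.nan)
    return CVResult(
        experiment=experiment,
        output_names=list(output_names or [f"y{j}" for j in range(outputs.shape[1])]),
        r_h1=r[1],
        r_h2=r[2],
        n_test_h1=counts[1],
        n_test_h2=counts[2],
        n_skipped=n_skipped,
        n_hidden=n_hidden,
        max_delay=max_delay,
    )


def run_four_experiments(
    dt_regs: np.ndarray,
    dyn_regs: np.ndarray,
    bold: np.ndarray,
    neuron_grid=NEURON_GRID,
    delay_grid=DELAY_GRID,
    grid_window: int = GRID_WINDOW,
    initial: int = CV_INITIAL,
    reg: float = DEFAULT_REG,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    censor: np.ndarray | None = None,
) -> dict[str, CVResult]:
    """The four bidirectional prediction experiments for one subject.

    (a) microstate dynamics (AT+TS, r=20) -> BOLD (o=7);
    (b) direct time courses (DT, r=4) -> BOLD (o=7);
    (c) BOLD (r=7) -> microstate dynamics (o=20);
    (d) BOLD (r=7) -> direct time courses (o=4).
    An independent grid search runs per experiment.
    """
    dt_regs = np.atleast_2d(np.asarray(dt_regs, dtype=float).T).T
    dyn_regs = np.atleast_2d(np.asarray(dyn_regs, dtype=float).T).T
    bold = np.atleast_2d(np.asarray(bold, dtype=float).T).T
    n = bold.shape[0]
    if dt_regs.shape[0] != n or dyn_regs.shape[0] != n:
        raise ValueError("all series must share the number of TRs")
    wiring = {
        "a": (dyn_regs, bold),
        "b": (dt_regs, bold),
        "c": (bold, dyn_regs),
        "d": (bold, dt_regs),
    }
    results: dict[str, CVResult] = {}
    for exp, (xin, yout) in wiring.items():
        m, tau = grid_search(
            xin, yout, neuron_grid, delay_grid, grid_window, reg, seed, epochs
        )
        results[exp] = expanding_window_cv(
            xin, yout, m, tau,
            initial=initial, reg=reg, seed=seed, epochs=epochs,
            censor=censor, experiment=exp,
        )
    return results


def compare_experiments_wilcoxon(
    per_subject_a: np.ndarray, per_subject_b: np.ndarray
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on per-subject mean correlations."""
    stat, p = scipy.stats.wilcoxon(per_subject_a, per_subject_b)
    return float(stat), float(p)
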