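"""Network-based nMVAR estimation of linear and nonlinear directed connectivity.

The predictor is the nonlinear multivariate autoregressive model
``x(n) = f(x_p) + sigma(n)`` where ``x_p`` stacks the p past samples of all M
channels.  ``f`` is fit by a one-hidden-layer tanh perceptron trained with
incremental (per-sample) backpropagation with momentum, adaptive learning
rate, early stopping and 10-fold permuted cross-validation.  ``f`` is then
split as ``f = f_lin + f_nonlin``: the linear part is the first-order Taylor
expansion of the network at the origin, and per-edge connectivity is read off
the Jacobian,

    LC[i->j] = (1/p) sum_k | J0[j, (i,k)] |
    NC[i->j] = mean_x (1/p) sum_k | J(x)[j, (i,k)] - J0[j, (i,k)] |

so an input-independent sensitivity is linear transfer and any
input-dependent deviation is nonlinear transfer.  Significance comes from
time-shifted surrogates that destroy cross-channel alignment while preserving
each channel's dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._train import _forward_mse, train_network
from .core import EpochedSignal

__all__ = [
    "RegressorSet",
    "NCREANNConfig",
    "NCREANNModel",
    "ConnectivityResult",
    "OrderSelection",
    "select_model_order",
    "build_regressors",
    "fit_ncreann",
    "predict",
    "decompose_connectivity",
    "time_shift_surrogates",
    "surrogate_significance",
    "estimate_connectivity",
]


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

@dataclass
class RegressorSet:
    """Stacked-past design matrix and current-sample targets.

    ``X`` columns are ordered lag-major, channel-minor:
    [x_1(n-1), ..., x_M(n-1), x_1(n-2), ..., x_M(n-p)], i.e. column
    ``(k-1)*M + i`` holds channel i at lag k.  Rows never span a trial
    boundary.  Channels are standardized by moments computed over all
    included samples; the moments are kept for mapping back.
    """

    X: np.ndarray  # rows x (M*p)
    Y: np.ndarray  # rows x M
    n_channels: int
    order: int
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column(self, channel: int, lag: int) -> int:
        """Design-matrix column of ``channel`` (0-based) at ``lag`` (1..p)."""
        return (lag - 1) * self.n_channels + channel


def _as_trial_list(data, window_ms=None) -> list[np.ndarray]:
    if isinstance(data, EpochedSignal):
        if window_ms is not None:
            data = data.window(*window_ms)
        return [data.data[t] for t in range(data.n_trials)]
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        return [arr]
    return [arr[t] for t in range(arr.shape[0])]


def build_regressors(
    data,
    order: int = 10,
    window_ms: tuple[float, float] | None = (0.0, 1000.0),
    standardize: bool = True,
) -> RegressorSet:
    """Assemble the lagged design matrix from epochs or a raw series.

    ``data`` is an :class:`EpochedSignal` (the ``window_ms`` interval of each
    trial is used), a 2-D (channels x samples) array, or a 3-D
    (trials x channels x samples) array.  Each trial of T samples contributes
    T - p rows; the first p samples serve only as history.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    trials = _as_trial_list(data, window_ms)
    m = trials[0].shape[0]
    if any(t.shape[0] != m for t in trials):
        raise ValueError("inconsistent channel counts across trials")
    if any(t.shape[1] <= order for t in trials):
        raise ValueError(f"every trial needs more than order={order} samples")

    concat = np.concatenate(trials, axis=1)
    if standardize:
        mean = concat.mean(axis=1)
        sd = concat.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("constant channel cannot be standardized")
    else:
        mean = np.zeros(m)
        sd = np.ones(m)

    xs, ys = [], []
    for trial in trials:
        z = (trial - mean[:, None]) / sd[:, None]
        T = z.shape[1]
        # row n predicts z[:, n] from lags 1..p; lag-major column order
        cols = [z[:, order - k : T - k].T for k in range(1, order + 1)]
        xs.append(np.concatenate(cols, axis=1))
        ys.append(z[:, order:].T)
    return RegressorSet(
        X=np.ascontiguousarray(np.concatenate(xs, axis=0)),
        Y=np.ascontiguousarray(np.concatenate(ys, axis=0)),
        n_channels=m,
        order=order,
        mean=mean,
        sd=sd,
    )


# ---------------------------------------------------------------------------
# model order selection (linear MVAR + information criteria)
# ---------------------------------------------------------------------------

@dataclass
class OrderSelection:
    order: int  # AIC argmin
    order_bic: int
    table: pd.DataFrame


def select_model_order(series: np.ndarray, p_max: int) -> OrderSelection:
    """Score linear MVAR fits for p = 1..p_max by AIC and Schwartz (BIC).

    Least-squares fits share the same effective sample span (rows start at
    p_max) so criterion values are comparable across orders.  Criteria use
    the log-determinant of the residual covariance with parameter counts
    p*M^2 per order.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    series = np.asarray(series, dtype=float)
    m, L = series.shape
    n_eff = L - p_max
    if n_eff < p_max * m + 1:
        raise ValueError("series too short for requested p_max")
    rows = []
    for p in range(1, p_max + 1):
        cols = [series[:, p_max - k : L - k].T for k in range(1, p + 1)]
        X = np.concatenate(cols, axis=1)
        Y = series[:, p_max:].T
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k_params = p * m * m
        rows.append(
            {
                "p": p,
                "logdet": logdet,
                "aic": n_eff * logdet + 2.0 * k_params,
                "bic": n_eff * logdet + np.log(n_eff) * k_params,
            }
        )
    if not rows:
        raise ValueError("no model order could be scored")
    table = pd.DataFrame(rows)
    return OrderSelection(
        order=int(table.loc[table.aic.idxmin(), "p"]),
        order_bic=int(table.loc[table.bic.idxmin(), "p"]),
        table=table,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class NCREANNConfig:
    """Training hyperparameters for the nMVAR network.

    Splits are 80/10/10 after a fresh random row permutation per fold.  The
    learning rate multiplies by ``lr_up`` after an epoch that reduced the
    training error (capped at ``lr_max``, which bounds the steady-state SGD
    weight noise) and by ``lr_down`` (with the epoch rejected) after an
    increase beyond ``max_perf_inc``; weights update per presented sample
    with momentum.  The final model is one further early-stopped fit on a
    fresh split, the same protocol as every fold.
    """

    hidden: int = 10
    folds: int = 10
    momentum: float = 0.9
    learning_rate: float = 0.005
    lr_max: float = 0.02
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_perf_inc: float = 1.04
    patience: int = 30
    max_epochs: int = 1000
    init_range: float = 0.5
    eval_rows: int = 2000
    seed: int = 0


@dataclass
class NCREANNModel:
    config: NCREANNConfig
    n_channels: int
    order: int
    Wh: np.ndarray
    bh: np.ndarray
    Wo: np.ndarray
    bo: np.ndarray
    stop_epoch: int
    fold_metrics: pd.DataFrame
    residuals: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def summary(self) -> dict[str, float]:
        fm = self.fold_metrics
        return {
            "mse_train_mean": float(fm.mse_train.mean()),
            "mse_train_sd": float(fm.mse_train.std(ddof=1)) if len(fm) > 1 else 0.0,
            "mse_test_mean": float(fm.mse_test.mean()),
            "mse_test_sd": float(fm.mse_test.std(ddof=1)) if len(fm) > 1 else 0.0,
            "r2_train_mean": float(fm.r2_train.mean()),
            "r2_train_sd": float(fm.r2_train.std(ddof=1)) if len(fm) > 1 else 0.0,
            "r2_test_mean": float(fm.r2_test.mean()),
            "r2_test_sd": float(fm.r2_test.std(ddof=1)) if len(fm) > 1 else 0.0,
        }


def _mlp_forward(Wh, bh, Wo, bo, X):
    return np.tanh(X @ Wh.T + bh) @ Wo.T + bo


def predict(model: NCREANNModel, X: np.ndarray) -> np.ndarray:
    return _mlp_forward(model.Wh, model.bh, model.Wo, model.bo, X)


def _r2_channels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Per-channel 1 - SSE/SST, averaged over channels."""
    sse = ((y_true - y_pred) ** 2).sum(axis=0)
    sst = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    sst = np.where(sst == 0, np.nan, sst)
    return float(np.nanmean(1.0 - sse / sst))


def _init_weights(rng, hidden, dim_in, dim_out, init_range):
    Wh = rng.uniform(-init_range, init_range, size=(hidden, dim_in))
    bh = rng.uniform(-init_range, init_range, size=hidden)
    Wo = rng.uniform(-init_range, init_range, size=(dim_out, hidden))
    bo = rng.uniform(-init_range, init_range, size=dim_out)
    return Wh, bh, Wo, bo


def _train_once(X, Y, cfg, rng, train_idx, val_idx, early_stop, max_epochs):
    """One training run with the divergence-restart policy; returns weights+epoch."""
    lr = cfg.learning_rate
    for attempt in range(2):
        Wh, bh, Wo, bo = _init_weights(
            rng, cfg.hidden, X.shape[1], Y.shape[1], cfg.init_range
        )
        shuffle_seed = int(rng.integers(2**31 - 1))
        stop_epoch, best_val, train_mse = train_network(
            X, Y, Wh, bh, Wo, bo,
            train_idx, val_idx,
            lr, cfg.lr_max, cfg.momentum, cfg.lr_up, cfg.lr_down,
            cfg.max_perf_inc, max_epochs, cfg.patience, shuffle_seed, early_stop,
        )
        if np.isfinite(train_mse) and np.all(np.isfinite(Wh)):
            return Wh, bh, Wo, bo, stop_epoch
        lr /= 10.0
    raise RuntimeError("training diverged twice; inputs may be unscaled")


def fit_ncreann(regressors: RegressorSet, config: NCREANNConfig | None = None) -> NCREANNModel:
    """Cross-validated training of the nMVAR network.

    Each fold permutes the rows, splits 80/10/10 into train/validation/test,
    trains with early stopping on the validation split and scores MSE and
    per-channel R^2 on train and test.  The returned model comes from one
    further early-stopped fit on a fresh permuted split — the identical
    protocol as the folds — so connectivity read off the final model is
    statistically exchangeable with surrogate fits under the null.
    """
    cfg = config or NCREANNConfig()
    X, Y = regressors.X, regressors.Y
    n = X.shape[0]
    n_params = cfg.hidden * (X.shape[1] + 1) + Y.shape[1] * (cfg.hidden + 1)
    if n < 10 * n_params:
        import warnings

        warnings.warn(
            f"{n} rows < 10 x {n_params} parameters; fit may not generalize"
        )
    rng = np.random.default_rng(cfg.seed)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    if min(n_train, n_val, n - n_train - n_val) < 1:
        raise ValueError("too few rows for an 80/10/10 split")

    records = []
    stop_epochs = []
    for fold in range(cfg.folds):
        perm = rng.permutation(n)
        tr = np.ascontiguousarray(perm[:n_train])
        va = np.ascontiguousarray(perm[n_train : n_train + n_val])
        te = np.ascontiguousarray(perm[n_train + n_val :])
        Wh, bh, Wo, bo, stop_epoch = _train_once(
            X, Y, cfg, rng, tr, va, True, cfg.max_epochs
        )
        stop_epochs.append(max(stop_epoch, 1))
        pred_tr = _mlp_forward(Wh, bh, Wo, bo, X[tr])
        pred_te = _mlp_forward(Wh, bh, Wo, bo, X[te])
        records.append(
            {
                "fold": fold,
                "stop_epoch": stop_epoch,
                "mse_train": float(np.mean((pred_tr - Y[tr]) ** 2)),
                "mse_test": float(np.mean((pred_te - Y[te]) ** 2)),
                "r2_train": _r2_channels(Y[tr], pred_tr),
                "r2_test": _r2_channels(Y[te], pred_te),
            }
        )

    # Final model: one more early-stopped fit on a fresh permuted split, the
    # same protocol as every fold (and every surrogate fit).  Keeping the
    # training protocol identical makes observed and surrogate connectivity
    # exchangeable under the null, which the surrogate rank test requires.
    perm = rng.permutation(n)
    tr = np.ascontiguousarray(perm[:n_train])
    va = np.ascontiguousarray(perm[n_train : n_train + n_val])
    Wh, bh, Wo, bo, final_epochs = _train_once(
        X, Y, cfg, rng, tr, va, True, cfg.max_epochs
    )
    resid = Y - _mlp_forward(Wh, bh, Wo, bo, X)
    return NCREANNModel(
        config=cfg,
        n_channels=regressors.n_channels,
        order=regressors.order,
        Wh=Wh, bh=bh, Wo=Wo, bo=bo,
        stop_epoch=final_epochs,
        fold_metrics=pd.DataFrame(records),
        residuals=resid,
        mean=regressors.mean,
        sd=regressors.sd,
    )


# ---------------------------------------------------------------------------
# LC / NC decomposition
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityResult:
    """M x M linear (LC) and nonlinear (NC) connectivity with surrogate stats.

    Entry [j, i] is the influence of source i on target j.  Diagonals hold
    self-dynamics and are excluded from significance masks and network
    strength by default.
    """

    lc: np.ndarray
    nc: np.ndarray
    surrogate_lc: np.ndarray | None = None  # n_surrogates x M x M
    surrogate_nc: np.ndarray | None = None
    p_lc: np.ndarray | None = None
    p_nc: np.ndarray | None = None
    sig_lc: np.ndarray | None = None
    sig_nc: np.ndarray | None = None
    alpha: float = 0.05
    node_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.lc.shape[0]

    def edge(self, kind: str, source: int, target: int) -> float:
        mat = self.lc if kind == "lc" else self.nc
        return float(mat[target, source])

    def to_frame(self, band: str = "", condition: str = "") -> pd.DataFrame:
        """Long-format table: one row per directed off-diagonal edge."""
        names = self.node_names or [f"node{i}" for i in range(self.n_nodes)]
        rows = []
        for j in range(self.n_nodes):
            for i in range(self.n_nodes):
                if i == j:
                    continue
                rows.append(
                    {
                        "source": names[i],
                        "target": names[j],
                        "band": band,
                        "condition": condition,
                        "lc": float(self.lc[j, i]),
                        "nc": float(self.nc[j, i]),
                        "p_lc": float(self.p_lc[j, i]) if self.p_lc is not None else np.nan,
                        "p_nc": float(self.p_nc[j, i]) if self.p_nc is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _jacobian_origin(model: NCREANNModel) -> np.ndarray:
    """Network Jacobian at the origin: Wo diag(1 - tanh^2(bh)) Wh."""
    gain = 1.0 - np.tanh(model.bh) ** 2
    return model.Wo @ (gain[:, None] * model.Wh)


def jacobian(model: NCREANNModel, X: np.ndarray) -> np.ndarray:
    """Per-row network Jacobians d f / d x_p, shape (rows, M, M*p)."""
    act = np.tanh(X @ model.Wh.T + model.bh)  # rows x H
    gain = 1.0 - act**2
    return np.einsum("jh,nh,hd->njd", model.Wo, gain, model.Wh)


def decompose_connectivity(
    model: NCREANNModel,
    regressors: RegressorSet,
    eval_rows: int | None = None,
    seed: int | None = None,
) -> ConnectivityResult:
    """Split the fitted predictor into linear and nonlinear connectivity.

    LC averages the absolute origin-Jacobian over lags per (source, target);
    NC averages — over lags and a fixed subsample of training rows — the
    absolute deviation of the local Jacobian from the origin Jacobian.  A
    linear map has zero deviation everywhere, so NC isolates curvature.
    """
    if not np.all(np.isfinite(model.Wh)):
        raise ValueError("model is untrained or diverged")
    m, p = model.n_channels, model.order
    if regressors.n_channels != m or regressors.order != p:
        raise ValueError("regressors do not match the model's shape")
    n_eval = eval_rows if eval_rows is not None else model.config.eval_rows
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    if regressors.n_rows > n_eval:
        idx = np.sort(rng.choice(regressors.n_rows, size=n_eval, replace=False))
    else:
        idx = np.arange(regressors.n_rows)

    j0 = _jacobian_origin(model)  # M x (M*p)
    jx = jacobian(model, regressors.X[idx])  # rows x M x (M*p)
    # reshape lag-major columns to (..., p, M) and average absolute values over lags
    lc = np.abs(j0.reshape(m, p, m)).mean(axis=1)
    dev = np.abs(jx - j0[None]).mean(axis=0)
    nc = dev.reshape(m, p, m).mean(axis=1)
    return ConnectivityResult(lc=lc, nc=nc)


# ---------------------------------------------------------------------------
# surrogates and significance
# ---------------------------------------------------------------------------

def time_shift_surrogates(
    series: np.ndarray,
    n_surrogates: int = 100,
    min_shift_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Circularly shift each channel by an independent random offset.

    Offsets are uniform on [min_shift*L, (1-min_shift)*L], drawn per channel
    and surrogate, so per-channel marginals and autocorrelation are preserved
    exactly while cross-channel temporal alignment is destroyed.
    """
    series = np.asarray(series, dtype=float)
    m, L = series.shape
    lo = int(np.ceil(min_shift_fraction * L))
    hi = int(np.floor((1.0 - min_shift_fraction) * L))
    if hi < lo:
        raise ValueError(f"series of length {L} too short for min shift {min_shift_fraction}")
    rng = np.random.default_rng(seed)
    out = np.empty((n_surrogates, m, L))
    for s in range(n_surrogates):
        for c in range(m):
            out[s, c] = np.roll(series[c], int(rng.integers(lo, hi + 1)))
    return out


def surrogate_significance(
    observed: ConnectivityResult,
    surrogate_lc: np.ndarray,
    surrogate_nc: np.ndarray,
    alpha: float = 0.05,
) -> ConnectivityResult:
    """One-sided empirical p-values with the +1 rank correction.

    p[j,i] = (1 + #{surrogate >= observed}) / (1 + n_surrogates); an edge is
    significant when p < alpha.  Self-connections are excluded from masks.
    """
    if surrogate_lc is None or len(surrogate_lc) == 0:
        raise ValueError("surrogate results are required")
    n_surr = surrogate_lc.shape[0]
    p_lc = (1.0 + (surrogate_lc >= observed.lc[None]).sum(axis=0)) / (1.0 + n_surr)
    p_nc = (1.0 + (surrogate_nc >= observed.nc[None]).sum(axis=0)) / (1.0 + n_surr)
    off = ~np.eye(observed.n_nodes, dtype=bool)
    return replace(
        observed,
        surrogate_lc=surrogate_lc,
        surrogate_nc=surrogate_nc,
        p_lc=p_lc,
        p_nc=p_nc,
        sig_lc=(p_lc < alpha) & off,
        sig_nc=(p_nc < alpha) & off,
        alpha=alpha,
    )


def _concat_trials(data, window_ms):
    trials = _as_trial_list(data, window_ms)
    lengths = [t.shape[1] for t in trials]
    return np.concatenate(trials, axis=1), lengths


def _split_trials(series, lengths):
    out, pos = [], 0
    for L in lengths:
        out.append(series[:, pos : pos + L])
        pos += L
    return np.stack(out) if len(out) > 1 else out[0]


def estimate_connectivity(
    data,
    order: int = 10,
    config: NCREANNConfig | None = None,
    window_ms: tuple[float, float] | None = (0.0, 1000.0),
    n_surrogates: int = 100,
    min_shift_fraction: float = 0.1,
    alpha: float = 0.05,
    seed: int | None = None,
    node_names: list[str] | None = None,
) -> ConnectivityResult:
    """End-to-end connectivity estimation with surrogate significance.

    The observed fit uses the full cross-validation protocol from ``config``.
    Surrogates circularly shift each channel in the concatenated-trial index
    space (preserving within-trial dynamics seen by the model order), and are
    fit with the same architecture and training protocol on a single 80/10/10
    split each, since only their connectivity values enter the null
    distribution.
    """
    cfg = config or NCREANNConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    series, lengths = _concat_trials(data, window_ms)

    reg = build_regressors(_split_trials(series, lengths), order=order, window_ms=None)
    model = fit_ncreann(reg, cfg)
    observed = decompose_connectivity(model, reg)
    observed.node_names = list(node_names or [])

    surr = time_shift_surrogates(
        series, n_surrogates, min_shift_fraction, seed=cfg.seed + 7_001
    )
    surr_cfg = replace(cfg, folds=1)
    s_lc = np.empty((n_surrogates,) + observed.lc.shape)
    s_nc = np.empty_like(s_lc)
    for s in range(n_surrogates):
        reg_s = build_regressors(
            _split_trials(surr[s], lengths), order=order, window_ms=None
        )
        model_s = fit_ncreann(reg_s, replace(surr_cfg, seed=cfg.seed + 13_000 + s))
        res_s = decompose_connectivity(model_s, reg_s)
        s_lc[s], s_nc[s] = res_s.lc, res_s.nc

    result = surrogate_significance(observed, s_lc, s_nc, alpha=alpha)
    result._model = model  # attached for reporting; not part of the dataclass
    return result
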