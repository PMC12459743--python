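"""Numba kernels for per-sample (incremental) MLP training.

The predictor is a single hidden tanh layer: y = Wo tanh(Wh x + bh) + bo.
Weights are updated after every presented sample with a momentum term; the
learning rate adapts at epoch granularity (grown after an epoch that lowered
the training error, shrunk — with the epoch's step rejected — after an epoch
that raised it beyond a small tolerance).  Early stopping monitors a held-out
validation split.  All loops are compiled; the Python layer only prepares
index splits and initial weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _forward_mse(X, Y, Wh, bh, Wo, bo, idx):
    """Mean squared error over rows ``idx`` (mean over rows and channels)."""
    n = idx.shape[0]
    m = Wo.shape[0]
    total = 0.0
    for r in range(n):
        x = X[idx[r]]
        h = np.tanh(Wh @ x + bh)
        y = Wo @ h + bo
        for j in range(m):
            d = y[j] - Y[idx[r], j]
            total += d * d
    return total / (n * m)


@njit(cache=True)
def _one_epoch(X, Y, Wh, bh, Wo, bo, vWh, vbh, vWo, vbo, order, lr, momentum):
    """One incremental pass over ``order``; weights and velocities mutate."""
    H = Wh.shape[0]
    D = Wh.shape[1]
    M = Wo.shape[0]
    for r in range(order.shape[0]):
        x = X[order[r]]
        a = Wh @ x + bh
        h = np.tanh(a)
        y = Wo @ h + bo
        e = y - Y[order[r]]
        # output layer
        for j in range(M):
            ej = e[j]
            vbo[j] = momentum * vbo[j] - lr * ej
            bo[j] += vbo[j]
            for k in range(H):
                vWo[j, k] = momentum * vWo[j, k] - lr * ej * h[k]
                Wo[j, k] += vWo[j, k]
        # hidden layer
        for k in range(H):
            back = 0.0
            for j in range(M):
                back += Wo[j, k] * e[j]
            dk = back * (1.0 - h[k] * h[k])
            vbh[k] = momentum * vbh[k] - lr * dk
            bh[k] += vbh[k]
            for d in range(D):
                vWh[k, d] = momentum * vWh[k, d] - lr * dk * x[d]
                Wh[k, d] += vWh[k, d]


@njit(cache=True)
def train_network(
    X,
    Y,
    Wh,
    bh,
    Wo,
    bo,
    train_idx,
    val_idx,
    lr0,
    lr_max,
    momentum,
    lr_up,
    lr_down,
    max_perf_inc,
    max_epochs,
    patience,
    shuffle_seed,
    use_early_stop,
):
    """Train in place; returns (stop_epoch, best_val_mse, train_mse_at_best).

    With ``use_early_stop`` the weights left in the arrays are those of the
    best-validation epoch; otherwise training runs exactly ``max_epochs``
    accepted-or-rejected epochs and leaves the final weights.
    """
    np.random.seed(shuffle_seed)
    vWh = np.zeros_like(Wh)
    vbh = np.zeros_like(bh)
    vWo = np.zeros_like(Wo)
    vbo = np.zeros_like(bo)

    best_Wh = Wh.copy()
    best_bh = bh.copy()
    best_Wo = Wo.copy()
    best_bo = bo.copy()

    lr = lr0
    prev_train = _forward_mse(X, Y, Wh, bh, Wo, bo, train_idx)
    best_val = np.inf
    best_epoch = 0
    train_at_best = prev_train
    since_best = 0

    for epoch in range(1, max_epochs + 1):
        snap_Wh = Wh.copy()
        snap_bh = bh.copy()
        snap_Wo = Wo.copy()
        snap_bo = bo.copy()

        order = train_idx[np.random.permutation(train_idx.shape[0])]
        _one_epoch(X, Y, Wh, bh, Wo, bo, vWh, vbh, vWo, vbo, order, lr, momentum)
        train_mse = _forward_mse(X, Y, Wh, bh, Wo, bo, train_idx)

        if not np.isfinite(train_mse) or train_mse > prev_train * max_perf_inc:
            # reject the step, cool down
            Wh[:, :] = snap_Wh
            bh[:] = snap_bh
            Wo[:, :] = snap_Wo
            bo[:] = snap_bo
            vWh[:, :] = 0.0
            vbh[:] = 0.0
            vWo[:, :] = 0.0
            vbo[:] = 0.0
            lr *= lr_down
            if lr < 1e-12:
                break
            if use_early_stop:
                since_best += 1
                if since_best > patience:
                    break
            continue
        if train_mse < prev_train:
            lr = min(lr * lr_up, lr_max)
        prev_train = train_mse

        if use_early_stop:
            val_mse = _forward_mse(X, Y, Wh, bh, Wo, bo, val_idx)
            if val_mse < best_val:
                best_val = val_mse
                best_epoch = epoch
                train_at_best = train_mse
                best_Wh[:, :] = Wh
                best_bh[:] = bh
                best_Wo[:, :] = Wo
                best_bo[:] = bo
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    break
        else:
            best_epoch = epoch
            train_at_best = train_mse

    if use_early_stop:
        Wh[:, :] = best_Wh
        bh[:] = best_bh
        Wo[:, :] = best_Wo
        bo[:] = best_bo
    return best_epoch, best_val, train_at_best
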