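"""Masked LSTM/GRU classifiers in pure NumPy.

The architecture mirrors the study's sequential models: a stack of recurrent
layers (input 41, hidden 256, 3 layers in the reference configuration) feeding
a two-layer head (linear 256->256, ReLU, linear 256->4).  Each recurrent layer
carries *two* bias vectors (input-to-hidden and hidden-to-hidden), which is
the parameterization the printed parameter counts are consistent with.

Padding handling follows the "masked" design: input rows are multiplied by the
pad mask, and the recurrence carries the previous state through padded steps,
so logits - read at the last valid step - are provably invariant to appended
padding.  Training is plain class-weighted cross-entropy with Adam (L2-coupled
weight decay), implemented with hand-derived backpropagation through time; the
gradients are validated against numerical differentiation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "RecurrentArchitecture",
    "TrainConfig",
    "count_parameters",
    "MaskedRecurrentClassifier",
    "train_recurrent",
]

_GATES = {"lstm": 4, "gru": 3}


@dataclass(frozen=True)
class RecurrentArchitecture:
    """Shape of a masked recurrent classifier."""

    cell: str = "lstm"
    input_size: int = 41
    hidden_size: int = 256
    num_layers: int = 3
    head_hidden: int = 256
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.cell not in _GATES:
            raise ValueError(f"cell must be one of {sorted(_GATES)}, got {self.cell!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (reference values of the sequential models)."""

    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 15
    weight_decay: float = 0.0001
    seed: int = 0


def count_parameters(arch: RecurrentArchitecture, include_head: bool = True) -> int:
    """Closed-form trainable-parameter count.

    Per layer with G gates (4 for LSTM, 3 for GRU), input width I and hidden
    width H: G*H*(I + H) weights plus 2*G*H biases (dual bias vectors).  The
    head adds (Hh*H + Hh) + (C*Hh + C).
    """
    g = _GATES[arch.cell]
    h = arch.hidden_size
    total = 0
    for layer in range(arch.num_layers):
        i = arch.input_size if layer == 0 else h
        total += g * h * (i + h) + 2 * g * h
    if include_head:
        total += arch.head_hidden * h + arch.head_hidden
        total += arch.n_classes * arch.head_hidden + arch.n_classes
    return total


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MaskedRecurrentClassifier:
    """A masked multi-layer LSTM/GRU with a 2-layer classification head."""

    def __init__(self, arch: RecurrentArchitecture, seed: int = 0) -> None:
        self.arch = arch
        rng = np.random.default_rng(seed)
        g = _GATES[arch.cell]
        h = arch.hidden_size
        bound = 1.0 / np.sqrt(h)
        self.params: dict[str, np.ndarray] = {}

        def init(name: str, shape: tuple[int, ...]) -> None:
            self.params[name] = rng.uniform(-bound, bound, size=shape)

        for layer in range(arch.num_layers):
            i = arch.input_size if layer == 0 else h
            init(f"W_ih_{layer}", (g * h, i))
            init(f"W_hh_{layer}", (g * h, h))
            init(f"b_ih_{layer}", (g * h,))
            init(f"b_hh_{layer}", (g * h,))
        init("W_fc1", (arch.head_hidden, h))
        init("b_fc1", (arch.head_hidden,))
        init("W_fc2", (arch.n_classes, arch.head_hidden))
        init("b_fc2", (arch.n_classes,))

    # -- forward ---------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, X: np.ndarray, pad_mask: np.ndarray | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Logits (B, C) from sequences (B, T, F) with pad mask (B, T)."""
        X = np.asarray(X, dtype=float)
        B, T, _ = X.shape
        m = np.ones((B, T)) if pad_mask is None else np.asarray(pad_mask, dtype=float)
        seq = X * m[:, :, None]  # input masking: x = x * mask
        if cache is not None:
            cache["mask"] = m
            cache["layers"] = []
        for layer in range(self.arch.num_layers):
            seq = self._layer_forward(seq, m, layer, cache)
        h_final = seq[:, -1]  # masked carry => state at last valid step
        a1 = h_final @ self.params["W_fc1"].T + self.params["b_fc1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ self.params["W_fc2"].T + self.params["b_fc2"]
        if cache is not None:
            cache["h_final"], cache["a1"], cache["r1"] = h_final, a1, r1
        return logits

    def _layer_forward(self, X: np.ndarray, m: np.ndarray, layer: int,
                       cache: dict | None) -> np.ndarray:
        p = self.params
        H = self.arch.hidden_size
        B, T, _ = X.shape
        Wi, Wh = p[f"W_ih_{layer}"], p[f"W_hh_{layer}"]
        bi, bh = p[f"b_ih_{layer}"], p[f"b_hh_{layer}"]
        h = np.zeros((B, H))
        out = np.empty((B, T, H))
        steps = []
        if self.arch.cell == "lstm":
            c = np.zeros((B, H))
            for t in range(T):
                x_t, m_t = X[:, t], m[:, t, None]
                a = x_t @ Wi.T + bi + h @ Wh.T + bh
                i_g = _sigmoid(a[:, :H])
                f_g = _sigmoid(a[:, H : 2 * H])
                g_g = np.tanh(a[:, 2 * H : 3 * H])
                o_g = _sigmoid(a[:, 3 * H :])
                c_new = f_g * c + i_g * g_g
                tc = np.tanh(c_new)
                h_new = o_g * tc
                h_prev, c_prev = h, c
                h = m_t * h_new + (1 - m_t) * h
                c = m_t * c_new + (1 - m_t) * c
                out[:, t] = h
                if cache is not None:
                    steps.append((x_t, h_prev, c_prev, i_g, f_g, g_g, o_g, c_new, tc))
        else:  # gru
            for t in range(T):
                x_t, m_t = X[:, t], m[:, t, None]
                ai = x_t @ Wi.T + bi
                ah = h @ Wh.T + bh
                r_g = _sigmoid(ai[:, :H] + ah[:, :H])
                z_g = _sigmoid(ai[:, H : 2 * H] + ah[:, H : 2 * H])
                n_g = np.tanh(ai[:, 2 * H :] + r_g * ah[:, 2 * H :])
                h_new = (1 - z_g) * n_g + z_g * h
                h_prev = h
                h = m_t * h_new + (1 - m_t) * h
                out[:, t] = h
                if cache is not None:
                    steps.append((x_t, h_prev, r_g, z_g, n_g, ah))
        if cache is not None:
            cache["layers"].append({"input": X, "steps": steps, "out": out})
        return out

    def predict_proba(self, X: np.ndarray, pad_mask: np.ndarray | None = None) -> np.ndarray:
        logits = self.forward(X, pad_mask)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray, pad_mask: np.ndarray | None = None) -> np.ndarray:
        return np.argmax(self.forward(X, pad_mask), axis=1)

    # -- backward --------------------------------------------------------

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        pad_mask: np.ndarray | None = None,
        class_weight: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Weighted cross-entropy loss and exact parameter gradients.

        Uses the weighted-mean convention: loss = sum_b w_{y_b} nll_b / sum_b
        w_{y_b}.
        """
        y = np.asarray(y, dtype=int)
        cache: dict = {}
        logits = self.forward(X, pad_mask, cache=cache)
        B, C = logits.shape
        w = np.ones(C) if class_weight is None else np.asarray(class_weight, dtype=float)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        wy = w[y]
        loss = float(-(wy * logp[np.arange(B), y]).sum() / wy.sum())

        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = np.exp(logp)
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (wy / wy.sum())[:, None]

        grads["W_fc2"] = dlogits.T @ cache["r1"]
        grads["b_fc2"] = dlogits.sum(axis=0)
        dr1 = dlogits @ p["W_fc2"]
        da1 = dr1 * (cache["a1"] > 0)
        grads["W_fc1"] = da1.T @ cache["h_final"]
        grads["b_fc1"] = da1.sum(axis=0)
        dh_final = da1 @ p["W_fc1"]

        m = cache["mask"]
        T = m.shape[1]
        dout = np.zeros((B, T, self.arch.hidden_size))
        dout[:, -1] = dh_final
        for layer in reversed(range(self.arch.num_layers)):
            dout = self._layer_backward(dout, m, layer, cache["layers"][layer], grads)
        return loss, grads

    def _layer_backward(self, dout: np.ndarray, m: np.ndarray, layer: int,
                        lcache: dict, grads: dict) -> np.ndarray:
        p = self.params
        H = self.arch.hidden_size
        Wi, Wh = p[f"W_ih_{layer}"], p[f"W_hh_{layer}"]
        gWi = grads[f"W_ih_{layer}"]
        gWh = grads[f"W_hh_{layer}"]
        gbi = grads[f"b_ih_{layer}"]
        gbh = grads[f"b_hh_{layer}"]
        X = lcache["input"]
        B, T, _ = X.shape
        dX = np.zeros_like(X)
        dh = np.zeros((B, H))
        if self.arch.cell == "lstm":
            dc = np.zeros((B, H))
            for t in reversed(range(T)):
                x_t, h_prev, c_prev, i_g, f_g, g_g, o_g, c_new, tc = lcache["steps"][t]
                m_t = m[:, t, None]
                dh = dh + dout[:, t]
                dh_new = dh * m_t
                dc_new = dc * m_t + dh_new * o_g * (1 - tc**2)
                do = dh_new * tc
                di = dc_new * g_g
                df = dc_new * c_prev
                dg = dc_new * i_g
                da = np.concatenate(
                    [
                        di * i_g * (1 - i_g),
                        df * f_g * (1 - f_g),
                        dg * (1 - g_g**2),
                        do * o_g * (1 - o_g),
                    ],
                    axis=1,
                )
                gWi += da.T @ x_t
                gWh += da.T @ h_prev
                gbi += da.sum(axis=0)
                gbh += da.sum(axis=0)
                dX[:, t] = da @ Wi
                dh = dh * (1 - m_t) + da @ Wh
                dc = dc * (1 - m_t) + dc_new * f_g
        else:  # gru
            for t in reversed(range(T)):
                x_t, h_prev, r_g, z_g, n_g, ah = lcache["steps"][t]
                m_t = m[:, t, None]
                dh = dh + dout[:, t]
                dh_new = dh * m_t
                dh_prev = dh * (1 - m_t) + dh_new * z_g
                dz = dh_new * (h_prev - n_g)
                dn = dh_new * (1 - z_g)
                dan = dn * (1 - n_g**2)  # pre-tanh of the n gate
                dr = dan * ah[:, 2 * H :]
                dar = dr * r_g * (1 - r_g)
                daz = dz * z_g * (1 - z_g)
                dai = np.concatenate([dar, daz, dan], axis=1)
                dah = np.concatenate([dar, daz, dan * r_g], axis=1)
                gWi += dai.T @ x_t
                gWh += dah.T @ h_prev
                gbi += dai.sum(axis=0)
                gbh += dah.sum(axis=0)
                dX[:, t] = dai @ Wi
                dh = dh_prev + dah @ Wh
        # input masking: x = x * m
        return dX * m[:, :, None]


@dataclass
class _AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0


def _adam_step(
    model: MaskedRecurrentClassifier,
    grads: Mapping[str, np.ndarray],
    state: _AdamState,
    lr: float,
    weight_decay: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    state.t += 1
    for name, param in model.params.items():
        g = grads[name] + weight_decay * param
        state.m[name] = beta1 * state.m[name] + (1 - beta1) * g
        state.v[name] = beta2 * state.v[name] + (1 - beta2) * g**2
        mhat = state.m[name] / (1 - beta1**state.t)
        vhat = state.v[name] / (1 - beta2**state.t)
        param -= lr * mhat / (np.sqrt(vhat) + eps)


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    f1s = []
    for c in range(n_classes):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def train_recurrent(
    model: MaskedRecurrentClassifier,
    config: TrainConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    class_weight: np.ndarray | None = None,
    pad_mask_train: np.ndarray | None = None,
    pad_mask_val: np.ndarray | None = None,
    checkpoint_dir=None,
) -> tuple[MaskedRecurrentClassifier, list[dict]]:
    """Mini-batch Adam training with per-epoch checkpoints.

    Tracks validation loss and macro-F1 per epoch, optionally saves per-epoch
    checkpoints, and reloads the parameters of the best (lowest validation
    loss) epoch before returning.
    """
    rng = np.random.default_rng(config.seed)
    n = len(y_train)
    state = _AdamState(
        m={k: np.zeros_like(v) for k, v in model.params.items()},
        v={k: np.zeros_like(v) for k, v in model.params.items()},
    )
    history: list[dict] = []
    best = {"epoch": -1, "val_loss": np.inf, "params": None}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            mb_mask = None if pad_mask_train is None else pad_mask_train[idx]
            if mb_mask is not None and not mb_mask.any():
                warnings.warn("skipping all-padding batch", stacklevel=2)
                continue
            loss, grads = model.loss_and_grads(
                X_train[idx], y_train[idx], mb_mask, class_weight
            )
            _adam_step(model, grads, state, config.learning_rate, config.weight_decay)
            losses.append(loss)
        val_loss, _ = model.loss_and_grads(X_val, y_val, pad_mask_val, class_weight)
        val_pred = model.predict(X_val, pad_mask_val)
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else np.nan,
            "val_loss": float(val_loss),
            "val_macro_f1": _macro_f1(np.asarray(y_val), val_pred, model.arch.n_classes),
        }
        history.append(record)
        if checkpoint_dir is not None:
            from pathlib import Path

            path = Path(checkpoint_dir) / f"epoch_{epoch:03d}.npz"
            np.savez(path, **model.params)
        if val_loss < best["val_loss"]:
            best = {
                "epoch": epoch,
                "val_loss": val_loss,
                "params": {k: v.copy() for k, v in model.params.items()},
            }
    if best["params"] is not None:  # reload the optimal epoch
        model.params = best["params"]
        for rec in history:
            rec["best_epoch"] = best["epoch"]
    return model, history
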