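"""A small numpy LSTM for sequence-to-label classification.

Architecture: sequence input -> single LSTM layer -> fully connected layer ->
softmax over the classes, with the label read from the hidden state at the
final time step.  Training is full backpropagation through time with the
Adam optimizer and a step learning-rate decay schedule.

The implementation is deliberately compact (single layer, dense numpy math)
because the sequences involved are short (one to a few hundred frames) and
the datasets small; on this scale a hand-rolled batched LSTM trains in
seconds to minutes on one CPU while remaining fully deterministic under a
fixed seed.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SequenceLSTM:
    """Single-layer LSTM + fully connected softmax head.

    Gate layout along the 4H axis is (input, forget, cell, output).  Weights
    use uniform Glorot initialization; the forget-gate bias starts at 1 so
    early training does not wash out the cell state.
    """

    def __init__(self, n_inputs: int, hidden_units: int, n_classes: int = 2,
                 rng_seed: int | None = None):
        if hidden_units <= 0:
            raise ValueError(f"hidden_units must be positive, got {hidden_units}")
        rng = np.random.default_rng(rng_seed)
        H, C, K = hidden_units, n_inputs, n_classes

        def glorot(shape):
            bound = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-bound, bound, size=shape).astype(_DTYPE)

        self.n_inputs = C
        self.hidden_units = H
        self.n_classes = K
        self.params = {
            "Wx": glorot((C, 4 * H)),
            "Wh": glorot((H, 4 * H)),
            "b": np.zeros(4 * H, dtype=_DTYPE),
            "Wf": glorot((H, K)),
            "bf": np.zeros(K, dtype=_DTYPE),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, X: np.ndarray, lengths: np.ndarray | None = None):
        """Run the network over a padded batch.

        Parameters
        ----------
        X : (B, T, C) array
            Zero-padded batch of sequences.
        lengths : (B,) int array, optional
            True sequence lengths.  When given, the classification state is
            the hidden state at each sequence's own final step (masking);
            when omitted, the state after the last padded step is used.

        Returns
        -------
        logits : (B, K) array
        cache : dict for :meth:`backward`
        """
        X = np.ascontiguousarray(X, dtype=_DTYPE)
        B, T, C = X.shape
        H = self.hidden_units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H), dtype=_DTYPE)
        c = np.zeros((B, H), dtype=_DTYPE)
        gates = np.empty((T, B, 4 * H), dtype=_DTYPE)
        cells = np.empty((T, B, H), dtype=_DTYPE)
        tanh_c = np.empty((T, B, H), dtype=_DTYPE)
        hiddens = np.empty((T + 1, B, H), dtype=_DTYPE)
        hiddens[0] = h
        x_proj = X.reshape(B * T, C) @ Wx  # all input projections at once
        x_proj = x_proj.reshape(B, T, 4 * H)
        for t in range(T):
            z = x_proj[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            cells[t] = c
            tanh_c[t] = tc
            hiddens[t + 1] = h

        if lengths is not None:
            last = np.asarray(lengths, dtype=int)
            h_out = hiddens[last, np.arange(B)]
        else:
            last = np.full(B, T, dtype=int)
            h_out = h
        logits = h_out @ self.params["Wf"] + self.params["bf"]
        cache = {
            "X": X, "gates": gates, "cells": cells, "tanh_c": tanh_c,
            "hiddens": hiddens, "last": last, "h_out": h_out,
        }
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """BPTT gradients of the loss w.r.t. all parameters."""
        X, gates = cache["X"], cache["gates"]
        cells, tanh_c, hiddens = cache["cells"], cache["tanh_c"], cache["hiddens"]
        last, h_out = cache["last"], cache["h_out"]
        B, T, C = X.shape
        H = self.hidden_units
        Wh, Wf = self.params["Wh"], self.params["Wf"]
        dlogits = dlogits.astype(_DTYPE)

        grads = {
            "Wf": h_out.T @ dlogits,
            "bf": dlogits.sum(axis=0),
            "Wx": np.zeros_like(self.params["Wx"]),
            "Wh": np.zeros_like(self.params["Wh"]),
            "b": np.zeros_like(self.params["b"]),
        }
        dh_inject = dlogits @ Wf.T  # enters each sequence at its own last step
        dh = np.zeros((B, H), dtype=_DTYPE)
        dc = np.zeros((B, H), dtype=_DTYPE)
        dz_all = np.empty((T, B, 4 * H), dtype=_DTYPE)
        for t in range(T - 1, -1, -1):
            dh = dh + np.where((last == t + 1)[:, None], dh_inject, 0.0)
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            tc = tanh_c[t]
            c_prev = cells[t - 1] if t > 0 else np.zeros((B, H), dtype=_DTYPE)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = dz_all[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            grads["Wh"] += hiddens[t].T @ dz
            dh = dz @ Wh.T
            dc = dc * f
        grads["b"] = dz_all.sum(axis=(0, 1))
        grads["Wx"] = X.reshape(B * T, C).T @ dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        return grads

    def clip_gradients(self, grads: dict, max_norm: float) -> dict:
        """Rescale gradients so their global L2 norm is at most ``max_norm``."""
        total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
        if total > max_norm:
            scale = max_norm / total
            grads = {k: g * scale for k, g in grads.items()}
        return grads

    def adam_step(self, grads: dict, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        """One Adam update over all parameters."""
        self._adam_t += 1
        t = self._adam_t
        for key, p in self.params.items():
            g = grads[key]
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= (lr * m_hat / (np.sqrt(v_hat) + eps)).astype(_DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  sample_weights: np.ndarray | None = None):
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``targets`` are integer class indices; ``sample_weights`` optionally
    reweight each sequence (used for class weighting).
    """
    B = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    if sample_weights is None:
        sample_weights = np.ones(B)
    w = sample_weights / sample_weights.sum()
    loss = float(-(w * np.log(probs[np.arange(B), targets] + 1e-12)).sum())
    dlogits = probs
    dlogits[np.arange(B), targets] -= 1.0
    dlogits *= w[:, None]
    return loss, dlogits
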