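"""Recurrent attention classifier for multivariate time courses.

The architecture is a unidirectional LSTM (or GRU) encoder over the ``T x N``
input, followed by a concatenation attention head — the last hidden state is
tiled and concatenated with every step's hidden state, scored through two
linear layers (tanh between them), softmax-normalised over time, and used to
form a context vector — and a decoder of two linear layers with dropout
between them, ending in a sigmoid that emits the probability of the positive
class.

All forward and backward passes are written directly in NumPy (float64).
The backward pass returns both parameter gradients (for training) and the
gradient with respect to the input (required by integrated gradients);
both are verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["ModelConfig", "ForwardOutput", "SequenceClassifier", "init_model"]

_PROB_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` is the number of components N. ``use_attention=False``
    and ``encoder_kind="gru"`` are the ablation switches; with attention off
    the context vector is simply the last hidden state.
    """

    input_size: int
    lstm_hidden: int = 64
    lstm_layers: int = 1
    attention_hidden: int = 64
    decoder_hidden: int = 32
    dropout_rate: float = 0.3
    use_attention: bool = True
    encoder_kind: str = "lstm"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_size", "lstm_hidden", "lstm_layers", "attention_hidden", "decoder_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.encoder_kind not in ("lstm", "gru"):
            raise ValueError(f"encoder_kind must be 'lstm' or 'gru', got {self.encoder_kind!r}")


@dataclass
class ForwardOutput:
    """Single-sequence inference result."""

    probability: float
    attention_weights: Optional[np.ndarray]  # length T, on the simplex; None if attention off
    context: np.ndarray  # length lstm_hidden


def _xavier_normal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SequenceClassifier:
    """LSTM/GRU + attention + decoder binary classifier (the TrainedModel container).

    Attributes
    ----------
    config : ModelConfig
    parameters : dict[str, ndarray]
        Named weight matrices and bias vectors.
    provenance : str
        ``"scratch"`` or ``"pretrained:<tag>"``.
    """

    def __init__(self, config: ModelConfig, parameters: dict[str, np.ndarray], provenance: str = "scratch"):
        self.config = config
        self.parameters = parameters
        self.provenance = provenance

    # ---------------------------------------------------------------- init

    @classmethod
    def initialize(cls, config: ModelConfig) -> "SequenceClassifier":
        """Fresh model: Xavier-normal weights, zero biases, deterministic in ``config.seed``."""
        rng = np.random.default_rng(config.seed)
        H, A, D = config.lstm_hidden, config.attention_hidden, config.decoder_hidden
        G = 4 if config.encoder_kind == "lstm" else 3
        p: dict[str, np.ndarray] = {}
        in_size = config.input_size
        for layer in range(config.lstm_layers):
            p[f"enc{layer}.Wx"] = _xavier_normal(rng, (in_size, G * H))
            p[f"enc{layer}.Wh"] = _xavier_normal(rng, (H, G * H))
            p[f"enc{layer}.bx"] = np.zeros(G * H)
            p[f"enc{layer}.bh"] = np.zeros(G * H)
            in_size = H
        if config.use_attention:
            p["attn.W1"] = _xavier_normal(rng, (2 * H, A))
            p["attn.b1"] = np.zeros(A)
            p["attn.W2"] = _xavier_normal(rng, (A, 1))
            p["attn.b2"] = np.zeros(1)
        p["dec.W1"] = _xavier_normal(rng, (H, D))
        p["dec.b1"] = np.zeros(D)
        p["dec.W2"] = _xavier_normal(rng, (D, 1))
        p["dec.b2"] = np.zeros(1)
        return cls(config, p, provenance="scratch")

    def copy(self) -> "SequenceClassifier":
        return SequenceClassifier(
            self.config, {k: v.copy() for k, v in self.parameters.items()}, self.provenance
        )

    # ------------------------------------------------------------- encoder

    def _encoder_forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """Run the recurrent stack; X is (B, T, N). Returns top-layer states (B, T, H) and caches."""
        caches = []
        inp = X
        for layer in range(self.config.lstm_layers):
            if self.config.encoder_kind == "lstm":
                inp, cache = self._lstm_layer_forward(layer, inp)
            else:
                inp, cache = self._gru_layer_forward(layer, inp)
            caches.append(cache)
        return inp, caches

    def _lstm_layer_forward(self, layer: int, X: np.ndarray):
        p = self.parameters
        Wx, Wh = p[f"enc{layer}.Wx"], p[f"enc{layer}.Wh"]
        b = p[f"enc{layer}.bx"] + p[f"enc{layer}.bh"]
        B, T, _ = X.shape
        H = self.config.lstm_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        # precompute the input projection for all steps at once
        ZX = X @ Wx + b
        steps = []
        for t in range(T):
            z = ZX[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            steps.append((i, f, g, o, c_prev, tc, h))
        return Hs, {"X": X, "steps": steps, "layer": layer}

    def _lstm_layer_backward(self, cache: dict, dHs: np.ndarray):
        p = self.parameters
        layer = cache["layer"]
        Wx, Wh = p[f"enc{layer}.Wx"], p[f"enc{layer}.Wh"]
        X, steps = cache["X"], cache["steps"]
        B, T, _ = X.shape
        H = self.config.lstm_hidden
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.empty_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dZ = np.empty((B, T, 4 * H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, _h = steps[t]
            dh = dHs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dZ[:, t] = dz
            h_prev = steps[t - 1][6] if t > 0 else np.zeros((B, H))
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        # batched input-side accumulation
        dWx = np.einsum("btn,btk->nk", X, dZ)
        db = dZ.sum(axis=(0, 1))
        dX = dZ @ Wx.T
        return {f"enc{layer}.Wx": dWx, f"enc{layer}.Wh": dWh,
                f"enc{layer}.bx": db, f"enc{layer}.bh": db.copy()}, dX

    def _gru_layer_forward(self, layer: int, X: np.ndarray):
        p = self.parameters
        Wx, Wh = p[f"enc{layer}.Wx"], p[f"enc{layer}.Wh"]
        bx, bh = p[f"enc{layer}.bx"], p[f"enc{layer}.bh"]
        B, T, _ = X.shape
        H = self.config.lstm_hidden
        h = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        ZX = X @ Wx + bx
        steps = []
        for t in range(T):
            zh = h @ Wh + bh
            r = _sigmoid(ZX[:, t, :H] + zh[:, :H])
            z = _sigmoid(ZX[:, t, H : 2 * H] + zh[:, H : 2 * H])
            zh_n = zh[:, 2 * H :]
            n = np.tanh(ZX[:, t, 2 * H :] + r * zh_n)
            h_prev = h
            h = (1.0 - z) * n + z * h_prev
            Hs[:, t] = h
            steps.append((r, z, n, zh_n, h_prev))
        return Hs, {"X": X, "steps": steps, "layer": layer}

    def _gru_layer_backward(self, cache: dict, dHs: np.ndarray):
        p = self.parameters
        layer = cache["layer"]
        Wx, Wh = p[f"enc{layer}.Wx"], p[f"enc{layer}.Wh"]
        X, steps = cache["X"], cache["steps"]
        B, T, _ = X.shape
        H = self.config.lstm_hidden
        dWh = np.zeros_like(Wh)
        dbh = np.zeros(3 * H)
        dh_next = np.zeros((B, H))
        dZX = np.empty((B, T, 3 * H))
        for t in range(T - 1, -1, -1):
            r, z, n, zh_n, h_prev = steps[t]
            dh = dHs[:, t] + dh_next
            dz_gate = dh * (h_prev - n) * z * (1 - z)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1 - n * n)
            dr = dn_pre * zh_n
            dzh_n = dn_pre * r
            dr_pre = dr * r * (1 - r)
            dzx = np.concatenate([dr_pre, dz_gate, dn_pre], axis=1)
            dzh = np.concatenate([dr_pre, dz_gate, dzh_n], axis=1)
            dZX[:, t] = dzx
            dWh += h_prev.T @ dzh
            dbh += dzh.sum(axis=0)
            dh_next = dh_prev + dzh @ Wh.T
        dWx = np.einsum("btn,btk->nk", X, dZX)
        dbx = dZX.sum(axis=(0, 1))
        dX = dZX @ Wx.T
        return {f"enc{layer}.Wx": dWx, f"enc{layer}.Wh": dWh,
                f"enc{layer}.bx": dbx, f"enc{layer}.bh": dbh}, dX

    # ----------------------------------------------------------- attention

    def _attention_forward(self, Hs: np.ndarray):
        p = self.parameters
        B, T, H = Hs.shape
        h_last = Hs[:, -1]
        C = np.concatenate([Hs, np.broadcast_to(h_last[:, None, :], Hs.shape)], axis=2)
        A1 = np.tanh(C @ p["attn.W1"] + p["attn.b1"])
        S = (A1 @ p["attn.W2"] + p["attn.b2"])[..., 0]
        w = _softmax(S, axis=1)
        ctx = np.einsum("bt,bth->bh", w, Hs)
        return ctx, w, {"Hs": Hs, "C": C, "A1": A1, "w": w}

    def _attention_backward(self, cache: dict, dctx: np.ndarray):
        p = self.parameters
        Hs, C, A1, w = cache["Hs"], cache["C"], cache["A1"], cache["w"]
        B, T, H = Hs.shape
        dHs = w[:, :, None] * dctx[:, None, :]
        dw = np.einsum("bh,bth->bt", dctx, Hs)
        dS = w * (dw - (w * dw).sum(axis=1, keepdims=True))
        dW2 = np.einsum("bta,bt->a", A1, dS)[:, None]
        db2 = np.array([dS.sum()])
        dA1 = dS[:, :, None] * p["attn.W2"][:, 0][None, None, :]
        dpre = dA1 * (1.0 - A1 * A1)
        dW1 = np.einsum("btc,bta->ca", C, dpre)
        db1 = dpre.sum(axis=(0, 1))
        dC = dpre @ p["attn.W1"].T
        dHs = dHs + dC[:, :, :H]
        dHs[:, -1] += dC[:, :, H:].sum(axis=1)
        grads = {"attn.W1": dW1, "attn.b1": db1, "attn.W2": dW2, "attn.b2": db2}
        return grads, dHs

    def attend(self, hidden_states: np.ndarray, last_state: np.ndarray):
        """Attention weights and context for one ``T x d`` hidden-state matrix.

        Scores each step by ``linear2(tanh(linear1([h_t ; h_last])))``,
        softmax-normalises over time and returns the weighted sum of states.
        """
        p = self.parameters
        if not self.config.use_attention:
            raise ValueError("model was built with use_attention=False")
        Hs = np.asarray(hidden_states, dtype=float)
        C = np.concatenate(
            [Hs, np.broadcast_to(np.asarray(last_state, dtype=float), Hs.shape)], axis=1
        )
        A1 = np.tanh(C @ p["attn.W1"] + p["attn.b1"])
        scores = (A1 @ p["attn.W2"] + p["attn.b2"])[:, 0]
        w = _softmax(scores, axis=0)
        ctx = w @ Hs
        return w, ctx

    # -------------------------------------------------------- full network

    def forward_batch(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, dict]:
        """Probabilities for a batch (B, T, N); returns (probs, cache).

        Dropout on the decoder hidden layer is active only when
        ``training=True`` (inverted dropout, scaled at train time).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected input of shape (B, T, {self.config.input_size}), got {X.shape}"
            )
        p = self.parameters
        Hs, enc_caches = self._encoder_forward(X)
        if self.config.use_attention:
            ctx, w, attn_cache = self._attention_forward(Hs)
        else:
            ctx, w, attn_cache = Hs[:, -1], None, None
        d1 = ctx @ p["dec.W1"] + p["dec.b1"]
        if training and self.config.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("training-mode forward requires dropout_rng")
            keep = 1.0 - self.config.dropout_rate
            mask = (dropout_rng.random(d1.shape) < keep) / keep
        else:
            mask = None
        d1d = d1 if mask is None else d1 * mask
        logit = (d1d @ p["dec.W2"] + p["dec.b2"])[:, 0]
        probs = _sigmoid(logit)
        cache = {
            "enc_caches": enc_caches,
            "attn_cache": attn_cache,
            "ctx": ctx,
            "weights": w,
            "d1d": d1d,
            "mask": mask,
            "probs": probs,
        }
        return probs, cache

    def backward_batch(self, cache: dict, dlogit: np.ndarray):
        """Backprop from logit gradients; returns (parameter grads, input grads)."""
        p = self.parameters
        grads: dict[str, np.ndarray] = {}
        d1d, mask, ctx = cache["d1d"], cache["mask"], cache["ctx"]
        grads["dec.W2"] = d1d.T @ dlogit[:, None]
        grads["dec.b2"] = np.array([dlogit.sum()])
        dd1 = dlogit[:, None] * p["dec.W2"][:, 0][None, :]
        if mask is not None:
            dd1 = dd1 * mask
        grads["dec.W1"] = ctx.T @ dd1
        grads["dec.b1"] = dd1.sum(axis=0)
        dctx = dd1 @ p["dec.W1"].T
        if self.config.use_attention:
            attn_grads, dHs = self._attention_backward(cache["attn_cache"], dctx)
            grads.update(attn_grads)
        else:
            Hs_shape = cache["enc_caches"][-1]["steps"]
            B = dctx.shape[0]
            T = len(Hs_shape)
            dHs = np.zeros((B, T, self.config.lstm_hidden))
            dHs[:, -1] = dctx
        dcur = dHs
        for cache_l in reversed(cache["enc_caches"]):
            if self.config.encoder_kind == "lstm":
                g, dcur = self._lstm_layer_backward(cache_l, dcur)
            else:
                g, dcur = self._gru_layer_backward(cache_l, dcur)
            grads.update(g)
        return grads, dcur

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities for a batch (B, T, N); deterministic."""
        probs, _ = self.forward_batch(X, training=False)
        return probs

    def forward(self, values: np.ndarray) -> ForwardOutput:
        """Single-sequence evaluation-mode inference on a ``T x N`` matrix."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a T x N matrix")
        probs, cache = self.forward_batch(values[None], training=False)
        prob = float(np.clip(probs[0], _PROB_EPS, 1.0 - _PROB_EPS))
        w = cache["weights"][0] if cache["weights"] is not None else None
        return ForwardOutput(probability=prob, attention_weights=w, context=cache["ctx"][0])

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d probability / d input for a batch (B, T, N), evaluation mode."""
        probs, cache = self.forward_batch(X, training=False)
        dlogit = probs * (1.0 - probs)  # sigmoid derivative
        _, dX = self.backward_batch(cache, dlogit)
        return dX

    # ------------------------------------------------------- serialization

    def save(self, path: str | Path) -> None:
        """Write ``<path>.npz`` (parameters) and ``<path>.json`` (config + provenance)."""
        path = Path(path)
        np.savez(str(path) + ".npz", **self.parameters)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"config": asdict(self.config), "provenance": self.provenance}, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SequenceClassifier":
        path = Path(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        config = ModelConfig(**meta["config"])
        with np.load(str(path) + ".npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        return cls(config, params, provenance=meta.get("provenance", "scratch"))


def init_model(config: ModelConfig) -> SequenceClassifier:
    """Convenience alias for :meth:`SequenceClassifier.initialize`."""
    return SequenceClassifier.initialize(config)
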