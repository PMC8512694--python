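"""Recurrent cells (Elman RNN, GRU, LSTM) and the multi-horizon classifier.

All three cells are implemented directly from their defining update
equations in NumPy, with analytically derived backpropagation-through-time
gradients — no autodiff framework.  The Elman network uses the
power-sigmoid activation (x^alpha outside the unit interval, a scaled
bipolar sigmoid inside), chosen for fast convergence; GRU and LSTM use the
standard logistic / tanh gates.

A :class:`HorizonClassifier` wraps one cell with a linear readout into
``n_horizons`` independent 3-way softmax heads: given a short window of
consecutive beat-pair feature vectors it predicts the class at every
configured lead time.  Training is deterministic mini-batch gradient
descent with global-norm clipping.

Notes on fidelity: the printed LSTM cell update omits the previous cell
state from the forget path; the standard ``C_t = f⊙C_{t-1} + i⊙C~_t`` is
used instead (otherwise the forget gate gates nothing).  The GRU update
is kept exactly as printed, ``h_t = (1-u)⊙h_{t-1} + u⊙h~_t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .signal_io import N_CLASSES, FeatureSample

# hidden pre-activations in the trained RNN are clipped here so the
# polynomial branch of the power-sigmoid stays bounded through time
RNN_PREACT_CLIP = 3.0


# ---------------------------------------------------------------------------
# Power-sigmoid activation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSigmoidParams:
    """alpha must be an odd integer >= 3 (keeps the map odd and monotone); beta > 2."""

    alpha: int = 3
    beta: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha < 3 or self.alpha % 2 == 0:
            raise ValueError(f"alpha must be an odd integer >= 3, got {self.alpha}")
        if not self.beta > 2:
            raise ValueError(f"beta must exceed 2, got {self.beta}")


def power_sigmoid(x, p: PowerSigmoidParams = PowerSigmoidParams()):
    """x^alpha for |x| >= 1; (1+e^-b)(1-e^-bx) / ((1-e^-b)(1+e^-bx)) for |x| < 1.

    The inner branch equals c·tanh(beta·x/2) with c = (1+e^-beta)/(1-e^-beta),
    which makes the map odd, strictly increasing and continuous at |x| = 1
    (both branches give ±1 there).
    """
    x = np.asarray(x, dtype=float)
    c = (1 + np.exp(-p.beta)) / (1 - np.exp(-p.beta))
    inner = c * np.tanh(0.5 * p.beta * x)
    outer = np.sign(x) * np.abs(x) ** p.alpha
    return np.where(np.abs(x) >= 1.0, outer, inner)


def power_sigmoid_deriv(x, p: PowerSigmoidParams = PowerSigmoidParams()):
    x = np.asarray(x, dtype=float)
    c = (1 + np.exp(-p.beta)) / (1 - np.exp(-p.beta))
    inner = c * 0.5 * p.beta / np.cosh(0.5 * p.beta * x) ** 2
    outer = p.alpha * np.abs(x) ** (p.alpha - 1)
    return np.where(np.abs(x) >= 1.0, outer, inner)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# Cell parameter containers and single-step operations (from the equations)
# ---------------------------------------------------------------------------


@dataclass
class RnnParams:
    """Elman network weights: h_t = σ_h(W_ih x_t + W_h h_{t-1} + b_h),
    y_t = σ_o(W_ho h_t + b_o)."""

    W_ih: np.ndarray
    W_h: np.ndarray
    W_ho: np.ndarray
    b_h: np.ndarray
    b_o: np.ndarray
    act_h: PowerSigmoidParams = PowerSigmoidParams()
    act_o: PowerSigmoidParams = PowerSigmoidParams()


def rnn_step(x_t: np.ndarray, h_prev: np.ndarray, p: RnnParams
             ) -> tuple[np.ndarray, np.ndarray]:
    """One Elman step.  The output activation sees its input clipped to
    [-1, 1] (bounded branch only) so y stays finite."""
    a = p.W_ih @ x_t + p.W_h @ h_prev + p.b_h
    h_t = power_sigmoid(a, p.act_h)
    y_t = power_sigmoid(np.clip(p.W_ho @ h_t + p.b_o, -1.0, 1.0), p.act_o)
    return h_t, y_t


@dataclass
class GruParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t]."""

    W_u: np.ndarray   # update gate
    W_r: np.ndarray   # reset gate
    W_hhat: np.ndarray  # candidate state


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, p: GruParams) -> np.ndarray:
    """u = σ(W_u[h,x]); r = σ(W_r[h,x]); h~ = tanh(W_h~[r⊙h, x]);
    h_t = (1-u)⊙h_{t-1} + u⊙h~ (polarity as printed)."""
    z = np.concatenate([h_prev, x_t])
    u = _sigmoid(p.W_u @ z)
    r = _sigmoid(p.W_r @ z)
    zc = np.concatenate([r * h_prev, x_t])
    h_hat = np.tanh(p.W_hhat @ zc)
    return (1.0 - u) * h_prev + u * h_hat


@dataclass
class LstmParams:
    """Three-gate LSTM weights, input (x) and recurrent (h) parts per gate."""

    w_ix: np.ndarray
    w_ih: np.ndarray
    w_fx: np.ndarray
    w_fh: np.ndarray
    w_ox: np.ndarray
    w_oh: np.ndarray
    w_cx: np.ndarray
    w_ch: np.ndarray


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
              p: LstmParams) -> tuple[np.ndarray, np.ndarray]:
    """Gates i/f/o, candidate C~, cell C_t = f⊙C_{t-1} + i⊙C~, h_t = o⊙tanh(C_t)."""
    i = _sigmoid(p.w_ix @ x_t + p.w_ih @ h_prev)
    f = _sigmoid(p.w_fx @ x_t + p.w_fh @ h_prev)
    o = _sigmoid(p.w_ox @ x_t + p.w_oh @ h_prev)
    g = np.tanh(p.w_cx @ x_t + p.w_ch @ h_prev)
    C_t = f * C_prev + i * g
    h_t = o * np.tanh(C_t)
    return h_t, C_t


# ---------------------------------------------------------------------------
# Multi-horizon classifier
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    hidden_size: int = 32
    window: int = 8
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    clip_norm: float = 1.0
    seed: int = 0
    power_sigmoid: PowerSigmoidParams = field(default_factory=PowerSigmoidParams)


def make_sequences(samples: Sequence[FeatureSample], window: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding windows of consecutive samples, grouped per record.

    Each labeled sample becomes one sequence of the ``window`` samples
    ending at it (time order within a record); sequences near a record's
    start are left-padded by repeating the record's earliest sample.
    Returns X (N, window, D) and Y (N, n_horizons).
    """
    by_record: dict[str, list[FeatureSample]] = {}
    for s in samples:
        by_record.setdefault(s.record_id, []).append(s)
    xs, ys = [], []
    for rec in by_record.values():
        rec = sorted(rec, key=lambda s: s.t_ref_s)
        feats = np.stack([s.features for s in rec])
        for i in range(len(rec)):
            idx = np.clip(np.arange(i - window + 1, i + 1), 0, None)
            xs.append(feats[idx])
            ys.append(rec[i].labels)
    if not xs:
        raise ValueError("no samples to window")
    return np.stack(xs), np.stack(ys)


class HorizonClassifier:
    """One recurrent cell + per-horizon softmax readout.

    Parameters
    ----------
    cell : {'rnn', 'gru', 'lstm'}
    n_horizons : number of lead times (heads); each head is a 3-way softmax.
    input_size : feature dimension (398 for L=100 beat pairs).
    """

    def __init__(self, cell: str, n_horizons: int, input_size: int = 398,
                 config: Optional[TrainConfig] = None):
        if cell not in ("rnn", "gru", "lstm"):
            raise ValueError(f"unknown cell kind {cell!r}")
        self.cell = cell
        self.n_horizons = int(n_horizons)
        self.input_size = int(input_size)
        self.config = config or TrainConfig()
        self.params: dict[str, np.ndarray] = {}
        self.loss_trace: list[float] = []
        self.feat_mean: Optional[np.ndarray] = None
        self.feat_std: Optional[np.ndarray] = None
        self._trained = False
        self._init_params()

    # -- initialization ----------------------------------------------------

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        H, D, K = self.config.hidden_size, self.input_size, self.n_horizons * N_CLASSES

        def mat(rows, cols):
            return rng.normal(0.0, 0.5 / np.sqrt(cols), size=(rows, cols))

        if self.cell == "rnn":
            self.params = {"W_ih": mat(H, D), "W_h": mat(H, H), "b_h": np.zeros(H)}
        elif self.cell == "gru":
            self.params = {"W_u": mat(H, H + D), "W_r": mat(H, H + D),
                           "W_hhat": mat(H, H + D)}
        else:
            self.params = {}
            for g in ("i", "f", "o", "c"):
                self.params[f"w_{g}x"] = mat(H, D)
                self.params[f"w_{g}h"] = mat(H, H)
        self.params["W_out"] = mat(K, H)
        self.params["b_out"] = np.zeros(K)

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (B, W, D) normalized.  Returns final hidden (B, H) and caches."""
        B, W, _ = X.shape
        H = self.config.hidden_size
        p = self.params
        h = np.zeros((B, H))
        caches: list = []
        if self.cell == "rnn":
            for t in range(W):
                a = X[:, t] @ p["W_ih"].T + h @ p["W_h"].T + p["b_h"]
                a_c = np.clip(a, -RNN_PREACT_CLIP, RNN_PREACT_CLIP)
                mask = (np.abs(a) < RNN_PREACT_CLIP).astype(float)
                h_new = power_sigmoid(a_c, self.config.power_sigmoid)
                caches.append((X[:, t], h, a_c, mask))
                h = h_new
        elif self.cell == "gru":
            for t in range(W):
                z = np.concatenate([h, X[:, t]], axis=1)
                u = _sigmoid(z @ p["W_u"].T)
                r = _sigmoid(z @ p["W_r"].T)
                zc = np.concatenate([r * h, X[:, t]], axis=1)
                c = np.tanh(zc @ p["W_hhat"].T)
                h_new = (1.0 - u) * h + u * c
                caches.append((X[:, t], h, z, u, r, zc, c))
                h = h_new
        else:
            C = np.zeros((B, H))
            for t in range(W):
                x = X[:, t]
                i = _sigmoid(x @ p["w_ix"].T + h @ p["w_ih"].T)
                f = _sigmoid(x @ p["w_fx"].T + h @ p["w_fh"].T)
                o = _sigmoid(x @ p["w_ox"].T + h @ p["w_oh"].T)
                g = np.tanh(x @ p["w_cx"].T + h @ p["w_ch"].T)
                C_new = f * C + i * g
                h_new = o * np.tanh(C_new)
                caches.append((x, h, C, i, f, o, g, C_new))
                h, C = h_new, C_new
        return h, caches

    def _logits(self, h_last: np.ndarray) -> np.ndarray:
        K = self.params["W_out"].shape[0]
        out = h_last @ self.params["W_out"].T + self.params["b_out"]
        return out.reshape(-1, self.n_horizons, N_CLASSES)

    # -- backward ----------------------------------------------------------

    def _backward(self, caches: list, dh: np.ndarray,
                  grads: dict[str, np.ndarray]) -> None:
        p = self.params
        if self.cell == "rnn":
            for x, h_prev, a_c, mask in reversed(caches):
                da = dh * power_sigmoid_deriv(a_c, self.config.power_sigmoid) * mask
                grads["W_ih"] += da.T @ x
                grads["W_h"] += da.T @ h_prev
                grads["b_h"] += da.sum(axis=0)
                dh = da @ p["W_h"]
        elif self.cell == "gru":
            H = self.config.hidden_size
            for x, h_prev, z, u, r, zc, c in reversed(caches):
                du = dh * (c - h_prev)
                dc = dh * u
                dh_prev = dh * (1.0 - u)
                dc_pre = dc * (1.0 - c * c)
                grads["W_hhat"] += dc_pre.T @ zc
                dzc = dc_pre @ p["W_hhat"]
                drh = dzc[:, :H]
                dr = drh * h_prev
                dh_prev = dh_prev + drh * r
                du_pre = du * u * (1.0 - u)
                dr_pre = dr * r * (1.0 - r)
                grads["W_u"] += du_pre.T @ z
                grads["W_r"] += dr_pre.T @ z
                dz = du_pre @ p["W_u"] + dr_pre @ p["W_r"]
                dh = dh_prev + dz[:, :H]
        else:
            dC_next = np.zeros_like(dh)
            for x, h_prev, C_prev, i, f, o, g, C_new in reversed(caches):
                tC = np.tanh(C_new)
                dC = dC_next + dh * o * (1.0 - tC * tC)
                do = dh * tC
                di, dg, df = dC * g, dC * i, dC * C_prev
                dC_next = dC * f
                di_pre = di * i * (1.0 - i)
                df_pre = df * f * (1.0 - f)
                do_pre = do * o * (1.0 - o)
                dg_pre = dg * (1.0 - g * g)
                grads["w_ix"] += di_pre.T @ x
                grads["w_ih"] += di_pre.T @ h_prev
                grads["w_fx"] += df_pre.T @ x
                grads["w_fh"] += df_pre.T @ h_prev
                grads["w_ox"] += do_pre.T @ x
                grads["w_oh"] += do_pre.T @ h_prev
                grads["w_cx"] += dg_pre.T @ x
                grads["w_ch"] += dg_pre.T @ h_prev
                dh = (di_pre @ p["w_ih"] + df_pre @ p["w_fh"]
                      + do_pre @ p["w_oh"] + dg_pre @ p["w_ch"])

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean softmax cross-entropy over heads; full analytic gradients."""
        B = X.shape[0]
        h_last, caches = self._forward(X)
        logits = self._logits(h_last)
        logits = logits - logits.max(axis=2, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=2, keepdims=True)
        idx = np.arange(B)[:, None], np.arange(self.n_horizons)[None, :]
        loss = float(-np.log(probs[idx[0], idx[1], Y] + 1e-300).mean())

        dlogits = probs.copy()
        dlogits[idx[0], idx[1], Y] -= 1.0
        dlogits /= B * self.n_horizons
        dflat = dlogits.reshape(B, -1)
        grads = {name: np.zeros_like(arr) for name, arr in self.params.items()}
        grads["W_out"] = dflat.T @ h_last
        grads["b_out"] = dflat.sum(axis=0)
        dh = dflat @ self.params["W_out"]
        self._backward(caches, dh, grads)
        return loss, grads

    # -- training ----------------------------------------------------------

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_std

    def fit(self, samples: Sequence[FeatureSample]) -> "HorizonClassifier":
        """Deterministic mini-batch gradient descent on windowed sequences."""
        X, Y = make_sequences(samples, self.config.window)
        if Y.shape[1] != self.n_horizons:
            raise ValueError(
                f"samples carry {Y.shape[1]} horizon labels, model has {self.n_horizons}"
            )
        if np.unique(Y).size < 2:
            warnings.warn("training data contains a single class", stacklevel=2)
        self.feat_mean = X.reshape(-1, X.shape[2]).mean(axis=0)
        self.feat_std = X.reshape(-1, X.shape[2]).std(axis=0) + 1e-8
        Xn = self._normalize(X)

        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        n = Xn.shape[0]
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                b = order[start : start + cfg.batch_size]
                loss, grads = self.loss_and_grads(Xn[b], Y[b])
                epoch_loss += loss * b.size
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                scale = cfg.clip_norm / gnorm if gnorm > cfg.clip_norm else 1.0
                for name in self.params:
                    self.params[name] -= cfg.learning_rate * scale * grads[name]
            self.loss_trace.append(epoch_loss / n)
        self._trained = True
        return self

    # -- prediction ----------------------------------------------------------

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (N, n_horizons, 3) for sequences X (N, W, D)."""
        if not self._trained:
            raise RuntimeError("model is not trained")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        logits = self._logits(self._forward(self._normalize(X))[0])
        logits = logits - logits.max(axis=2, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=2, keepdims=True)

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-horizon class ids and scores for one feature vector or window.

        1-D input is treated as a single-step sequence.  Ties break toward
        the lowest class id (argmax convention).
        """
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None, :]
        scores = self.predict_scores(features[None])[0]
        return scores.argmax(axis=1), scores


def train(model: HorizonClassifier, data: Sequence[FeatureSample],
          config: Optional[TrainConfig] = None) -> HorizonClassifier:
    """Functional wrapper: (re)configure, fit, return the trained model."""
    if config is not None:
        model.config = config
        model._init_params()
    return model.fit(data)


def grid_search_power_sigmoid(
    samples: Sequence[FeatureSample],
    n_horizons: int,
    input_size: int,
    base_config: TrainConfig,
    alphas: Sequence[int] = (3, 5, 7),
    betas: Sequence[float] = (3.0, 4.0, 5.0),
    val_fraction: float = 0.25,
) -> tuple[PowerSigmoidParams, HorizonClassifier]:
    """Select (alpha, beta) for the RNN by validation overall accuracy."""
    n = len(samples)
    n_val = max(1, int(round(n * val_fraction)))
    train_set, val_set = list(samples[:-n_val]), list(samples[-n_val:])
    Xv, Yv = make_sequences(val_set, base_config.window)
    best: tuple[float, PowerSigmoidParams, Optional[HorizonClassifier]] = (
        -1.0, PowerSigmoidParams(), None)
    for a in alphas:
        for b in betas:
            cfg = replace(base_config, power_sigmoid=PowerSigmoidParams(a, b))
            m = HorizonClassifier("rnn", n_horizons, input_size, cfg).fit(train_set)
            acc = float(
                (m.predict_scores(Xv).argmax(axis=2) == Yv).mean())
            if acc > best[0]:
                best = (acc, cfg.power_sigmoid, m)
    assert best[2] is not None
    return best[1], best[2]
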