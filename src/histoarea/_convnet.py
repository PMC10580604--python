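"""A small convolutional network trained with the Cox partial likelihood.

Pure-numpy implementation of the desk-scale deep survival feature
extractor: a stack of strided 3x3 convolutions with ReLU, a fully connected
hidden layer of 32 units (the feature layer) and a scalar risk head. Weights
are He-initialized; optimization is Adam on the negative log partial
likelihood of the Cox proportional-hazards model with Breslow handling of
tied event times.

The partial-likelihood loss and its analytic gradient with respect to the
per-sample risks live here as standalone functions so they can be verified
against finite differences independently of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["cox_partial_nll", "cox_partial_nll_grad", "ConvSurvNet"]


def _risk_matrix_terms(risks, times, events):
    r = np.asarray(risks, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events).ravel().astype(bool)
    if r.shape != t.shape or r.shape != e.shape:
        raise ValueError("risks, times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not e.any():
        raise ValueError("at least one event is required")
    return r, t, e


def _logsumexp_risk_sets(r: np.ndarray, t: np.ndarray):
    """For each sample i, log sum_{j: t_j >= t_i} exp(r_j), plus sort data.

    Computed by sorting times in descending order and running a cumulative
    log-sum-exp, so tied times share one risk set (Breslow).
    """
    order = np.argsort(-t, kind="stable")
    r_s, t_s = r[order], t[order]
    m = r_s.max()
    cum = np.cumsum(np.exp(r_s - m))
    n = len(t_s)
    # tie-block boundaries: every member of a tie block shares the block's
    # last cumsum position (full Breslow risk set including all tied samples)
    last_idx = np.arange(n)
    for i in range(n - 2, -1, -1):
        if t_s[i] == t_s[i + 1]:
            last_idx[i] = last_idx[i + 1]
    first_idx = np.arange(n)
    for i in range(1, n):
        if t_s[i] == t_s[i - 1]:
            first_idx[i] = first_idx[i - 1]
    lse_s = m + np.log(cum[last_idx])
    return order, lse_s, m, last_idx, first_idx


def cox_partial_nll(risks, times, events) -> float:
    """Negative log Cox partial likelihood, averaged over events.

    loss = -(1/m) * sum_{i: event} [ r_i - log sum_{j: T_j >= T_i} exp(r_j) ]
    with Breslow handling of ties (tied samples share the full risk set).
    Raises if no event is present.
    """
    r, t, e = _risk_matrix_terms(risks, times, events)
    order, lse_s, _, _, _ = _logsumexp_risk_sets(r, t)
    e_s = e[order]
    r_s = r[order]
    m_events = e.sum()
    return float(-(r_s[e_s] - lse_s[e_s]).sum() / m_events)


def cox_partial_nll_grad(risks, times, events) -> np.ndarray:
    """Analytic gradient of cox_partial_nll with respect to the risks.

    d loss / d r_k = (1/m) * [ exp(r_k) * sum_{i: event, T_k >= T_i} 1/S_i
                               - event_k ]
    where S_i is the risk-set sum of exp(r) at event i.
    """
    r, t, e = _risk_matrix_terms(risks, times, events)
    order, lse_s, mmax, _last_idx, first_idx = _logsumexp_risk_sets(r, t)
    e_s = e[order]
    n = len(r)
    m_events = e.sum()
    # inv_s[i] = exp(mmax)/S_i at event positions, in descending-time order
    inv_s = np.where(e_s, np.exp(-(lse_s - mmax)), 0.0)
    # sample k belongs to the risk set of event i iff t_i <= t_k, i.e. the
    # event sits at or after the first position of k's tie block in the
    # descending-time order: accumulate inv_s as a suffix sum
    suffix = np.cumsum(inv_s[::-1])[::-1]
    grad_s = np.exp(r[order] - mmax) * suffix[first_idx]
    grad_s -= e_s
    grad = np.empty(n)
    grad[order] = grad_s / m_events
    return grad


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


@dataclass
class _Adam:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvSurvNet:
    """Strided-conv network with an FC-32 feature layer and scalar risk head.

    Parameters
    ----------
    input_edge : patch edge length in pixels.
    channels : output channels of each 3x3 stride-2 conv block.
    feature_width : hidden layer width treated as the feature vector
        (32 by convention across the pipeline).
    lr : Adam learning rate.
    seed : weight-init and shuffling seed; runs are bit-reproducible.
    """

    KERNEL = 3
    STRIDE = 2

    def __init__(
        self,
        input_edge: int = 32,
        channels: tuple[int, ...] = (8, 16, 32),
        feature_width: int = 32,
        lr: float = 1e-4,
        seed: int = 0,
    ):
        self.input_edge = input_edge
        self.channels = tuple(channels)
        self.feature_width = feature_width
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        edge, cin = input_edge, 3
        for i, cout in enumerate(self.channels):
            fan_in = cin * self.KERNEL * self.KERNEL
            self.params[f"W{i}"] = _he_init(
                self.rng, (self.KERNEL, self.KERNEL, cin, cout), fan_in
            )
            self.params[f"b{i}"] = np.zeros(cout)
            edge = (edge - self.KERNEL) // self.STRIDE + 1
            if edge < 1:
                raise ValueError("input_edge too small for the conv stack")
            cin = cout
        self.flat_dim = edge * edge * cin
        self.params["Wf"] = _he_init(
            self.rng, (self.flat_dim, feature_width), self.flat_dim
        )
        self.params["bf"] = np.zeros(feature_width)
        self.params["Wr"] = _he_init(self.rng, (feature_width, 1), feature_width)
        self.params["br"] = np.zeros(1)
        self.opt = _Adam(lr=lr)

    # conv forward/backward via sliding windows -------------------------
    def _conv_forward(self, x: np.ndarray, W: np.ndarray, b: np.ndarray):
        k, s = self.KERNEL, self.STRIDE
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, Ho, Wo, Cin, k, k) -> (N, Ho, Wo, k, k, Cin)
        win = np.moveaxis(win, 3, -1)
        cols = win.reshape(*win.shape[:3], -1)
        out = cols @ W.reshape(-1, W.shape[-1]) + b
        return out, cols

    def _conv_backward(self, x_shape, cols, W, dout):
        k, s = self.KERNEL, self.STRIDE
        n, ho, wo, cout = dout.shape
        Wmat = W.reshape(-1, cout)
        dW = (cols.reshape(-1, cols.shape[-1]).T @ dout.reshape(-1, cout)).reshape(
            W.shape
        )
        db = dout.sum(axis=(0, 1, 2))
        dcols = dout @ Wmat.T  # (N,Ho,Wo, k*k*Cin)
        dcols = dcols.reshape(n, ho, wo, k, k, x_shape[-1])
        dx = np.zeros(x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        return dx, dW, db

    def _forward(self, x: np.ndarray, cache: bool = False):
        x = np.asarray(x, dtype=float)
        if x.max() > 1.5:  # uint8 pixel input
            x = x / 255.0
        acts = []
        for i in range(len(self.channels)):
            z, cols = self._conv_forward(x, self.params[f"W{i}"], self.params[f"b{i}"])
            a = np.maximum(z, 0.0)
            acts.append((x.shape, cols, z, a))
            x = a
        flat = x.reshape(x.shape[0], -1)
        zf = flat @ self.params["Wf"] + self.params["bf"]
        feat = np.maximum(zf, 0.0)
        risk = (feat @ self.params["Wr"] + self.params["br"]).ravel()
        if cache:
            return risk, feat, (acts, flat, zf)
        return risk, feat

    def features(self, patches: np.ndarray) -> np.ndarray:
        """Feature-layer activations, shape (n, feature_width)."""
        _, feat = self._forward(np.asarray(patches))
        return feat

    def predict_risk(self, patches: np.ndarray) -> np.ndarray:
        risk, _ = self._forward(np.asarray(patches))
        return risk

    def _backward(self, drisk: np.ndarray, feat: np.ndarray, caches) -> dict:
        acts, flat, zf = caches
        grads: dict[str, np.ndarray] = {}
        drisk = drisk[:, None]
        grads["Wr"] = feat.T @ drisk
        grads["br"] = drisk.sum(axis=0)
        dfeat = drisk @ self.params["Wr"].T
        dzf = dfeat * (zf > 0)
        grads["Wf"] = flat.T @ dzf
        grads["bf"] = dzf.sum(axis=0)
        dflat = dzf @ self.params["Wf"].T
        dx = dflat.reshape(acts[-1][3].shape)
        for i in range(len(self.channels) - 1, -1, -1):
            x_shape, cols, z, _a = acts[i]
            dz = dx * (z > 0)
            dx, dW, db = self._conv_backward(x_shape, cols, self.params[f"W{i}"], dz)
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        return grads

    def fit(
        self,
        patches: np.ndarray,
        times: np.ndarray,
        events: np.ndarray,
        epochs: int = 20,
        batch_size: int | None = None,
    ) -> list[float]:
        """Train on patches labeled with their patient's (time, event).

        Full-batch by default; with batch_size set, per-epoch shuffled
        batches are merged forward until each contains at least one event
        (the partial likelihood is undefined otherwise). Returns the loss
        per epoch.
        """
        patches = np.asarray(patches)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(bool)
        if not events.any():
            raise ValueError("all-censored input: partial likelihood undefined")
        n = len(patches)
        history: list[float] = []
        for _ in range(epochs):
            if batch_size is None or batch_size >= n:
                batches = [np.arange(n)]
            else:
                perm = self.rng.permutation(n)
                raw = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
                batches, pending = [], []
                for b in raw:
                    pending.append(b)
                    cat = np.concatenate(pending)
                    if events[cat].any():
                        batches.append(cat)
                        pending = []
                if pending and batches:
                    batches[-1] = np.concatenate([batches[-1], *pending])
            epoch_loss = 0.0
            for b in batches:
                risk, feat, caches = self._forward(patches[b], cache=True)
                loss = cox_partial_nll(risk, times[b], events[b])
                drisk = cox_partial_nll_grad(risk, times[b], events[b])
                grads = self._backward(drisk, feat, caches)
                self.opt.step(self.params, grads)
                epoch_loss += loss * len(b)
            history.append(epoch_loss / n)
        return history

    # checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        """Save weights and architecture to a single .npz file."""
        meta = dict(
            input_edge=self.input_edge,
            channels=np.array(self.channels),
            feature_width=self.feature_width,
        )
        np.savez(path, **self.params, **{f"meta_{k}": v for k, v in meta.items()})

    @classmethod
    def load(cls, path) -> "ConvSurvNet":
        data = np.load(path)
        net = cls(
            input_edge=int(data["meta_input_edge"]),
            channels=tuple(int(c) for c in data["meta_channels"]),
            feature_width=int(data["meta_feature_width"]),
        )
        for k in net.params:
            net.params[k] = data[k]
        return net
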