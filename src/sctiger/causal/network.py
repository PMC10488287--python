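"""Per-target attention-based dilated depthwise causal convolution network.

One network is trained per target series j. The learnable attention vector
is multiplied element-wise with the N input series; a stack of depthwise
(per-channel) dilated causal convolutions with PReLU activations and
residual connections (after every layer except the first) follows, and a
pointwise 1x1 combination produces the one-step prediction of the target.

The exogenous channels i != j may see inputs up to time t when predicting
position t; the autoregressive channel i == j is pre-shifted one step so it
only sees its own past. Left context is zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag


@dataclass
class ADDSTCNConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the published operating point: kernel size K=4, dilation
    coefficient c=4, L=2 hidden layers (so dilations 1, c, c^2), Adam at
    learning rate 1e-2 for 5000 epochs, and permutation-importance
    acceptance ratio 0.8.
    """

    kernel_size: int = 4
    dilation_c: int = 4
    layers: int = 2
    epochs: int = 5000
    learning_rate: float = 1e-2
    pi_ratio: float = 0.8
    pi_shuffles: int = 1
    pi_aggregate: str = "mean"  # "mean" or "all" across shuffles
    pi_reference: str = "final"  # compare delta to "final" loss or to the
    # "improvement" (first - final); the latter suits smooth, strongly
    # self-predictable series where the absolute final loss is tiny
    seed: int = 0
    use_gpu: bool = False

    def __post_init__(self) -> None:
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if self.dilation_c < 1:
            raise ValueError("dilation_c must be >= 1")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.pi_ratio <= 1):
            raise ValueError("pi_ratio must lie in (0, 1]")
        if self.pi_shuffles < 1:
            raise ValueError("pi_shuffles must be >= 1")
        if self.pi_aggregate not in ("mean", "all"):
            raise ValueError("pi_aggregate must be 'mean' or 'all'")
        if self.pi_reference not in ("final", "improvement"):
            raise ValueError("pi_reference must be 'final' or 'improvement'")


def receptive_field(cfg: ADDSTCNConfig) -> int:
    """Positions of input history that can influence one output position.

    Equals ``1 + (K - 1) * sum_{l=0..L} c**l`` for kernel size K, dilation
    coefficient c and L hidden layers (L + 1 convolution layers in total).
    """
    K, c, L = cfg.kernel_size, cfg.dilation_c, cfg.layers
    return 1 + (K - 1) * sum(c**l for l in range(L + 1))


class ADDSTCN:
    """The trainable per-target network. ``n_inputs`` channels, target ``j``."""

    def __init__(
        self,
        n_inputs: int,
        target: int,
        cfg: ADDSTCNConfig,
        rng: np.random.Generator,
        channel_rngs: list[np.random.Generator] | None = None,
    ):
        if n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        self.n = n_inputs
        self.j = target
        self.cfg = cfg
        K = cfg.kernel_size
        n_layers = cfg.layers + 1

        # every per-channel parameter is drawn from that channel's own rng so
        # a row permutation of the inputs permutes the initialization with it
        if channel_rngs is None:
            channel_rngs = rng.spawn(n_inputs)
        bound = 1.0 / np.sqrt(K)
        pbound = 1.0 / np.sqrt(n_inputs)
        tap_vals = np.zeros((n_layers, K, n_inputs))
        bias_vals = np.zeros((n_layers, n_inputs))
        pw_vals = np.zeros(n_inputs)
        for i, crng in enumerate(channel_rngs):
            for l in range(n_layers):
                tap_vals[l, :, i] = crng.uniform(-bound, bound, size=K)
                bias_vals[l, i] = crng.uniform(-bound, bound)
            pw_vals[i] = crng.uniform(-pbound, pbound)

        self.attention = ag.Tensor(np.ones((n_inputs, 1)), requires_grad=True)
        # taps[l][k]: (n, 1) depthwise weight for tap k of layer l (k=0 oldest)
        self.taps: list[list[ag.Tensor]] = []
        self.biases: list[ag.Tensor] = []
        self.alphas: list[ag.Tensor] = []
        for l in range(n_layers):
            self.taps.append([
                ag.Tensor(tap_vals[l, k].reshape(-1, 1), requires_grad=True)
                for k in range(K)
            ])
            self.biases.append(ag.Tensor(bias_vals[l].reshape(-1, 1), requires_grad=True))
            self.alphas.append(ag.Tensor(np.array(0.25), requires_grad=True))
        self.pointwise = ag.Tensor(pw_vals.reshape(-1, 1), requires_grad=True)
        self.out_bias = ag.Tensor(np.array(0.0), requires_grad=True)

    @property
    def params(self) -> list[ag.Tensor]:
        ps: list[ag.Tensor] = [self.attention]
        for l in range(len(self.taps)):
            ps.extend(self.taps[l])
            ps.append(self.biases[l])
            ps.append(self.alphas[l])
        ps.extend([self.pointwise, self.out_bias])
        return ps

    # -- forward ----------------------------------------------------------

    def _causal_input(self, X: np.ndarray) -> np.ndarray:
        """Shift the autoregressive channel one step into the past."""
        Xc = np.asarray(X, dtype=np.float64).copy()
        if 0 <= self.j < self.n:
            Xc[self.j, 1:] = Xc[self.j, :-1]
            Xc[self.j, 0] = 0.0
        return Xc

    def forward(self, X: np.ndarray) -> ag.Tensor:
        """Predict all T positions of the target series; returns (1, T)."""
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in input series")
        if X.shape[1] == 0:
            raise ValueError("zero-length series")
        K, c = self.cfg.kernel_size, self.cfg.dilation_c
        h = ag.mul(self.attention, ag.Tensor(self._causal_input(X)))
        for l in range(self.cfg.layers + 1):
            d = c**l
            z = None
            for k in range(K):
                term = ag.mul(self.taps[l][k], ag.shift_right(h, (K - 1 - k) * d))
                z = term if z is None else ag.add(z, term)
            z = ag.add(z, self.biases[l])
            z = ag.prelu(z, self.alphas[l])
            h = z if l == 0 else ag.add(z, h)
        return ag.add(ag.sum_channels(ag.mul(self.pointwise, h)), self.out_bias)

    def loss(self, X: np.ndarray, target_series: np.ndarray) -> ag.Tensor:
        return ag.mse(self.forward(X), target_series.reshape(1, -1))

    def evaluate(self, X: np.ndarray, target_series: np.ndarray) -> float:
        """MSE without building gradients (inputs treated as constants)."""
        return float(self.loss(X, target_series).data)

    def attention_scores(self) -> np.ndarray:
        return self.attention.data.ravel().copy()

    def first_layer_kernel(self, channel: int) -> np.ndarray:
        """Tap weights (oldest first) of the dilation-1 layer for one channel."""
        return np.array([t.data[channel, 0] for t in self.taps[0]])
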