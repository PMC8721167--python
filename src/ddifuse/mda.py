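"""Multimodal deep autoencoder (MDA) fusing the topological networks.

Each of the five networks gets its own sigmoid encoder branch (m -> d_j);
the branch codes are concatenated and passed through L shared sigmoid
integration layers down to the unified bottleneck (d_u), whose activations
are the unified drug embedding. The decoder mirrors the encoder: L shared
layers back to the concatenation width, then per-network branches (-> d_j
-> m, both sigmoid) reconstructing each input network. All parameters are
trained jointly by Adam on the summed per-network mean-squared
reconstruction error.

Because the final sigmoid lives in (0, 1) while PPMI values are unbounded,
inputs are min-max scaled to [0, 1] per network first (``scale_networks``);
the scaling parameters are recorded so a run is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import MDAConfig
from .netembed import PPMINetwork
from .nn import Adam, Dense, Dropout, Sequential, Sigmoid

logger = logging.getLogger("ddifuse")


@dataclass
class UnifiedEmbedding:
    """Fused per-drug representation; rows are drugs, entries in (0, 1)."""

    values: np.ndarray  # (m, d_u)
    drug_ids: tuple[str, ...] | None = None

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def scale_networks(
    nets: list[PPMINetwork],
) -> tuple[list[np.ndarray], dict[str, tuple[float, float]]]:
    """Min-max scale each network to [0, 1] independently.

    Returns the scaled matrices and a {source: (min, max)} record. A constant
    network scales to all zeros with a warning.
    """
    scaled, record = [], {}
    for k, net in enumerate(nets):
        v = np.asarray(net.values, dtype=float)
        if (v < 0).any():
            raise ValueError("network scaling expects nonnegative matrices")
        lo, hi = float(v.min()), float(v.max())
        name = net.source_name or f"net{k}"
        if hi == lo:
            logger.warning("network %s is constant; scaled to all zeros", name)
            scaled.append(np.zeros_like(v))
        else:
            scaled.append((v - lo) / (hi - lo))
        record[name] = (lo, hi)
    return scaled, record


def _trunk_dims(width_in: int, width_out: int, n_layers: int) -> list[int]:
    """Layer widths interpolating geometrically from width_in to width_out."""
    if n_layers < 1:
        raise ValueError("need at least one integration layer")
    ratio = width_out / width_in
    return [max(1, round(width_in * ratio ** (l / n_layers))) for l in range(1, n_layers + 1)]


class MDAModel:
    """Branch encoders + shared trunk + mirrored decoder, with training log."""

    def __init__(self, m: int, n_nets: int, embed_dim: int, unified_dim: int,
                 integration_layers: int, dropout: float, rng: np.random.Generator):
        self.m, self.n_nets = m, n_nets
        self.embed_dim, self.unified_dim = embed_dim, unified_dim
        self.integration_layers = integration_layers
        concat_dim = n_nets * embed_dim

        def block(n_in: int, n_out: int) -> list:
            layers: list = [Dense(n_in, n_out, rng), Sigmoid()]
            if dropout > 0:
                layers.append(Dropout(dropout, rng))
            return layers

        self.branch_enc = [Sequential(block(m, embed_dim)) for _ in range(n_nets)]
        enc_dims = _trunk_dims(concat_dim, unified_dim, integration_layers)
        dims = [concat_dim, *enc_dims]
        self.trunk_enc = Sequential(
            [lyr for a, b in zip(dims[:-1], dims[1:]) for lyr in block(a, b)]
        )
        dec_dims = [unified_dim, *enc_dims[-2::-1], concat_dim]
        self.trunk_dec = Sequential(
            [lyr for a, b in zip(dec_dims[:-1], dec_dims[1:]) for lyr in block(a, b)]
        )
        self.branch_dec1 = [
            Sequential([Dense(concat_dim, embed_dim, rng), Sigmoid()])
            for _ in range(n_nets)
        ]
        self.branch_dec2 = [
            Sequential([Dense(embed_dim, m, rng), Sigmoid()]) for _ in range(n_nets)
        ]
        self.training_log: list[float] = []
        self.scaling: dict[str, tuple[float, float]] = {}

    # -- parameter plumbing --------------------------------------------------

    def _modules(self) -> list[Sequential]:
        return [*self.branch_enc, self.trunk_enc, self.trunk_dec,
                *self.branch_dec1, *self.branch_dec2]

    def params(self) -> list[np.ndarray]:
        return [p for mod in self._modules() for p in mod.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for mod in self._modules() for g in mod.grads()]

    # -- forward / backward --------------------------------------------------

    def _check_inputs(self, x_list: list[np.ndarray]) -> list[np.ndarray]:
        if len(x_list) != self.n_nets:
            raise ValueError(f"expected {self.n_nets} networks, got {len(x_list)}")
        x_list = [np.asarray(x, dtype=float) for x in x_list]
        widths = {x.shape[1] for x in x_list}
        if widths != {self.m}:
            raise ValueError(f"network widths {widths} do not match model m={self.m}")
        if len({x.shape[0] for x in x_list}) != 1:
            raise ValueError("networks disagree on the number of drug rows")
        return x_list

    def forward(self, x_list: list[np.ndarray], training: bool):
        """Return (reconstructions, bottleneck H_c,L)."""
        x_list = self._check_inputs(x_list)
        codes = [enc.forward(x, training) for enc, x in zip(self.branch_enc, x_list)]
        h = np.concatenate(codes, axis=1)
        h_bottleneck = self.trunk_enc.forward(h, training)
        h_dec = self.trunk_dec.forward(h_bottleneck, training)
        recons = [
            d2.forward(d1.forward(h_dec, training), training)
            for d1, d2 in zip(self.branch_dec1, self.branch_dec2)
        ]
        return recons, h_bottleneck

    def loss_and_grads(
        self, x_list: list[np.ndarray], training: bool = True
    ) -> tuple[float, list[np.ndarray]]:
        """Summed per-network MSE and its gradient for every parameter."""
        x_list = self._check_inputs(x_list)
        recons, _ = self.forward(x_list, training)
        n = x_list[0].shape[0]
        loss = sum(float(np.mean((r - x) ** 2)) for r, x in zip(recons, x_list))
        grad_hdec = 0.0
        for r, x, d1, d2 in zip(recons, x_list, self.branch_dec1, self.branch_dec2):
            g = 2.0 * (r - x) / r.size
            grad_hdec = grad_hdec + d1.backward(d2.backward(g))
        grad_h = self.trunk_enc.backward(self.trunk_dec.backward(grad_hdec))
        d = self.embed_dim
        for j, enc in enumerate(self.branch_enc):
            enc.backward(grad_h[:, j * d:(j + 1) * d])
        return loss, self.grads()

    def loss(self, x_list: list[np.ndarray]) -> float:
        recons, _ = self.forward(x_list, training=False)
        return sum(float(np.mean((r - x) ** 2)) for r, x in zip(recons, x_list))


def train_mda(
    nets: list[np.ndarray],
    config: MDAConfig,
    seed: int,
    source_names: list[str] | None = None,
) -> tuple[MDAModel, UnifiedEmbedding]:
    """Train the autoencoder on min-max-scaled networks; deterministic in seed.

    ``nets`` are m x m matrices already scaled to [0, 1] (see
    ``scale_networks``). Returns the trained model and the bottleneck
    activations on the full input.
    """
    nets = [np.asarray(x, dtype=float) for x in nets]
    shapes = {x.shape for x in nets}
    if len(shapes) != 1:
        raise ValueError(f"networks disagree on shape: {shapes}")
    m = nets[0].shape[0]
    for x in nets:
        if x.min() < 0 or x.max() > 1:
            raise ValueError("train_mda expects networks scaled to [0, 1]")
    rng = np.random.default_rng(seed)
    model = MDAModel(m, len(nets), config.embed_dim, config.unified_dim,
                     config.integration_layers, config.dropout, rng)
    opt = Adam(model.params(), model.grads(), lr=config.lr)
    for epoch in range(config.epochs):
        perm = rng.permutation(m)
        epoch_losses = []
        for start in range(0, m, config.batch_size):
            idx = perm[start:start + config.batch_size]
            batch = [x[idx] for x in nets]
            loss, _ = model.loss_and_grads(batch, training=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite reconstruction loss at epoch {epoch}")
            opt.step()
            epoch_losses.append(loss)
        model.training_log.append(float(np.mean(epoch_losses)))
    return model, encode(model, nets)


def encode(model: MDAModel, nets: list[np.ndarray],
           drug_ids: tuple[str, ...] | None = None) -> UnifiedEmbedding:
    """Deterministic forward pass to the unified bottleneck."""
    _, h = model.forward([np.asarray(x, dtype=float) for x in nets], training=False)
    return UnifiedEmbedding(h, drug_ids)
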