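"""Convolutional variational autoencoder over dynamism tensors.

Each frame's 2-channel binary dynamism tensor is embedded into a
d-dimensional latent space by a convolutional VAE:

* encoder — four convolutional layers with f filters of kernel 1×7, stride 2
  along the protein-atom axis and 1 along the row axis, valid convolutions
  (no padding, no pooling), ReLU activations; a flatten feeds two affine
  heads producing the latent mean and log-variance;
* decoder — mirror image built from transposed convolutions whose per-layer
  output lengths are read off the encoder's shape trace so the reconstruction
  matches the input shape exactly; sigmoid output;
* loss — summed binary cross-entropy reconstruction plus the KL divergence
  of the latent Gaussian against the standard normal (unit weight), trained
  with RMSProp (lr 0.005) for up to 600 epochs with early stopping after 10
  epochs without strict improvement of the training loss.

Because the kernel is 1 row tall and the row stride is 1, the convolution
never mixes the contact and change channels ("the convolutions between
contacts and dynamism are kept separated"): the two channels are stacked as
image rows and every layer slides along the protein axis only.

The implementation is pure numpy with hand-written gradients; all random
draws (init, shuffling, reparameterization noise) come from one seeded
generator, so a fixed seed reproduces the loss history bit for bit at a
fixed BLAS thread count. Embeddings used downstream are the latent means,
not samples, for determinism.

An ensemble of six architectures — f ∈ {32, 64} × d ∈ {3, 5, 10} — is
trained per atom subtype; downstream metrics are averaged over the ensemble
and their spread serves as an agreement score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dynamism import DynamismSeries, flatten_whole_molecule
from .exceptions import ConfigurationError

__all__ = [
    "CVAEConfig",
    "LatentEmbedding",
    "ConvVAE",
    "build_cvae",
    "train_cvae",
    "build_ensemble",
    "conv_trace",
    "min_input_length",
    "DEFAULT_FILTER_GRID",
    "DEFAULT_LATENT_GRID",
]

DEFAULT_FILTER_GRID = (32, 64)
DEFAULT_LATENT_GRID = (3, 5, 10)


@dataclass(frozen=True)
class CVAEConfig:
    """Hyperparameters of one CVAE architecture."""

    filters: int = 32
    latent_dim: int = 5
    kernel_length: int = 7
    stride: int = 2
    n_conv_layers: int = 4
    learning_rate: float = 0.005
    max_epochs: int = 600
    patience: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filters < 1 or self.latent_dim < 1:
            raise ConfigurationError("filters and latent_dim must be >= 1")
        if self.kernel_length < 1 or self.stride < 1 or self.n_conv_layers < 1:
            raise ConfigurationError("kernel, stride and layer count must be >= 1")


@dataclass
class LatentEmbedding:
    """Per-frame latent mean vectors from one trained architecture."""

    vectors: np.ndarray  # (T, d)
    model_tag: tuple  # (filters, latent_dim, seed)
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


def conv_trace(
    length: int, kernel: int = 7, stride: int = 2, n_layers: int = 4
) -> list[int]:
    """Per-layer lengths [L0..Ln] under valid convolution; errors if infeasible."""
    trace = [length]
    for _ in range(n_layers):
        L = trace[-1]
        if L < kernel:
            raise ConfigurationError(
                f"input length {length} cannot survive {n_layers} valid "
                f"stride-{stride} kernel-{kernel} convolutions; minimum length "
                f"is {min_input_length(kernel, stride, n_layers)}"
            )
        trace.append((L - kernel) // stride + 1)
    return trace


def min_input_length(kernel: int = 7, stride: int = 2, n_layers: int = 4) -> int:
    """Smallest protein-axis length surviving the encoder stack."""
    L = 1
    for _ in range(n_layers):
        L = (L - 1) * stride + kernel
    return L


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class ConvVAE:
    """Numpy CVAE; see module docstring for the architecture."""

    def __init__(self, config: CVAEConfig, input_shape: tuple[int, ...]):
        if len(input_shape) == 3:
            channels, rows, M = input_shape
        elif len(input_shape) == 2:
            channels, (rows, M) = 1, input_shape
        else:
            raise ConfigurationError("input_shape must be (channels, rows, M)")
        self.config = config
        self.rows = channels * rows  # kernel is 1 row tall: fold channels into rows
        self.M = int(M)
        k, s, f = config.kernel_length, config.stride, config.filters
        self.trace = conv_trace(self.M, k, s, config.n_conv_layers)
        self.flat_dim = self.rows * self.trace[-1] * f
        self.rng = np.random.default_rng(config.seed)
        d = config.latent_dim

        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i in range(config.n_conv_layers):
            self.params[f"Wc{i}"] = _glorot(self.rng, k * c_in, f, (k * c_in, f))
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            c_in = f
        D = self.flat_dim
        self.params["Wmu"] = _glorot(self.rng, D, d, (D, d))
        self.params["bmu"] = np.zeros(d, dtype=np.float32)
        self.params["Wlv"] = _glorot(self.rng, D, d, (D, d))
        self.params["blv"] = np.zeros(d, dtype=np.float32)
        self.params["Wd"] = _glorot(self.rng, d, D, (d, D))
        self.params["bd"] = np.zeros(D, dtype=np.float32)
        # transposed convs mirror the encoder: f->f (x3), f->1
        for i in range(config.n_conv_layers):
            c_out = 1 if i == config.n_conv_layers - 1 else f
            self.params[f"Wt{i}"] = _glorot(self.rng, k * f, c_out, (k, f, c_out))
            self.params[f"bt{i}"] = np.zeros(c_out, dtype=np.float32)
        self._opt_state = {name: np.zeros_like(p) for name, p in self.params.items()}

    # ---- primitive layers -------------------------------------------------

    @staticmethod
    def _conv_fwd(X, W, b, k, s):
        B, R, L, C = X.shape
        Lp = (L - k) // s + 1
        idx = (np.arange(Lp) * s)[:, None] + np.arange(k)
        cols = X[:, :, idx, :].reshape(B, R, Lp, k * C)
        return cols @ W + b, cols

    @staticmethod
    def _conv_bwd(dY, cols, X_shape, W, k, s):
        B, R, L, C = X_shape
        Lp = dY.shape[2]
        F = W.shape[1]
        dW = cols.reshape(-1, k * C).T @ dY.reshape(-1, F)
        db = dY.sum(axis=(0, 1, 2))
        dcols = (dY @ W.T).reshape(B, R, Lp, k, C)
        dX = np.zeros(X_shape, dtype=dY.dtype)
        pos = np.arange(Lp) * s
        for j in range(k):
            dX[:, :, pos + j, :] += dcols[:, :, :, j, :]
        return dX, dW, db

    @staticmethod
    def _tconv_fwd(X, W, b, k, s, L_out):
        B, R, L, C = X.shape
        F = W.shape[2]
        Y = np.zeros((B, R, L_out, F), dtype=X.dtype)
        pos = np.arange(L) * s
        for j in range(k):
            Y[:, :, pos + j, :] += X @ W[j]
        return Y + b

    @staticmethod
    def _tconv_bwd(dY, X, W, k, s):
        B, R, L, C = X.shape
        F = W.shape[2]
        dX = np.zeros_like(X)
        dW = np.zeros_like(W)
        pos = np.arange(L) * s
        Xr = X.reshape(-1, C)
        for j in range(k):
            sl = dY[:, :, pos + j, :]
            dX += sl @ W[j].T
            dW[j] = Xr.T @ sl.reshape(-1, F)
        db = dY.sum(axis=(0, 1, 2))
        return dX, dW, db

    # ---- forward / backward ----------------------------------------------

    def _encode_batch(self, X, keep_cache: bool = False):
        cfg = self.config
        k, s = cfg.kernel_length, cfg.stride
        A = X[..., None]  # (B, rows, M, 1)
        cache = []
        for i in range(cfg.n_conv_layers):
            Z, cols = self._conv_fwd(A, self.params[f"Wc{i}"], self.params[f"bc{i}"], k, s)
            mask = Z > 0
            A_next = Z * mask
            if keep_cache:
                cache.append((A.shape, cols, mask))
            A = A_next
        B = X.shape[0]
        H = A.reshape(B, self.flat_dim)
        mu = H @ self.params["Wmu"] + self.params["bmu"]
        logvar = H @ self.params["Wlv"] + self.params["blv"]
        return mu, logvar, H, cache

    def encode(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Latent mean vectors for inputs of shape (T, rows, M)."""
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, X.shape[0], chunk):
            mu, _, _, _ = self._encode_batch(X[start : start + chunk])
            out.append(mu)
        return np.concatenate(out, axis=0)

    def _decode_batch(self, z, keep_cache: bool = False):
        cfg = self.config
        k, s, f = cfg.kernel_length, cfg.stride, cfg.filters
        B = z.shape[0]
        Hd = z @ self.params["Wd"] + self.params["bd"]
        mask_d = Hd > 0
        A = (Hd * mask_d).reshape(B, self.rows, self.trace[-1], f)
        cache = []
        n = cfg.n_conv_layers
        for i in range(n):
            L_out = self.trace[n - 1 - i]
            Z = self._tconv_fwd(A, self.params[f"Wt{i}"], self.params[f"bt{i}"], k, s, L_out)
            if i < n - 1:
                mask = Z > 0
                A_next = Z * mask
                if keep_cache:
                    cache.append((A, mask))
                A = A_next
            else:
                if keep_cache:
                    cache.append((A, None))
                logits = Z[..., 0]  # (B, rows, M)
        return logits, mask_d, Hd, cache

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction (decoder applied to the latent mean)."""
        X = np.asarray(X, dtype=np.float32)
        mu, _, _, _ = self._encode_batch(X)
        logits, _, _, _ = self._decode_batch(mu)
        from scipy.special import expit

        return expit(logits)

    def _loss_and_grads(self, X: np.ndarray, eps: np.ndarray):
        cfg = self.config
        k, s, f = cfg.kernel_length, cfg.stride, cfg.filters
        B = X.shape[0]
        n = cfg.n_conv_layers
        p = self.params

        mu, logvar, H, enc_cache = self._encode_batch(X, keep_cache=True)
        logvar = np.clip(logvar, -15.0, 15.0)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        logits, mask_d, Hd, dec_cache = self._decode_batch(z, keep_cache=True)

        # numerically stable BCE from logits: softplus(l) - x*l
        bce = float(np.sum(np.logaddexp(0.0, logits) - X * logits))
        kl = float(0.5 * np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar))
        loss = (bce + kl) / B

        grads: dict[str, np.ndarray] = {}
        from scipy.special import expit

        sig = expit(logits)
        dY = ((sig - X) / B)[..., None].astype(np.float32)  # (B, rows, M, 1)
        # decoder backward; dec_cache[i] = (layer input, relu mask of its output)
        for i in range(n - 1, -1, -1):
            A_in, _ = dec_cache[i]
            dA, dW, db = self._tconv_bwd(dY, A_in, p[f"Wt{i}"], k, s)
            grads[f"Wt{i}"] = dW
            grads[f"bt{i}"] = db
            if i > 0:
                dY = dA * dec_cache[i - 1][1]
            else:
                dA0 = dA
        dHd = dA0.reshape(B, -1) * mask_d
        grads["Wd"] = z.T @ dHd
        grads["bd"] = dHd.sum(axis=0)
        dz = dHd @ p["Wd"].T
        dmu = dz + mu / B
        dlv = dz * 0.5 * (z - mu) + 0.5 * (np.exp(logvar) - 1.0) / B
        grads["Wmu"] = H.T @ dmu
        grads["bmu"] = dmu.sum(axis=0)
        grads["Wlv"] = H.T @ dlv
        grads["blv"] = dlv.sum(axis=0)
        dH = dmu @ p["Wmu"].T + dlv @ p["Wlv"].T
        dA = dH.reshape(B, self.rows, self.trace[-1], f)
        for i in range(n - 1, -1, -1):
            X_shape, cols, mask = enc_cache[i]
            dZ = dA * mask
            dA, dW, db = self._conv_bwd(dZ, cols, X_shape, p[f"Wc{i}"], k, s)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return loss * B, grads  # summed loss for epoch bookkeeping

    def _train_step(self, X: np.ndarray, eps: np.ndarray) -> float:
        loss_sum, grads = self._loss_and_grads(X, eps)
        lr = self.config.learning_rate
        for name, g in grads.items():
            v = self._opt_state[name]
            v *= 0.9
            v += 0.1 * g * g
            self.params[name] -= (lr * g / (np.sqrt(v) + 1e-8)).astype(np.float32)
        return loss_sum


def build_cvae(config: CVAEConfig, input_shape: tuple[int, ...]) -> ConvVAE:
    """Build an untrained CVAE for inputs of shape (channels, rows, M)."""
    return ConvVAE(config, input_shape)


def _as_training_array(dyn) -> np.ndarray:
    if isinstance(dyn, DynamismSeries):
        X = flatten_whole_molecule(dyn)
    else:
        X = np.asarray(dyn)
        if X.ndim == 4:
            T, c, r, M = X.shape
            X = X.reshape(T, c * r, M)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("CVAE inputs must be binary (BCE reconstruction loss)")
    return X.astype(np.float32)


def train_cvae(
    model: ConvVAE, dyn, config: CVAEConfig | None = None
) -> tuple[ConvVAE, LatentEmbedding]:
    """Train a CVAE on a dynamism series and embed every frame.

    Training stops at ``max_epochs`` or after ``patience`` epochs without a
    strict decrease of the epoch training loss. Returns the trained model and
    the per-frame latent means.
    """
    cfg = config or model.config
    X = _as_training_array(dyn)
    T = X.shape[0]
    if T < 100:
        warnings.warn(
            f"only {T} frames; density clustering with the default minimum "
            "cluster size of 50 may label everything noise",
            stacklevel=2,
        )
    rng = model.rng
    best = np.inf
    wait = 0
    history: list[float] = []
    bs = min(cfg.batch_size, T)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(T)
        total = 0.0
        for start in range(0, T, bs):
            batch = X[order[start : start + bs]]
            eps = rng.standard_normal(
                (batch.shape[0], cfg.latent_dim)
            ).astype(np.float32)
            total += model._train_step(batch, eps)
        epoch_loss = total / T
        history.append(float(epoch_loss))
        if epoch_loss < best:
            best = epoch_loss
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    vectors = model.encode(X).astype(np.float64)
    tag = (cfg.filters, cfg.latent_dim, cfg.seed)
    return model, LatentEmbedding(vectors=vectors, model_tag=tag, loss_history=history)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def build_ensemble(
    subtype_dyn,
    filters: Sequence[int] = DEFAULT_FILTER_GRID,
    latent_dims: Sequence[int] = DEFAULT_LATENT_GRID,
    base_seed: int = 0,
    base_config: CVAEConfig | None = None,
) -> list[LatentEmbedding]:
    """Train one CVAE per (f, d) grid point; default grid gives 6 embeddings.

    Seeds are derived deterministically from ``base_seed`` and the grid
    position, so the whole ensemble is reproducible from one integer.
    """
    X = _as_training_array(subtype_dyn)
    T, rows, M = X.shape
    base = base_config or CVAEConfig()
    embeddings = []
    for gi, f in enumerate(filters):
        for gj, d in enumerate(latent_dims):
            cfg = replace(
                base, filters=int(f), latent_dim=int(d),
                seed=derive_seed(base_seed, gi, gj),
            )
            model = ConvVAE(cfg, (1, rows, M))
            _, emb = train_cvae(model, X, cfg)
            embeddings.append(emb)
    return embeddings
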