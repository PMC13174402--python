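"""Per-layer dimensionality reduction and feature integration.

Four complementary channels produce, for each omics layer, a compact
``n x m_k`` representation that is then column-concatenated into one
integrated feature matrix ``H`` per channel:

* ``DAE`` — denoising autoencoder: a single ReLU bottleneck trained to
  reconstruct the clean input from a masking-corrupted copy (squared
  error, L1/L2 weight penalties), full-batch Adam.
* ``SAE`` — sparse autoencoder: same architecture without corruption but
  with an L1 penalty on the mean absolute bottleneck activation.
* ``PCA`` — scores on the top-m variance-ordered principal components.
* ``ICA`` — FastICA source estimates under unit-variance whitening.

Every layer is standardized feature-wise before reduction so that
heterogeneous omics scales cannot dominate; all four channels are
deterministic given (data, config, seed).  The autoencoders are trained
full-batch: at the benchmark scale (a few hundred samples) mini-batching
would only add a stochasticity source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .exceptions import TrainingError, ValidationError
from .simdata import MultiOmicsDataset

__all__ = [
    "DimRedConfig",
    "IntegratedFeatures",
    "METHODS",
    "standardize",
    "fit_transform_pca",
    "fit_transform_ica",
    "fit_transform_dae",
    "fit_transform_sae",
    "reduce_and_concat",
]

METHODS = ("DAE", "SAE", "PCA", "ICA")

# Default reduced dimension per layer, per channel.  The autoencoders use a
# maximally narrow bottleneck so reconstruction pressure concentrates on the
# dominant (signal-bearing) variance direction of each layer; PCA keeps a
# few leading components; ICA estimates a wider unit-variance source set,
# as is conventional.
DEFAULT_M = {"DAE": 1, "SAE": 1, "PCA": 3, "ICA": 4}


@dataclass
class DimRedConfig:
    """Settings for one dimensionality-reduction channel.

    ``m_per_layer`` may be a single int (same width for every layer),
    one int per layer, or None for the channel default (``DEFAULT_M``).
    The autoencoder fields are ignored by the linear channels;
    ``hidden_widths`` is reserved for deeper encoders and unused by the
    single-bottleneck architecture.
    """

    method: str = "PCA"
    m_per_layer: int | list[int] | None = None
    epochs: int = 500
    hidden_widths: tuple[int, ...] = ()
    corruption_rate: float = 0.2
    sparsity_strength: float = 1e-3
    l1_weight: float = 1e-5
    l2_weight: float = 1e-5
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (0.0 <= self.corruption_rate < 1.0):
            raise ValidationError("corruption_rate must lie in [0, 1)")
        for name in ("sparsity_strength", "l1_weight", "l2_weight"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")

    def m_for_layer(self, k: int, n_layers: int) -> int:
        if self.m_per_layer is None:
            return DEFAULT_M[self.method]
        if isinstance(self.m_per_layer, int):
            return self.m_per_layer
        if len(self.m_per_layer) != n_layers:
            raise ValidationError(
                f"m_per_layer has {len(self.m_per_layer)} entries for "
                f"{n_layers} layers")
        return int(self.m_per_layer[k])


@dataclass
class IntegratedFeatures:
    """Concatenated low-dimensional representation H for one channel."""

    H: np.ndarray
    method: str
    layer_offsets: list[tuple[int, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.H)):
            raise ValidationError("integrated feature matrix has non-finite entries")
        if self.layer_offsets[-1][1] != self.H.shape[1]:
            raise ValidationError("layer_offsets do not partition the columns")


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise standardization: mean 0, unit variance where defined.

    Zero-variance columns map to all-zeros (they carry no information and
    would otherwise divide by zero).  Idempotent up to float tolerance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("standardize expects a 2-d matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("standardize: input has non-finite entries")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mean
    positive = sd > 0
    out[:, positive] /= sd[positive]
    out[:, ~positive] = 0.0
    return out


def fit_transform_pca(matrix: np.ndarray, m: int) -> np.ndarray:
    """Scores on the top-``m`` principal components of the standardized input."""
    X = standardize(matrix)
    n, p = X.shape
    if not (1 <= m <= min(n - 1, p)):
        raise ValidationError(
            f"PCA components m={m} out of range [1, {min(n - 1, p)}]")
    return PCA(n_components=m, svd_solver="full").fit_transform(X)


def fit_transform_ica(matrix: np.ndarray, m: int, seed: int = 0,
                      return_info: bool = False):
    """FastICA source estimates (unit-variance whitening) on standardized input.

    Non-convergence of the fixed-point iteration is not fatal: the
    warning is captured and reported in the info dict; if the estimate
    itself is unusable (non-finite) the whitened PCA scores are returned
    instead, flagged as a fallback.
    """
    X = standardize(matrix)
    n, p = X.shape
    if not (1 <= m <= min(n, p)):
        raise ValidationError(
            f"ICA components m={m} out of range [1, {min(n, p)}]")
    info = {"converged": True, "fallback": False}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(n_components=m, whiten="unit-variance",
                      random_state=int(seed) % (2**31), max_iter=500)
        S = ica.fit_transform(X)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        info["converged"] = False
    if not np.all(np.isfinite(S)):
        # whitened PCA scores: unit-variance decorrelated projection
        scores = PCA(n_components=m, svd_solver="full").fit_transform(X)
        S = scores / scores.std(axis=0, keepdims=True)
        info.update(converged=False, fallback=True)
    return (S, info) if return_info else S


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _train_autoencoder(X: np.ndarray, m: int, config: DimRedConfig,
                       corruption_rate: float, sparsity_strength: float,
                       seed: int) -> tuple[np.ndarray, list[float]]:
    """Single-bottleneck ReLU autoencoder trained with full-batch Adam.

    Encoder and decoder share tied weights (decoder = encoder transpose),
    which stabilises training of narrow bottlenecks and anchors the
    learnt subspace to the dominant variance structure.  Returns the
    bottleneck activations of the clean input and the per-epoch loss
    history.  The reconstruction target is always the uncorrupted input;
    corruption (masking entries to zero) is redrawn every epoch.
    """
    n, p = X.shape
    if not (1 <= m < p):
        raise ValidationError(f"bottleneck m={m} must satisfy 1 <= m < p={p}")
    rng = np.random.default_rng(seed)
    # single precision: training is bandwidth-bound and the bottleneck
    # subspace is insensitive to the extra mantissa bits
    X = X.astype(np.float32)
    W = rng.normal(0.0, np.sqrt(2.0 / p), size=(p, m)).astype(np.float32)
    b1 = np.full(m, 0.1, dtype=np.float32)  # positive: keeps ReLU units live
    b2 = np.zeros(p, dtype=np.float32)
    params = [W, b1, b2]
    moments = [(np.zeros_like(w), np.zeros_like(w)) for w in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    l1, l2 = config.l1_weight, config.l2_weight
    losses: list[float] = []

    for epoch in range(config.epochs):
        if corruption_rate > 0:
            Xin = X * (rng.random((n, p), dtype=np.float32) >= corruption_rate)
        else:
            Xin = X
        pre = Xin @ W + b1
        hid = _relu(pre)
        out = hid @ W.T + b2
        resid = out - X
        recon = float(np.mean(resid**2))
        loss = (recon
                + l1 * np.abs(W).sum()
                + l2 * (W**2).sum()
                + sparsity_strength * float(np.abs(hid).mean()))
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite autoencoder loss at epoch {epoch}",
                epoch=epoch, learning_rate=lr)
        losses.append(loss)

        gout = 2.0 * resid / resid.size
        gb2 = gout.sum(axis=0)
        ghid = gout @ W
        if sparsity_strength > 0:
            ghid = ghid + sparsity_strength * np.sign(hid) / hid.size
        gpre = ghid * (pre > 0)
        gW = (Xin.T @ gpre + (hid.T @ gout).T  # encoder + decoder paths
              + l1 * np.sign(W) + 2.0 * l2 * W)
        gb1 = gpre.sum(axis=0)

        t = epoch + 1
        for w, g, (mom, vel) in zip(params, [gW, gb1, gb2], moments):
            mom *= beta1
            mom += (1 - beta1) * g
            vel *= beta2
            vel += (1 - beta2) * g**2
            mhat = mom / (1 - beta1**t)
            vhat = vel / (1 - beta2**t)
            w -= lr * mhat / (np.sqrt(vhat) + eps)

    return _relu(X @ W + b1).astype(np.float64), losses


def fit_transform_dae(matrix: np.ndarray, m: int, config: DimRedConfig,
                      return_losses: bool = False):
    """Denoising-autoencoder bottleneck features (standardizes internally)."""
    X = standardize(matrix)
    H, losses = _train_autoencoder(
        X, m, config, corruption_rate=config.corruption_rate,
        sparsity_strength=0.0, seed=config.seed)
    return (H, losses) if return_losses else H


def fit_transform_sae(matrix: np.ndarray, m: int, config: DimRedConfig,
                      return_losses: bool = False):
    """Sparse-autoencoder bottleneck features (standardizes internally)."""
    X = standardize(matrix)
    H, losses = _train_autoencoder(
        X, m, config, corruption_rate=0.0,
        sparsity_strength=config.sparsity_strength, seed=config.seed)
    return (H, losses) if return_losses else H


def _layer_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def reduce_and_concat(dataset: MultiOmicsDataset, method: str | None = None,
                      config: DimRedConfig | None = None) -> IntegratedFeatures:
    """Apply one channel to every layer and concatenate the results.

    The channel is applied independently per layer with its own child
    seed; columns are concatenated in layer order and ``layer_offsets``
    records each layer's column span in H.
    """
    config = config if config is not None else DimRedConfig(method=method or "PCA")
    method = method or config.method
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    K = dataset.n_layers
    blocks, offsets, meta = [], [], {}
    start = 0
    for k, layer in enumerate(dataset.layers):
        m_k = config.m_for_layer(k, K)
        seed_k = _layer_seed(config.seed, k)
        try:
            if method == "PCA":
                block = fit_transform_pca(layer, m_k)
            elif method == "ICA":
                block, info = fit_transform_ica(layer, m_k, seed=seed_k,
                                                return_info=True)
                meta[f"layer_{k + 1}_ica"] = info
            else:
                layer_config = DimRedConfig(**{**config.__dict__,
                                               "method": method,
                                               "seed": seed_k})
                fit = fit_transform_dae if method == "DAE" else fit_transform_sae
                block = fit(layer, m_k, layer_config)
        except Exception as err:
            raise type(err)(f"layer {k + 1}: {err}") from err
        blocks.append(block)
        offsets.append((start, start + m_k))
        start += m_k
    return IntegratedFeatures(H=np.hstack(blocks), method=method,
                              layer_offsets=offsets, meta=meta)
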