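"""Synthetic multi-omics benchmark data with a planted subtype structure.

The generator emulates a standard multi-omics subtyping benchmark: three
omics layers measured on the same 200 samples, 1000 features per layer,
and four equally sized subtypes (50 samples each).  Within each layer a
small fraction of "signal" features carries a block-constant mean that
depends on the sample's subtype; every entry (signal or background) is
perturbed by i.i.d. Gaussian noise with variance sigma^2.  No single
layer separates all four subtypes — only the combination of the three
block patterns identifies the planted partition, which is what makes the
benchmark a genuine integration problem.

Scenarios SimData1/2/3 differ only in the fraction of signal features
(6%, 8%, 10%); noise levels low/moderate/high set sigma^2 to 2, 4, 8.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "SimulationConfig",
    "MultiOmicsDataset",
    "SCENARIOS",
    "NOISE_LEVELS",
    "DEFAULT_BLOCK_MEANS",
    "build_scenario",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# Per-layer block structure: list of (sample ranges, block mean), ranges are
# 0-based half-open [start, stop).  Layer 1 splits (1-50 | 51-150 | 151-200),
# layer 2 (1-50 & 101-150 | 51-100 | 151-200), layer 3 (1-100 | 101-150 |
# 151-200); the intersection of the three patterns yields four subtypes of 50.
BlockSpec = list[tuple[list[tuple[int, int]], float]]

DEFAULT_BLOCK_MEANS: list[BlockSpec] = [
    [([(0, 50)], 1.0), ([(50, 150)], 0.0), ([(150, 200)], 3.0)],
    [([(0, 50), (100, 150)], 0.0), ([(50, 100)], 2.0), ([(150, 200)], 3.0)],
    [([(0, 100)], 2.0), ([(100, 150)], 1.0), ([(150, 200)], 3.0)],
]

SCENARIOS = {"SimData1": 0.06, "SimData2": 0.08, "SimData3": 0.10}
NOISE_LEVELS = {"low": 2.0, "moderate": 4.0, "high": 8.0}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic benchmark scenario."""

    signal_fraction: float
    noise_variance: float
    n_samples: int = 200
    subtype_sizes: tuple[int, ...] = (50, 50, 50, 50)
    n_features_per_layer: int = 1000
    layer_block_means: list[BlockSpec] = field(
        default_factory=lambda: [list(b) for b in DEFAULT_BLOCK_MEANS])
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subtype_sizes) != self.n_samples:
            raise ConfigurationError(
                f"subtype_sizes sum to {sum(self.subtype_sizes)}, "
                f"expected n_samples={self.n_samples}")
        if not (0.0 < self.signal_fraction <= 1.0):
            raise ConfigurationError(
                f"signal_fraction must lie in (0, 1], got {self.signal_fraction}")
        if self.noise_variance <= 0.0:
            raise ConfigurationError(
                f"noise_variance must be positive, got {self.noise_variance}")
        if self.n_signal_features < 1:
            raise ConfigurationError(
                "signal_fraction * n_features_per_layer rounds below 1")
        for k, blocks in enumerate(self.layer_block_means):
            covered = np.zeros(self.n_samples, dtype=int)
            for ranges, _mean in blocks:
                for start, stop in ranges:
                    covered[start:stop] += 1
            if not np.all(covered == 1):
                raise ConfigurationError(
                    f"layer {k + 1}: blocks must cover every sample exactly once")

    @property
    def n_signal_features(self) -> int:
        return int(round(self.signal_fraction * self.n_features_per_layer))

    @property
    def n_layers(self) -> int:
        return len(self.layer_block_means)

    def true_labels(self) -> np.ndarray:
        """Subtype index (1-based) per sample, in sample order."""
        return np.repeat(np.arange(1, len(self.subtype_sizes) + 1),
                         self.subtype_sizes)


@dataclass
class MultiOmicsDataset:
    """K aligned sample-by-feature matrices plus optional true subtype labels."""

    layers: list[np.ndarray]
    sample_ids: list[str]
    true_labels: np.ndarray | None = None
    layer_names: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for k, layer in enumerate(self.layers):
            if layer.ndim != 2 or layer.shape[0] != n:
                raise ValidationError(
                    f"layer {k + 1} has shape {layer.shape}, expected {n} rows")
            if not np.all(np.isfinite(layer)):
                raise ValidationError(f"layer {k + 1} contains non-finite entries")
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValidationError("true_labels length does not match sample count")
        if self.layer_names is None:
            self.layer_names = [f"layer_{k + 1}" for k in range(len(self.layers))]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def build_scenario(name: str, noise_level: str) -> SimulationConfig:
    """Return the configuration of a named benchmark scenario.

    ``name`` selects the signal-feature fraction (SimData1/2/3 -> 6/8/10%),
    ``noise_level`` the Gaussian noise variance (low/moderate/high -> 2/4/8).
    """
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")
    if noise_level not in NOISE_LEVELS:
        raise ConfigurationError(
            f"unknown noise level {noise_level!r}; "
            f"expected one of {sorted(NOISE_LEVELS)}")
    return SimulationConfig(signal_fraction=SCENARIOS[name],
                            noise_variance=NOISE_LEVELS[noise_level])


def generate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> MultiOmicsDataset:
    """Draw one multi-omics dataset from the planted block-mean model.

    Each layer holds ``round(signal_fraction * p)`` signal features (the
    leading columns) whose entries are the sample's block mean plus
    N(0, sigma^2) noise; the remaining features are pure N(0, sigma^2)
    noise.  A master seed spawns one independent child stream per layer,
    so generation is bit-reproducible and layers are mutually independent.
    """
    if config.noise_variance <= 0.0:
        raise ConfigurationError("noise_variance must be positive")
    master = config.seed if seed is None else seed
    sigma = float(np.sqrt(config.noise_variance))
    n, p = config.n_samples, config.n_features_per_layer
    n_signal = config.n_signal_features

    children = np.random.SeedSequence(master).spawn(config.n_layers)
    layers = []
    for blocks, child in zip(config.layer_block_means, children):
        rng = np.random.default_rng(child)
        X = rng.normal(0.0, sigma, size=(n, p))
        block_mean = np.zeros(n)
        for ranges, mean in blocks:
            for start, stop in ranges:
                block_mean[start:stop] = mean
        X[:, :n_signal] += block_mean[:, None]
        layers.append(X)

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    return MultiOmicsDataset(layers=layers, sample_ids=sample_ids,
                             true_labels=config.true_labels())


def write_dataset(dataset: MultiOmicsDataset, directory: str | os.PathLike) -> list[str]:
    """Write one TSV per layer plus labels.tsv; returns the file paths.

    Matrices are samples-by-features with a header row of feature names and
    the sample ID as first column; floats use shortest-exact repr so a
    write/read round trip is lossless.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, layer in zip(dataset.layer_names, dataset.layers):
        df = pd.DataFrame(
            layer, index=pd.Index(dataset.sample_ids, name="sample_id"),
            columns=[f"f{j + 1}" for j in range(layer.shape[1])])
        path = os.path.join(directory, f"{name}.tsv")
        df.to_csv(path, sep="\t", float_format="%.17g")  # lossless round trip
        paths.append(path)
    labels_path = os.path.join(directory, "labels.tsv")
    if dataset.true_labels is not None:
        pd.DataFrame({"sample_id": dataset.sample_ids,
                      "subtype": dataset.true_labels}).to_csv(
            labels_path, sep="\t", index=False)
        paths.append(labels_path)
    return paths


def read_dataset(directory: str | os.PathLike) -> MultiOmicsDataset:
    """Read a dataset written by :func:`write_dataset` (or any set of
    aligned ``*.tsv`` sample-by-feature matrices plus optional labels.tsv)."""
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"no such directory: {directory}")
    layer_files = sorted(
        f for f in os.listdir(directory)
        if f.endswith(".tsv") and f != "labels.tsv")
    if not layer_files:
        raise ValidationError(f"no layer matrices found in {directory}")
    layers, layer_names = [], []
    sample_ids: list[str] | None = None
    for fname in layer_files:
        df = pd.read_csv(os.path.join(directory, fname), sep="\t", index_col=0,
                         float_precision="round_trip")
        ids = [str(s) for s in df.index]
        if sample_ids is None:
            sample_ids = ids
        elif ids != sample_ids:
            raise ValidationError(
                f"sample IDs in {fname} do not match the other layers")
        layers.append(df.to_numpy(dtype=float))
        layer_names.append(fname[:-len(".tsv")])
    true_labels = None
    labels_path = os.path.join(directory, "labels.tsv")
    if os.path.exists(labels_path):
        lab = pd.read_csv(labels_path, sep="\t")
        lab = lab.set_index(lab.columns[0])
        true_labels = lab.loc[sample_ids].iloc[:, 0].to_numpy()
    return MultiOmicsDataset(layers=layers, sample_ids=sample_ids,
                             true_labels=true_labels, layer_names=layer_names)
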