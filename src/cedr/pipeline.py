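"""End-to-end orchestration and the simulation benchmark.

The full consensus pipeline runs in three stages:

1. each enabled dimensionality-reduction channel (DAE, SAE, PCA, ICA)
   maps every omics layer to a low-dimensional block and concatenates
   the blocks into an integrated matrix H;
2. the robust improper-likelihood clusterer is applied to each H, with
   the cluster number chosen by the Calinski-Harabasz index, yielding
   one base partition per channel (label 0 = noise/outlier);
3. the base partitions are fused by the multinomial mixture-of-partitions
   ensemble, with BIC selecting the number of consensus clusters.

``run_benchmark`` reproduces the simulation study design: for each
scenario x noise-level cell it simulates replicate datasets, runs the
full pipeline plus the four single-channel arms, and scores every
partition against the planted subtypes with NMI/ARI/AMI/ACC.

All randomness derives from one master seed: replicate seeds, per-channel
reduction seeds and clustering seeds are spawned deterministically, so a
rerun with the same inputs and configuration is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, SpectralClustering

from . import __version__
from .dimred import METHODS, DimRedConfig, IntegratedFeatures, reduce_and_concat
from .ensemble import ConsensusResult, build_label_matrix, fit_consensus
from .exceptions import ValidationError
from .metrics import score_partition
from .otrimle import (
    BaseClustering,
    OTRIMLEConstraints,
    calinski_harabasz,
    select_num_clusters,
)
from .simdata import MultiOmicsDataset, build_scenario, generate_dataset

__all__ = ["CEDRConfig", "CEDRResult", "run_cedr", "run_benchmark",
           "benchmark_table"]

logger = logging.getLogger("cedr")

BASE_CLUSTERERS = ("otrimle", "kmeans", "spectral")


def _child_seed(*parts: int) -> int:
    """Deterministic 31-bit child seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class CEDRConfig:
    """Configuration of the full pipeline."""

    methods: tuple[str, ...] = METHODS
    dimred: dict[str, DimRedConfig] = field(default_factory=dict)
    constraints: OTRIMLEConstraints = field(default_factory=OTRIMLEConstraints)
    G_range: tuple[int, int] = (2, 8)
    Q_range: tuple[int, int] = (2, 8)
    otrimle_restarts: int = 5
    n_delta: int = 10
    ensemble_restarts: int = 20
    ensemble_tol: float = 1e-4
    base_clusterer: str = "otrimle"
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValidationError(f"unknown DR method {m!r}")
            self.dimred.setdefault(m, DimRedConfig(method=m))
        if self.base_clusterer not in BASE_CLUSTERERS:
            raise ValidationError(
                f"base_clusterer must be one of {BASE_CLUSTERERS}")
        if self.G_range[0] < 2 or self.G_range[1] < self.G_range[0]:
            raise ValidationError(f"invalid G_range {self.G_range}")
        if self.Q_range[0] < 2 or self.Q_range[1] < self.Q_range[0]:
            raise ValidationError(f"invalid Q_range {self.Q_range}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CEDRConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "dimred" in d:
            d["dimred"] = {m: DimRedConfig(**cfg) if isinstance(cfg, dict) else cfg
                           for m, cfg in d["dimred"].items()}
        if isinstance(d.get("constraints"), dict):
            d["constraints"] = OTRIMLEConstraints(**d["constraints"])
        for key in ("G_range", "Q_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CEDRResult:
    """Full pipeline output: base partitions, consensus, provenance."""

    base: dict[str, BaseClustering]
    features: dict[str, IntegratedFeatures]
    consensus: ConsensusResult
    sample_ids: list[str]
    provenance: dict

    def consensus_labels(self) -> np.ndarray:
        """Consensus labels over all input samples (TRIMMED for outliers)."""
        return self.consensus.full_labels(self.sample_ids)


def _cluster_by_ch(H: np.ndarray, G_values, clusterer: str,
                   seed: int) -> BaseClustering:
    """Ablation arm: k-means or spectral clustering with CH-selected G."""
    best = None
    best_score = -np.inf
    for G in G_values:
        if clusterer == "kmeans":
            labels0 = KMeans(n_clusters=G, n_init=10,
                             random_state=seed).fit_predict(H)
        else:
            labels0 = SpectralClustering(
                n_clusters=G, random_state=seed, affinity="nearest_neighbors",
                n_neighbors=min(10, H.shape[0] - 1)).fit_predict(H)
        labels = labels0 + 1  # no noise class for these clusterers
        score = calinski_harabasz(H, labels) if len(np.unique(labels)) > 1 \
            else -np.inf
        if best is None or score > best_score:
            n = H.shape[0]
            tau = np.zeros((n, G + 1))
            tau[np.arange(n), labels] = 1.0
            best = BaseClustering(labels=labels, tau=tau, G=G, source=clusterer)
            best_score = score
    return best


def run_cedr(dataset: MultiOmicsDataset, config: CEDRConfig | None = None) -> CEDRResult:
    """Run the full three-stage consensus pipeline on one dataset."""
    config = config or CEDRConfig()
    base: dict[str, BaseClustering] = {}
    features: dict[str, IntegratedFeatures] = {}
    G_values = range(config.G_range[0], config.G_range[1] + 1)
    for mi, method in enumerate(config.methods):
        dr_cfg = config.dimred[method]
        dr_cfg = DimRedConfig(**{**dr_cfg.__dict__, "method": method,
                                 "seed": _child_seed(config.seed, 1, mi)})
        try:
            feats = reduce_and_concat(dataset, method, dr_cfg)
        except Exception as err:
            raise type(err)(f"stage 1 ({method}): {err}") from err
        features[method] = feats
        clus_seed = _child_seed(config.seed, 2, mi)
        try:
            if config.base_clusterer == "otrimle":
                _, clustering = select_num_clusters(
                    feats.H, G_values, constraints=config.constraints,
                    seed=clus_seed, n_restarts=config.otrimle_restarts,
                    n_delta=config.n_delta, source=method)
            else:
                clustering = _cluster_by_ch(feats.H, G_values,
                                            config.base_clusterer, clus_seed)
        except Exception as err:
            raise type(err)(f"stage 2 ({method}): {err}") from err
        base[method] = clustering
        logger.debug("channel %s: G=%d, noise=%d", method, clustering.G,
                     int((clustering.labels == 0).sum()))
    try:
        Y = build_label_matrix([base[m] for m in config.methods],
                               sample_ids=list(dataset.sample_ids))
        consensus = fit_consensus(
            Y, Q_range=range(config.Q_range[0], config.Q_range[1] + 1),
            n_restarts=config.ensemble_restarts,
            seed=_child_seed(config.seed, 3), tol=config.ensemble_tol)
    except Exception as err:
        raise type(err)(f"stage 3 (ensemble): {err}") from err
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "version": __version__,
                  "G_per_channel": {m: base[m].G for m in config.methods},
                  "Q": consensus.model.Q,
                  "n_trimmed": len(consensus.trimmed_ids)}
    return CEDRResult(base=base, features=features, consensus=consensus,
                      sample_ids=list(dataset.sample_ids), provenance=provenance)


def score_result(result: CEDRResult, true_labels: np.ndarray) -> pd.DataFrame:
    """Metric rows for the consensus and every single-channel arm.

    Noise (label 0) and trimmed samples enter as their own predicted
    level, penalising over-trimming instead of dropping samples.
    """
    rows = []
    for method, clustering in result.base.items():
        rows.append({"method": method,
                     **score_partition(true_labels, clustering.labels)})
    rows.append({"method": "CEDR",
                 **score_partition(true_labels, result.consensus_labels())})
    return pd.DataFrame(rows)


def run_benchmark(scenarios=("SimData1", "SimData2", "SimData3"),
                  noise_levels=("low", "moderate", "high"),
                  reps: int = 20, seed: int = 0,
                  config: CEDRConfig | None = None) -> pd.DataFrame:
    """Simulation benchmark: replicate datasets scored per method.

    Returns a tidy frame (scenario, noise, replicate, method, NMI, ARI,
    AMI, ACC).  Per-replicate failures are logged and excluded; the
    count of failures is attached as ``df.attrs['n_failed']``.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if isinstance(scenarios, str):
        scenarios = (scenarios,)
    if isinstance(noise_levels, str):
        noise_levels = (noise_levels,)
    base_config = config or CEDRConfig()
    rows = []
    n_failed = 0
    for si, scenario in enumerate(scenarios):
        for ni, noise in enumerate(noise_levels):
            sim_cfg = build_scenario(scenario, noise)
            for rep in range(reps):
                data_seed = _child_seed(seed, 11, si, ni, rep)
                pipe_seed = _child_seed(seed, 13, si, ni, rep)
                try:
                    dataset = generate_dataset(sim_cfg, seed=data_seed)
                    rep_config = CEDRConfig.from_dict(
                        {**base_config.to_dict(), "seed": pipe_seed})
                    result = run_cedr(dataset, rep_config)
                    scores = score_result(result, dataset.true_labels)
                except Exception:  # pragma: no cover - defensive
                    logger.exception("replicate failed: %s/%s rep %d",
                                     scenario, noise, rep)
                    n_failed += 1
                    continue
                scores.insert(0, "scenario", scenario)
                scores.insert(1, "noise", noise)
                scores.insert(2, "replicate", rep)
                rows.append(scores)
    df = pd.concat(rows, ignore_index=True)
    df.attrs["n_failed"] = n_failed
    return df


def benchmark_table(df: pd.DataFrame, metric: str = "NMI") -> pd.DataFrame:
    """Pivot a tidy benchmark frame into a mean(sd) table.

    Rows are methods (consensus first), columns scenario x noise cells.
    """
    order = ["CEDR"] + [m for m in METHODS if m in set(df["method"])]
    noise_order = ["low", "moderate", "high"]
    out = {}
    for (scenario, noise), cell in df.groupby(["scenario", "noise"]):
        stats = cell.groupby("method")[metric].agg(["mean", "std"])
        col = {m: f"{stats.loc[m, 'mean']:.3f}"
                  f"({0.0 if np.isnan(stats.loc[m, 'std']) else stats.loc[m, 'std']:.3f})"
               for m in order if m in stats.index}
        out[(scenario, noise)] = col
    cols = sorted(out, key=lambda sn: (sn[0], noise_order.index(sn[1])))
    table = pd.DataFrame({f"{s} {n} noise": out[(s, n)] for s, n in cols})
    return table.reindex([m for m in order if m in table.index])
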