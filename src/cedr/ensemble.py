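"""Consensus clustering via a mixture of multivariate multinomials.

The S base partitions of n samples form a categorical matrix Y whose
row y_i = (y_i1, ..., y_iS) collects sample i's label under each base
method.  Rows are modelled as draws from a Q-component mixture

    P(y_i) = sum_q alpha_q  prod_l nu_lq(y_il),

i.e. conditionally on the consensus cluster q the base labels are
independent multinomials; nu_lq(j) is the probability that a member of
consensus cluster q receives label j in base partition l.  The model is
fit by EM (best of several Dirichlet-initialised restarts), the number
of consensus clusters Q is selected by BIC, and the consensus partition
is the posterior argmax.  Missing base labels contribute a unit factor
to the likelihood (they are marginalised out).

Noise labels from the robust base clusterer (label 0) are kept as an
ordinary category level, so a sample flagged as an outlier by one
channel still contributes its remaining labels; only samples flagged as
noise by *every* channel are trimmed from the consensus fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import NumericalError, ValidationError
from .otrimle import BaseClustering

__all__ = [
    "TRIMMED",
    "MISSING",
    "LabelMatrix",
    "EnsembleModel",
    "ConsensusResult",
    "build_label_matrix",
    "em_fit",
    "log_likelihood",
    "bic",
    "fit_consensus",
]

TRIMMED = -1  # consensus label for samples trimmed before the ensemble fit
MISSING = -1  # sentinel for a missing base label inside Y

_SMOOTH = 1e-9  # additive smoothing on nu to avoid log(0)


@dataclass
class LabelMatrix:
    """n x S categorical base-partition labels (MISSING = -1 allowed)."""

    Y: np.ndarray
    sample_ids: list[str]
    trimmed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2 or self.Y.shape[0] != len(self.sample_ids):
            raise ValidationError("Y must be n x S with one row per sample id")
        self.column_levels = [
            np.unique(self.Y[:, l][self.Y[:, l] != MISSING])
            for l in range(self.Y.shape[1])]
        if all(len(lev) < 2 for lev in self.column_levels):
            raise ValidationError(
                "at least one base partition must have >= 2 levels")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def S(self) -> int:
        return self.Y.shape[1]

    @property
    def category_counts(self) -> list[int]:
        return [len(lev) for lev in self.column_levels]

    def encoded(self) -> np.ndarray:
        """Y with levels recoded to 0..C(l)-1 per column (MISSING stays -1)."""
        out = np.full_like(self.Y, MISSING)
        for l, levels in enumerate(self.column_levels):
            col = self.Y[:, l]
            obs = col != MISSING
            out[obs, l] = np.searchsorted(levels, col[obs])
        return out


@dataclass
class EnsembleModel:
    """Fitted mixture-of-partitions parameters."""

    Q: int
    alpha: np.ndarray
    nu: list[np.ndarray]  # per column: (Q, C(l)) category probabilities
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    column_levels: list[np.ndarray]
    n_samples: int


@dataclass
class ConsensusResult:
    """Consensus partition with posteriors and trimming bookkeeping."""

    labels: np.ndarray  # per retained sample, in 1..Q
    posteriors: np.ndarray  # n x Q responsibilities E[z_iq]
    model: EnsembleModel
    sample_ids: list[str]
    trimmed_ids: list[str]
    bic_trace: dict[int, float] = field(default_factory=dict)

    def full_labels(self, all_sample_ids: list[str]) -> np.ndarray:
        """Labels over an arbitrary sample list; trimmed samples get TRIMMED."""
        lookup = dict(zip(self.sample_ids, self.labels))
        return np.array([lookup.get(s, TRIMMED) for s in all_sample_ids])


def build_label_matrix(base_clusterings: list[BaseClustering],
                       sample_ids: list[str] | None = None) -> LabelMatrix:
    """Stack base partitions into a label matrix, trimming all-noise samples.

    Noise labels (0) become an ordinary category level in their column;
    a sample labelled noise by every base clustering carries no grouping
    information at all and is removed (recorded in ``trimmed_ids``).
    """
    if not base_clusterings:
        raise ValidationError("no base clusterings supplied")
    n = len(base_clusterings[0].labels)
    for bc in base_clusterings:
        if len(bc.labels) != n:
            raise ValidationError("base clusterings cover different sample sets")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    Y = np.column_stack([np.asarray(bc.labels) for bc in base_clusterings])
    all_noise = np.all(Y == 0, axis=1)
    trimmed = [sample_ids[i] for i in np.flatnonzero(all_noise)]
    keep = ~all_noise
    if not keep.any():
        raise ValidationError("every sample was noise in every base partition")
    return LabelMatrix(Y=Y[keep],
                       sample_ids=[s for s, k in zip(sample_ids, keep) if k],
                       trimmed_ids=trimmed)


def _one_hot(Y_enc: np.ndarray, counts: list[int]) -> np.ndarray:
    """(n, sum C(l)) indicator matrix; missing entries are all-zero blocks."""
    n = Y_enc.shape[0]
    X = np.zeros((n, sum(counts)))
    offset = 0
    for l, C in enumerate(counts):
        col = Y_enc[:, l]
        obs = col != MISSING
        X[np.flatnonzero(obs), offset + col[obs]] = 1.0
        offset += C
    return X


def _em_single(X: np.ndarray, counts: list[int], Q: int,
               rng: np.random.Generator, tol: float, max_iter: int):
    """One EM run from a flat-Dirichlet initialisation."""
    n = X.shape[0]
    alpha = rng.dirichlet(np.ones(Q))
    lognu = np.empty((sum(counts), Q))
    offset = 0
    for C in counts:
        lognu[offset:offset + C] = np.log(
            rng.dirichlet(np.ones(C), size=Q).T)
        offset += C
    loglik_prev = -np.inf
    trace = []
    converged = False
    z = None
    for it in range(max_iter):
        # E-step: log responsibilities; missing labels contribute factor 1
        logr = np.log(alpha)[None, :] + X @ lognu
        row_logsum = logsumexp(logr, axis=1)
        loglik = float(row_logsum.sum())
        if not np.isfinite(loglik):
            raise NumericalError("non-finite ensemble log-likelihood")
        trace.append(loglik)
        z = np.exp(logr - row_logsum[:, None])
        if abs(loglik - loglik_prev) < tol:
            converged = True
            break
        loglik_prev = loglik
        # M-step
        alpha = z.mean(axis=0)
        weighted = X.T @ z  # (sum C, Q) responsibility-weighted counts
        offset = 0
        for C in counts:
            block = weighted[offset:offset + C] + _SMOOTH
            lognu[offset:offset + C] = np.log(block / block.sum(axis=0))
            offset += C
    nu_blocks = []
    offset = 0
    for C in counts:
        nu_blocks.append(np.exp(lognu[offset:offset + C]).T)  # (Q, C)
        offset += C
    return alpha, nu_blocks, trace, z, converged


def em_fit(Y: LabelMatrix, Q: int, seed: int = 0, tol: float = 1e-4,
           max_iter: int = 500, n_restarts: int = 20) -> EnsembleModel:
    """Fit the Q-component multinomial mixture; best of ``n_restarts`` runs.

    Parameters are initialised from flat Dirichlet draws; EM stops when
    the log-likelihood change between consecutive iterations falls below
    ``tol`` (default 1e-4).
    """
    if Q < 1:
        raise ValidationError(f"Q must be >= 1, got {Q}")
    if Q > Y.n:
        raise ValidationError(f"Q={Q} exceeds the number of samples {Y.n}")
    counts = Y.category_counts
    X = _one_hot(Y.encoded(), counts)
    seeds = np.random.SeedSequence([int(seed), Q]).generate_state(n_restarts)
    best = None
    for s in seeds:
        rng = np.random.default_rng(int(s))
        alpha, nu, trace, z, converged = _em_single(
            X, counts, Q, rng, tol, max_iter)
        if best is None or trace[-1] > best[2][-1]:
            best = (alpha, nu, trace, z, converged)
    alpha, nu, trace, z, converged = best
    model = EnsembleModel(Q=Q, alpha=alpha, nu=nu, loglik=float(trace[-1]),
                          bic=np.nan, n_iter=len(trace), converged=converged,
                          column_levels=Y.column_levels, n_samples=Y.n)
    model.bic = bic(model, Y)
    return model


def _log_prob_matrix(model: EnsembleModel, Y: LabelMatrix) -> np.ndarray:
    """(n, Q) matrix of log alpha_q + sum_l log nu_lq(y_il)."""
    if len(model.column_levels) != Y.S:
        raise ValidationError("model and label matrix have different S")
    logr = np.broadcast_to(np.log(model.alpha), (Y.n, model.Q)).copy()
    enc = Y.encoded()
    for l in range(Y.S):
        if not np.array_equal(model.column_levels[l], Y.column_levels[l]):
            raise ValidationError(
                f"column {l}: label levels differ from the fitted model")
        col = enc[:, l]
        obs = col != MISSING
        logr[obs] += np.log(model.nu[l][:, col[obs]]).T
    return logr


def log_likelihood(model: EnsembleModel, Y: LabelMatrix) -> float:
    """Direct evaluation of sum_i log sum_q alpha_q prod_l nu_lq(y_il)."""
    return float(logsumexp(_log_prob_matrix(model, Y), axis=1).sum())


def bic(model: EnsembleModel, Y: LabelMatrix) -> float:
    """BIC = -2 loglik + p log n, p = (Q-1) + Q sum_l (C(l)-1).

    Every estimated category level counts, including the noise level
    where a column contains one.
    """
    p = (model.Q - 1) + model.Q * sum(C - 1 for C in Y.category_counts)
    return -2.0 * model.loglik + p * np.log(Y.n)


def fit_consensus(Y: LabelMatrix, Q_range=range(2, 9), n_restarts: int = 20,
                  seed: int = 0, tol: float = 1e-4,
                  max_iter: int = 500) -> ConsensusResult:
    """Fit the ensemble for each Q and keep the minimum-BIC model.

    Ties go to the smallest Q.  Consensus labels are the posterior
    argmax (1-based); trimming bookkeeping is carried through from the
    label matrix.
    """
    Q_values = sorted(set(int(q) for q in Q_range))
    if not Q_values:
        raise ValidationError("empty Q range")
    best_model = None
    bic_trace: dict[int, float] = {}
    for Q in Q_values:
        model = em_fit(Y, Q, seed=seed, tol=tol, max_iter=max_iter,
                       n_restarts=n_restarts)
        bic_trace[Q] = model.bic
        if best_model is None or model.bic < best_model.bic:
            best_model = model
    logr = _log_prob_matrix(best_model, Y)
    post = np.exp(logr - logsumexp(logr, axis=1)[:, None])
    labels = post.argmax(axis=1) + 1  # argmax takes the smallest q on ties
    return ConsensusResult(labels=labels, posteriors=post, model=best_model,
                           sample_ids=list(Y.sample_ids),
                           trimmed_ids=list(Y.trimmed_ids),
                           bic_trace=bic_trace)
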