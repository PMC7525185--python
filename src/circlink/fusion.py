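"""Similarity kernel fusion (SKF) by iterative cross-diffusion.

Given K similarity kernels over one entity set, each kernel is column-
normalized (the anchor) and row-normalized over a top-k neighborhood
(the diffusion operator).  Each kernel's status matrix is then repeatedly
pushed through the other kernels' neighborhoods:

    S_m(t+1) = alpha * F_m @ mean_{r != m} S_r(t) @ F_m^T
               + (1 - alpha) * mean_{r != m} S_r(0)

The fused kernel is the mean of the final status matrices, masked by a
mutual-neighbor weight matrix (1 for mutual neighbors, 0 for mutual
non-neighbors, 0.5 one-sided) and symmetrized.  With alpha in (0,1) the
update is a contraction, so the per-kernel relative change decays
geometrically; the trace of those relative errors is returned alongside
the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateKernelError, NumericalFailureError
from .io_net import SimilarityKernel

STOCHASTIC_TOL = 1e-12


@dataclass(frozen=True)
class SkfConfig:
    """Cross-diffusion parameters.

    alpha balances diffusion against the anchor term; neighbor_count is the
    top-k neighborhood size (clamped to n-1 for small entity sets);
    iterations is fixed rather than tolerance-driven, matching the observed
    fast geometric convergence.
    """

    alpha: float = 0.1
    neighbor_count: int = 36
    iterations: int = 10
    convergence_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.neighbor_count < 1 or self.iterations < 1:
            raise ConfigurationError("neighbor_count and iterations must be >= 1")

    def clamped_neighbors(self, n: int) -> int:
        return min(self.neighbor_count, n - 1)


@dataclass(frozen=True)
class FusionTrace:
    """Relative Frobenius change per kernel per iteration, shape (iters, K)."""

    errors: np.ndarray

    def final(self) -> float:
        """Largest per-kernel relative error at the last iteration."""
        return float(self.errors[-1].max())


@dataclass(frozen=True)
class FusedKernel:
    """The fused similarity kernel with its weight mask and convergence trace."""

    kernel: SimilarityKernel
    weights: np.ndarray = field(repr=False)
    trace: FusionTrace = field(repr=False)


def normalize_kernel(S: np.ndarray, name: str = "kernel") -> np.ndarray:
    """Column-stochastic normalization NS[i,j] = S[i,j] / sum_k S[k,j]."""
    S = np.asarray(S, dtype=float)
    col = S.sum(axis=0)
    dead = np.nonzero(col == 0)[0]
    if dead.size:
        raise DegenerateKernelError(
            f"{name}: all-zero column(s) at positions {dead.tolist()[:5]}"
        )
    return S / col[None, :]


def _neighborhoods(S: np.ndarray, k: int) -> list[np.ndarray]:
    """Top-k neighbor index sets per row, self always included, ties by index."""
    n = S.shape[0]
    hoods = []
    for i in range(n):
        order = np.argsort(-S[i], kind="stable")
        order = order[order != i][:k]
        hoods.append(np.concatenate(([i], order)))
    return hoods


def sparse_kernel(S: np.ndarray, neighbor_count: int, name: str = "kernel") -> np.ndarray:
    """Row-stochastic top-k sparsification F of S (the diffusion operator).

    Each row keeps the entity itself plus its neighbor_count strongest
    neighbors and renormalizes over that support; everything else is zero.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    k = min(neighbor_count, n - 1)
    F = np.zeros_like(S)
    for i, hood in enumerate(_neighborhoods(S, k)):
        mass = S[i, hood].sum()
        if mass == 0:
            raise DegenerateKernelError(f"{name}: row {i} has zero neighborhood mass")
        F[i, hood] = S[i, hood] / mass
    return F


def skf_iterate(
    kernels: list[SimilarityKernel], config: SkfConfig = SkfConfig()
) -> tuple[list[np.ndarray], FusionTrace]:
    """Run the cross-diffusion iteration over K >= 2 kernels.

    Returns the final status matrices and the relative-error trace
    (Frobenius norm of the step change over the norm of the previous state,
    one column per kernel, one row per iteration).
    """
    if len(kernels) < 2:
        raise ConfigurationError("cross-diffusion needs at least 2 kernels")
    shapes = {k.matrix.shape for k in kernels}
    if len(shapes) != 1:
        raise ConfigurationError(f"kernel shapes differ: {shapes}")
    n = kernels[0].n
    K = len(kernels)
    k_neighbors = config.clamped_neighbors(n)

    normalized = [normalize_kernel(k.matrix, k.name) for k in kernels]
    sparse = [sparse_kernel(k.matrix, k_neighbors, k.name) for k in kernels]

    # anchor: mean over the *other* kernels' initial states, fixed throughout
    total0 = np.sum(normalized, axis=0)
    anchors = [(total0 - normalized[m]) / (K - 1) for m in range(K)]

    status = [ns.copy() for ns in normalized]
    errors = np.empty((config.iterations, K))
    for t in range(config.iterations):
        total = np.sum(status, axis=0)
        new_status = []
        for m in range(K):
            cross = (total - status[m]) / (K - 1)
            updated = (
                config.alpha * (sparse[m] @ cross @ sparse[m].T)
                + (1.0 - config.alpha) * anchors[m]
            )
            if not np.isfinite(updated).all():
                raise NumericalFailureError(
                    f"non-finite values in kernel {kernels[m].name!r} at iteration {t + 1}"
                )
            errors[t, m] = np.linalg.norm(updated - status[m]) / np.linalg.norm(
                status[m]
            )
            new_status.append(updated)
        status = new_status
    return status, FusionTrace(errors=errors)


def fuse(
    status: list[np.ndarray],
    neighbor_count: int,
    ids: tuple[str, ...],
    name: str = "fused",
    trace: FusionTrace | None = None,
) -> FusedKernel:
    """Average the status matrices, apply the mutual-neighbor mask, symmetrize.

    The weight w[i,j] is 1 when i and j are in each other's top-k
    neighborhoods of the averaged kernel S (self included), 0 when neither
    is, and 0.5 one-sided; the fused kernel is (w o S) symmetrized.
    """
    S = np.mean(status, axis=0)
    n = S.shape[0]
    k = min(neighbor_count, n - 1)
    member = np.zeros((n, n), dtype=bool)  # member[i,j]: j in N_i
    for i, hood in enumerate(_neighborhoods(S, k)):
        member[i, hood] = True
    w = (member.astype(float) + member.T.astype(float)) / 2.0
    fused = w * S
    fused = (fused + fused.T) / 2.0
    if trace is None:
        trace = FusionTrace(errors=np.zeros((0, len(status))))
    return FusedKernel(
        kernel=SimilarityKernel(matrix=fused, ids=ids, name=name),
        weights=w,
        trace=trace,
    )


def skf_fuse(
    kernels: list[SimilarityKernel],
    config: SkfConfig = SkfConfig(),
    name: str = "fused",
) -> FusedKernel:
    """Normalize, cross-diffuse and fuse a kernel stack in one call."""
    status, trace = skf_iterate(kernels, config)
    n = kernels[0].n
    return fuse(
        status,
        config.clamped_neighbors(n),
        ids=kernels[0].ids,
        name=name,
        trace=trace,
    )


def average_fusion(kernels: list[SimilarityKernel], name: str = "avg") -> SimilarityKernel:
    """Baseline fusion: the element-wise mean of the input kernels."""
    return SimilarityKernel(
        matrix=np.mean([k.matrix for k in kernels], axis=0),
        ids=kernels[0].ids,
        name=name,
    )
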