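"""Laplacian-regularized least-squares (LapRLS) classifiers and score fusion.

The semi-supervised model treats the known 0/1 adjacency as labels and asks
for a score matrix that (i) stays close to the labels and (ii) varies
smoothly over the GIP similarity graph of each side. In each space the
trade-off

    min_F  ||A_side - F||_F^2 + eta * tr(F^T L F)

has the closed-form minimizer F = K (K + eta L K)^{-1} A_side, algebraically
equal to (I + eta L)^{-1} A_side for invertible K, where L is the symmetric
normalized Laplacian of the kernel K. The microbe-space and disease-space
classifiers are fused by a weighted mean (weight ``lw``, default 0.5 = plain
mean) into the final nm x nd score matrix.

Orientation convention: with A the disease x microbe matrix (A = Y^T), the
microbe-space classifier consumes A^T = Y and is nm x nd, the disease-space
classifier consumes A and is nd x nm; the fused matrix is reported nm x nd,
aligned with the adjacency indexes.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .associations import AdjacencyNetwork
from .gip import kernel_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "ScoreMatrix",
    "UnknownDiseaseError",
    "normalized_laplacian",
    "optimal_classifier",
    "combine",
    "predict",
    "rank_candidates",
]

#: relative residual beyond which the direct solve is deemed unreliable
_RESIDUAL_TOL = 1e-8
#: relative singular-value cutoff for the pseudo-inverse fallback
_PINV_RCOND = 1e-10
#: condition number above which a warning is logged
_COND_WARN = 1e12


@dataclass(frozen=True)
class ModelParams:
    """Tunable model parameters.

    eta_m, eta_d
        Nonnegative smoothness/data-fit trade-off weights per space
        (default 1). eta = 0 reproduces the adjacency exactly.
    lw
        Fusion weight in [0, 1] on the microbe-space classifier; 0.5 is the
        plain mean of the two spaces.
    gamma_prime_m, gamma_prime_d
        Raw GIP bandwidths before density normalization (default 1).
    """

    eta_m: float = 1.0
    eta_d: float = 1.0
    lw: float = 0.5
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if self.eta_m < 0 or self.eta_d < 0:
            raise ValueError("eta_m and eta_d must be nonnegative")
        if not 0.0 <= self.lw <= 1.0:
            raise ValueError("lw must lie in [0, 1]")
        if self.gamma_prime_m <= 0 or self.gamma_prime_d <= 0:
            raise ValueError("bandwidths must be positive")


@dataclass
class ScoreMatrix:
    """Predicted association scores, nm x nd, aligned with the network indexes."""

    values: np.ndarray
    microbe_index: list[str]
    disease_index: list[str]


class UnknownDiseaseError(KeyError):
    """Disease name not in the network; carries near matches for the message."""

    def __init__(self, name: str, candidates: list[str]):
        near = difflib.get_close_matches(name, candidates, n=3, cutoff=0.4)
        hint = f"; did you mean {near}?" if near else ""
        super().__init__(f"unknown disease {name!r}{hint}")
        self.near_matches = near


def normalized_laplacian(K: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian L = D^(-1/2) (D - K) D^(-1/2).

    D is the diagonal of row sums of K. Because the GIP kernel has unit
    diagonal and positive entries, every row sum is strictly positive.
    The spectrum lies in [0, 2] and L annihilates the sqrt-degree vector.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel must be symmetric")
    deg = K.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("kernel row sums must be strictly positive")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -K * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, np.diagonal(L) + 1.0)
    return 0.5 * (L + L.T)


def optimal_classifier(
    K: np.ndarray, L: np.ndarray, A_side: np.ndarray, eta: float
) -> np.ndarray:
    """Closed-form LapRLS classifier F = K (K + eta L K)^{-1} A_side.

    Solved through the algebraically reduced, always well-posed system
    (I + eta L) F = A_side: since K (K + eta L K)^{-1} = (I + eta L)^{-1}
    for invertible K, the two agree exactly there, and the reduced form is
    the unique minimizer of the trace-form cost even when K is singular.
    Singular kernels are not hypothetical -- entities with identical
    interaction profiles (e.g. many degree-1 microbes attached to the same
    disease) produce duplicate kernel rows. A linear solve is used, never an
    explicit inverse; an ill-conditioned or failed solve falls back to a
    pseudo-inverse least-squares solution with a logged warning.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    A_side = np.asarray(A_side, dtype=float)
    B = eta * np.asarray(L, dtype=float)
    np.fill_diagonal(B, np.diagonal(B) + 1.0)  # B = I + eta*L, SPD
    try:
        F = scipy.linalg.solve(B, A_side, assume_a="pos")
        resid = np.linalg.norm(B @ F - A_side)
        scale = max(np.linalg.norm(A_side), 1.0)
        if not np.all(np.isfinite(F)) or resid > _RESIDUAL_TOL * scale:
            raise np.linalg.LinAlgError("direct solve unreliable")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        cond = np.linalg.cond(B)
        if cond > _COND_WARN:
            logger.warning(
                "classifier system ill-conditioned (cond=%.3g); "
                "falling back to pseudo-inverse",
                cond,
            )
        F = np.linalg.pinv(B, rcond=_PINV_RCOND) @ A_side
    return F


def combine(FM: np.ndarray, FD: np.ndarray, lw: float = 0.5) -> np.ndarray:
    """Fuse the two space classifiers: F* = lw * FM + (1 - lw) * FD^T.

    ``FM`` is the microbe-space classifier (nm x nd), ``FD`` the
    disease-space classifier (nd x nm); the result is nm x nd.
    """
    FM = np.asarray(FM, dtype=float)
    FD = np.asarray(FD, dtype=float)
    if FM.shape != FD.T.shape:
        raise ValueError(f"incompatible classifier shapes {FM.shape} vs {FD.shape}")
    if not 0.0 <= lw <= 1.0:
        raise ValueError("lw must lie in [0, 1]")
    return lw * FM + (1.0 - lw) * FD.T


def predict(
    network: AdjacencyNetwork, params: ModelParams = ModelParams()
) -> ScoreMatrix:
    """Full pipeline: profiles -> bandwidths -> kernels -> Laplacians ->
    per-space classifiers -> fused nm x nd score matrix.

    Deterministic for a fixed network and parameters.
    """
    Y = np.asarray(network.Y, dtype=float)
    SM, SD = kernel_pair(network, params.gamma_prime_m, params.gamma_prime_d)
    LM = normalized_laplacian(SM)
    LD = normalized_laplacian(SD)
    A = Y.T  # disease x microbe
    FM = optimal_classifier(SM, LM, A.T, params.eta_m)  # nm x nd
    FD = optimal_classifier(SD, LD, A, params.eta_d)  # nd x nm
    F = combine(FM, FD, params.lw)
    return ScoreMatrix(F, list(network.microbe_index), list(network.disease_index))


def scores_long_frame(
    scores: ScoreMatrix,
    network: AdjacencyNetwork,
    include_known: bool = False,
):
    """Long-format score table (microbe, disease, score, known) sorted by
    descending score; known pairs excluded by default (candidates only)."""
    import pandas as pd

    nm, nd = scores.values.shape
    df = pd.DataFrame(
        {
            "microbe": np.repeat(scores.microbe_index, nd),
            "disease": np.tile(scores.disease_index, nm),
            "score": scores.values.ravel(),
            "known": np.asarray(network.Y, dtype=int).ravel(),
        }
    )
    if not include_known:
        df = df[df["known"] == 0]
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def rank_candidates(
    scores: ScoreMatrix,
    network: AdjacencyNetwork,
    disease: str,
    top_k: int | None = 10,
) -> list[tuple[str, float]]:
    """Rank candidate microbes (unknown pairs only) for one disease.

    Microbes already associated with the disease are excluded; the rest are
    sorted by descending score, ties broken by microbe index order. Returns
    at most ``top_k`` (microbe, score) tuples, or all candidates if
    ``top_k`` is None or exceeds the candidate count.
    """
    if disease not in network.disease_index:
        raise UnknownDiseaseError(disease, network.disease_index)
    j = network.disease_pos(disease)
    col = scores.values[:, j]
    known = np.asarray(network.Y[:, j], dtype=bool)
    candidates = [
        (network.microbe_index[i], float(col[i]))
        for i in range(network.nm)
        if not known[i]
    ]
    # stable sort preserves index order among exact ties
    candidates.sort(key=lambda t: -t[1])
    if top_k is not None:
        candidates = candidates[:top_k]
    return candidates
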