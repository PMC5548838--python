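"""Gaussian interaction-profile (GIP) kernel similarity.

Each entity's interaction profile is its 0/1 association vector against the
opposite node set (a row of Y for a microbe, a column for a disease). Two
entities are similar when their profiles are close in squared Euclidean
distance:

    K(i, j) = exp(-gamma * ||IP_i - IP_j||^2)

with the bandwidth normalized by the mean squared profile norm,
gamma = gamma' / mean_i ||IP_i||^2, so that the kernel scale adapts to the
overall density of the network. For 0/1 profiles ||IP_i||^2 is simply the
degree of entity i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .associations import AdjacencyNetwork

__all__ = [
    "DegenerateProfilesError",
    "InteractionProfiles",
    "KernelBandwidth",
    "interaction_profiles",
    "bandwidth",
    "gip_kernel",
    "kernel_pair",
]

Side = Literal["microbe", "disease"]


class DegenerateProfilesError(ValueError):
    """All interaction profiles are zero; the bandwidth is undefined."""


@dataclass
class InteractionProfiles:
    """0/1 profile vectors, one per row, for one side of the network."""

    vectors: np.ndarray
    side: Side

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class KernelBandwidth:
    """Effective bandwidth gamma = gamma' / mean squared profile norm."""

    gamma: float
    gamma_prime: float = 1.0


def interaction_profiles(network: AdjacencyNetwork, side: Side) -> InteractionProfiles:
    """Extract profile vectors: rows of Y (microbes) or columns of Y (diseases)."""
    if side == "microbe":
        return InteractionProfiles(np.asarray(network.Y, dtype=float), "microbe")
    if side == "disease":
        return InteractionProfiles(np.asarray(network.Y, dtype=float).T, "disease")
    raise ValueError(f"side must be 'microbe' or 'disease', got {side!r}")


def bandwidth(profiles: InteractionProfiles, gamma_prime: float = 1.0) -> KernelBandwidth:
    """Normalize the raw bandwidth gamma' by the mean squared profile norm.

    Raises
    ------
    DegenerateProfilesError
        If every profile is zero (mean squared norm 0). A *single* zero
        profile -- e.g. an entity whose only association was masked during
        cross-validation -- is fine.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    sq_norms = np.einsum("ij,ij->i", profiles.vectors, profiles.vectors)
    mean_sq = sq_norms.mean()
    if mean_sq <= 0:
        raise DegenerateProfilesError(
            f"all {profiles.side} profiles are zero; bandwidth undefined"
        )
    return KernelBandwidth(gamma=gamma_prime / mean_sq, gamma_prime=gamma_prime)


def gip_kernel(profiles: InteractionProfiles, bw: KernelBandwidth) -> np.ndarray:
    """Dense GIP kernel matrix K(i,j) = exp(-gamma ||IP_i - IP_j||^2).

    Symmetric with unit diagonal by construction; computed from the Gram
    matrix, with the squared distance clipped at zero to absorb rounding.
    """
    if not np.isfinite(bw.gamma) or bw.gamma <= 0:
        raise ValueError("bandwidth must be finite and positive")
    V = profiles.vectors
    gram = V @ V.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    K = np.exp(-bw.gamma * d2)
    # exact symmetry/unit diagonal, immune to float noise in the Gram route
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def kernel_pair(
    network: AdjacencyNetwork,
    gamma_prime_m: float = 1.0,
    gamma_prime_d: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute (SM, SD): the microbe-side and disease-side GIP kernels of Y."""
    pm = interaction_profiles(network, "microbe")
    pd_ = interaction_profiles(network, "disease")
    SM = gip_kernel(pm, bandwidth(pm, gamma_prime_m))
    SD = gip_kernel(pd_, bandwidth(pd_, gamma_prime_d))
    return SM, SD
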