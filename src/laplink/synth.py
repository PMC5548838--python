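"""Synthetic bipartite association networks for testing and benchmarking.

Two generators cover the statistical roles real curated networks play:

* :func:`random_bipartite` -- i.i.d. Bernoulli edges (an Erdos-Renyi-style
  null with no structure; a sane predictor should score ~0.5 AUC on it);
* :func:`planted_block_network` -- microbes and diseases partitioned into
  co-clusters with dense within-block and sparse cross-block edges (the
  planted structure a similarity-propagation model is supposed to exploit).

Defaults emulate the scale of the genus-level HMDAD curation: 292 microbes,
39 diseases, about 450 distinct associations (density ~0.04).

Every generated network is repaired to have no all-zero row or column (one
uniform edge added per empty line, capped), because an entity appears in a
curated table only if it has at least one association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AdjacencyNetwork

__all__ = ["FixtureSpec", "GenerationError", "random_bipartite", "planted_block_network", "hmdad_like"]

#: HMDAD-scale defaults: 292 microbes x 39 diseases, ~450 distinct pairs
HMDAD_NM = 292
HMDAD_ND = 39
HMDAD_DENSITY = 450 / (292 * 39)

_REPAIR_ROUNDS = 100


class GenerationError(RuntimeError):
    """Generator could not produce a valid network within the retry cap."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic bipartite network.

    For ``n_blocks == 1`` only ``density`` matters; otherwise edges appear
    with probability ``p_in`` inside a (microbe-block, disease-block)
    co-cluster and ``p_out`` across.
    """

    nm: int = HMDAD_NM
    nd: int = HMDAD_ND
    density: float = HMDAD_DENSITY
    n_blocks: int = 1
    p_in: float = 0.6
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nm < 2 or self.nd < 2:
            raise ValueError("need nm, nd >= 2")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_blocks < 1 or self.n_blocks > min(self.nm, self.nd):
            raise ValueError("n_blocks must be in [1, min(nm, nd)]")


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k + 1}" for k in range(n)]


def _repair_empty_lines(Y: np.ndarray, rng: np.random.Generator) -> None:
    """Add one uniform edge to each empty row/column, a few rounds at most."""
    for _ in range(_REPAIR_ROUNDS):
        empty_rows = np.flatnonzero(Y.sum(axis=1) == 0)
        empty_cols = np.flatnonzero(Y.sum(axis=0) == 0)
        if len(empty_rows) == 0 and len(empty_cols) == 0:
            return
        for i in empty_rows:
            Y[i, rng.integers(Y.shape[1])] = 1
        for j in empty_cols:
            Y[rng.integers(Y.shape[0]), j] = 1
    raise GenerationError("could not eliminate empty rows/columns")


def random_bipartite(spec: FixtureSpec) -> AdjacencyNetwork:
    """Unstructured Bernoulli(density) bipartite network; seeded, repaired."""
    if not 0.0 < spec.density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    Y = (rng.random((spec.nm, spec.nd)) < spec.density).astype(np.int8)
    _repair_empty_lines(Y, rng)
    return AdjacencyNetwork(Y, _names("m", spec.nm), _names("d", spec.nd))


def planted_block_network(
    spec: FixtureSpec,
) -> tuple[AdjacencyNetwork, np.ndarray, np.ndarray]:
    """Co-clustered bipartite network.

    Microbes and diseases are assigned round-robin to ``n_blocks`` blocks;
    an edge appears with probability ``p_in`` when the two blocks match and
    ``p_out`` otherwise. Returns the network plus the microbe and disease
    block labels for test assertions.
    """
    rng = np.random.default_rng(spec.seed)
    mb = np.arange(spec.nm) % spec.n_blocks
    db = np.arange(spec.nd) % spec.n_blocks
    same = mb[:, None] == db[None, :]
    P = np.where(same, spec.p_in, spec.p_out)
    Y = (rng.random((spec.nm, spec.nd)) < P).astype(np.int8)
    _repair_empty_lines(Y, rng)
    net = AdjacencyNetwork(Y, _names("m", spec.nm), _names("d", spec.nd))
    return net, mb, db


def hmdad_like(
    seed: int = 0,
    n_blocks: int = 4,
    contrast: float = 9.0,
    popularity_sigma: float = 1.3,
    n_edges: float = 450.0,
) -> AdjacencyNetwork:
    """Synthetic stand-in for a genus-level curated network at HMDAD scale.

    Emulates three first-order features of such curations: the 292 x 39
    scale with ~450 distinct associations; a heavy-tailed disease degree
    distribution (a few intensively studied "hub" diseases carry a large
    share of the literature-curated edges -- modelled by lognormal
    popularity weights with log-sd ``popularity_sigma``); and block-wise
    co-occurrence structure (within-block edge probability ``contrast``
    times the cross-block one). Edge probabilities are rescaled so the
    expected edge count is ``n_edges``.

    It does not emulate taxonomy, per-study reporting correlations, or
    duplicate entries; it is a synthetic benchmark, not a reconstruction
    of any real curation.
    """
    rng = np.random.default_rng(seed)
    nm, nd = HMDAD_NM, HMDAD_ND
    mb = np.arange(nm) % n_blocks
    db = np.arange(nd) % n_blocks
    w = rng.lognormal(0.0, popularity_sigma, nd)
    w /= w.mean()
    P = np.where(mb[:, None] == db[None, :], contrast, 1.0) * w[None, :]
    P *= (n_edges / (nm * nd)) / P.mean()
    Y = (rng.random((nm, nd)) < np.clip(P, 0.0, 1.0)).astype(np.int8)
    _repair_empty_lines(Y, rng)
    return AdjacencyNetwork(Y, _names("m", nm), _names("d", nd))
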