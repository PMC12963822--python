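"""Random walk with restart — the network-propagation comparator.

Scores every gene by its steady-state visiting probability for a walker
that, at each step, either restarts (probability ``r``) at a uniformly
chosen seed gene or moves to a uniformly chosen neighbor:

    p(t+1) = (1 - r) * W^T p(t) + r * p0

with ``W`` the column-normalized adjacency of the undirected graph (the
paired directed edges make this symmetric out-degree normalization) and
``p0`` uniform over the seeds. Degree-0 genes are dangling: their
outgoing mass teleports back to the restart distribution, so the score
vector stays a probability distribution at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .ppi_graph import PPINetwork


@dataclass(frozen=True)
class RWRConfig:
    restart_prob: float = 0.7
    tolerance: float = 1e-8
    max_iter: int = 10000
    seed_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tolerance <= 0 or self.max_iter < 1:
            raise ValueError("tolerance and max_iter must be positive")


def _restart_vector(net: PPINetwork, seeds) -> np.ndarray:
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed gene set is empty")
    p0 = np.zeros(net.n_nodes)
    for g in seeds:
        i = net.node_index.get(g)
        if i is None:
            raise KeyError(f"seed gene {g!r} is not in the network")
        p0[i] = 1.0
    return p0 / p0.sum()


def _transition(net: PPINetwork) -> tuple[sp.csr_matrix, np.ndarray]:
    """(column-normalized adjacency transposed, dangling indicator)."""
    n = net.n_nodes
    deg = net.degrees.astype(float)
    dangling = deg == 0
    inv = np.where(dangling, 0.0, 1.0 / np.maximum(deg, 1.0))
    # entry (dst, src): probability of stepping src -> dst
    WT = sp.csr_matrix(
        (inv[net.edge_src], (net.edge_dst, net.edge_src)), shape=(n, n)
    )
    return WT, dangling


def rwr(net: PPINetwork, config: RWRConfig) -> np.ndarray:
    """Iterate to the stationary distribution; L1 change < tolerance."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    p0 = _restart_vector(net, config.seed_genes)
    r = config.restart_prob
    if r == 1.0:
        return p0.copy()
    WT, dangling = _transition(net)
    p = p0.copy()
    for _ in range(config.max_iter):
        dangling_mass = p[dangling].sum() if dangling.any() else 0.0
        p_next = (1 - r) * (WT @ p + dangling_mass * p0) + r * p0
        if np.abs(p_next - p).sum() < config.tolerance:
            return p_next
        p = p_next
    raise RuntimeError(
        f"RWR did not converge within {config.max_iter} iterations "
        f"(tolerance {config.tolerance})"
    )


def rwr_closed_form(net: PPINetwork, config: RWRConfig) -> np.ndarray:
    """Direct linear solve p = (I - (1-r) M)^-1 r p0 — the testing oracle.

    ``M`` is the transition matrix with dangling columns replaced by the
    restart distribution, matching the iterative treatment exactly.
    """
    p0 = _restart_vector(net, config.seed_genes)
    r = config.restart_prob
    WT, dangling = _transition(net)
    M = WT.toarray()
    if dangling.any():
        M[:, dangling] = p0[:, None]
    n = net.n_nodes
    return np.linalg.solve(np.eye(n) - (1 - r) * M, r * p0)


def sample_seed_genes(features, n: int, seed: int) -> frozenset[str]:
    """Uniform sample (without replacement) of n modified (label-1) genes."""
    positives = sorted({f.gene_id for f in features if f.label == 1})
    if n > len(positives):
        raise ValueError(
            f"asked for {n} seed genes but only {len(positives)} modified "
            "genes are available"
        )
    rng = np.random.default_rng(seed)
    return frozenset(rng.choice(positives, size=n, replace=False).tolist())
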