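"""The merged protein-protein interaction graph the model operates on.

Every undirected interaction is stored as two directed, typed edges of
unit weight, supporting message propagation while preserving the
undirected biology. Node order is lexicographic over symbols so runs are
reproducible across platforms. Degree-preserving randomization (repeated
double-edge swaps) provides the topological null model used by the
robustness benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import EdgeListRecord

logger = logging.getLogger("gatmerip")

SELF_LOOP_TYPE = "__self__"  # reserved edge type appended by the model layer


@dataclass
class PPINetwork:
    """Deduplicated gene interaction graph with paired directed edges.

    ``edge_src``, ``edge_dst`` and ``edge_type`` describe the directed
    edges; for every edge (u, v, t) the reverse (v, u, t) is present and
    all weights are implicitly 1. ``degrees`` is the undirected degree.
    """

    nodes: list[str]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_type: np.ndarray
    edge_type_vocab: list[str]
    node_index: dict[str, int] = field(init=False)
    degrees: np.ndarray = field(init=False)

    def __post_init__(self):
        self.node_index = {g: i for i, g in enumerate(self.nodes)}
        self.edge_src = np.asarray(self.edge_src, dtype=np.intp)
        self.edge_dst = np.asarray(self.edge_dst, dtype=np.intp)
        self.edge_type = np.asarray(self.edge_type, dtype=np.intp)
        deg = np.zeros(len(self.nodes), dtype=np.intp)
        np.add.at(deg, self.edge_src, 1)  # directed pairs -> undirected degree
        self.degrees = deg

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_directed_edges(self) -> int:
        return int(self.edge_src.size)

    @property
    def n_undirected_edges(self) -> int:
        return self.n_directed_edges // 2

    def undirected_edges(self) -> np.ndarray:
        """(m, 3) array of (u, v, type) with u < v, sorted, one per pair."""
        mask = self.edge_src < self.edge_dst
        out = np.column_stack(
            [self.edge_src[mask], self.edge_dst[mask], self.edge_type[mask]]
        )
        return out[np.lexsort((out[:, 1], out[:, 0]))]

    def validate(self) -> None:
        """Check the structural invariants; raise on any violation."""
        if self.edge_src.size != self.edge_dst.size != self.edge_type.size:
            raise ValueError("edge arrays have inconsistent lengths")
        if np.any(self.edge_src == self.edge_dst):
            raise ValueError("stored graph must not contain self-edges")
        fwd = set(zip(self.edge_src.tolist(), self.edge_dst.tolist(),
                      self.edge_type.tolist()))
        if len(fwd) != self.edge_src.size:
            raise ValueError("duplicate directed edges present")
        for u, v, t in fwd:
            if (v, u, t) not in fwd:
                raise ValueError(f"edge ({u}, {v}) lacks its reverse")
        pairs = {(min(u, v), max(u, v)) for u, v, _ in fwd}
        if 2 * len(pairs) != self.edge_src.size:
            raise ValueError("some undirected pair appears with >1 type")


def build_network(
    records: list[EdgeListRecord],
    source_precedence: list[str] | None = None,
) -> PPINetwork:
    """Merge edge records from any number of sources into one network.

    Undirected pairs are deduplicated across sources; a pair reported by
    several databases keeps the type of the highest-precedence source
    (default precedence: order of first appearance in the input). Each
    unique pair expands to two directed edges.
    """
    if not records:
        raise ValueError("cannot build a network from zero interactions")

    vocab: list[str] = list(source_precedence) if source_precedence else []
    for r in records:
        if r.source not in vocab:
            vocab.append(r.source)
    precedence = {s: i for i, s in enumerate(vocab)}

    best: dict[tuple[str, str], str] = {}
    for r in records:
        if r.gene_a == r.gene_b:
            raise ValueError(f"self-interaction {r.gene_a} reached build_network")
        key = (min(r.gene_a, r.gene_b), max(r.gene_a, r.gene_b))
        if key not in best or precedence[r.source] < precedence[best[key]]:
            best[key] = r.source

    nodes = sorted({g for pair in best for g in pair})
    index = {g: i for i, g in enumerate(nodes)}
    src, dst, typ = [], [], []
    for (a, b), source in sorted(best.items()):
        ia, ib, t = index[a], index[b], precedence[source]
        src += [ia, ib]
        dst += [ib, ia]
        typ += [t, t]
    net = PPINetwork(nodes, np.array(src), np.array(dst), np.array(typ), vocab)
    logger.info(
        "built PPI network: %d nodes, %d interactions (%d directed edges), "
        "%d edge types", net.n_nodes, net.n_undirected_edges,
        net.n_directed_edges, len(vocab),
    )
    return net


def align_features(
    net: PPINetwork,
    features,
    dataset_id: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map a dataset's standardized features onto the network's node order.

    Returns (X, y, n_outside): X is (n_nodes, 2) with columns
    (expression_z, m5c_z), y the 0/1 labels. Network nodes missing from
    the feature table receive the Z-value a 0-RPM gene would get under
    that dataset's standardization, and label 0. Feature-table genes not
    in the network are dropped and counted in ``n_outside``.
    """
    from .features import dataset_standardization_stats, _z

    group = [f for f in features if f.dataset_id == dataset_id]
    if not group:
        raise ValueError(f"no features for dataset {dataset_id!r}")
    stats = dataset_standardization_stats(group)
    zero_expr = _z(0.0, stats["expression"])
    zero_m5c = _z(0.0, stats["m5c"])

    X = np.tile([zero_expr, zero_m5c], (net.n_nodes, 1)).astype(float)
    y = np.zeros(net.n_nodes, dtype=np.intp)
    n_outside = 0
    for f in group:
        i = net.node_index.get(f.gene_id)
        if i is None:
            n_outside += 1
            continue
        X[i, 0] = f.expression_z
        X[i, 1] = f.m5c_z
        y[i] = f.label
    if n_outside:
        logger.info(
            "dataset %s: %d feature genes absent from the network (dropped)",
            dataset_id, n_outside,
        )
    if not np.all(np.isfinite(X)):
        raise ValueError(f"dataset {dataset_id}: non-finite standardized features")
    return X, y, n_outside


def align_all(net: PPINetwork, features) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Aligned (X, y) per dataset, keyed by dataset id."""
    datasets = sorted({f.dataset_id for f in features})
    out = {}
    for ds in datasets:
        X, y, _ = align_features(net, features, ds)
        out[ds] = (X, y)
    return out


def degree_preserving_randomize(
    net: PPINetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    max_tries_factor: int = 100,
) -> PPINetwork:
    """Rewire by repeated double-edge swaps, preserving every degree.

    A swap picks two undirected edges (a-b, c-d) and replaces them with
    (a-d, c-b); proposals creating self-edges or duplicating an existing
    edge are rejected and retried, so the graph stays simple and the
    degree multiset, node set and edge count are untouched. Edge types
    travel with their first endpoint. ``n_swaps`` defaults to 10x the
    undirected edge count.
    """
    edges = net.undirected_edges()
    m = edges.shape[0]
    if m < 2:
        raise ValueError("need >= 2 undirected edges to swap")
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps <= 0:
        raise ValueError(f"n_swaps must be positive, got {n_swaps}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = edges[:, 0].tolist()
    v = edges[:, 1].tolist()
    t = edges[:, 2].tolist()
    present = {(a, b) if a < b else (b, a) for a, b in zip(u, v)}

    done = 0
    tries = 0
    max_tries = max_tries_factor * n_swaps
    # draw random numbers in blocks: the python loop dominates otherwise
    block = max(1024, min(1 << 16, 4 * n_swaps))
    idx_buf = rng.integers(0, m, size=(block, 2))
    flip_buf = rng.random(block)
    ptr = 0
    while done < n_swaps:
        if ptr >= block:
            idx_buf = rng.integers(0, m, size=(block, 2))
            flip_buf = rng.random(block)
            ptr = 0
        i, j = int(idx_buf[ptr, 0]), int(idx_buf[ptr, 1])
        flip = flip_buf[ptr] < 0.5
        ptr += 1
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"degree-preserving randomization stalled after {tries} tries "
                f"({done}/{n_swaps} swaps)"
            )
        if i == j:
            continue
        a, b = u[i], v[i]
        c, d = u[j], v[j]
        if flip:  # orient the second edge both ways for mixing
            c, d = d, c
        # propose a-d, c-b
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in present or e2 in present:
            continue
        old1 = (a, b) if a < b else (b, a)
        old2 = (c, d) if c < d else (d, c)
        present.discard(old1)
        present.discard(old2)
        present.add(e1)
        present.add(e2)
        u[i], v[i] = a, d
        u[j], v[j] = c, b
        done += 1

    src, dst, typ = [], [], []
    for a, b, tt in zip(u, v, t):
        src += [a, b]
        dst += [b, a]
        typ += [tt, tt]
    out = PPINetwork(
        list(net.nodes), np.array(src), np.array(dst), np.array(typ),
        list(net.edge_type_vocab),
    )
    assert np.array_equal(out.degrees, net.degrees)
    return out


# ---------------------------------------------------------------------------
# Serialization: directed TSV edge list with a '#types:' vocabulary header
# ---------------------------------------------------------------------------

def write_network(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("#types:" + ",".join(net.edge_type_vocab) + "\n")
        fh.write("#source\ttarget\tedge_type\n")
        order = np.lexsort((net.edge_dst, net.edge_src))
        for k in order:
            fh.write(
                f"{net.nodes[net.edge_src[k]]}\t{net.nodes[net.edge_dst[k]]}"
                f"\t{net.edge_type_vocab[net.edge_type[k]]}\n"
            )


def read_network(path) -> PPINetwork:
    vocab: list[str] | None = None
    directed: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#types:"):
                vocab = line[len("#types:"):].split(",")
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            directed.append((parts[0], parts[1], parts[2]))
    if vocab is None:
        raise ValueError(f"{path}: missing '#types:' header")
    if not directed:
        raise ValueError(f"{path}: no edges")
    type_id = {s: i for i, s in enumerate(vocab)}
    nodes = sorted({g for a, b, _ in directed for g in (a, b)})
    index = {g: i for i, g in enumerate(nodes)}
    src = np.array([index[a] for a, _, _ in directed])
    dst = np.array([index[b] for _, b, _ in directed])
    typ = np.array([type_id[t] for _, _, t in directed])
    net = PPINetwork(nodes, src, dst, typ, vocab)
    net.validate()
    return net
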