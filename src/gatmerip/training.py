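"""Optimization loop and final gene scoring.

All datasets share the PPI topology and the model parameters; each epoch
runs one full-graph forward/backward per dataset with the binary
cross-entropy masked to the (gene, dataset) pairs of the split under
evaluation — the standard transductive protocol. Adam (lr 5e-4, weight
decay 1e-4) drives at most 200 epochs, with early stopping once the
validation loss has not improved for 30 consecutive epochs; the
parameters returned are those of the best validation epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict
from typing import Callable, Sequence

import numpy as np

from ._autodiff import Adam, masked_bce_with_logits
from .gat_model import GATConfig, GATParameters, forward, forward_logits, init_parameters
from .ppi_graph import PPINetwork

logger = logging.getLogger("gatmerip")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    max_epochs: int = 200
    patience: int = 30
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class ScoreRow:
    gene_id: str
    raw_score: float
    minmax_score: float
    z_score: float
    rank: int


class ScoreTable:
    """Per-gene importance scores with Min-Max / Z-score normalizations."""

    def __init__(self, rows: Sequence[ScoreRow]):
        if not rows:
            raise ValueError("empty score table")
        ranks = sorted(r.rank for r in rows)
        if ranks != list(range(1, len(rows) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        self.rows = list(rows)
        self._by_gene = {r.gene_id: r for r in rows}

    @classmethod
    def from_raw(cls, genes: Sequence[str], raw: np.ndarray) -> "ScoreTable":
        """Build from raw scores; degenerate (constant) vectors map to
        minmax 0.5 and z 0 so downstream ranking stays defined."""
        raw = np.asarray(raw, dtype=float)
        if len(genes) != raw.size:
            raise ValueError("genes and scores differ in length")
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            minmax = (raw - lo) / (hi - lo)
        else:
            minmax = np.full_like(raw, 0.5)
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        order = sorted(range(len(genes)), key=lambda i: (-raw[i], genes[i]))
        rank = {i: pos + 1 for pos, i in enumerate(order)}
        rows = [
            ScoreRow(genes[i], float(raw[i]), float(minmax[i]), float(z[i]), rank[i])
            for i in range(len(genes))
        ]
        return cls(rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, gene_id: str) -> ScoreRow:
        return self._by_gene[gene_id]

    @property
    def genes(self) -> list[str]:
        return [r.gene_id for r in self.rows]

    def raw_scores(self) -> dict[str, float]:
        return {r.gene_id: r.raw_score for r in self.rows}

    def sorted_rows(self) -> list[ScoreRow]:
        return sorted(self.rows, key=lambda r: r.rank)

    def top_k(self, k: int) -> list[str]:
        """The k highest-scoring genes (descending raw score, then symbol)."""
        return [r.gene_id for r in self.sorted_rows()[:k]]


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    samples: Sequence[tuple[str, str, int]],
    val_fraction: float,
    seed: int,
) -> tuple[list[tuple[str, str, int]], list[tuple[str, str, int]]]:
    """Split (gene, dataset, label) triples into train/validation.

    Stratified by dataset x label so both the dataset mix and the class
    balance are maintained. Each stratum contributes
    round(val_fraction * size) validation samples, with exact .5 ties
    resolved toward the floor. Disjoint and exhaustive; seeded shuffle.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    strata: dict[tuple[str, int], list[tuple[str, str, int]]] = defaultdict(list)
    for s in samples:
        strata[(s[1], s[2])].append(s)
    rng = np.random.default_rng(seed)
    train: list[tuple[str, str, int]] = []
    val: list[tuple[str, str, int]] = []
    for key in sorted(strata):
        group = sorted(strata[key])
        target = val_fraction * len(group)
        n_val = int(np.floor(target)) if abs(target % 1 - 0.5) < 1e-9 \
            else int(np.floor(target + 0.5))
        if n_val == 0:
            logger.warning(
                "stratum %s too small for a validation share; all %d samples "
                "go to training", key, len(group),
            )
        perm = rng.permutation(len(group))
        val.extend(group[i] for i in perm[:n_val])
        train.extend(group[i] for i in perm[n_val:])
    return train, val


# ---------------------------------------------------------------------------
# Early-stopping loop (generic so the stopping rule is testable in isolation)
# ---------------------------------------------------------------------------

def run_early_stopping_loop(
    epoch_fn: Callable[[int], tuple[float, float, object]],
    max_epochs: int,
    patience: int,
) -> tuple[object, list[tuple[int, float, float]], int, int]:
    """Drive ``epoch_fn(epoch) -> (train_loss, val_loss, state)`` until the
    validation loss stops improving for ``patience`` consecutive epochs or
    ``max_epochs`` is reached (epochs are 1-based).

    Returns (best_state, history, best_epoch, last_epoch). ``best_state``
    is whatever ``epoch_fn`` returned at the minimum-validation-loss epoch
    (first such epoch on exact ties), never a later one.
    """
    best_state = None
    best_val = np.inf
    best_epoch = 0
    history: list[tuple[int, float, float]] = []
    last = 0
    for epoch in range(1, max_epochs + 1):
        train_loss, val_loss, state = epoch_fn(epoch)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append((epoch, float(train_loss), float(val_loss)))
        last = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = state
        if epoch - best_epoch >= patience:
            break
    return best_state, history, best_epoch, last


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    net: PPINetwork,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    gat_config: GATConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[GATParameters, list[tuple[int, float, float]]]:
    """Fit the attention model on aligned multi-dataset features.

    ``data`` maps dataset id -> (X, y) with X the (n_nodes, 2) aligned
    standardized features and y the 0/1 modification labels, both in the
    network's node order. Returns the best parameters (lowest validation
    loss) and the (epoch, train loss, validation loss) history.
    """
    if not data:
        raise ValueError("need at least one dataset")
    tcfg = train_config or TrainConfig()
    gcfg = gat_config or GATConfig(n_edge_types=len(net.edge_type_vocab))
    if gcfg.n_edge_types < len(net.edge_type_vocab):
        raise ValueError(
            f"model configured for {gcfg.n_edge_types} edge types but the "
            f"network has {len(net.edge_type_vocab)}"
        )
    dataset_ids = sorted(data)
    for ds in dataset_ids:
        X, y = data[ds]
        if X.shape != (net.n_nodes, gcfg.in_dim) or y.shape != (net.n_nodes,):
            raise ValueError(f"dataset {ds}: features not aligned to the network")

    samples = [
        (gene, ds, int(data[ds][1][i]))
        for ds in dataset_ids
        for i, gene in enumerate(net.nodes)
    ]
    train_set, val_set = stratified_split(samples, tcfg.val_fraction, tcfg.seed)
    train_mask = {ds: np.zeros(net.n_nodes) for ds in dataset_ids}
    val_mask = {ds: np.zeros(net.n_nodes) for ds in dataset_ids}
    for gene, ds, _ in train_set:
        train_mask[ds][net.node_index[gene]] = 1.0
    for gene, ds, _ in val_set:
        val_mask[ds][net.node_index[gene]] = 1.0

    params = init_parameters(gcfg, seed=tcfg.seed)
    opt = Adam(params.trainable(), lr=tcfg.learning_rate,
               weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed + 1)

    def epoch_fn(epoch: int):
        train_losses = []
        for ds in dataset_ids:
            X, y = data[ds]
            logits = forward_logits(net, X, params, mode="train", rng=rng)
            loss = masked_bce_with_logits(logits, y, train_mask[ds])
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = []
        for ds in dataset_ids:
            X, y = data[ds]
            logits = forward_logits(net, X, params, mode="eval")
            loss = masked_bce_with_logits(logits, y, val_mask[ds])
            val_losses.append(float(loss.data))
        return float(np.mean(train_losses)), float(np.mean(val_losses)), params.copy()

    try:
        best_params, history, best_epoch, last = run_early_stopping_loop(
            epoch_fn, tcfg.max_epochs, tcfg.patience
        )
    except FloatingPointError as exc:
        raise FloatingPointError(f"training diverged: {exc}") from exc
    logger.info(
        "training stopped at epoch %d; best validation loss %.6f at epoch %d",
        last, min(v for _, _, v in history), best_epoch,
    )
    return best_params, history


def score_genes(
    params: GATParameters,
    net: PPINetwork,
    data: dict[str, np.ndarray],
) -> ScoreTable:
    """Deterministic eval-mode scores, averaged across datasets.

    ``data`` maps dataset id -> aligned feature matrix. Each gene's raw
    score is the mean of its per-dataset sigmoid outputs; Min-Max and
    Z-score normalized columns and 1-based ranks are attached.
    """
    if not data:
        raise ValueError("need at least one dataset")
    per_ds = [forward(net, X, params, mode="eval") for _, X in sorted(data.items())]
    raw = np.mean(per_ds, axis=0)
    return ScoreTable.from_raw(net.nodes, raw)
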