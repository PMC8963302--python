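"""Losses, optimizers and the two-phase training loop.

Phase 1 trains the five networks independently by minimizing the in-frame
RMSD between each member's prediction and the true loop coordinates (RAdam,
lr 1e-3, weight decay 1e-3).  Phase 2 adds, with weight 1.0, an L1 loss on
backbone bonded distances computed on the final *averaged* structure — the
term that pushes the combined prediction toward physically plausible
geometry — and switches to Adam at lr 1e-4 with early stopping on a
validation split.

Both losses are means (not sums) over atoms / pair instances / members, so
their scale is comparable across loop lengths.  Losses are computed on
loop-interior atoms only; anchors are inputs, not targets (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, gather_rows
from .egnn import (
    EGNNConfig,
    forward_ensemble,
    init_ensemble,
    initial_coordinates,
    iter_params,
    true_coordinates,
)
from .features import FeatureMatrix, build_graph, encode_nodes
from .structures import LoopRecord


@dataclass(frozen=True)
class BondedPairSchema:
    """The five backbone bonded-pair classes used by the distance L1 loss."""

    classes: tuple[str, ...] = ("CA-CA+1", "CA-CB", "CA-N", "CA-C", "C-N+1")

    # (atom offset in residue i, atom offset in residue i+delta, delta)
    _layout = {
        "CA-CA+1": (0, 0, 1),
        "CA-CB": (0, 3, 0),
        "CA-N": (0, 1, 0),
        "CA-C": (0, 2, 0),
        "C-N+1": (2, 1, 1),
    }

    def pair_indices(
        self,
        loop_atom_slices: dict[str, slice],
        interior_mask: np.ndarray,
        include_anchors: bool = False,
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Resolve every pair instance to flat node indices.

        Cross-residue classes skip the last residue of each loop's selected
        stretch; a 1-residue loop therefore contributes no cross-residue
        instances.
        """
        ia, ib, names = [], [], []
        for lid, sl in loop_atom_slices.items():
            starts = np.arange(sl.start, sl.stop, 4)
            if not include_anchors:
                starts = starts[interior_mask[starts]]
            n = len(starts)
            for cname in self.classes:
                oa, ob, delta = self._layout[cname]
                for i in range(n - delta):
                    ia.append(starts[i] + oa)
                    ib.append(starts[i + delta] + ob)
                    names.append(cname)
        return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), names


@dataclass
class TrainingConfig:
    phase1_lr: float = 1e-3
    phase1_weight_decay: float = 1e-3
    phase2_lr: float = 1e-4
    l1_weight: float = 1.0  # phase 2 only; phase 1 uses 0 by definition
    patience: int = 20
    convergence_tol: float = 1e-3
    max_epochs_phase1: int = 500
    max_epochs_phase2: int = 100
    seed: int = 0
    include_anchors_in_loss: bool = False
    val_fraction: float = 0.2
    stop_below: float | None = None  # stop a phase once validation loss < this


# ---------------------------------------------------------------------------
# Losses (operate on autodiff Tensors; use .data for plain evaluation)
# ---------------------------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def per_network_rmsd_loss(preds, truth: np.ndarray, interior_idx: np.ndarray) -> Tensor:
    """Mean over ensemble members of the in-frame RMSD to the truth.

    ``preds`` is (n_networks, n_nodes, 3) — or (n_nodes, 3) for a single
    network.  No superposition: predictions live in the frame pinned by the
    true anchors, so raw deviation is the trained quantity.
    """
    preds = _as_tensor(preds)
    if preds.data.shape[-2:] != truth.shape[-2:] and preds.data.shape[-1] != 3:
        raise ValueError("prediction/truth shape mismatch")
    diff = gather_rows(preds, interior_idx) - Tensor(truth[interior_idx])
    msd = diff.square().sum(axis=(-1, -2)) / float(len(interior_idx))
    return msd.sqrt().mean()


def bonded_l1_loss(
    averaged,
    truth: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray, list[str]],
) -> Tensor:
    """Mean |d_pred - d_true| over every bonded-pair instance.

    Computed only on the averaged prediction; distances make the loss
    rigid-motion invariant by construction.
    """
    averaged = _as_tensor(averaged)
    ia, ib, _ = pairs
    if averaged.data.shape != truth.shape:
        raise ValueError("shape mismatch between averaged prediction and truth")
    d_pred = (
        (gather_rows(averaged, ia) - gather_rows(averaged, ib))
        .square()
        .sum(axis=-1)
        .sqrt()
    )
    d_true = np.linalg.norm(truth[ia] - truth[ib], axis=1)
    return (d_pred - Tensor(d_true)).abs().mean()


def total_loss(
    preds,
    truth: np.ndarray,
    phase: int,
    interior_idx: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray, list[str]],
    l1_weight: float = 1.0,
) -> Tensor:
    """Phase 1: per-network RMSD.  Phase 2: + l1_weight x bonded L1 on the
    member-averaged structure."""
    if phase not in (1, 2):
        raise ValueError(f"unknown training phase {phase}")
    preds = _as_tensor(preds)
    loss = per_network_rmsd_loss(preds, truth, interior_idx)
    if phase == 2:
        if preds.data.ndim == 3:
            k = preds.data.shape[0]
            avg = preds.sum(axis=0) / float(k)
        else:
            avg = preds
        loss = loss + l1_weight * bonded_l1_loss(avg, truth, pairs)
    return loss


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _direction(self, i: int, g: np.ndarray) -> np.ndarray:
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        m_hat = self.m[i] / (1 - self.b1**self.t)
        v_hat = self.v[i] / (1 - self.b2**self.t)
        return m_hat / (np.sqrt(v_hat) + self.eps)

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            p.data = p.data - self.lr * self._direction(i, g)


class RAdam(Adam):
    """Rectified Adam: warms up the adaptive term by the variance-rectification
    factor; falls back to an un-adapted momentum step while the second-moment
    estimate is unreliable."""

    def _direction(self, i: int, g: np.ndarray) -> np.ndarray:
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        t = self.t
        m_hat = self.m[i] / (1 - self.b1**t)
        rho_inf = 2.0 / (1.0 - self.b2) - 1.0
        rho_t = rho_inf - 2.0 * t * self.b2**t / (1.0 - self.b2**t)
        if rho_t > 4.0:
            v_hat = np.sqrt(self.v[i] / (1 - self.b2**t))
            r = np.sqrt(
                ((rho_t - 4) * (rho_t - 2) * rho_inf)
                / ((rho_inf - 4) * (rho_inf - 2) * rho_t)
            )
            return r * m_hat / (v_hat + self.eps)
        return m_hat


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    fm: FeatureMatrix
    edges: object  # GraphOps
    init: np.ndarray
    truth: np.ndarray
    interior_idx: np.ndarray
    pairs: tuple[np.ndarray, np.ndarray, list[str]]


def _prepare(example: list[LoopRecord], cfg: TrainingConfig,
             egnn_cfg: EGNNConfig) -> _Prepared:
    from .egnn import GraphOps

    fm = encode_nodes(example)
    src, dst = build_graph(fm.n_nodes, fm.loop_atom_slices,
                           per_loop=egnn_cfg.per_loop_graph)
    edges = GraphOps.from_edges(src, dst, fm.n_nodes)
    init = initial_coordinates(example)
    truth = true_coordinates(example)
    mask = fm.interior_mask if not cfg.include_anchors_in_loss else np.ones(
        fm.n_nodes, dtype=bool
    )
    pairs = BondedPairSchema().pair_indices(
        fm.loop_atom_slices, fm.interior_mask, cfg.include_anchors_in_loss
    )
    return _Prepared(fm, edges, init, truth, np.flatnonzero(mask), pairs)


def _epoch_loss(ensemble: dict, prepared: list[_Prepared], phase: int,
                cfg: TrainingConfig, egnn_cfg: EGNNConfig) -> float:
    from .autodiff import no_grad

    vals = []
    with no_grad():
        for prep in prepared:
            pred = forward_ensemble(prep.fm, prep.init, ensemble, egnn_cfg,
                                    prep.edges)
            vals.append(
                total_loss(pred, prep.truth, phase, prep.interior_idx, prep.pairs,
                           cfg.l1_weight).data.item()
            )
    return float(np.mean(vals))


def train(
    dataset: list[list[LoopRecord]],
    cfg: TrainingConfig,
    egnn_cfg: EGNNConfig | None = None,
    validation: list[list[LoopRecord]] | None = None,
) -> tuple[dict, list[dict]]:
    """Two-phase training over examples (each a list of true LoopRecords).

    Returns (ensemble parameters, history).  History rows carry phase, epoch
    and train/validation losses.  The parameters restored at the end of each
    phase are the best-validation checkpoint.  Deterministic given the seeds;
    aborts on a non-finite loss.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    egnn_cfg = egnn_cfg or EGNNConfig()
    rng = np.random.default_rng(cfg.seed)

    if validation is None:
        n_val = max(1, int(round(cfg.val_fraction * len(dataset)))) if len(dataset) > 2 else 0
        perm = rng.permutation(len(dataset))
        val_ids = set(perm[:n_val].tolist())
        validation = [dataset[i] for i in sorted(val_ids)] or dataset
        dataset = [dataset[i] for i in range(len(dataset)) if i not in val_ids]

    ensemble = init_ensemble(egnn_cfg)
    params = iter_params(ensemble)
    train_prep = [_prepare(ex, cfg, egnn_cfg) for ex in dataset]
    val_prep = [_prepare(ex, cfg, egnn_cfg) for ex in validation]

    history: list[dict] = []
    for phase, opt, max_epochs in (
        (1, RAdam(params, cfg.phase1_lr, cfg.phase1_weight_decay), cfg.max_epochs_phase1),
        (2, Adam(params, cfg.phase2_lr), cfg.max_epochs_phase2),
    ):
        best_val = np.inf
        best_state = None
        stale = 0
        for epoch in range(max_epochs):
            order = rng.permutation(len(train_prep))
            batch_losses = []
            for i in order:
                prep = train_prep[i]
                pred = forward_ensemble(prep.fm, prep.init, ensemble, egnn_cfg,
                                        prep.edges)
                loss = total_loss(pred, prep.truth, phase, prep.interior_idx,
                                  prep.pairs, cfg.l1_weight)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at phase {phase} epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(loss.data.item())
            val_loss = _epoch_loss(ensemble, val_prep, phase, cfg, egnn_cfg)
            history.append(
                {
                    "phase": phase,
                    "epoch": epoch,
                    "train_loss": float(np.mean(batch_losses)),
                    "val_loss": val_loss,
                }
            )
            if val_loss < best_val - cfg.convergence_tol:
                best_val = val_loss
                best_state = [p.data.copy() for p in params]
                stale = 0
            else:
                stale += 1
            if cfg.stop_below is not None and val_loss < cfg.stop_below:
                break
            if stale >= cfg.patience:
                break
        if best_state is not None:
            for p, d in zip(params, best_state):
                p.data = d
    return ensemble, history


def evaluate_ensemble_rmsd(
    ensemble: dict,
    dataset: list[list[LoopRecord]],
    cfg: TrainingConfig,
    egnn_cfg: EGNNConfig,
) -> float:
    """Mean per-network in-frame RMSD (phase-1 loss) over a dataset."""
    prepared = [_prepare(ex, cfg, egnn_cfg) for ex in dataset]
    return _epoch_loss(ensemble, prepared, 1, cfg, egnn_cfg)
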