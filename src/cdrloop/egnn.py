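"""E(n)-equivariant graph network over loop backbone atoms.

Each network is four message-passing layers.  A layer computes per-edge
messages from the two node feature vectors and the squared inter-node
distance, moves each node along the vector sum of its edge directions
weighted by a learned scalar, and updates node features from the aggregated
messages.  Because coordinates enter only through distances and relative
vectors, the coordinate output is exactly covariant under rotations and
translations of the input, and the feature output is invariant.

Five independently initialized networks form the ensemble; their per-atom
mean is the final prediction, and their spread is the confidence signal
(see :mod:`cdrloop.confidence`).  The members share no weights — their
parameters are stored stacked along a leading member axis purely so one
batched forward pass evaluates all of them.  Anchor atoms participate in
message passing but are re-pinned to their trusted input coordinates after
every layer, so predictions stay conditioned on real framework geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import ScatterOp, Tensor, concat, gather_rows, segment_sum
from .features import FeatureMatrix, FeatureSchema, build_graph, encode_nodes
from .geometry import line_initialize
from .structures import LoopRecord


@dataclass
class EGNNConfig:
    n_layers: int = 4
    n_networks: int = 5
    hidden_width: int = 64
    message_width: int = 32
    coord_gain: float = 10.0  # fixed gain on the coordinate update
    nonlinearity: str = "silu"
    seed: int = 0
    per_loop_graph: bool = False
    freeze_anchors: bool = False  # alternative to between-layer re-pinning

    def __post_init__(self) -> None:
        if self.hidden_width <= 0 or self.message_width <= 0:
            raise ValueError("widths must be positive")


@dataclass
class DecoySet:
    """The per-network coordinate predictions for one antibody's loops."""

    decoys: np.ndarray  # (n_networks, n_nodes, 3)
    mean: np.ndarray  # (n_nodes, 3)
    loop_atom_slices: dict[str, slice]
    interior_mask: np.ndarray
    member_seeds: tuple[int, ...] = ()

    def loop_interior_coords(self, loop_id: str) -> np.ndarray:
        """(n_networks, n_interior_atoms, 3) for one loop."""
        sl = self.loop_atom_slices[loop_id]
        local = self.interior_mask[sl]
        return self.decoys[:, sl][:, local]

    def mean_interior_coords(self, loop_id: str) -> np.ndarray:
        sl = self.loop_atom_slices[loop_id]
        return self.mean[sl][self.interior_mask[sl]]


@dataclass
class GraphOps:
    """Edge list plus precomputed scatter operators and node degrees."""

    src: np.ndarray
    dst: np.ndarray
    scatter_src: ScatterOp
    scatter_dst: ScatterOp
    degree: np.ndarray

    @classmethod
    def from_edges(cls, src: np.ndarray, dst: np.ndarray, n_nodes: int) -> "GraphOps":
        degree = np.bincount(src, minlength=n_nodes).astype(float)
        degree[degree == 0] = 1.0
        return cls(src, dst, ScatterOp(src, n_nodes), ScatterOp(dst, n_nodes), degree)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> list[np.ndarray]:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return [rng.uniform(-limit, limit, size=(n_in, n_out)), np.zeros((1, n_out))]


def _network_arrays(cfg: EGNNConfig, rng: np.random.Generator, in_width: int) -> dict:
    h, m = cfg.hidden_width, cfg.message_width
    return {
        "embed": _linear_init(rng, in_width, h),
        "layers": [
            {
                "phi_e": [_linear_init(rng, 2 * h + 1, m), _linear_init(rng, m, m)],
                "phi_x": [_linear_init(rng, m, m), _linear_init(rng, m, 1)],
                "phi_h": [_linear_init(rng, h + m, h), _linear_init(rng, h, h)],
            }
            for _ in range(cfg.n_layers)
        ],
    }


def _map_trees(fn, trees):
    """Apply fn to corresponding leaves (ndarray/Tensor) of parallel trees."""
    first = trees[0]
    if isinstance(first, dict):
        return {k: _map_trees(fn, [t[k] for t in trees]) for k in first}
    if isinstance(first, list):
        return [_map_trees(fn, [t[i] for t in trees]) for i in range(len(first))]
    return fn(trees)


def init_network_params(
    cfg: EGNNConfig, rng: np.random.Generator, in_width: int | None = None
) -> dict:
    """Parameter tree for a single network (leaves are (n_in, n_out) Tensors)."""
    f = in_width if in_width is not None else FeatureSchema().width
    return _map_trees(
        lambda leaves: Tensor(leaves[0], requires_grad=True),
        [_network_arrays(cfg, rng, f)],
    )


def init_ensemble(cfg: EGNNConfig, in_width: int | None = None) -> dict:
    """Independently seeded parameters for all members, stacked member-first.

    Leaves are Tensors of shape (n_networks, n_in, n_out); member i's weights
    are leaf[i] and are never mixed with another member's.
    """
    f = in_width if in_width is not None else FeatureSchema().width
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_networks)
    trees = [_network_arrays(cfg, np.random.default_rng(ss), f) for ss in seeds]
    stacked = _map_trees(
        lambda leaves: Tensor(np.stack(leaves), requires_grad=True), trees
    )
    stacked["seeds"] = [int(ss.generate_state(1)[0] % (2**31)) for ss in seeds]
    return stacked


def member_params(ensemble: dict, i: int) -> dict:
    """View of one member's parameters (2-D leaves, shared storage)."""

    def slice_leaf(leaves):
        leaf = leaves[0]
        if not isinstance(leaf, Tensor):
            return leaf
        t = Tensor(leaf.data[i])
        return t

    out = _map_trees(slice_leaf, [{k: v for k, v in ensemble.items() if k != "seeds"}])
    return out


def iter_params(tree) -> list[Tensor]:
    out: list[Tensor] = []

    def walk(node):
        if isinstance(node, Tensor):
            out.append(node)
        elif isinstance(node, dict):
            for k in sorted(node):
                walk(node[k])
        elif isinstance(node, (list, tuple)):
            for v in node:
                walk(v)

    walk(tree)
    return out


def save_ensemble(ensemble: dict, path, cfg: EGNNConfig | None = None) -> None:
    embed_w = ensemble["embed"][0].data
    k, _, h = embed_w.shape
    m = ensemble["layers"][0]["phi_e"][0][0].data.shape[-1]
    gain = cfg.coord_gain if cfg else EGNNConfig().coord_gain
    per_loop = cfg.per_loop_graph if cfg else False
    flat = {
        "seeds": np.asarray(ensemble.get("seeds", [])),
        "meta": np.array([len(ensemble["layers"]), k, h, m, gain, float(per_loop)]),
    }
    for j, t in enumerate(iter_params(ensemble)):
        flat[f"p{j}"] = t.data
    np.savez(path, **flat)


def infer_config(path) -> EGNNConfig:
    """Reconstruct the network configuration stored in a checkpoint."""
    meta = np.load(path)["meta"]
    return EGNNConfig(
        n_layers=int(meta[0]),
        n_networks=int(meta[1]),
        hidden_width=int(meta[2]),
        message_width=int(meta[3]),
        coord_gain=float(meta[4]),
        per_loop_graph=bool(meta[5]) if len(meta) > 5 else False,
    )


def load_ensemble(path, cfg: EGNNConfig | None = None,
                  in_width: int | None = None) -> dict:
    """Load a checkpoint; the configuration is read from it when not given."""
    data = np.load(path)
    cfg = cfg or infer_config(path)
    ensemble = init_ensemble(cfg, in_width)
    ensemble["seeds"] = [int(s) for s in data["seeds"]]
    for j, t in enumerate(iter_params(ensemble)):
        stored = data[f"p{j}"]
        if stored.shape != t.data.shape:
            raise ValueError("checkpoint does not match configuration")
        t.data = stored.astype(np.float64)
    return ensemble


# ---------------------------------------------------------------------------
# Forward computation
# ---------------------------------------------------------------------------


def _mlp(x: Tensor, layers: list, final_activation: bool = True) -> Tensor:
    for i, (w, b) in enumerate(layers):
        x = x @ w + b
        if final_activation or i < len(layers) - 1:
            x = x.silu()
    return x


def egnn_layer(
    h: Tensor,
    x: Tensor,
    graph: GraphOps | tuple[np.ndarray, np.ndarray],
    layer_params: dict,
    coord_gain: float = 10.0,
) -> tuple[Tensor, Tensor]:
    """One equivariant message-passing layer.

    m_ij = phi_e(h_i, h_j, ||x_i - x_j||^2)
    x_i' = x_i + (gain/deg_i) * sum_j (x_i - x_j)/(d_ij + 1) * phi_x(m_ij)
    h_i' = h_i + phi_h(h_i, mean_j m_ij)

    Works on single (n_nodes, width) tensors or member-stacked
    (n_networks, n_nodes, width) tensors.  Stabilising transforms, all rigid-
    motion invariant: the squared distance enters phi_e as log(1 + d2) (useful
    dynamic range from bonded 1.3 A to cross-loop tens of A); the relative
    vector is divided by (d + 1) so per-neighbour steps are order phi_x; and
    messages are mean-aggregated so magnitudes stay bounded on the fully
    connected graph.  The fixed coordinate gain lets the update span several
    Angstrom while phi_x outputs (and hence its weights, which weight decay
    pulls toward zero) stay order one.
    """
    if not (np.all(np.isfinite(h.data)) and np.all(np.isfinite(x.data))):
        raise ValueError("non-finite input to layer")
    if not isinstance(graph, GraphOps):
        graph = GraphOps.from_edges(graph[0], graph[1], h.data.shape[-2])
    rel = gather_rows(x, graph.src, graph.scatter_src) - gather_rows(
        x, graph.dst, graph.scatter_dst
    )
    d2 = rel.square().sum(axis=-1, keepdims=True)
    m = _mlp(
        concat(
            [
                gather_rows(h, graph.src, graph.scatter_src),
                gather_rows(h, graph.dst, graph.scatter_dst),
                d2.log1p(),
            ]
        ),
        layer_params["phi_e"],
    )
    w = _mlp(m, layer_params["phi_x"], final_activation=False)
    inv_deg = Tensor((1.0 / graph.degree)[:, None])
    rel_n = rel / (d2.sqrt() + 1.0)
    x_new = x + segment_sum(rel_n * w, graph.scatter_src) * inv_deg * coord_gain
    agg = segment_sum(m, graph.scatter_src) * inv_deg
    h_new = h + _mlp(concat([h, agg]), layer_params["phi_h"])
    return h_new, x_new


def forward_ensemble(
    features: FeatureMatrix,
    init_coords: np.ndarray,
    ensemble: dict,
    cfg: EGNNConfig,
    edges: tuple[np.ndarray, np.ndarray] | GraphOps | None = None,
) -> Tensor:
    """All members in one batched pass; returns (n_networks, n_nodes, 3).

    Anchor rows (``~features.interior_mask``) are reset to their input values
    after every layer and at the output, so every decoy carries the trusted
    anchors exactly.
    """
    if edges is None:
        edges = build_graph(
            features.n_nodes, features.loop_atom_slices, per_loop=cfg.per_loop_graph
        )
    graph = (
        edges
        if isinstance(edges, GraphOps)
        else GraphOps.from_edges(edges[0], edges[1], features.n_nodes)
    )
    embed_w = ensemble["embed"][0]
    stacked = embed_w.data.ndim == 3
    k = embed_w.data.shape[0] if stacked else 1
    if isinstance(init_coords, Tensor):
        x = init_coords
        x0 = init_coords.data
    else:
        x0 = np.asarray(init_coords, dtype=float)
        x = (
            Tensor(np.broadcast_to(x0, (k,) + x0.shape).copy())
            if stacked
            else Tensor(x0.copy())
        )

    anchor_mask = ~features.interior_mask
    int_col = Tensor(features.interior_mask.astype(float)[:, None])
    anchor_full = np.zeros(x0.shape[-2:])
    anchor_src = x0 if x0.ndim == 2 else x0[0]
    anchor_full[anchor_mask] = anchor_src[anchor_mask]
    anchor_const = Tensor(anchor_full)

    h = (Tensor(features.matrix) @ ensemble["embed"][0] + ensemble["embed"][1]).silu()
    for layer_params in ensemble["layers"]:
        # anchors inform messages but are re-pinned to truth between layers
        x = x * int_col + anchor_const
        h, x = egnn_layer(h, x, graph, layer_params, cfg.coord_gain)
    x = x * int_col + anchor_const
    return x


def forward_network(
    features: FeatureMatrix,
    init_coords: np.ndarray,
    params: dict,
    cfg: EGNNConfig,
    edges: tuple[np.ndarray, np.ndarray] | GraphOps | None = None,
) -> Tensor:
    """Run one network (2-D parameter leaves, e.g. from ``member_params``)."""
    return forward_ensemble(features, init_coords, params, cfg, edges)


def initial_coordinates(loops: list[LoopRecord]) -> np.ndarray:
    """Flat (n_nodes, 3) line-initialized geometry in FeatureMatrix node order."""
    order = {lid: i for i, lid in enumerate(FeatureSchema().loop_classes)}
    chunks = []
    for rec in sorted(loops, key=lambda r: order[r.loop_id]):
        interior = line_initialize(rec)
        span = np.concatenate(
            [rec.anchor_coords[:2], interior, rec.anchor_coords[2:]], axis=0
        )
        chunks.append(span.reshape(-1, 3))
    return np.concatenate(chunks, axis=0)


def true_coordinates(loops: list[LoopRecord]) -> np.ndarray:
    """Flat (n_nodes, 3) ground-truth geometry in FeatureMatrix node order."""
    order = {lid: i for i, lid in enumerate(FeatureSchema().loop_classes)}
    chunks = [
        rec.span_coords().reshape(-1, 3)
        for rec in sorted(loops, key=lambda r: order[r.loop_id])
    ]
    return np.concatenate(chunks, axis=0)


def predict_decoys(
    features: FeatureMatrix,
    init_coords: np.ndarray,
    ensemble: dict,
    cfg: EGNNConfig,
) -> DecoySet:
    """Run every ensemble member and average the predictions per atom."""
    from .autodiff import no_grad

    k = ensemble["embed"][0].data.shape[0]
    if k != cfg.n_networks:
        warnings.warn(
            f"ensemble has {k} members (configured {cfg.n_networks})", stacklevel=2
        )
    with no_grad():
        decoys = forward_ensemble(features, init_coords, ensemble, cfg).data
    return DecoySet(
        decoys=decoys,
        mean=decoys.mean(axis=0),
        loop_atom_slices=dict(features.loop_atom_slices),
        interior_mask=features.interior_mask.copy(),
        member_seeds=tuple(ensemble.get("seeds", ())),
    )


def predict_loops(
    loops: list[LoopRecord], ensemble: dict, cfg: EGNNConfig
) -> tuple[DecoySet, list[LoopRecord]]:
    """End-to-end prediction for one antibody's extracted loops.

    Returns the decoy set plus LoopRecords carrying the averaged coordinates,
    ready for grafting.
    """
    fm = encode_nodes(loops)
    init = initial_coordinates(loops)
    ds = predict_decoys(fm, init, ensemble, cfg)
    order = {lid: i for i, lid in enumerate(FeatureSchema().loop_classes)}
    out = []
    for rec in sorted(loops, key=lambda r: order[r.loop_id]):
        coords = ds.mean_interior_coords(rec.loop_id).reshape(-1, 4, 3)
        out.append(rec.with_coords(coords, kind="predicted"))
    return ds, out
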