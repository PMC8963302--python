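"""Per-node input encodings and graph construction.

Every backbone atom of every anchored CDR span is one graph node.  Nodes get
a 41-dimensional feature vector: amino-acid one-hot (20), atom-class one-hot
(4: Ca, N, C, Cb), loop one-hot (6: H1..L3) and an 11-wide sinusoidal
positional block describing how close the residue sits to the anchors.
Features are a pure function of sequence and topology — never of coordinates —
so they are rigid-motion invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import LOOP_ORDER, LoopRecord

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FeatureSchema:
    amino_alphabet: str = AMINO_ALPHABET
    atom_classes: tuple[str, ...] = ("CA", "N", "C", "CB")
    loop_classes: tuple[str, ...] = LOOP_ORDER
    positional_width: int = 11

    @property
    def width(self) -> int:
        return (
            len(self.amino_alphabet)
            + len(self.atom_classes)
            + len(self.loop_classes)
            + self.positional_width
        )


@dataclass
class FeatureMatrix:
    """Node features aligned row-for-row with the flat coordinate array.

    Node order: loops concatenated H1..L3; within a loop the anchored span in
    chain order (2 N-anchors, interior, 2 C-anchors); within a residue the
    four atoms in (Ca, N, C, Cb) order.
    """

    matrix: np.ndarray  # (n_nodes, 41)
    loop_atom_slices: dict[str, slice] = field(default_factory=dict)
    interior_mask: np.ndarray | None = None  # (n_nodes,) True off-anchor

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def interior_indices(self, loop_id: str) -> np.ndarray:
        sl = self.loop_atom_slices[loop_id]
        local = self.interior_mask[sl]
        return np.arange(sl.start, sl.stop)[local]


def positional_embedding(residue_index: int, span_length: int) -> np.ndarray:
    """Sinusoidal anchor-proximity embedding for one residue of a span.

    The index runs over the anchored span (anchors included) so the anchors
    receive the endpoint embeddings.  With p = index/(span-1) in [0, 1] the
    embedding is (2p-1, sin(pi k p), cos(pi k p)) for k = 1..5.
    """
    if span_length < 2:
        raise ValueError("span must contain at least 2 residues")
    if not 0 <= residue_index < span_length:
        raise ValueError("residue index outside span")
    p = residue_index / (span_length - 1)
    k = np.arange(1, 6)
    return np.concatenate([[2.0 * p - 1.0], np.sin(np.pi * k * p), np.cos(np.pi * k * p)])


def encode_nodes(
    loops: list[LoopRecord], schema: FeatureSchema | None = None
) -> FeatureMatrix:
    """One feature row per backbone-atom node, anchors included.

    All four atoms of a residue share the residue-level blocks and differ only
    in the atom-class one-hot.  Unknown amino-acid letters are an error — the
    alphabet has no wildcard class.
    """
    schema = schema or FeatureSchema()
    n_aa = len(schema.amino_alphabet)
    n_atom = len(schema.atom_classes)
    n_loop = len(schema.loop_classes)
    order = {lid: i for i, lid in enumerate(schema.loop_classes)}
    loops = sorted(loops, key=lambda r: order[r.loop_id])

    rows: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    interior: list[bool] = []
    cursor = 0
    for rec in loops:
        span = rec.span_sequence
        loop_onehot = np.zeros(n_loop)
        loop_onehot[order[rec.loop_id]] = 1.0
        start = cursor
        for ridx, aa in enumerate(span):
            if aa not in schema.amino_alphabet:
                raise ValueError(f"unknown amino-acid letter {aa!r} in loop {rec.loop_id}")
            aa_onehot = np.zeros(n_aa)
            aa_onehot[schema.amino_alphabet.index(aa)] = 1.0
            pos = positional_embedding(ridx, len(span))
            is_interior = 2 <= ridx < len(span) - 2
            for aidx in range(n_atom):
                atom_onehot = np.zeros(n_atom)
                atom_onehot[aidx] = 1.0
                rows.append(np.concatenate([aa_onehot, atom_onehot, loop_onehot, pos]))
                interior.append(is_interior)
                cursor += 1
        slices[rec.loop_id] = slice(start, cursor)
    matrix = np.stack(rows)
    assert matrix.shape[1] == schema.width
    return FeatureMatrix(
        matrix=matrix,
        loop_atom_slices=slices,
        interior_mask=np.array(interior, dtype=bool),
    )


def build_graph(n_nodes: int, loop_atom_slices: dict[str, slice] | None = None,
                per_loop: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (src, dst) — fully connected, no self edges, both directions.

    By default one joint graph over all six loops' atoms; ``per_loop``
    restricts edges to within each loop's anchored span.
    """
    if n_nodes < 2:
        raise ValueError("graph needs at least 2 nodes")
    if per_loop and loop_atom_slices:
        srcs, dsts = [], []
        for sl in loop_atom_slices.values():
            ids = np.arange(sl.start, sl.stop)
            s, d = np.meshgrid(ids, ids, indexing="ij")
            mask = s != d
            srcs.append(s[mask])
            dsts.append(d[mask])
        return np.concatenate(srcs), np.concatenate(dsts)
    ids = np.arange(n_nodes)
    s, d = np.meshgrid(ids, ids, indexing="ij")
    mask = s != d
    return s[mask], d[mask]
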