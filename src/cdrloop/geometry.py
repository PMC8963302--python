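"""Coordinate mathematics: superposition, RMSD variants, loop initialization,
virtual C-beta construction and backbone-geometry auditing.

Two RMSD conventions coexist on purpose.  ``rmsd_in_frame`` compares two
coordinate sets with NO re-fit: during training the prediction lives in the
frame pinned by the true anchor residues, so raw deviation is meaningful.
``evaluate_cdr_rmsd`` follows the benchmark convention instead: superpose the
whole chain onto the reference, then measure each CDR window without
re-fitting on the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial.transform import Rotation

if TYPE_CHECKING:  # pragma: no cover
    from .structures import AntibodyModel, CDRDefinition, LoopRecord

# Atom order used everywhere for backbone coordinate arrays.
ATOM_ORDER = ("CA", "N", "C", "CB")

# Reference backbone bond lengths in Angstrom.  Keys name the bonded-pair
# classes: consecutive alpha carbons, the three intra-residue bonds from the
# alpha carbon, and the peptide bond.
BOND_REFERENCE_LENGTHS: dict[str, float] = {
    "CA-CA+1": 3.80,
    "CA-CB": 1.52,
    "CA-N": 1.46,
    "CA-C": 1.52,
    "C-N+1": 1.33,
}


class DegenerateGeometryError(ValueError):
    """Raised when a construction needs non-collinear / non-coincident points."""


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform mapping a mobile point set onto a target.

    ``apply`` realises x -> rotation @ x + translation.
    """

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # post-fit RMSD in Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Proper-rotation least-squares superposition (Kabsch).

    Parameters are (N, 3) arrays with corresponding rows.  Raises for N < 3 or
    a degenerate (collinear) mobile set, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    centered = mobile - mob_c
    # Collinear point sets leave a free rotation about the line.
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("mobile points are collinear; rotation ill-defined")
    rot, rssd = Rotation.align_vectors(target - tgt_c, centered)
    rotation = rot.as_matrix()
    translation = tgt_c - rotation @ mob_c
    rmsd = float(rssd / np.sqrt(n))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_in_frame(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between corresponding atoms with no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d2 = ((a.reshape(-1, 3) - b.reshape(-1, 3)) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def evaluate_cdr_rmsd(
    predicted: "AntibodyModel",
    reference: "AntibodyModel",
    definitions: "list[CDRDefinition] | None" = None,
    fit: str = "chain",
) -> dict[str, float]:
    """Per-loop backbone RMSD under the benchmark convention.

    For each CDR, the predicted chain is superposed onto the corresponding
    reference chain (``fit='chain'`` uses all backbone atoms of the chain,
    ``fit='framework'`` excludes CDR windows), then the Ca-N-C-Cb RMSD is
    reported over the loop window with no re-fit on the loop itself.
    """
    from .structures import default_cdr_definitions

    if definitions is None:
        definitions = default_cdr_definitions()
    if fit not in ("chain", "framework"):
        raise ValueError("fit must be 'chain' or 'framework'")

    out: dict[str, float] = {}
    fits: dict[str, Superposition] = {}
    for chain_id in predicted.chain_ids():
        pred_res = predicted.chain_residues(chain_id)
        ref_labels = {r.label for r in reference.chain_residues(chain_id)}
        labels = [r.label for r in pred_res]
        if set(labels) - ref_labels:
            missing = sorted(set(labels) - ref_labels)
            raise ValueError(f"chain {chain_id}: labels missing in reference: {missing}")
        if fit == "framework":
            cdr_labels: set[str] = set()
            for d in definitions:
                if d.chain == chain_id:
                    cdr_labels.update(
                        r.label for r in pred_res if d.contains(r.label)
                    )
            labels = [l for l in labels if l not in cdr_labels]
        mob = np.concatenate([predicted.residue_coords(chain_id, l) for l in labels])
        tgt = np.concatenate([reference.residue_coords(chain_id, l) for l in labels])
        fits[chain_id] = kabsch_superpose(mob, tgt)

    for d in definitions:
        window = [
            r.label for r in predicted.chain_residues(d.chain) if d.contains(r.label)
        ]
        if not window:
            raise ValueError(f"no residues found for loop {d.loop_id}")
        mob = np.concatenate([predicted.residue_coords(d.chain, l) for l in window])
        tgt = np.concatenate([reference.residue_coords(d.chain, l) for l in window])
        out[d.loop_id] = rmsd_in_frame(fits[d.chain].apply(mob), tgt)
    return out


def line_initialize(loop: "LoopRecord") -> np.ndarray:
    """Non-descriptive starting geometry: interior residues evenly spaced on
    the straight segment between the inner anchor alpha carbons.

    Residue i (1-based, n interior residues) sits at fraction i/(n+1) of the
    segment; all four atoms of a residue are co-located there.  Anchor atoms
    keep their true coordinates and are what breaks collinearity for the
    equivariant network downstream.
    """
    start = loop.anchor_coords[1, 0]  # inner N-side anchor Ca
    end = loop.anchor_coords[2, 0]  # inner C-side anchor Ca
    seg = end - start
    if np.linalg.norm(seg) < 1e-9:
        raise DegenerateGeometryError("anchor endpoints coincide; zero-length segment")
    n = len(loop.sequence)
    fracs = np.arange(1, n + 1, dtype=float) / (n + 1)
    points = start[None, :] + fracs[:, None] * seg[None, :]
    return np.repeat(points[:, None, :], 4, axis=1)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta built from the local N/Ca/C frame.

    Used for glycine, whose node still needs a fourth backbone atom.  The
    construction is the standard orthonormal-frame formula, scaled to put the
    C-beta 1.52 A from the alpha carbon; it is exactly covariant under rigid
    motions of the three inputs.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    v1 = n - ca
    v2 = c - ca
    cross = np.cross(v1, v2)
    if np.linalg.norm(cross) < 1e-9:
        raise DegenerateGeometryError("N, CA, C are collinear; frame undefined")
    bisector = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
    bisector /= np.linalg.norm(bisector)
    perp = cross / np.linalg.norm(cross)
    # Tetrahedral direction: opposite the N/C bisector, tilted out of plane.
    half_angle = np.deg2rad(109.5 / 2.0)
    direction = -np.cos(half_angle) * bisector + np.sin(half_angle) * perp
    return ca + 1.52 * direction


def backbone_geometry_report(
    loop_coords: np.ndarray,
    reference_lengths: dict[str, float] | None = None,
) -> list[tuple[str, float, float]]:
    """Audit the five bonded-pair classes of a loop's backbone.

    ``loop_coords`` is (n_residues, 4, 3) in ATOM_ORDER.  Returns
    (class, measured length, deviation from reference) per pair instance;
    cross-residue classes have no instance for the last residue.
    """
    ref = dict(BOND_REFERENCE_LENGTHS)
    if reference_lengths:
        ref.update(reference_lengths)
    x = np.asarray(loop_coords, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (4, 3):
        raise ValueError("loop coordinates must have shape (n, 4, 3)")
    ca, nn, cc, cb = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
    report: list[tuple[str, float, float]] = []

    def add(name: str, a: np.ndarray, b: np.ndarray) -> None:
        for d in np.linalg.norm(a - b, axis=1):
            report.append((name, float(d), float(abs(d - ref[name]))))

    if x.shape[0] >= 2:
        add("CA-CA+1", ca[:-1], ca[1:])
        add("C-N+1", cc[:-1], nn[1:])
    add("CA-CB", ca, cb)
    add("CA-N", ca, nn)
    add("CA-C", ca, cc)
    return report
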