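"""Idealized antibody-like fixtures with known ground truth.

Builds backbone chains by forward kinematics with exact reference bond
lengths (trans peptide bond, sampled phi/psi torsions), assembles them into
toy two-chain antibody models numbered to the configured Chothia windows, and
emulates a homology model whose CDRs need remodelling by adding isotropic
Gaussian noise to the loop interiors.  Everything downstream — extraction,
featurization, training, prediction, confidence and evaluation — is testable
against these fixtures with no external data.

The noise scale ``sigma`` is the RMS per-atom displacement in Angstrom
(per-coordinate standard deviation sigma/sqrt(3)), so the expected in-frame
RMSD of a noised loop equals sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .features import AMINO_ALPHABET
from .geometry import BOND_REFERENCE_LENGTHS, virtual_cbeta
from .structures import (
    AntibodyModel,
    CDRDefinition,
    LoopRecord,
    Residue,
    default_cdr_definitions,
    extract_loops,
)

# Ideal backbone bond angles (degrees); the Ca-C-N angle is solved so that the
# consecutive-Ca distance equals its reference length exactly.
ANGLE_N_CA_C = 111.0
ANGLE_C_N_CA = 121.7
OMEGA = 180.0  # trans peptide bond


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond_length: float, bond_angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d given three predecessors (natural-extension frame):
    |c-d| = bond_length, angle b-c-d = bond_angle, torsion a-b-c-d = torsion."""
    theta = np.deg2rad(bond_angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(phi),
            bond_length * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ d_local


@lru_cache(maxsize=8)
def _solve_ca_c_n_angle(d_ca_ca: float, d_ca_c: float, d_c_n: float, d_n_ca: float) -> float:
    """Ca-C-N bond angle (deg) making the consecutive-Ca distance exact."""

    def ca_ca(theta: float) -> float:
        ca0 = np.array([0.0, 0.0, 0.0])
        c0 = np.array([d_ca_c, 0.0, 0.0])
        dummy = np.array([0.0, 1.0, 0.0])
        n1 = place_atom(dummy, ca0, c0, d_c_n, theta, 0.0)
        ca1 = place_atom(ca0, c0, n1, d_n_ca, ANGLE_C_N_CA, OMEGA)
        return float(np.linalg.norm(ca1 - ca0)) - d_ca_ca

    return float(brentq(ca_ca, 95.0, 140.0, xtol=1e-12))


@dataclass
class FixtureSpec:
    """Study conditions for fixture generation."""

    sigma: float = 1.0  # RMS per-atom displacement of the "model" CDRs, A
    seed: int = 0
    heavy_length: int = 110
    light_length: int = 105
    phi_range: tuple[float, float] = (-160.0, -60.0)
    psi_range: tuple[float, float] = (90.0, 170.0)
    bond_lengths: dict[str, float] = field(
        default_factory=lambda: dict(BOND_REFERENCE_LENGTHS)
    )
    glycine_every: int = 7  # framework glycine spacing (exercises virtual Cb)
    loop_alphabet: str = AMINO_ALPHABET  # loop-interior sequence alphabet

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.heavy_length < 1 or self.light_length < 1:
            raise ValueError("chain lengths must be >= 1")


def build_backbone(
    n_residues: int,
    rng: np.random.Generator,
    spec: FixtureSpec | None = None,
) -> np.ndarray:
    """(n, 4, 3) ideal backbone in (Ca, N, C, Cb) order with sampled torsions."""
    spec = spec or FixtureSpec()
    bl = spec.bond_lengths
    theta_ca_c_n = _solve_ca_c_n_angle(
        bl["CA-CA+1"], bl["CA-C"], bl["C-N+1"], bl["CA-N"]
    )
    phis = rng.uniform(*spec.phi_range, size=n_residues)
    psis = rng.uniform(*spec.psi_range, size=n_residues)

    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([bl["CA-N"], 0.0, 0.0])
    c0 = place_atom(np.array([0.0, 1.0, 0.0]), n0, ca0, bl["CA-C"], ANGLE_N_CA_C,
                    float(rng.uniform(-180, 180)))
    coords = np.empty((n_residues, 4, 3))
    nn, ca, cc = n0, ca0, c0
    for i in range(n_residues):
        coords[i, 0], coords[i, 1], coords[i, 2] = ca, nn, cc
        coords[i, 3] = virtual_cbeta(nn, ca, cc)
        if i + 1 < n_residues:
            n_next = place_atom(nn, ca, cc, bl["C-N+1"], theta_ca_c_n, psis[i])
            ca_next = place_atom(ca, cc, n_next, bl["CA-N"], ANGLE_C_N_CA, OMEGA)
            c_next = place_atom(cc, n_next, ca_next, bl["CA-C"], ANGLE_N_CA_C,
                                phis[i + 1])
            nn, ca, cc = n_next, ca_next, c_next
    return coords


def make_idealized_loop(
    length: int,
    anchor_frame: np.ndarray | None = None,
    seed: int = 0,
    loop_id: str = "H3",
    sequence: str | None = None,
    spec: FixtureSpec | None = None,
) -> LoopRecord:
    """One anchored loop with exact reference bond geometry.

    The chain (2 anchors + interior + 2 anchors) is built by forward
    kinematics and, when ``anchor_frame`` — the (3, 3) N/Ca/C positions of the
    first anchor residue — is given, rigidly moved onto that frame; the C-side
    anchors come from the same ideal chain.
    """
    if length < 1:
        raise ValueError("loop length must be >= 1")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    coords = build_backbone(length + 4, rng, spec)
    if anchor_frame is not None:
        anchor_frame = np.asarray(anchor_frame, dtype=float)
        from .geometry import kabsch_superpose

        own = np.stack([coords[0, 1], coords[0, 0], coords[0, 2]])  # N, Ca, C
        sup = kabsch_superpose(own, anchor_frame)
        coords = sup.apply(coords.reshape(-1, 3)).reshape(coords.shape)
    if sequence is None:
        # poly-alanine with a central glycine to exercise the virtual-Cb path
        sequence = "".join(
            "G" if i == length // 2 else "A" for i in range(length)
        )
    if len(sequence) != length:
        raise ValueError("sequence length mismatch")
    labels = [str(100 + i) for i in range(length)]
    return LoopRecord(
        loop_id=loop_id,
        sequence=sequence,
        labels=labels,
        anchor_sequence="AAAA",
        anchor_labels=["98", "99", str(100 + length), str(101 + length)],
        anchor_coords=np.concatenate([coords[:2], coords[-2:]], axis=0),
        coords=coords[2:-2],
        kind="true",
    )


def _chain_residues(
    chain_id: str,
    length: int,
    rng: np.random.Generator,
    spec: FixtureSpec,
    definitions: list[CDRDefinition],
) -> list[Residue]:
    coords = build_backbone(length, rng, spec)
    windows = [d for d in definitions if d.chain == chain_id]
    residues = []
    for i in range(length):
        label = str(i + 1)
        in_cdr = any(d.contains(label) for d in windows)
        if in_cdr:
            aa = spec.loop_alphabet[rng.integers(len(spec.loop_alphabet))]
        elif spec.glycine_every and (i + 1) % spec.glycine_every == 0:
            aa = "G"
        else:
            aa = "A"
        residues.append(
            Residue(
                chain=chain_id,
                number=i + 1,
                icode="",
                aa=aa,
                coords=coords[i].copy(),
                cb_is_virtual=(aa == "G"),
            )
        )
    return residues


def make_toy_antibody(
    spec: FixtureSpec | None = None,
    definitions: list[CDRDefinition] | None = None,
    seed: int | None = None,
) -> tuple[AntibodyModel, AntibodyModel]:
    """A (model, reference) pair of toy two-chain antibodies.

    The reference carries idealized loops; the model is the reference with
    every CDR interior perturbed by isotropic Gaussian noise of RMS per-atom
    displacement ``spec.sigma`` (anchors and framework untouched).
    """
    spec = spec or FixtureSpec()
    defs = definitions or default_cdr_definitions()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chains = {
        "H": _chain_residues("H", spec.heavy_length, rng, spec, defs),
        "L": _chain_residues("L", spec.light_length, rng, spec, defs),
    }
    # keep the two chains spatially apart
    for r in chains["L"]:
        r.coords = r.coords + np.array([80.0, 0.0, 0.0])
    reference = AntibodyModel(chains=chains, provenance="reference")
    model = reference.copy()
    model.provenance = "model"
    per_coord = spec.sigma / np.sqrt(3.0)
    for d in defs:
        for r in model.chain_residues(d.chain):
            if d.contains(r.label):
                r.coords = r.coords + rng.normal(scale=per_coord, size=(4, 3))
    return model, reference


def make_training_set(
    n: int,
    spec: FixtureSpec | None = None,
    definitions: list[CDRDefinition] | None = None,
) -> tuple[list[LoopRecord], list[LoopRecord]]:
    """Loops of n toy antibodies, deterministically split train/validation.

    Returns (train, validation) lists of true LoopRecords (6 per antibody,
    ~80/20 split by antibody).  No interior sequence appears in both splits;
    colliding antibodies are regenerated from fresh sub-seeds.
    """
    if n < 1:
        raise ValueError("need at least one antibody")
    spec = spec or FixtureSpec()
    defs = definitions or default_cdr_definitions()
    seed_seq = np.random.SeedSequence(spec.seed)
    seen: set[str] = set()
    per_antibody: list[list[LoopRecord]] = []
    budget = 20 * n
    child = 0
    while len(per_antibody) < n:
        if child >= budget:
            raise RuntimeError("could not generate sequence-unique antibodies")
        sub = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        child += 1
        _, reference = make_toy_antibody(spec, defs, seed=sub)
        loops = extract_loops(reference, defs)
        seqs = {rec.sequence for rec in loops}
        if seqs & seen or len(seqs) < len(loops):
            continue
        seen |= seqs
        per_antibody.append(loops)
    n_val = max(1, n // 5) if n > 1 else 0
    val = [rec for loops in per_antibody[:n_val] for rec in loops]
    train = [rec for loops in per_antibody[n_val:] for rec in loops]
    return train, val
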