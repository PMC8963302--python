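"""Antibody structure I/O, CDR extraction and loop grafting.

Structures are two-chain (heavy + light) antibody variable domains in PDB
format, assumed already numbered under the Chothia convention.  Only the four
backbone atoms per residue (Ca, N, C, Cb) are kept; glycine receives a
virtual C-beta so every node has the same atom set.  PDB reading and writing
are backed by gemmi.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .geometry import ATOM_ORDER, virtual_cbeta

logger = logging.getLogger(__name__)

LOOP_ORDER = ("H1", "H2", "H3", "L1", "L2", "L3")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

MAX_UNWARNED_LOOP_LENGTH = 20


class PDBFormatError(ValueError):
    pass


class MissingResidueError(ValueError):
    pass


class MissingAtomError(ValueError):
    pass


@dataclass
class Residue:
    chain: str
    number: int
    icode: str  # "" when absent
    aa: str  # 1-letter code
    coords: np.ndarray  # (4, 3) in ATOM_ORDER
    cb_is_virtual: bool = False

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}"

    def copy(self) -> "Residue":
        return replace(self, coords=self.coords.copy())


@dataclass
class AntibodyModel:
    """Parsed two-chain antibody with per-residue backbone coordinates."""

    chains: dict[str, list[Residue]]
    provenance: str = "model"  # "model" | "reference"

    def chain_ids(self) -> tuple[str, ...]:
        return tuple(self.chains)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def get_residue(self, chain_id: str, label: str) -> Residue:
        for r in self.chains[chain_id]:
            if r.label == label:
                return r
        raise MissingResidueError(f"{chain_id}{label} not present")

    def residue_coords(self, chain_id: str, label: str) -> np.ndarray:
        return self.get_residue(chain_id, label).coords

    def copy(self) -> "AntibodyModel":
        return AntibodyModel(
            chains={c: [r.copy() for r in rs] for c, rs in self.chains.items()},
            provenance=self.provenance,
        )

    def validate(self, definitions: "list[CDRDefinition] | None" = None) -> None:
        """Check numbering uniqueness and CDR backbone completeness."""
        defs = definitions or default_cdr_definitions()
        for cid, residues in self.chains.items():
            labels = [r.label for r in residues]
            if len(labels) != len(set(labels)):
                dupes = sorted({l for l in labels if labels.count(l) > 1})
                raise PDBFormatError(f"chain {cid}: duplicate numbering labels {dupes}")
            for r in residues:
                if not np.all(np.isfinite(r.coords)):
                    raise MissingAtomError(f"{cid}{r.label}: non-finite coordinates")


def _parse_label(label: str) -> tuple[int, str]:
    digits = "".join(ch for ch in label if ch.isdigit() or ch == "-")
    icode = label[len(digits):]
    return int(digits), icode


@dataclass(frozen=True)
class CDRDefinition:
    """One CDR window: chain, inclusive numbering range, anchor width.

    Defaults follow the Chothia windows; they are configuration, not
    constants, so alternative conventions can be swapped in.
    """

    loop_id: str
    chain: str
    start: int
    end: int
    anchor_width: int = 2

    def contains(self, label: str) -> bool:
        num, _ = _parse_label(label)
        return self.start <= num <= self.end


def default_cdr_definitions(
    heavy: str = "H", light: str = "L", anchor_width: int = 2
) -> list[CDRDefinition]:
    """Chothia CDR windows, insertion codes included."""
    ranges = {
        "H1": (heavy, 26, 32),
        "H2": (heavy, 52, 56),
        "H3": (heavy, 95, 102),
        "L1": (light, 24, 34),
        "L2": (light, 50, 56),
        "L3": (light, 89, 97),
    }
    return [
        CDRDefinition(lid, ch, s, e, anchor_width)
        for lid, (ch, s, e) in ((k, ranges[k]) for k in LOOP_ORDER)
    ]


def load_cdr_definitions(path: str) -> list[CDRDefinition]:
    """Read CDR windows from a YAML mapping loop_id -> {chain, start, end}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for lid in LOOP_ORDER:
        entry = raw[lid]
        defs.append(
            CDRDefinition(
                lid,
                str(entry["chain"]),
                int(entry["start"]),
                int(entry["end"]),
                int(entry.get("anchor_width", 2)),
            )
        )
    return defs


@dataclass
class LoopRecord:
    """One CDR loop: interior residues plus two trusted anchors per side.

    ``anchor_coords`` rows follow chain order: N-side outer, N-side inner,
    C-side inner, C-side outer; each row holds the four backbone atoms in
    ATOM_ORDER.  ``coords`` is (n_interior, 4, 3) or None before prediction.
    Anchor coordinates are never altered by prediction.
    """

    loop_id: str
    sequence: str
    labels: list[str]
    anchor_sequence: str
    anchor_labels: list[str]
    anchor_coords: np.ndarray  # (4, 4, 3)
    coords: np.ndarray | None = None
    kind: str = "true"  # "true" | "predicted" | "initialized"

    def __post_init__(self) -> None:
        self.anchor_coords = np.asarray(self.anchor_coords, dtype=float)
        if self.anchor_coords.shape != (4, 4, 3):
            raise ValueError("anchor_coords must be (4 residues, 4 atoms, 3)")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.sequence), 4, 3):
                raise ValueError("coords must be (n_interior, 4, 3)")

    @property
    def span_sequence(self) -> str:
        return self.anchor_sequence[:2] + self.sequence + self.anchor_sequence[2:]

    def span_coords(self) -> np.ndarray:
        """(n+4, 4, 3) anchored-span coordinates; interior must be set."""
        if self.coords is None:
            raise ValueError(f"loop {self.loop_id} has no interior coordinates")
        return np.concatenate(
            [self.anchor_coords[:2], self.coords, self.anchor_coords[2:]], axis=0
        )

    def with_coords(self, coords: np.ndarray, kind: str) -> "LoopRecord":
        return LoopRecord(
            loop_id=self.loop_id,
            sequence=self.sequence,
            labels=list(self.labels),
            anchor_sequence=self.anchor_sequence,
            anchor_labels=list(self.anchor_labels),
            anchor_coords=self.anchor_coords.copy(),
            coords=np.asarray(coords, dtype=float).copy(),
            kind=kind,
        )


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------


def _read_gemmi_structure(pdb_source) -> gemmi.Structure:
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
        return gemmi.read_pdb_string(text)
    s = str(pdb_source)
    if "\n" in s:
        return gemmi.read_pdb_string(s)
    if not os.path.exists(s):
        raise PDBFormatError(f"no such PDB file: {s}")
    return gemmi.read_structure(s, format=gemmi.CoorFormat.Pdb)


def _pick_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy conformer wins; ties broken by altloc letter order."""
    candidates = [a for a in residue if a.name == name]
    if not candidates:
        return None
    return sorted(candidates, key=lambda a: (-a.occ, a.altloc))[0]


def parse_antibody(
    pdb_source,
    heavy_chain: str = "H",
    light_chain: str = "L",
    definitions: list[CDRDefinition] | None = None,
    provenance: str = "model",
) -> AntibodyModel:
    """Parse a PDB into an AntibodyModel with Ca/N/C/Cb per residue.

    A residue missing a backbone atom inside a CDR window is a hard error
    naming the residue; framework residues with incomplete backbones are
    skipped with a warning.  Glycine (or any residue without a C-beta) gets a
    virtual C-beta built from its N/Ca/C frame.
    """
    try:
        st = _read_gemmi_structure(pdb_source)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"could not parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError("PDB contains no models")
    model = st[0]
    defs = definitions or default_cdr_definitions(heavy_chain, light_chain)
    chains: dict[str, list[Residue]] = {}
    for cid in (heavy_chain, light_chain):
        chain = model.find_chain(cid)
        if chain is None:
            raise PDBFormatError(f"chain '{cid}' not found in PDB")
        residues: list[Residue] = []
        for res in chain:
            aa = AA3_TO_1.get(res.name)
            if aa is None:
                continue  # waters, ligands, non-standard residues
            icode = res.seqid.icode.strip()
            label = f"{res.seqid.num}{icode}"
            in_cdr = any(d.chain == cid and d.contains(label) for d in defs)
            atoms = {}
            for name in ("CA", "N", "C", "CB"):
                atom = _pick_atom(res, name)
                if atom is not None:
                    atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            missing = [n for n in ("CA", "N", "C") if n not in atoms]
            cb_needed = "CB" not in atoms and aa != "G"
            if missing or (in_cdr and cb_needed and aa != "G"):
                what = missing + (["CB"] if cb_needed else [])
                if in_cdr:
                    raise MissingAtomError(
                        f"residue {cid}{label} inside a CDR window is missing "
                        f"backbone atom(s): {', '.join(what)}"
                    )
                logger.warning(
                    "skipping framework residue %s%s (missing %s)",
                    cid, label, ", ".join(what),
                )
                continue
            cb_is_virtual = "CB" not in atoms
            if cb_is_virtual:
                atoms["CB"] = virtual_cbeta(atoms["N"], atoms["CA"], atoms["C"])
            coords = np.stack([atoms[a] for a in ATOM_ORDER])
            residues.append(Residue(cid, res.seqid.num, icode, aa, coords, cb_is_virtual))
        if not residues:
            raise PDBFormatError(f"chain '{cid}' has no standard residues")
        chains[cid] = residues
    out = AntibodyModel(chains=chains, provenance=provenance)
    out.validate(defs)
    return out


def write_pdb(model: AntibodyModel, destination, emit_virtual_cb: bool = False) -> None:
    """Write the model as standard PDB ATOM/TER records.

    Virtual C-beta atoms (glycine) are omitted unless ``emit_virtual_cb`` is
    set.  Coordinates round-trip through ``parse_antibody`` to 1e-3 A (the
    PDB field precision).
    """
    st = gemmi.Structure()
    st.name = "cdrloop"
    gmodel = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = AA1_TO_3[r.aa]
            res.seqid = gemmi.SeqId(r.number, r.icode if r.icode else " ")
            # Conventional PDB atom order within a residue.
            for name, idx in (("N", 1), ("CA", 0), ("C", 2), ("CB", 3)):
                if name == "CB" and r.cb_is_virtual and not emit_virtual_cb:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("N" if name == "N" else "C")
                atom.pos = gemmi.Position(*r.coords[idx])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    if hasattr(destination, "write"):
        destination.write(st.make_pdb_string())
    else:
        st.write_pdb(str(destination))


# ---------------------------------------------------------------------------
# Loop extraction / grafting
# ---------------------------------------------------------------------------


def _window_indices(model: AntibodyModel, d: CDRDefinition) -> list[int]:
    residues = model.chain_residues(d.chain)
    idx = [i for i, r in enumerate(residues) if d.contains(r.label)]
    if not idx:
        raise MissingResidueError(
            f"loop {d.loop_id}: no residues in window {d.chain}{d.start}-{d.chain}{d.end}"
        )
    present_numbers = {residues[i].number for i in idx}
    missing = [
        f"{d.chain}{k}" for k in range(d.start, d.end + 1) if k not in present_numbers
    ]
    if missing:
        raise MissingResidueError(
            f"loop {d.loop_id}: missing residue(s) {', '.join(missing)}"
        )
    if idx != list(range(idx[0], idx[-1] + 1)):
        raise MissingResidueError(f"loop {d.loop_id}: window is not contiguous")
    return idx


def extract_loops(
    model: AntibodyModel,
    definitions: list[CDRDefinition] | None = None,
    with_coords: bool = True,
) -> list[LoopRecord]:
    """Extract the six CDR loops plus two anchor residues per side.

    Anchor coordinates are copied from the model and treated as trusted.
    Interior coordinates are copied when ``with_coords`` (training
    references); otherwise left unset for prediction.
    """
    defs = definitions or default_cdr_definitions()
    records: list[LoopRecord] = []
    for d in defs:
        residues = model.chain_residues(d.chain)
        idx = _window_indices(model, d)
        w = d.anchor_width
        if idx[0] < w or idx[-1] + w >= len(residues):
            raise MissingResidueError(
                f"loop {d.loop_id}: fewer than {w} anchor residues on one side"
            )
        interior = [residues[i] for i in idx]
        anchors = [residues[i] for i in range(idx[0] - w, idx[0])] + [
            residues[i] for i in range(idx[-1] + 1, idx[-1] + 1 + w)
        ]
        if len(interior) > MAX_UNWARNED_LOOP_LENGTH:
            logger.warning(
                "loop %s has %d residues (> %d)",
                d.loop_id, len(interior), MAX_UNWARNED_LOOP_LENGTH,
            )
        records.append(
            LoopRecord(
                loop_id=d.loop_id,
                sequence="".join(r.aa for r in interior),
                labels=[r.label for r in interior],
                anchor_sequence="".join(r.aa for r in anchors),
                anchor_labels=[r.label for r in anchors],
                anchor_coords=np.stack([r.coords for r in anchors]),
                coords=np.stack([r.coords for r in interior]) if with_coords else None,
                kind="true" if with_coords else "initialized",
            )
        )
    logger.info(
        "extracted %d loops: %s",
        len(records),
        ", ".join(f"{r.loop_id}({len(r.sequence)})" for r in records),
    )
    return records


def graft_loops(
    model: AntibodyModel,
    predicted: list[LoopRecord],
    definitions: list[CDRDefinition] | None = None,
) -> AntibodyModel:
    """Replace the model's CDR-interior backbone coordinates with predictions.

    Framework and anchor coordinates are untouched.  Records must match the
    model's windows residue-for-residue.
    """
    defs = {d.loop_id: d for d in (definitions or default_cdr_definitions())}
    out = model.copy()
    for rec in predicted:
        if rec.coords is None:
            raise ValueError(f"loop {rec.loop_id} has no coordinates to graft")
        d = defs[rec.loop_id]
        residues = out.chain_residues(d.chain)
        idx = _window_indices(out, d)
        if len(idx) != len(rec.sequence):
            raise ValueError(
                f"loop {rec.loop_id}: record has {len(rec.sequence)} residues "
                f"but the model window has {len(idx)}"
            )
        for k, i in enumerate(idx):
            residues[i].coords = rec.coords[k].copy()
    return out
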