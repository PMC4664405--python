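"""Coordinate models, lysine anchor geometry, and cross-link restraints.

A BS3 cross-link observed between two lysines implies their side-chain
amines were simultaneously reachable by an 11.3 Å spacer, so on a correct
3D model the anchor atoms must lie within a distance cap (default 15 Å,
side-chain reach plus linker).  This module loads PDB coordinate models,
resolves lysine anchor atoms (NZ, falling back to CB then CA for truncated
side chains), evaluates restraint satisfaction, and answers the
single-ligand bridging question: can one ligand molecule satisfy two
cross-links whose receptor anchors are d_receptor apart?
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "AnchorSpec",
    "XLRestraint",
    "RestraintResult",
    "BridgingResult",
    "load_structure",
    "write_structure",
    "anchor_distance",
    "evaluate_restraints",
    "bridging_feasibility",
    "read_restraint_tsv",
    "write_restraint_tsv",
    "DEFAULT_CAP",
    "BS3_SPACER",
]

#: Restraint acceptance cap, Å: lysine side-chain reach plus the BS3 spacer.
DEFAULT_CAP = 15.0
#: BS3 spacer arm length, Å.
BS3_SPACER = 11.3


@dataclass
class Residue:
    name: str
    atoms: dict[str, np.ndarray]  # atom name -> xyz (Å)


@dataclass
class StructureModel:
    """Chain -> residue-number (author numbering) -> atoms hierarchy."""

    model_id: str
    chains: dict[str, dict[int, Residue]]

    def atom(self, chain: str, resnum: int, name: str) -> np.ndarray | None:
        res = self.chains.get(chain, {}).get(resnum)
        if res is None:
            return None
        return res.atoms.get(name)

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains.values() for r in ch.values())

    def ca_coords(self) -> np.ndarray:
        """All CA coordinates, (n, 3); empty (0, 3) when none."""
        pts = [
            r.atoms["CA"]
            for ch in self.chains.values()
            for r in ch.values()
            if "CA" in r.atoms
        ]
        return np.array(pts) if pts else np.empty((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy: x -> R x + t."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = {
            cid: {
                num: Residue(res.name, {a: rot @ xyz + t for a, xyz in res.atoms.items()})
                for num, res in ch.items()
            }
            for cid, ch in self.chains.items()
        }
        return StructureModel(self.model_id, chains)

    def with_numbering_offsets(self, offsets: dict[str, int]) -> "StructureModel":
        """Copy with per-chain residue-number offsets applied (new number =
        deposited number + offset), for deposits whose author numbering does
        not match the reference sequence numbering."""
        chains = {
            cid: (
                {num + offsets[cid]: res for num, res in ch.items()}
                if cid in offsets
                else dict(ch)
            )
            for cid, ch in self.chains.items()
        }
        return StructureModel(self.model_id, chains)

    def merged_with(self, other: "StructureModel", model_id: str | None = None) -> "StructureModel":
        """Composite of two models; chain ids must be disjoint."""
        overlap = set(self.chains) & set(other.chains)
        if overlap:
            raise ValueError(f"chain ids not disjoint: {sorted(overlap)}")
        chains = dict(self.chains)
        chains.update(other.chains)
        return StructureModel(model_id or f"{self.model_id}+{other.model_id}", chains)


@dataclass(frozen=True)
class AnchorSpec:
    """A cross-linked residue and the atom preference order used to place it."""

    chain: str
    resnum: int
    atom_order: tuple[str, ...] = ("NZ", "CB", "CA")

    def resolve(self, m: StructureModel) -> tuple[str, np.ndarray]:
        res = m.chains.get(self.chain, {}).get(self.resnum)
        if res is None:
            raise KeyError(
                f"anchor {self.chain}/{self.resnum} not found in model {m.model_id!r}"
            )
        for name in self.atom_order:
            xyz = res.atoms.get(name)
            if xyz is not None:
                if name != self.atom_order[0]:
                    logger.info(
                        "anchor %s/%d: fell back to atom %s", self.chain, self.resnum, name
                    )
                return name, xyz
        raise KeyError(
            f"anchor {self.chain}/{self.resnum}: none of atoms "
            f"{'/'.join(self.atom_order)} present"
        )


@dataclass(frozen=True)
class XLRestraint:
    anchor1: AnchorSpec
    anchor2: AnchorSpec
    cap: float = DEFAULT_CAP
    spacer: float = BS3_SPACER
    label: str = ""
    role: str = "evidence"  # "evidence" | "control"

    def __post_init__(self) -> None:
        if self.role not in ("evidence", "control"):
            raise ValueError(f"restraint role must be evidence or control, got {self.role!r}")


@dataclass(frozen=True)
class RestraintResult:
    restraint: XLRestraint
    distance: float | None
    satisfied: bool | None
    evaluable: bool
    note: str = ""


@dataclass(frozen=True)
class BridgingResult:
    feasible: bool
    bound: float
    mode: str
    d_receptor: float
    d_ligand: float | None


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def load_structure(path: str | Path, first_model_only: bool = True) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Alternate locations collapse to the highest-occupancy copy of each atom.
    When a chain id occurs more than once only the first instance is kept,
    so multi-copy crystals contribute one copy of each protein.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    models = [st[0]] if first_model_only else list(st)
    out_chains: dict[str, dict[int, Residue]] = {}
    occ: dict[tuple[str, int, str], float] = {}
    seen: set[str] = set()
    for model in models:
        for chain in model:
            cid = chain.name
            if cid in seen:
                continue  # duplicate chain id: keep the first instance only
            residues = out_chains.setdefault(cid, {})
            for res in chain:
                num = res.seqid.num
                rec = residues.setdefault(num, Residue(res.name, {}))
                for atom in res:
                    key = (cid, num, atom.name)
                    if atom.name in rec.atoms and occ.get(key, 1.0) >= atom.occ:
                        continue
                    rec.atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
                    occ[key] = atom.occ
        seen.update(c.name for c in model)
    total_atoms = sum(len(r.atoms) for ch in out_chains.values() for r in ch.values())
    if total_atoms == 0:
        raise ValueError(f"{path}: no ATOM records parsed (empty model)")
    return StructureModel(path.stem, out_chains)


def write_structure(path: str | Path, m: StructureModel) -> None:
    """Write a StructureModel to a single-model PDB file."""
    st = gemmi.Structure()
    st.name = m.model_id
    model = gemmi.Model("1")
    for cid, residues in m.chains.items():
        chain = gemmi.Chain(cid)
        for num in sorted(residues):
            res = residues[num]
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(num, " ")
            for aname, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry

def anchor_distance(m: StructureModel, a: AnchorSpec, b: AnchorSpec) -> float:
    """Euclidean distance (Å) between the resolved anchor atoms."""
    _, xa = a.resolve(m)
    _, xb = b.resolve(m)
    return float(np.linalg.norm(xa - xb))


def evaluate_restraints(
    m: StructureModel, restraints: Sequence[XLRestraint]
) -> list[RestraintResult]:
    """Distance and satisfied/violated verdict per restraint.

    A distance exactly equal to the cap is satisfied (the rule is <= cap).
    Unresolvable restraints are reported unevaluable, never dropped.
    """
    out = []
    for r in restraints:
        try:
            d = anchor_distance(m, r.anchor1, r.anchor2)
        except KeyError as exc:
            out.append(RestraintResult(r, None, None, False, str(exc)))
            continue
        out.append(RestraintResult(r, d, d <= r.cap, True))
    return out


def bridging_feasibility(
    d_receptor: float,
    d_ligand: float | None,
    cap: float = DEFAULT_CAP,
    mode: str = "paper",
) -> BridgingResult:
    """Can a single ligand molecule satisfy both cross-links at once?

    ``paper`` mode treats the two ligand anchors as colocated: feasible iff
    d_receptor <= 2*cap (the 30 Å combined-reach bound at the default cap).
    ``triangle`` mode uses the necessary condition from rigid anchor
    geometry: feasible iff |d_receptor - d_ligand| <= 2*cap.
    """
    if d_receptor < 0 or (d_ligand is not None and d_ligand < 0):
        raise ValueError("distances must be non-negative")
    bound = 2.0 * cap
    if mode == "paper":
        return BridgingResult(d_receptor <= bound, bound, mode, d_receptor, d_ligand)
    if mode == "triangle":
        if d_ligand is None:
            raise ValueError("triangle mode requires the ligand anchor distance")
        return BridgingResult(
            abs(d_receptor - d_ligand) <= bound, bound, mode, d_receptor, d_ligand
        )
    raise ValueError(f"unknown bridging mode {mode!r}")


# ---------------------------------------------------------------------------
# Restraint tables

_TSV_COLUMNS = ["label", "chain1", "res1", "chain2", "res2", "cap", "role"]


def read_restraint_tsv(path: str | Path, spacer: float = BS3_SPACER) -> list[XLRestraint]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"restraint table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            XLRestraint(
                AnchorSpec(str(row.chain1), int(row.res1)),
                AnchorSpec(str(row.chain2), int(row.res2)),
                cap=float(row.cap),
                spacer=spacer,
                label=str(row.label),
                role=str(row.role),
            )
        )
    return out


def write_restraint_tsv(path: str | Path, restraints: Sequence[XLRestraint]) -> None:
    rows = [
        {
            "label": r.label,
            "chain1": r.anchor1.chain,
            "res1": r.anchor1.resnum,
            "chain2": r.anchor2.chain,
            "res2": r.anchor2.resnum,
            "cap": r.cap,
            "role": r.role,
        }
        for r in restraints
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
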