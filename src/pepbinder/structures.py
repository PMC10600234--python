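"""Two-chain structure model with per-residue confidence.

Structures are read from PDB files following the AF2 output convention:
the B-factor column carries the per-residue plDDT on a 0-100 scale.
Hydrogens are dropped on parse; all downstream distance metrics are
heavy-atom only. Alternate locations are resolved to the highest-occupancy
conformer (ties keep the first encountered). Only model 1 of multi-model
files is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue", "Chain", "Structure", "ComplexPair", "ParseReport",
    "read_structure", "write_structure", "effective_cb", "mean_plddt",
    "StructureError", "PlddtScaleError",
]

BACKBONE_ATOMS = ("N", "CA", "C")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


class StructureError(ValueError):
    """Malformed or unusable structure input."""


class PlddtScaleError(StructureError):
    """B-factors look like plDDT on a 0-1 scale instead of 0-100."""


@dataclass
class Residue:
    """One residue: author number, one-letter code, named heavy atoms, plDDT.

    ``atoms`` maps atom names (``"CA"``, ``"CB"``, ...) to 3-vectors in Å.
    ``plddt`` is the per-residue predicted lDDT on [0, 100].
    """

    index: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float = 0.0

    def __post_init__(self) -> None:
        for name, coord in self.atoms.items():
            coord = np.asarray(coord, dtype=float)
            if coord.shape != (3,) or not np.all(np.isfinite(coord)):
                raise StructureError(
                    f"residue {self.index}: atom {name} has non-finite or "
                    f"malformed coordinate {coord!r}"
                )
            self.atoms[name] = coord
        if not (0.0 <= self.plddt <= 100.0):
            raise StructureError(
                f"residue {self.index}: plddt {self.plddt} outside [0, 100]"
            )

    def heavy_coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates (hydrogens are never stored)."""
        return np.array(list(self.atoms.values()), dtype=float).reshape(-1, 3)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


def effective_cb(residue: Residue) -> np.ndarray:
    """Coordinate used by the Cβ interface rule: CB, or CA for glycine.

    Falls back to CA whenever CB is absent, which keeps the rule total over
    glycine and over residues with truncated side chains.
    """
    if "CB" in residue.atoms:
        return residue.atoms["CB"]
    if "CA" in residue.atoms:
        return residue.atoms["CA"]
    raise StructureError(f"residue {residue.index} has neither CB nor CA")


@dataclass
class Chain:
    """Ordered, non-empty list of residues under one chain id."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"chain {self.id!r} is empty")
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise StructureError(
                f"chain {self.id!r}: residue indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue_by_index(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"chain {self.id!r} has no residue with author index {index}")

    def position_of(self, index: int) -> int:
        """1-based ordinal position of the residue with the given author index."""
        for pos, r in enumerate(self.residues, start=1):
            if r.index == index:
                return pos
        raise KeyError(f"chain {self.id!r} has no residue with author index {index}")

    def ca_coords(self) -> np.ndarray:
        coords = [r.atoms["CA"] for r in self.residues if "CA" in r.atoms]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues]
        return np.vstack(parts)

    def effective_cb_coords(self) -> np.ndarray:
        return np.array([effective_cb(r) for r in self.residues], dtype=float)


@dataclass
class ParseReport:
    """Per-structure parse diagnostics.

    ``missing_backbone`` lists (chain id, residue index, missing atom names)
    for residues that lack any of N, CA, C — such regions make a structure
    unusable as an inverse-folding input and are flagged rather than dropped.
    """

    missing_backbone: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.missing_backbone


@dataclass
class Structure:
    """A collection of chains plus parse diagnostics."""

    chains: list[Chain]
    report: ParseReport = field(default_factory=ParseReport)

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}; have {self.chain_ids()}")


@dataclass
class ComplexPair:
    """A two-chain complex with designated receptor and binder roles."""

    structure: Structure
    receptor_chain: str
    binder_chain: str

    def __post_init__(self) -> None:
        if self.receptor_chain == self.binder_chain:
            raise StructureError("receptor and binder chains must be distinct")
        # raises KeyError early if either chain is absent
        self.structure.get_chain(self.receptor_chain)
        self.structure.get_chain(self.binder_chain)

    @property
    def receptor(self) -> Chain:
        return self.structure.get_chain(self.receptor_chain)

    @property
    def binder(self) -> Chain:
        return self.structure.get_chain(self.binder_chain)


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties keep the first seen."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return list(chosen.values())


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    B-factors are read as per-residue plDDT (the residue value is taken from
    CA, or the first heavy atom if CA is absent). Structures whose plDDT
    values all fall in (0, 1] are rejected: the toolkit fixes the 0-100
    convention and silently rescaling would corrupt every threshold.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}; only 'pdb' is handled")
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]

    report = ParseReport()
    chains: list[Chain] = []
    plddt_seen: list[float] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms: dict[str, np.ndarray] = {}
            bvals: dict[str, float] = {}
            for atom in _resolve_altlocs(gres):
                if atom.element.is_hydrogen:
                    continue
                pos = atom.pos
                atoms[atom.name] = np.array([pos.x, pos.y, pos.z])
                bvals[atom.name] = atom.b_iso
            if not atoms:
                continue
            b = bvals.get("CA", next(iter(bvals.values())))
            if not (0.0 <= b <= 100.0):
                raise PlddtScaleError(
                    f"{path}: B-factor {b} at residue {gres.seqid.num} is outside "
                    "[0, 100]; plDDT must follow the AF2 0-100 convention"
                )
            aa = THREE_TO_ONE.get(gres.name, "X")
            residue = Residue(index=gres.seqid.num, aa=aa, atoms=atoms, plddt=b)
            missing = tuple(a for a in BACKBONE_ATOMS if a not in atoms)
            if missing:
                report.missing_backbone.append((gchain.name, gres.seqid.num, missing))
            residues.append(residue)
            plddt_seen.append(b)
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains:
        raise StructureError(f"{path} contains no protein chains with heavy atoms")
    if plddt_seen and 0.0 < max(plddt_seen) <= 1.0:
        raise PlddtScaleError(
            f"{path}: all plDDT values are in (0, 1] — they look like a 0-1 "
            "scale. Rescale to 0-100 before use; automatic rescaling is refused."
        )
    return Structure(chains=chains, report=report)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write standard ATOM records, 3-decimal coordinates, plDDT as B-factor."""
    st = gemmi.Structure()
    st.name = "pepbinder"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.index, " ")
            for name, coord in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                atom.b_iso = res.plddt
                atom.element = gemmi.Element(_element_of(name))
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _element_of(atom_name: str) -> str:
    """Element symbol for standard protein heavy-atom names (N, CA, CB, SD, OG...)."""
    lead = atom_name.strip()[0]
    return lead if lead in "CNOS" else "C"


def mean_plddt(structure: Structure | Chain, chain: str | None = None) -> float:
    """Arithmetic mean of per-residue plDDT over one chain.

    Accepts either a :class:`Structure` plus a chain id, or a :class:`Chain`
    directly.
    """
    if isinstance(structure, Chain):
        target = structure
    else:
        if chain is None:
            raise ValueError("chain id required when passing a Structure")
        target = structure.get_chain(chain)
    return float(np.mean([r.plddt for r in target.residues]))
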