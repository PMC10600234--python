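"""Interface geometry: Cβ contacts, superposition, interface RMSD, ΔCOM.

The interface between a receptor and a binder chain is the set of residue
pairs whose effective Cβ atoms (CA for glycine) lie within 8 Å of each
other; the comparison is inclusive at the cutoff. Interface RMSD is
computed over the binder's native interface Cβ atoms after least-squares
superposition of the two receptors on their shared CA atoms, so the
receptor frame — not the binder pose — defines the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from pepbinder.structures import Chain, ComplexPair, effective_cb

__all__ = [
    "ContactPair", "InterfaceDefinition", "RigidTransform",
    "contact_pairs", "contact_density", "superpose_receptor",
    "interface_rmsd", "delta_com", "receptor_if_distance",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 8.0  # Å, inclusive


@dataclass(frozen=True)
class ContactPair:
    """One cross-chain residue contact under the Cβ rule."""

    receptor_residue: int
    binder_residue: int
    cb_distance: float


@dataclass
class InterfaceDefinition:
    """All Cβ contacts at a cutoff, plus the projected interface residue sets."""

    cutoff: float
    pairs: list[ContactPair]
    receptor_interface: frozenset[int] = field(init=False)
    binder_interface: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        self.receptor_interface = frozenset(p.receptor_residue for p in self.pairs)
        self.binder_interface = frozenset(p.binder_residue for p in self.pairs)

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


@dataclass
class RigidTransform:
    """Proper rigid-body transform x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1); reflections disallowed")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def contact_pairs(
    complex: ComplexPair, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> InterfaceDefinition:
    """All receptor-binder residue pairs with effective-Cβ distance ≤ cutoff."""
    receptor, binder = complex.receptor, complex.binder
    rcb = receptor.effective_cb_coords()
    bcb = binder.effective_cb_coords()
    tree = cKDTree(bcb)
    pairs: list[ContactPair] = []
    for i, hits in enumerate(tree.query_ball_point(rcb, r=cutoff)):
        for j in sorted(hits):
            d = float(np.linalg.norm(rcb[i] - bcb[j]))
            pairs.append(
                ContactPair(
                    receptor_residue=receptor.residues[i].index,
                    binder_residue=binder.residues[j].index,
                    cb_distance=d,
                )
            )
    return InterfaceDefinition(cutoff=cutoff, pairs=pairs)


def contact_density(interface: InterfaceDefinition, binder_length: int) -> float:
    """Contacts per binder residue: |pairs| / binder length."""
    if binder_length < 1:
        raise ValueError("binder_length must be >= 1")
    return interface.n_contacts / binder_length


def _paired_receptor_ca(native: ComplexPair, predicted: ComplexPair) -> tuple[np.ndarray, np.ndarray]:
    """Receptor CA coordinate pairs matched by author residue index."""
    nat_ca = {r.index: r.atoms["CA"] for r in native.receptor.residues if "CA" in r.atoms}
    pred_ca = {r.index: r.atoms["CA"] for r in predicted.receptor.residues if "CA" in r.atoms}
    shared = sorted(nat_ca.keys() & pred_ca.keys())
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 receptor residues pairable by index with CA; found {len(shared)}"
        )
    return (
        np.array([nat_ca[i] for i in shared]),
        np.array([pred_ca[i] for i in shared]),
    )


def superpose_receptor(native: ComplexPair, predicted: ComplexPair) -> RigidTransform:
    """Kabsch least-squares transform mapping predicted receptor CAs onto native.

    Only proper rotations are considered, so a mirror-image receptor yields a
    valid transform with a large residual rather than a reflection.
    """
    nat, pred = _paired_receptor_ca(native, predicted)
    nat_c = nat.mean(axis=0)
    pred_c = pred.mean(axis=0)
    rot, _ = Rotation.align_vectors(nat - nat_c, pred - pred_c)
    r = rot.as_matrix()
    return RigidTransform(rotation=r, translation=nat_c - r @ pred_c)


def interface_rmsd(
    native: ComplexPair,
    predicted: ComplexPair,
    interface: InterfaceDefinition | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """Binder interface RMSD after receptor CA superposition.

    Deviations are measured over the effective-Cβ atoms of the *native*
    binder interface residues; the predicted partner of each is found by
    sequence position (designed binders carry no meaningful author
    numbering). The receptor enters only through the superposition.
    """
    if interface is None:
        interface = contact_pairs(native, cutoff=cutoff)
    if not interface.binder_interface:
        raise ValueError("native complex has no binder interface residues")
    frame = superpose_receptor(native, predicted)

    nat_binder = native.binder
    pred_binder = predicted.binder
    nat_pts, pred_pts = [], []
    unpairable = []
    for idx in sorted(interface.binder_interface):
        res = nat_binder.residue_by_index(idx)
        pos = nat_binder.position_of(idx)  # 1-based ordinal
        if pos > len(pred_binder):
            unpairable.append(idx)
            continue
        nat_pts.append(effective_cb(res))
        pred_pts.append(effective_cb(pred_binder.residues[pos - 1]))
    if unpairable:
        raise ValueError(
            f"native binder interface residues with no positional partner in the "
            f"predicted binder: {unpairable}"
        )
    nat_pts = np.array(nat_pts)
    pred_pts = frame.apply(np.array(pred_pts))
    return float(np.sqrt(np.mean(np.sum((nat_pts - pred_pts) ** 2, axis=1))))


def delta_com(
    predicted_binder: Chain, reference_binder: Chain, frame: RigidTransform
) -> float:
    """Distance between binder CA centroids in the receptor-aligned frame.

    The reference binder (seed, or native binder when no seed exists) stays
    in its own frame; ``frame`` — from :func:`superpose_receptor` — carries
    the predicted binder into it.
    """
    pred_ca = predicted_binder.ca_coords()
    ref_ca = reference_binder.ca_coords()
    if pred_ca.size == 0 or ref_ca.size == 0:
        raise ValueError("both binders need at least one CA atom")
    pred_centroid = frame.apply(pred_ca).mean(axis=0)
    ref_centroid = ref_ca.mean(axis=0)
    return float(np.linalg.norm(pred_centroid - ref_centroid))


def receptor_if_distance(
    receptor: Chain, target_residues: set[int] | frozenset[int], binder: Chain
) -> float:
    """Mean over receptor-target heavy atoms of the shortest distance to the binder.

    For every heavy atom of every listed receptor residue, take the minimum
    distance to any binder heavy atom, then average those minima.
    """
    if not target_residues:
        raise ValueError("target residue set is empty")
    target_atoms = np.vstack(
        [receptor.residue_by_index(i).heavy_coords() for i in sorted(target_residues)]
    )
    binder_atoms = binder.heavy_coords()
    dists = cdist(target_atoms, binder_atoms)
    return float(dists.min(axis=1).mean())
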