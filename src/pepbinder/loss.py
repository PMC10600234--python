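"""The bind-score loss used to evaluate and select designed binders.

The loss combines three signals — how confident the structure predictor is
in the binder (mean binder plDDT), how close binder and receptor target
residues sit (two directed mean shortest-atom distances), and whether the
binder landed at the intended interface rather than a symmetry-equivalent
site (ΔCOM to a reference binder in the receptor-aligned frame):

    loss = binder_plddt^-1 * ( d̄_target→binder + d̄_binder→target * 1/2 * ΔCOM )

where d̄_target→binder averages, over the m heavy atoms of the receptor
target residues, each atom's shortest distance to any binder heavy atom,
and d̄_binder→target averages the n binder heavy atoms' shortest distances
back to the target atoms. Low loss means a confident, tightly packed,
on-target placement. The ΔCOM factor multiplies only the binder→target
term; ``com_scales_sum=True`` switches to the alternative grouping in
which ½·ΔCOM scales the whole parenthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from pepbinder.geometry import RigidTransform, delta_com
from pepbinder.structures import Chain, ComplexPair

__all__ = ["LossBreakdown", "SelectionThresholds", "compute_loss", "select_binders"]


@dataclass
class LossBreakdown:
    """All components of the bind score plus the assembled value.

    ``delta_com`` is ``None`` when no reference binder was available; the
    ΔCOM term is then zeroed and ``loss`` reflects only the target→binder
    distance, which callers should treat as a degenerate mode.
    """

    binder_plddt: float
    mean_target_to_binder: float   # d̄_i over m receptor-target heavy atoms
    mean_binder_to_target: float   # d̄_j over n binder heavy atoms
    n_target_atoms: int
    n_binder_atoms: int
    delta_com: float | None
    loss: float

    @property
    def has_reference(self) -> bool:
        return self.delta_com is not None


@dataclass
class SelectionThresholds:
    """Inclusive selection cutoffs for designed binders.

    The zero-shot campaign uses a strict loss cutoff (0.11) on its own;
    convergence campaigns pair a looser loss cutoff (1.0) with a plDDT
    floor of 80. Success for a design means interface RMSD ≤ 2 Å.
    """

    loss_cutoff: float = 1.0
    min_plddt: float = 80.0
    success_rmsd: float = 2.0

    ZERO_SHOT_LOSS_CUTOFF = 0.11

    def __post_init__(self) -> None:
        if min(self.loss_cutoff, self.min_plddt, self.success_rmsd) <= 0:
            raise ValueError("all thresholds must be positive")


def compute_loss(
    predicted: ComplexPair,
    target_residues: set[int] | frozenset[int],
    reference_binder: Chain | None = None,
    frame: RigidTransform | None = None,
    com_scales_sum: bool = False,
) -> LossBreakdown:
    """Evaluate the bind score of a predicted complex against target residues.

    ``frame`` must come from superposing the predicted receptor onto the
    reference (seed or native) receptor; it is applied only inside the ΔCOM
    term, since atom-atom distances within the predicted complex are frame
    invariant. With no reference binder the ΔCOM term is zeroed and flagged.
    """
    if not target_residues:
        raise ValueError("target residue set is empty")
    binder = predicted.binder
    plddt = float(np.mean([r.plddt for r in binder.residues]))
    if plddt <= 0:
        raise ValueError("binder plDDT is zero; the loss is undefined")

    target_atoms = np.vstack(
        [
            predicted.receptor.residue_by_index(i).heavy_coords()
            for i in sorted(target_residues)
        ]
    )
    binder_atoms = binder.heavy_coords()
    dists = cdist(target_atoms, binder_atoms)
    d_target = float(dists.min(axis=1).mean())  # m terms
    d_binder = float(dists.min(axis=0).mean())  # n terms

    dcom: float | None = None
    if reference_binder is not None:
        if frame is None:
            frame = RigidTransform.identity()
        dcom = delta_com(binder, reference_binder, frame)
    dcom_term = 0.0 if dcom is None else dcom

    if com_scales_sum:
        loss = (d_target + d_binder) * 0.5 * dcom_term / plddt
    else:
        loss = (d_target + d_binder * 0.5 * dcom_term) / plddt

    return LossBreakdown(
        binder_plddt=plddt,
        mean_target_to_binder=d_target,
        mean_binder_to_target=d_binder,
        n_target_atoms=target_atoms.shape[0],
        n_binder_atoms=binder_atoms.shape[0],
        delta_com=dcom,
        loss=loss,
    )


def select_binders(records: Iterable, thresholds: SelectionThresholds) -> list:
    """Designs passing loss ≤ cutoff and binder plDDT ≥ floor, order preserved.

    Works on any records exposing ``loss`` and ``binder_plddt`` attributes
    (e.g. :class:`~pepbinder.evaluation.DesignRecord`).
    """
    return [
        r
        for r in records
        if r.loss <= thresholds.loss_cutoff and r.binder_plddt >= thresholds.min_plddt
    ]
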