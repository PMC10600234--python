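"""Synthetic receptor-binder complexes and design tables with known ground truth.

Real evaluation data comes from GPU-scale structure-prediction campaigns;
these generators build geometrically controlled stand-ins so every metric
in the toolkit can be checked against analytic expectations. Complexes are
idealised two-strand arrangements in which the number of Cβ contacts, the
rigid displacement of the "predicted" binder, and the per-residue plDDT
are all dialed in exactly; design tables plant a joint loss/RMSD structure
so selection statistics have a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from pepbinder.evaluation import DesignRecord
from pepbinder.structures import Chain, ComplexPair, Residue, Structure

__all__ = ["FixtureSpec", "make_ideal_complex", "make_design_table"]

_RISE = 4.0          # Å between consecutive residues along the chain axis
_CONTACT_CB = 7.5    # Å Cβ-Cβ distance for engineered contacts (inside 8 Å)
# 7.5 Å laterally with a 4 Å axial stagger puts off-register pairs at
# sqrt(7.5² + 4²) ≈ 8.5 Å, so each engaged binder residue contributes
# exactly one contact.


@dataclass
class FixtureSpec:
    """Recipe for one synthetic native/predicted complex pair.

    ``displacement`` is applied rigidly to the predicted binder (a scalar
    means along +x); ``rotation_deg`` additionally rotates the whole
    predicted complex, which receptor superposition must absorb. plDDT is
    drawn uniformly from [50, 95] unless ``plddt_values`` is given.
    """

    receptor_length: int = 20
    binder_length: int = 10
    n_contacts: int = 5
    displacement: float | tuple[float, float, float] = 0.0
    rotation_deg: float = 0.0
    plddt_values: np.ndarray | None = None
    rng_seed: int = 0

    def displacement_vector(self) -> np.ndarray:
        if np.isscalar(self.displacement):
            return np.array([float(self.displacement), 0.0, 0.0])
        return np.asarray(self.displacement, dtype=float)


def _strand_residue(index: int, ca: np.ndarray, cb: np.ndarray, plddt: float) -> Residue:
    """An alanine-like residue with full backbone and an explicit Cβ."""
    ca = np.asarray(ca, dtype=float)
    atoms = {
        "N": ca + np.array([-0.5, 1.2, -0.8]),
        "CA": ca,
        "C": ca + np.array([0.6, 1.1, 0.8]),
        "O": ca + np.array([0.6, 2.3, 0.8]),
        "CB": np.asarray(cb, dtype=float),
    }
    return Residue(index=index, aa="A", atoms=atoms, plddt=plddt)


def _ca_wobble(ordinal: int) -> np.ndarray:
    """Small helical offset (100° twist) so chain CAs are never collinear.

    Collinear CAs would make the receptor superposition rotationally
    degenerate; the 0.9 Å radius keeps the Cβ contact lattice untouched.
    """
    theta = np.deg2rad(100.0) * ordinal
    return 0.9 * np.array([np.cos(theta), np.sin(theta), 0.0])


def make_ideal_complex(
    spec: FixtureSpec,
) -> tuple[ComplexPair, ComplexPair, dict[str, float]]:
    """Build a native complex with an exact contact count, plus a displaced copy.

    The receptor runs along z with Cβs pointing toward the binder. The
    first ``n_contacts`` binder residues sit in register with receptor
    residues at an engineered 7.5 Å Cβ-Cβ distance (one contact each);
    the remaining binder residues trail past the receptor's end, out of
    contact range. The predicted complex is the native one with the binder
    rigidly displaced and the whole complex optionally rotated, so the
    analytic ground truth is: interface RMSD = ΔCOM = |displacement|.
    """
    R, B, c = spec.receptor_length, spec.binder_length, spec.n_contacts
    if R < 1 or B < 1:
        raise ValueError("chain lengths must be >= 1")
    if not 0 <= c <= min(R, B):
        raise ValueError(
            f"contact count {c} infeasible for receptor {R} / binder {B}: "
            f"this construction yields at most one contact per binder residue"
        )
    rng = np.random.default_rng(spec.rng_seed)
    if spec.plddt_values is not None:
        plddt = np.asarray(spec.plddt_values, dtype=float)
        if plddt.size != R + B:
            raise ValueError(f"need {R + B} plddt values, got {plddt.size}")
    else:
        plddt = rng.uniform(50.0, 95.0, size=R + B)

    receptor = Chain(
        id="A",
        residues=[
            _strand_residue(
                i,
                np.array([0.0, 0.0, _RISE * i]) + _ca_wobble(i),
                np.array([1.5, 0.0, _RISE * i]),
                plddt[i - 1],
            )
            for i in range(1, R + 1)
        ],
    )
    # engaged binder Cβ sits at x = 1.5 + 7.5 = 9.0, its CA a further 1.5 Å out
    binder_res = []
    for j in range(1, B + 1):
        if j <= c:
            z = _RISE * j
        else:
            z = _RISE * (R + 3 + (j - c))  # past the receptor end, out of range
        cb = np.array([1.5 + _CONTACT_CB, 0.0, z])
        ca = cb + np.array([1.5, 0.0, 0.0]) + _ca_wobble(j)
        binder_res.append(_strand_residue(j, ca, cb, plddt[R + j - 1]))
    binder = Chain(id="B", residues=binder_res)
    native = ComplexPair(Structure([receptor, binder]), "A", "B")

    disp = spec.displacement_vector()
    rot = Rotation.from_rotvec(
        np.deg2rad(spec.rotation_deg) * np.array([0.36, 0.48, 0.8])
    ).as_matrix()

    def transform_chain(chain: Chain, extra: np.ndarray) -> Chain:
        return Chain(
            id=chain.id,
            residues=[
                Residue(
                    index=r.index,
                    aa=r.aa,
                    atoms={n: rot @ (xyz + extra) for n, xyz in r.atoms.items()},
                    plddt=r.plddt,
                )
                for r in chain.residues
            ],
        )

    pred_receptor = transform_chain(receptor, np.zeros(3))
    pred_binder = transform_chain(binder, disp)
    predicted = ComplexPair(Structure([pred_receptor, pred_binder]), "A", "B")

    ground_truth = {
        "contact_count": float(c),
        "interface_rmsd": float(np.linalg.norm(disp)),
        "delta_com": float(np.linalg.norm(disp)),
    }
    return native, predicted, ground_truth


def make_design_table(
    n_targets: int,
    designs_per_target: int,
    success_prob: float = 0.065,
    rng_seed: int = 0,
    noise: float = 0.15,
) -> list[DesignRecord]:
    """A reproducible design campaign with planted structure.

    Each target gets a seed contact density; the per-target success
    probability scales with density around the campaign-wide
    ``success_prob`` (default 6.5%, a realistic rate for heteromeric
    interfaces). Successful designs draw interface RMSD below 2 Å,
    failures above 2.5 Å; binder plDDT falls with RMSD and the loss is a
    noisy monotone function of RMSD over plDDT, so low loss implies low
    RMSD up to the configured noise.
    """
    if not 0.0 <= success_prob <= 1.0:
        raise ValueError("success_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    records: list[DesignRecord] = []
    lengths = (10, 20, 30, 40, 50)
    for t in range(n_targets):
        target_id = f"T{t:04d}"
        density = rng.uniform(0.5, 9.0)
        p_t = float(np.clip(success_prob * density / 4.75, 0.0, 1.0))
        length = int(rng.choice(lengths))
        for k in range(1, designs_per_target + 1):
            success = bool(rng.random() < p_t)
            if success:
                rmsd = float(rng.uniform(0.3, 2.0))
            else:
                rmsd = float(rng.uniform(2.5, 15.0))
            plddt = float(np.clip(95.0 - 4.0 * rmsd + rng.normal(0.0, 5.0), 20.0, 99.0))
            loss = float(rmsd * 2.0 / plddt * np.exp(noise * rng.normal()))
            recov = float(np.clip(1.0 - rmsd / 10.0 + rng.normal(0.0, 0.05), 0.0, 1.0))
            seq_rec = float(np.clip(recov + rng.normal(0.0, 0.1), 0.0, 1.0))
            records.append(
                DesignRecord(
                    target_id=target_id,
                    design_id=f"{target_id}_d{k:03d}",
                    design_order=k,
                    length=length,
                    loss=loss,
                    binder_plddt=plddt,
                    interface_rmsd=rmsd,
                    contact_recovery=recov,
                    seq_recovery=seq_rec,
                    contact_density=density,
                )
            )
    return records
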