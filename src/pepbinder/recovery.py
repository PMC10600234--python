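"""Sequence-level design metrics: contact recovery, interface identity, mutation scans.

Designed binders rarely reproduce the native sequence exactly, and do not
need to: different amino acids of the same physical character can satisfy
the same receptor contact. Contact recovery therefore compares the
*categories* of binder residues contacting each receptor interface
position — five classes (Hydrophobic / Small / Polar / Positive /
Negative) partitioning the 20 standard amino acids — and scores the
fraction of the native per-position category annotations preserved by the
design. Extra categories introduced by the design are ignored: the
measure is recall of native interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pepbinder.geometry import InterfaceDefinition

__all__ = [
    "AA_CATEGORIES", "aa_category", "RecoveryResult",
    "contact_recovery", "interface_sequence_recovery", "mutation_scan",
]

AA_CATEGORIES: dict[str, frozenset[str]] = {
    "Hydrophobic": frozenset("AFILMPVWY"),
    "Small": frozenset("G"),
    "Polar": frozenset("NCQST"),
    "Positive": frozenset("RHK"),
    "Negative": frozenset("DE"),
}

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

_CODE_TO_CATEGORY = {
    code: name for name, members in AA_CATEGORIES.items() for code in members
}


def aa_category(code: str) -> str:
    """Category name for a standard one-letter amino-acid code."""
    try:
        return _CODE_TO_CATEGORY[code.upper()]
    except KeyError:
        raise ValueError(f"{code!r} is not a standard one-letter amino-acid code")


@dataclass
class RecoveryResult:
    """Contact-recovery fraction plus the per-receptor-position category sets."""

    fraction: float
    per_position: dict[int, tuple[frozenset[str], frozenset[str]]]


def _categories_per_receptor_position(
    interface: InterfaceDefinition, binder_seq: str
) -> dict[int, frozenset[str]]:
    """Unique contacting-residue categories per receptor interface residue.

    Binder residue indices in the interface are interpreted as 1-based
    positions into ``binder_seq``. Non-standard residues ('X') carry no
    category and are excluded.
    """
    cats: dict[int, set[str]] = {}
    for pair in interface.pairs:
        pos = pair.binder_residue
        if not 1 <= pos <= len(binder_seq):
            raise ValueError(
                f"interface binder position {pos} outside sequence of length "
                f"{len(binder_seq)}"
            )
        code = binder_seq[pos - 1]
        if code not in _CODE_TO_CATEGORY:
            continue
        cats.setdefault(pair.receptor_residue, set()).add(_CODE_TO_CATEGORY[code])
    return {k: frozenset(v) for k, v in cats.items()}


def contact_recovery(
    native_interface: InterfaceDefinition,
    design_interface: InterfaceDefinition,
    native_binder_seq: str,
    design_seq: str,
) -> RecoveryResult:
    """Fraction of native per-receptor-position category annotations preserved.

    For each receptor interface residue, the unique categories of its
    contacting binder residues are collected for native and design; repeat
    contacts within a category count once (native contacts to A, F and R
    annotate {Hydrophobic, Positive}). A design annotation is recovered only
    if the same category appears at the same receptor position natively.
    """
    if not native_interface.pairs:
        raise ValueError("native interface is empty")
    native_cats = _categories_per_receptor_position(native_interface, native_binder_seq)
    design_cats = _categories_per_receptor_position(design_interface, design_seq)

    total = sum(len(v) for v in native_cats.values())
    recovered = sum(
        len(v & design_cats.get(pos, frozenset())) for pos, v in native_cats.items()
    )
    per_position = {
        pos: (v, design_cats.get(pos, frozenset())) for pos, v in native_cats.items()
    }
    return RecoveryResult(fraction=recovered / total, per_position=per_position)


def interface_sequence_recovery(
    native_seq: str, design_seq: str, interface_positions: Sequence[int]
) -> float:
    """Identity over the native binder interface positions (1-based, linear).

    The number of positions where native and design carry the same residue,
    divided by the number of interface positions N.
    """
    if not interface_positions:
        raise ValueError("no interface positions given")
    for pos in interface_positions:
        if not 1 <= pos <= len(design_seq) or pos > len(native_seq):
            raise ValueError(f"interface position {pos} outside sequence bounds")
    matches = sum(1 for pos in interface_positions if native_seq[pos - 1] == design_seq[pos - 1])
    return matches / len(interface_positions)


def mutation_scan(
    native_seq: str,
    contact_positions: Sequence[int],
    per_count: int = 10,
    rng_seed: int = 0,
) -> list[str]:
    """Randomly mutate receptor-contacting positions, sweeping mutation load.

    For each k in 1..L (L = number of contact positions), emits ``per_count``
    sequences differing from native at exactly k randomly chosen contact
    positions, each substituted by a uniformly drawn non-identical standard
    amino acid — 10·L sequences at the default. Deterministic under
    ``rng_seed``.
    """
    if per_count < 1:
        raise ValueError("per_count must be >= 1")
    for pos in contact_positions:
        if not 1 <= pos <= len(native_seq):
            raise ValueError(f"contact position {pos} outside sequence of length {len(native_seq)}")
    rng = np.random.default_rng(rng_seed)
    positions = list(contact_positions)
    out: list[str] = []
    for k in range(1, len(positions) + 1):
        for _ in range(per_count):
            chosen = rng.choice(len(positions), size=k, replace=False)
            seq = list(native_seq)
            for ci in chosen:
                pos = positions[ci]
                alternatives = [a for a in STANDARD_AAS if a != native_seq[pos - 1]]
                seq[pos - 1] = alternatives[rng.integers(len(alternatives))]
            out.append("".join(seq))
    return out
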