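"""Backbone seed selection from scaffold hits and design-input assembly.

A seed is a contiguous 10-50 residue backbone fragment cropped from a
scaffold structure (e.g. a Foldseek hit against the PDB) so as to maximise
the number of Cβ contacts to a chosen receptor target interface. Seeds
with high contact density make downstream sequence design far more likely
to succeed, so crops are ranked by contact count.

The assembled inverse-folding input places the receptor backbone first,
then a masked spacer, then the seed. The binder is deliberately never
placed first: sequence models trained on single chains carry a strong
bias toward methionine at position 1, which receptor-first ordering
avoids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pepbinder.geometry import DEFAULT_CONTACT_CUTOFF
from pepbinder.structures import BACKBONE_ATOMS, Chain, Residue, effective_cb

__all__ = [
    "SeedCrop", "DesignInput", "best_crop", "rank_crops",
    "build_design_input", "read_foldseek_hits", "SEED_LENGTHS",
]

SEED_LENGTHS = (10, 20, 30, 40, 50)

FOLDSEEK_COLUMNS = [
    "query", "target", "fident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bits",
]


@dataclass
class SeedCrop:
    """A contiguous scaffold window scored by contacts to the target interface.

    ``start`` is the 1-based ordinal of the first residue within the
    scaffold chain. ``length`` may be shorter than requested when the
    scaffold itself is shorter — the whole scaffold is then used.
    """

    source_id: str
    start: int
    length: int
    contact_count: int
    contact_density: float
    residues: list[Residue] = field(default_factory=list, repr=False)

    @property
    def zero_contact(self) -> bool:
        return self.contact_count == 0


def best_crop(
    scaffold: Chain,
    receptor: Chain,
    target_interface: set[int] | frozenset[int],
    length: int,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    source_id: str | None = None,
) -> SeedCrop:
    """The window of the requested length with the most Cβ contacts to the target.

    Contacts are counted only toward the listed receptor target residues.
    Ties break toward the smallest start; a scaffold shorter than ``length``
    is returned whole. A crop with no contacts anywhere is still returned,
    flagged via :attr:`SeedCrop.zero_contact`.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not target_interface:
        raise ValueError("target interface is empty")
    target_cb = np.array(
        [effective_cb(receptor.residue_by_index(i)) for i in sorted(target_interface)]
    )
    scaffold_cb = scaffold.effective_cb_coords()
    # per-scaffold-residue contact counts to the target interface
    diffs = scaffold_cb[:, None, :] - target_cb[None, :, :]
    per_residue = (np.linalg.norm(diffs, axis=2) <= cutoff).sum(axis=1)

    eff_len = min(length, len(scaffold))
    window_sums = np.convolve(per_residue, np.ones(eff_len, dtype=int), mode="valid")
    start0 = int(np.argmax(window_sums))  # argmax takes the first maximum
    count = int(window_sums[start0])
    return SeedCrop(
        source_id=source_id if source_id is not None else scaffold.id,
        start=start0 + 1,
        length=eff_len,
        contact_count=count,
        contact_density=count / eff_len,
        residues=scaffold.residues[start0 : start0 + eff_len],
    )


def rank_crops(
    hits: list[tuple[Chain, str]],
    receptor: Chain,
    target_interface: set[int] | frozenset[int],
    lengths: tuple[int, ...] = SEED_LENGTHS,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[SeedCrop]:
    """Best crop per hit per length, ordered best-first.

    Sorted by contact count (descending), then contact density (descending),
    then scaffold id.
    """
    if not hits:
        raise ValueError("no scaffold hits given")
    crops = [
        best_crop(chain, receptor, target_interface, L, cutoff=cutoff, source_id=hit_id)
        for chain, hit_id in hits
        for L in sorted(lengths)
    ]
    crops.sort(key=lambda c: (-c.contact_count, -c.contact_density, c.source_id))
    return crops


@dataclass
class DesignInput:
    """Concatenated backbone blocks for an inverse-folding model.

    ``blocks`` is an ordered list of (role, coords) where role is one of
    "receptor", "mask", "seed"; masked positions carry no coordinates
    (``None``), only a sentinel. The receptor block always comes first.
    """

    blocks: list[tuple[str, list[dict[str, list[float]] | None]]]
    mask_length: int

    def __post_init__(self) -> None:
        roles = [role for role, _ in self.blocks]
        if roles and roles[0] != "receptor":
            raise ValueError("receptor block must come first")

    @property
    def total_length(self) -> int:
        return sum(len(positions) for _, positions in self.blocks)

    def masked_positions(self) -> list[int]:
        """1-based positions flagged as masked in the concatenated input."""
        out, offset = [], 0
        for role, positions in self.blocks:
            if role == "mask":
                out.extend(range(offset + 1, offset + len(positions) + 1))
            offset += len(positions)
        return out

    def to_json(self) -> str:
        return json.dumps({"mask_length": self.mask_length, "blocks": self.blocks})

    @classmethod
    def from_json(cls, text: str) -> "DesignInput":
        data = json.loads(text)
        blocks = [(role, positions) for role, positions in data["blocks"]]
        return cls(blocks=blocks, mask_length=data["mask_length"])


def _backbone_block(chain_or_residues, label: str) -> list[dict[str, list[float]]]:
    residues = getattr(chain_or_residues, "residues", chain_or_residues)
    block = []
    for res in residues:
        missing = [a for a in BACKBONE_ATOMS if a not in res.atoms]
        if missing:
            raise ValueError(
                f"{label} residue {res.index} is missing backbone atoms {missing}"
            )
        block.append({a: [float(x) for x in res.atoms[a]] for a in BACKBONE_ATOMS})
    return block


def build_design_input(
    receptor: Chain, seed: SeedCrop, mask_length: int = 10
) -> DesignInput:
    """Assemble receptor → mask → seed backbone blocks.

    Every receptor and seed residue must carry N, CA and C coordinates;
    masked spacer positions carry a sentinel instead of coordinates.
    ``mask_length`` 0 gives direct concatenation.
    """
    if mask_length < 0:
        raise ValueError("mask_length must be >= 0")
    if not seed.residues:
        raise ValueError("seed crop carries no residues")
    blocks: list[tuple[str, list]] = [("receptor", _backbone_block(receptor, "receptor"))]
    if mask_length:
        blocks.append(("mask", [None] * mask_length))
    blocks.append(("seed", _backbone_block(seed.residues, "seed")))
    return DesignInput(blocks=blocks, mask_length=mask_length)


def read_foldseek_hits(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a Foldseek-style tab-separated hit table.

    Assumes the default 12-column output layout unless ``columns`` is given.
    """
    return pd.read_csv(path, sep="\t", header=None, names=columns or FOLDSEEK_COLUMNS)
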