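"""Campaign-level analytics for binder-design runs.

Operates on tables of per-design records (one row per designed sequence
evaluated against a target interface): ROC analysis of how well the bind
score separates successful designs, success-rate convergence as more
sequences are sampled per target, on- vs off-target specificity, and the
relationship between seed contact density and design success.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "DesignRecord", "ROCResult", "roc_auc", "success_curve",
    "specificity_summary", "density_success_profile", "spearman_rho",
    "interface_ss_fractions", "reduce_dssp",
    "read_design_table", "write_design_table", "DEFAULT_SUCCESS_RMSD",
]

DEFAULT_SUCCESS_RMSD = 2.0  # Å, inclusive

SS_CLASSES = ("Helix", "Sheet", "Loop")


@dataclass
class DesignRecord:
    """One evaluated design.

    ``design_order`` is the generation index within its target (1-based),
    used for convergence analysis. ``success`` is derived from the
    interface RMSD at the configured threshold when not supplied.
    """

    target_id: str
    design_id: str
    design_order: int
    length: int
    loss: float
    binder_plddt: float
    interface_rmsd: float
    contact_recovery: float = float("nan")
    seq_recovery: float = float("nan")
    contact_density: float = float("nan")
    success: bool | None = None
    success_rmsd: float = DEFAULT_SUCCESS_RMSD

    def __post_init__(self) -> None:
        derived = self.interface_rmsd <= self.success_rmsd
        if self.success is None:
            self.success = derived
        elif self.success != derived:
            raise ValueError(
                f"design {self.design_id}: success flag {self.success} inconsistent "
                f"with interface RMSD {self.interface_rmsd} at threshold "
                f"{self.success_rmsd} Å"
            )


@dataclass
class ROCResult:
    """Threshold sweep: (FPR, TPR) vertices, thresholds, trapezoidal AUC."""

    points: np.ndarray          # (k, 2) array of (fpr, tpr)
    thresholds: np.ndarray
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]

    def tpr_at_fpr(self, fpr_cap: float) -> float:
        """Highest TPR attainable with FPR ≤ fpr_cap."""
        ok = self.points[:, 0] <= fpr_cap
        return float(self.points[ok, 1].max()) if ok.any() else 0.0


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    higher_is_positive: bool = True,
) -> ROCResult:
    """ROC curve and AUC for a score separating positives from negatives.

    For loss-based selection pass ``higher_is_positive=False``: low loss
    ranks a design as a likely binder. Tied scores collapse to one curve
    vertex; the AUC then equals the Mann-Whitney pairwise probability with
    half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    oriented = scores if higher_is_positive else -scores
    fpr, tpr, thr = roc_curve(labels, oriented, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if not higher_is_positive:
        thr = -thr
    return ROCResult(points=np.column_stack([fpr, tpr]), thresholds=thr, auc=auc)


def success_curve(records: Sequence[DesignRecord], max_n: int) -> np.ndarray:
    """Fraction of targets with ≥1 success among their first n designs, n = 1..max_n.

    Designs are ordered per target by ``design_order``; targets with fewer
    than n designs contribute their full design list at that n. The curve
    is non-decreasing in n by construction.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    by_target: dict[str, list[DesignRecord]] = {}
    for r in records:
        by_target.setdefault(r.target_id, []).append(r)
    if not by_target:
        raise ValueError("no records given")
    # per target: position of first success in generation order (inf if none)
    first_success = []
    for recs in by_target.values():
        recs = sorted(recs, key=lambda r: r.design_order)
        pos = next((i + 1 for i, r in enumerate(recs) if r.success), np.inf)
        first_success.append(pos)
    first_success = np.array(first_success)
    ns = np.arange(1, max_n + 1)
    return (first_success[None, :] <= ns[:, None]).mean(axis=1)


def specificity_summary(
    on_target: Sequence[float], off_target: Sequence[float]
) -> dict[str, float]:
    """Median plDDT on- vs off-target and the AUC for discriminating them.

    Higher plDDT ranks a prediction as on-target. Returns keys
    ``on_target_median``, ``off_target_median``, ``auc``.
    """
    on = np.asarray(on_target, dtype=float)
    off = np.asarray(off_target, dtype=float)
    if on.size == 0 or off.size == 0:
        raise ValueError("both plDDT lists must be non-empty")
    scores = np.concatenate([on, off])
    labels = np.concatenate([np.ones(on.size, int), np.zeros(off.size, int)])
    return {
        "on_target_median": float(np.median(on)),
        "off_target_median": float(np.median(off)),
        "auc": roc_auc(scores, labels, higher_is_positive=True).auc,
    }


def density_success_profile(
    records: Sequence[tuple[float, bool]], n_partitions: int = 30
) -> tuple[pd.DataFrame, float]:
    """Success rate as a function of seed contact density.

    Sorts designs by contact density and splits them into ``n_partitions``
    near-equal contiguous blocks (any remainder goes to the leading blocks),
    then reports each block's mean density and success fraction plus the
    Spearman rank correlation across blocks.
    """
    if len(records) < n_partitions:
        raise ValueError(
            f"need at least {n_partitions} records, got {len(records)}"
        )
    order = sorted(records, key=lambda r: r[0])
    dens = np.array([r[0] for r in order], dtype=float)
    succ = np.array([bool(r[1]) for r in order])
    rows = []
    for block_d, block_s in zip(
        np.array_split(dens, n_partitions), np.array_split(succ, n_partitions)
    ):
        rows.append(
            {
                "n": len(block_d),
                "mean_density": float(block_d.mean()),
                "success_rate": float(block_s.mean()),
            }
        )
    profile = pd.DataFrame(rows)
    rho = spearman_rho(profile["mean_density"], profile["success_rate"])
    return profile, rho


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def reduce_dssp(code: str) -> str:
    """Reduce an 8-class DSSP code to Helix / Sheet / Loop."""
    if code in ("H", "G", "I"):
        return "Helix"
    if code in ("E", "B"):
        return "Sheet"
    return "Loop"


def interface_ss_fractions(
    ss_labels: dict[int, str], interface_residues: set[int] | frozenset[int]
) -> dict[str, float]:
    """Secondary-structure composition of an interface.

    ``ss_labels`` maps residue index to one of Helix/Sheet/Loop (raw DSSP
    single-letter codes are reduced automatically). Fractions over the
    interface residues sum to 1.
    """
    if not interface_residues:
        raise ValueError("interface is empty")
    counts = dict.fromkeys(SS_CLASSES, 0)
    for idx in interface_residues:
        if idx not in ss_labels:
            raise ValueError(f"interface residue {idx} has no secondary-structure label")
        label = ss_labels[idx]
        if label not in counts:
            label = reduce_dssp(label)
        counts[label] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


_TABLE_COLUMNS = [
    "target_id", "design_id", "design_order", "length", "loss", "binder_plddt",
    "interface_rmsd", "contact_recovery", "seq_recovery", "contact_density",
    "success",
]


def write_design_table(records: Sequence[DesignRecord], path: str | Path) -> None:
    """Write per-design records as CSV (TSV when the path ends in .tsv)."""
    rows = [{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in records]
    sep = "\t" if str(path).endswith(".tsv") else ","
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep=sep, index=False)


def read_design_table(
    path: str | Path, success_rmsd: float = DEFAULT_SUCCESS_RMSD
) -> list[DesignRecord]:
    """Read a per-design table back into records; errors list missing columns."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    required = [c for c in _TABLE_COLUMNS if c != "success"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"design table is missing required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DesignRecord(
                target_id=str(row.target_id),
                design_id=str(row.design_id),
                design_order=int(row.design_order),
                length=int(row.length),
                loss=float(row.loss),
                binder_plddt=float(row.binder_plddt),
                interface_rmsd=float(row.interface_rmsd),
                contact_recovery=float(getattr(row, "contact_recovery", float("nan"))),
                seq_recovery=float(getattr(row, "seq_recovery", float("nan"))),
                contact_density=float(getattr(row, "contact_density", float("nan"))),
                success=bool(row.success) if hasattr(row, "success") else None,
                success_rmsd=success_rmsd,
            )
        )
    return records
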