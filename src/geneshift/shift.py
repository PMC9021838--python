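"""Replicate sorting and between-condition pattern-shift classification.

This is the decision layer of the workflow. Replicates are never averaged:
each replicate trajectory carries its own cluster label, and a gene only
qualifies for a between-condition comparison when at least ``min_agree``
of its replicates agree on one label within a condition (3/3 strict
sorting, or the looser 2/3 mode). The per-gene consensus labels under the
two conditions are then compared and classified:

    A  off -> dynamic       gene silent in control, expressed with a
                            temporal pattern under treatment
    B  dynamic -> off       expressed pattern in control, silenced under
                            treatment
    C  dynamic -> dynamic   expressed under both, but with different
                            temporal patterns
    non_shift               identical dynamic pattern under both
    off_both                silent under both (excluded from shift stats)
    unqualified             replicates disagree in at least one condition

Qualified genes sharing an identical (control label, treated label)
signature form a *trajectory set*, named by descending size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryLabel",
    "UNQUALIFIED",
    "ShiftRecord",
    "TrajectorySet",
    "CATEGORIES",
    "sort_replicates",
    "classify_shift",
    "compile_shift_table",
    "group_trajectory_sets",
    "is_t0_driven",
]

CATEGORIES = ("A_off_to_dynamic", "B_dynamic_to_off", "C_dynamic_to_dynamic",
              "non_shift", "off_both", "unqualified")


@dataclass(frozen=True)
class TrajectoryLabel:
    """Either OFF or a composite (initial cluster, fine sub-cluster) label."""

    kind: str                 # "OFF" or "DYNAMIC"
    composite_id: str = ""    # "K{init}_D{fine}" when DYNAMIC

    def __post_init__(self):
        if self.kind not in ("OFF", "DYNAMIC"):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind == "DYNAMIC" and not self.composite_id:
            raise ValueError("DYNAMIC label requires a composite id")
        if self.kind == "OFF" and self.composite_id:
            raise ValueError("OFF label carries no composite id")

    @classmethod
    def off(cls) -> "TrajectoryLabel":
        return cls("OFF")

    @classmethod
    def dynamic(cls, composite_id: str) -> "TrajectoryLabel":
        return cls("DYNAMIC", composite_id)

    def __str__(self):
        return "OFF" if self.kind == "OFF" else self.composite_id


class _Unqualified:
    """Sentinel for a gene-condition with no replicate consensus."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNQUALIFIED"


UNQUALIFIED = _Unqualified()


def sort_replicates(labels, min_agree: int):
    """Consensus label shared by >= min_agree replicates, else UNQUALIFIED.

    ``min_agree`` must exceed half the replicate count so the consensus is
    unique when it exists (2/3 and 3/3 are the modes used with triplicates).
    """
    labels = list(labels)
    m = len(labels)
    if m == 0:
        raise ValueError("no replicate labels")
    if min_agree * 2 <= m:
        raise ValueError(
            f"min_agree={min_agree} must exceed half of m={m} replicates")
    if min_agree > m:
        raise ValueError(f"min_agree={min_agree} exceeds m={m} replicates")
    label, count = Counter(labels).most_common(1)[0]
    return label if count >= min_agree else UNQUALIFIED


def classify_shift(control, treated) -> str:
    """Category of the (control, treated) consensus label pair.

    Total function over labels and the UNQUALIFIED sentinel; any
    unqualified side makes the gene unqualified.
    """
    if control is UNQUALIFIED or treated is UNQUALIFIED:
        return "unqualified"
    if control.kind == "OFF" and treated.kind == "OFF":
        return "off_both"
    if control.kind == "OFF":
        return "A_off_to_dynamic"
    if treated.kind == "OFF":
        return "B_dynamic_to_off"
    if control.composite_id != treated.composite_id:
        return "C_dynamic_to_dynamic"
    return "non_shift"


@dataclass
class ShiftRecord:
    """Per-gene consensus labels in both conditions plus category."""

    gene_id: str
    control_label: object
    treated_label: object
    category: str
    n_agree_control: int = 0
    n_agree_treated: int = 0

    @staticmethod
    def _label_str(lab) -> str:
        return "UNQUALIFIED" if lab is UNQUALIFIED else str(lab)

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "control_label": self._label_str(self.control_label),
            "treated_label": self._label_str(self.treated_label),
            "category": self.category,
            "n_agree_control": self.n_agree_control,
            "n_agree_treated": self.n_agree_treated,
        }


def _n_agree(labels) -> int:
    return Counter(labels).most_common(1)[0][1] if labels else 0


def compile_shift_table(genes: Iterable[str],
                        control_labels: Mapping[str, list],
                        treated_labels: Mapping[str, list],
                        min_agree: int = 3):
    """Build per-gene shift records plus mutually consistent summary counts.

    ``control_labels`` / ``treated_labels`` map gene id -> list of
    per-replicate TrajectoryLabel for that condition; a gene with labels
    under only one condition is an error. Summary counts reproduce the
    workflow report schema: total genes, per-condition off counts (off in
    >= 1 sorting replicate-threshold sense, i.e. consensus label OFF),
    genes qualified in both conditions, shift genes split by category, and
    non-shift genes; shift = A + B + C and qualified = shift + non_shift by
    construction.
    """
    genes = list(genes)
    records: list[ShiftRecord] = []
    counts = Counter()
    off_control = off_treated = 0
    for g in genes:
        if g not in control_labels or g not in treated_labels:
            raise ValueError(f"gene {g!r} lacks labels for one condition")
        cl = list(control_labels[g])
        tl = list(treated_labels[g])
        c_cons = sort_replicates(cl, min_agree)
        t_cons = sort_replicates(tl, min_agree)
        cat = classify_shift(c_cons, t_cons)
        counts[cat] += 1
        if c_cons is not UNQUALIFIED and c_cons.kind == "OFF":
            off_control += 1
        if t_cons is not UNQUALIFIED and t_cons.kind == "OFF":
            off_treated += 1
        records.append(ShiftRecord(g, c_cons, t_cons, cat,
                                   _n_agree(cl), _n_agree(tl)))
    n_shift = (counts["A_off_to_dynamic"] + counts["B_dynamic_to_off"]
               + counts["C_dynamic_to_dynamic"])
    summary = {
        "n_genes": len(genes),
        "n_off_control": off_control,
        "n_off_treated": off_treated,
        "n_off_both": counts["off_both"],
        "n_unqualified": counts["unqualified"],
        "n_qualified_both": n_shift + counts["non_shift"],
        "n_shift": n_shift,
        "n_shift_A_off_to_dynamic": counts["A_off_to_dynamic"],
        "n_shift_B_dynamic_to_off": counts["B_dynamic_to_off"],
        "n_shift_C_dynamic_to_dynamic": counts["C_dynamic_to_dynamic"],
        "n_non_shift": counts["non_shift"],
        "min_agree": min_agree,
    }
    return records, summary


@dataclass
class TrajectorySet:
    """Genes sharing one (control label, treated label) signature."""

    set_id: str
    condition_pair_signature: tuple
    member_genes: set

    @property
    def size(self) -> int:
        return len(self.member_genes)


def group_trajectory_sets(records: Iterable[ShiftRecord],
                          prefix: str = "T") -> list[TrajectorySet]:
    """Group qualified records by signature; name {prefix}{rank} by size.

    Only categories A/B/C and non_shift participate; ties in size break by
    signature lexicographic order so naming is deterministic.
    """
    groups: dict[tuple, set] = {}
    for rec in records:
        if rec.category in ("unqualified", "off_both"):
            continue
        sig = (ShiftRecord._label_str(rec.control_label),
               ShiftRecord._label_str(rec.treated_label))
        groups.setdefault(sig, set()).add(rec.gene_id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [TrajectorySet(f"{prefix}{rank}", sig, members)
            for rank, (sig, members) in enumerate(ordered)]


def is_t0_driven(control_centroid, treated_centroid,
                 threshold: float = 0.8) -> bool:
    """Heuristic flag for shifts driven only by the first time point.

    True when the absolute centroid difference at t0 makes up at least
    ``threshold`` of the total L1 difference between the two label
    centroids (an OFF side is the zero series). Differences concentrated
    at the pre-treatment baseline usually reflect noise, not response.
    """
    c = np.asarray(control_centroid, dtype=float)
    t = np.asarray(treated_centroid, dtype=float)
    diff = np.abs(c - t)
    total = diff.sum()
    if total == 0:
        return False
    return bool(diff[0] >= threshold * total)
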