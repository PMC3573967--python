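"""Accuracy of an alignment against simulation truth or an orthology table.

Counts follow the usual network-alignment bookkeeping: NA aligned pairs,
NC correct pairs, NO true pairs (or orthologous groups shared by the two
species), sensitivity = NC/NA and coverage = NC/NO.  A vertex aligned to a
wrong partner is *misaligned*; two vertices without any true partner
aligned to each other are neutral — aligned but neither correct nor wrong.
In the group-table mode NC counts pairs, so coverage can exceed 1 when
several correct pairs fall in one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

from .core import Alignment
from .simulate import SimulatedPair

__all__ = ["CategoryStats", "EvaluationReport", "evaluate_against_truth",
           "evaluate_against_groups"]

CATEGORIES = ("ortholog_vertex_similar", "analog", "paralog_case", "unrelated")


@dataclass
class CategoryStats:
    total: int = 0
    correct: int = 0
    misaligned: int = 0
    unaligned: int = 0

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else 0.0


@dataclass
class EvaluationReport:
    n_aligned: int
    n_correct: int
    n_groups: int
    misaligned: int
    neutral: int = 0
    per_category: Dict[str, CategoryStats] = field(default_factory=dict)
    sensitivity_defined: bool = True

    @property
    def sensitivity(self) -> float:
        """NC/NA; reported as 0 (with the flag cleared) for empty alignments."""
        if self.n_aligned == 0:
            return 0.0
        return self.n_correct / self.n_aligned

    @property
    def coverage(self) -> float:
        """NC/NO; may exceed 1 in group mode."""
        if self.n_groups == 0:
            return 0.0
        return self.n_correct / self.n_groups

    def to_text(self) -> str:
        lines = [
            f"aligned pairs (NA):    {self.n_aligned}",
            f"correct pairs (NC):    {self.n_correct}",
            f"true pairs/groups (NO): {self.n_groups}",
            f"misaligned vertices:   {self.misaligned}",
            f"neutral pairs:         {self.neutral}",
            f"sensitivity (NC/NA):   {self.sensitivity:.4f}"
            + ("" if self.sensitivity_defined else " (undefined: NA = 0)"),
            f"coverage (NC/NO):      {self.coverage:.4f}",
        ]
        for cat, st in self.per_category.items():
            lines.append(
                f"  {cat}: n={st.total} correct={st.correct} "
                f"misaligned={st.misaligned} unaligned={st.unaligned}"
            )
        return "\n".join(lines)


def evaluate_against_truth(a: Alignment, pair: SimulatedPair) -> EvaluationReport:
    """Compare an alignment with the simulator's ground-truth mapping.

    A pair (i, i') is correct iff truth[i] == i'; it is misaligned when i
    or i' has a true partner and truth[i] != i'; two truthless vertices
    aligned together are neutral.
    """
    truth = pair.truth
    truth_inv = {j: i for i, j in truth.items()}
    n_aligned = len(a)
    n_correct = 0
    misaligned = 0
    neutral = 0
    per_cat = {c: CategoryStats() for c in CATEGORIES}
    for v, lab in pair.labels.items():
        per_cat[lab].total += 1
    aligned_g = set(a.pairs)
    for i, ip in a.items():
        lab = pair.labels.get(i, "unrelated")
        if truth.get(i) == ip:
            n_correct += 1
            per_cat[lab].correct += 1
        elif i in truth or ip in truth_inv:
            misaligned += 1
            per_cat[lab].misaligned += 1
        else:
            neutral += 1
    for i in pair.labels:
        if i not in aligned_g:
            per_cat[pair.labels[i]].unaligned += 1
    return EvaluationReport(
        n_aligned=n_aligned,
        n_correct=n_correct,
        n_groups=len(truth),
        misaligned=misaligned,
        neutral=neutral,
        per_category=per_cat,
        sensitivity_defined=n_aligned > 0,
    )


def evaluate_against_groups(
    a: Alignment,
    groups_g: Mapping[str, str],
    groups_g2: Mapping[str, str],
) -> EvaluationReport:
    """Score an alignment against an orthologous-group table (one table per
    species, vertex id -> group id).

    NA counts aligned pairs in which both vertices carry a group id, NC the
    subset sharing the group, and NO the number of distinct groups present
    in both species (a group with several members still counts once).
    """
    n_aligned = 0
    n_correct = 0
    for i, ip in a.items():
        gi, gp = groups_g.get(i), groups_g2.get(ip)
        if gi is None or gp is None:
            continue
        n_aligned += 1
        if gi == gp:
            n_correct += 1
    shared = set(groups_g.values()) & set(groups_g2.values())
    return EvaluationReport(
        n_aligned=n_aligned,
        n_correct=n_correct,
        n_groups=len(shared),
        misaligned=n_aligned - n_correct,
        sensitivity_defined=n_aligned > 0,
    )
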