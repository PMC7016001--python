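"""Pauli semiquantitative histological scoring of meniscus degeneration.

The Pauli classification grades meniscus degeneration on four components:
surface integrity (femoral + tibial + inner surface, 0-3 each, i.e. 0-9),
cellularity (0-3), collagen organization and alignment (0-3), and matrix
(Safranin-O) staining intensity (0-3).  The sum score (0-18) is binned into
Grades I-IV; because severely degenerative samples are rare, Grades III and
IV are conventionally collapsed into a single ">=III" subgroup for analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PauliScore", "pauli_sum", "grade_from_sum", "score_table"]

#: inclusive sum-score bins for Pauli grades
GRADE_BINS = {
    "I": (0, 4),
    "II": (5, 9),
    "III": (10, 14),
    "IV": (15, 18),
}

_COMPONENT_RANGES = {
    "surface_integrity": (0, 9),
    "cellularity": (0, 3),
    "collagen_organization": (0, 3),
    "matrix_staining": (0, 3),
}


@dataclass(frozen=True)
class PauliScore:
    """One sample's Pauli component scores with derived sum, grade and group."""

    surface_integrity: int
    cellularity: int
    collagen_organization: int
    matrix_staining: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _COMPONENT_RANGES.items():
            value = getattr(self, name)
            if not (isinstance(value, (int,)) and lo <= value <= hi):
                raise ValueError(
                    f"Pauli component {name!r} must be an integer in "
                    f"[{lo}, {hi}], got {value!r}"
                )

    @property
    def sum(self) -> int:
        return (
            self.surface_integrity
            + self.cellularity
            + self.collagen_organization
            + self.matrix_staining
        )

    @property
    def grade(self) -> str:
        return grade_from_sum(self.sum)

    @property
    def collapsed_group(self) -> str:
        """Grade with III and IV collapsed into the '>=III' subgroup."""
        grade = self.grade
        return ">=III" if grade in ("III", "IV") else grade


def grade_from_sum(total: int) -> str:
    """Map a Pauli sum score (0-18) onto its grade bin."""
    for grade, (lo, hi) in GRADE_BINS.items():
        if lo <= total <= hi:
            return grade
    raise ValueError(f"Pauli sum score must be in [0, 18], got {total}")


def pauli_sum(
    surface: int, cellularity: int, collagen: int, staining: int
) -> tuple[int, str, str]:
    """Compute sum score, grade, and collapsed group from component scores.

    Parameters
    ----------
    surface : int
        Surface integrity score, summed over the femoral, tibial and inner
        surfaces (0-9).
    cellularity, collagen, staining : int
        The remaining component scores (0-3 each).

    Returns
    -------
    (sum, grade, collapsed_group)
        e.g. ``(4, "I", "I")`` or ``(12, "III", ">=III")``.
    """
    score = PauliScore(surface, cellularity, collagen, staining)
    return score.sum, score.grade, score.collapsed_group


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Grade a table of component scores.

    Expects columns ``sample, surface_integrity, cellularity,
    collagen_organization, matrix_staining``; returns the table with
    ``sum, grade, collapsed_group`` columns appended.
    """
    out = df.copy()
    sums, grades, groups = [], [], []
    for _, row in df.iterrows():
        s, g, c = pauli_sum(
            int(row["surface_integrity"]),
            int(row["cellularity"]),
            int(row["collagen_organization"]),
            int(row["matrix_staining"]),
        )
        sums.append(s)
        grades.append(g)
        groups.append(c)
    out["sum"] = sums
    out["grade"] = grades
    out["collapsed_group"] = groups
    return out
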