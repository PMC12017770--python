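"""Single-cell transcript detection tables and co-expression structure.

Works on boolean cells × transcripts detection calls from single-cell
RT-PCR panels (glutamatergic markers plus the prostaglandin-synthesis
cascade: COX-1/COX-2, the PGE2 terminal synthases mPGES1/mPGES2/cPGES and
the PGF2α branch PM-PGFS/CBR1/AKR1B3). Percentages are exact ratios
internally; rounding to integer percent happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_TRANSCRIPTS",
    "DEFAULT_GROUPS",
    "ExpressionMatrix",
    "Exclusivity",
    "Implication",
    "detection_rates",
    "cooccurrence",
    "check_rules",
    "example_expression_matrix",
    "example_rules",
]

CANONICAL_TRANSCRIPTS = (
    "vGluT1", "GAD65", "GAD67",
    "COX-1", "COX-2",
    "mPGES1", "mPGES2", "cPGES",
    "PM-PGFS", "CBR1", "AKR1B3",
)

#: "and/or" groupings used in co-expression summaries: a cell is
#: group-positive if any member transcript is detected.
DEFAULT_GROUPS = {
    "PGES": ("mPGES1", "mPGES2", "cPGES"),
    "PGFS": ("PM-PGFS", "CBR1", "AKR1B3"),
}


@dataclass(frozen=True)
class Exclusivity:
    """Two transcripts never detected in the same cell (symmetric)."""

    a: str
    b: str

    def describe(self) -> str:
        return f"{self.a} and {self.b} must not be co-detected"


@dataclass(frozen=True)
class Implication:
    """If ``antecedent`` is detected, at least one of ``consequents`` must be."""

    antecedent: str
    consequents: tuple[str, ...]

    def describe(self) -> str:
        return f"{self.antecedent} requires one of {'/'.join(self.consequents)}"


@dataclass
class ExpressionMatrix:
    """Boolean detection calls, cells as rows, transcripts as columns."""

    calls: pd.DataFrame

    def __post_init__(self):
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValueError("duplicate cell or transcript identifiers")
        self.calls = self.calls.astype(bool)

    @property
    def n_cells(self) -> int:
        return len(self.calls)

    @property
    def transcripts(self) -> list[str]:
        return list(self.calls.columns)

    def group_positive(self, members) -> pd.Series:
        cols = [m for m in members if m in self.calls.columns]
        if not cols:
            raise KeyError(f"none of {members} present in matrix")
        return self.calls[cols].any(axis=1)


def detection_rates(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-transcript detection count and percentage.

    Returns a frame indexed by transcript with columns ``count``, ``n`` and
    ``percent`` (exact, unrounded) plus ``percent_display`` rounded to the
    nearest integer for presentation (14/16 prints as 88).
    """
    if m.n_cells == 0:
        raise ValueError("expression matrix has no cells")
    counts = m.calls.sum(axis=0).astype(int)
    out = pd.DataFrame(
        {
            "count": counts,
            "n": m.n_cells,
            "percent": 100.0 * counts / m.n_cells,
        }
    )
    out["percent_display"] = out["percent"].round().astype(int)
    return out


def cooccurrence(
    m: ExpressionMatrix, group_defs: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Pairwise co-detection counts over transcripts and named groups.

    Groups (e.g. PGES = mPGES1/mPGES2/cPGES) are any-member-positive. The
    diagonal carries the marginal counts.
    """
    cols: dict[str, pd.Series] = {t: m.calls[t] for t in m.transcripts}
    for name, members in (group_defs or {}).items():
        cols[name] = m.group_positive(members)
    names = list(cols)
    mat = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            mat[i, j] = int((cols[a] & cols[b]).sum())
    return pd.DataFrame(mat, index=names, columns=names)


def check_rules(
    m: ExpressionMatrix, rules: list[Exclusivity | Implication]
) -> list[dict]:
    """Exhaustive per-cell rule check; empty list iff every rule holds."""
    violations: list[dict] = []
    for rule in rules:
        if isinstance(rule, Exclusivity):
            bad = m.calls[rule.a] & m.calls[rule.b]
        elif isinstance(rule, Implication):
            bad = m.calls[rule.antecedent] & ~m.group_positive(rule.consequents)
        else:
            raise TypeError(f"unknown rule type: {rule!r}")
        for cell in m.calls.index[bad]:
            violations.append({"cell": cell, "rule": rule.describe()})
    return violations


def example_expression_matrix() -> ExpressionMatrix:
    """Synthetic 16-cell layer II-III pyramidal-cell panel.

    Hand-constructed fixture reproducing the published detection-rate and
    co-expression structure: all cells vGluT1-positive and GAD-negative,
    COX-1 in 4/16 and COX-2 in 5/16 cells (never together), cPGES in 14/16,
    mPGES1 (1/16) and mPGES2 (6/16) always alongside cPGES, AKR1B3 in
    11/16, PM-PGFS in 5/16, CBR1 in 3/16 always with a PGES; 3 of 4 COX-1
    cells and all COX-2 cells are PGFS-positive.
    """
    rows = {
        #       vG  G65 G67 C1  C2  mP1 mP2 cP  PMP CBR AKR
        "c01": (1,  0,  0,  1,  0,  0,  1,  1,  1,  0,  1),
        "c02": (1,  0,  0,  1,  0,  0,  1,  1,  0,  1,  1),
        "c03": (1,  0,  0,  1,  0,  0,  0,  1,  0,  0,  1),
        "c04": (1,  0,  0,  1,  0,  0,  0,  1,  0,  0,  0),
        "c05": (1,  0,  0,  0,  1,  1,  1,  1,  1,  0,  1),
        "c06": (1,  0,  0,  0,  1,  0,  1,  1,  1,  0,  1),
        "c07": (1,  0,  0,  0,  1,  0,  1,  1,  0,  1,  1),
        "c08": (1,  0,  0,  0,  1,  0,  0,  1,  0,  0,  1),
        "c09": (1,  0,  0,  0,  1,  0,  0,  1,  0,  0,  1),
        "c10": (1,  0,  0,  0,  0,  0,  1,  1,  0,  1,  1),
        "c11": (1,  0,  0,  0,  0,  0,  0,  1,  0,  0,  1),
        "c12": (1,  0,  0,  0,  0,  0,  0,  1,  0,  0,  1),
        "c13": (1,  0,  0,  0,  0,  0,  0,  1,  1,  0,  0),
        "c14": (1,  0,  0,  0,  0,  0,  0,  1,  1,  0,  0),
        "c15": (1,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0),
        "c16": (1,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0),
    }
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(CANONICAL_TRANSCRIPTS)
    ).astype(bool)
    return ExpressionMatrix(frame)


def example_rules() -> list[Exclusivity | Implication]:
    """Rule set observed in the example panel."""
    return [
        Exclusivity("COX-1", "COX-2"),
        Implication("mPGES1", ("cPGES",)),
        Implication("mPGES2", ("cPGES",)),
        Implication("CBR1", DEFAULT_GROUPS["PGES"]),
        Implication("COX-1", DEFAULT_GROUPS["PGES"]),
        Implication("COX-2", DEFAULT_GROUPS["PGES"]),
        Implication("COX-2", DEFAULT_GROUPS["PGFS"]),
    ]
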