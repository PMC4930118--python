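"""Direction counting and Fisher over-representation of protein families.

The central object is a 2x2 contingency table of significantly altered
proteins, split family vs other and up vs down.  Over-representation is
a one-sided Fisher exact test asking whether the family's fraction of
up-regulated entries exceeds the global fraction, with the fold computed
against the global proportion *including* the family — the construction
consistent with summary counts of the form "a of a+b family entries up"
against "(a+c) of (a+b+c+d) entries up globally".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ContingencyTable:
    """Direction-by-family counts of significantly altered proteins.

    a: family up, b: family down, c: other up, d: other down.  Family and
    other are disjoint; the global up-count is a + c.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def family_total(self) -> int:
        return self.a + self.b

    @property
    def global_up(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    fold: float
    p_value: float
    sidedness: str = "one-sided (family up-fraction above global)"


def count_directions(
    direction: Sequence[str], is_family: Sequence[bool]
) -> ContingencyTable:
    """Tally up/down directions into a family-vs-other contingency table."""
    if len(direction) != len(is_family):
        raise ValueError("direction and is_family must have equal length")
    a = b = c = d = 0
    for direc, fam in zip(direction, is_family):
        if direc == "up":
            a, c = (a + 1, c) if fam else (a, c + 1)
        elif direc == "down":
            b, d = (b + 1, d) if fam else (b, d + 1)
        else:
            raise ValueError(f"protein with missing/unknown direction: {direc!r}")
    return ContingencyTable(a, b, c, d)


def contingency_from_results(table: pd.DataFrame, use_fdr: bool = False) -> ContingencyTable:
    """Build the contingency table from a differential-abundance table.

    Requires ``direction``, ``family`` and ``significant``/``fdr_flag``
    columns as produced by the differential-abundance pipeline.
    """
    flag = "fdr_flag" if use_fdr else "significant"
    sig = table[table[flag]]
    return count_directions(
        sig["direction"].tolist(), (sig["family"] != "other").tolist()
    )


def fisher_enrichment(table: ContingencyTable) -> EnrichmentResult:
    """One-sided Fisher exact over-representation of the family among ups.

    p = P(X >= a) with X hypergeometric: population a+b+c+d, successes
    (ups) a+c, draws (family entries) a+b.  fold = family up-fraction
    over the global up-fraction.
    """
    if table.family_total < 1:
        raise ValueError("family must contain at least one entry")
    M, n, N = table.total, table.global_up, table.family_total
    p = float(hypergeom.sf(table.a - 1, M, n, N))
    fold = (table.a / N) / (n / M) if n else math.inf
    return EnrichmentResult(table=table, fold=fold, p_value=p)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_directions(table: ContingencyTable) -> dict[str, int]:
    """Printed-style integer percentages of up-regulated entries."""
    if table.family_total == 0:
        raise ValueError("family total is zero; percentage undefined")
    return {
        "family_up_pct": _round_half_away(100.0 * table.a / table.family_total),
        "global_up_pct": _round_half_away(100.0 * table.global_up / table.total),
    }


# ---------------------------------------------------------------------
# published-table fixtures


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged direction-count fixture ('table1' or 'table2').

    Each fixture encodes, per pairwise comparison, the printed up/down
    counts for every translation-machinery family row (with the partial
    gene lists) and the comparison's global up/down totals.
    """
    ref = resources.files("npcquant.diffabund") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    frame["genes_up"] = frame.get("genes_up", "").fillna("")
    frame["genes_down"] = frame.get("genes_down", "").fillna("")
    return frame


def contingency_from_fixture(name: str) -> ContingencyTable:
    """Pooled family-vs-other contingency table from a packaged fixture.

    Family cells sum the family rows across comparisons; 'other' cells
    are the pooled global totals minus the family cells, keeping the two
    halves disjoint.
    """
    frame = load_fixture(name)
    fam = frame[frame["family"] != "global"]
    glob = frame[frame["family"] == "global"]
    a, b = int(fam["up"].sum()), int(fam["down"].sum())
    gu, gd = int(glob["up"].sum()), int(glob["down"].sum())
    return ContingencyTable(a, b, gu - a, gd - b)
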