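"""Integration of binding target sets with marks and expression.

The headline questions addressed here: how the common targets of the
TRB-containing complexes partition against PEAT (active chromatin) and
PRC2 (Polycomb) targets; what fraction of each subclass depends on
H3K4me3 demethylation (i.e. gains the mark in a demethylase-pathway
mutant); where mark changes fall across the genome-wide H3K4me3 decile
ladder; and how mark gains line up with expression gains at target genes.

The three subclasses (specific, PEAT-shared, PRC2-shared) are deliberately
NON-exclusive: a target shared with both PEAT and PRC2 is counted in both
shared groups, and the dual-shared count is reported explicitly so the
inclusion-exclusion identity |specific| = |T| - |T∩PEAT| - |T∩PRC2| +
|both| can always be checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .complex_targets import TargetSet
from .differential import DiffCall


@dataclass(frozen=True)
class SubclassPartition:
    targets: TargetSet
    specific: frozenset[str]
    peat_shared: frozenset[str]
    prc2_shared: frozenset[str]
    both_shared: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "targets": len(self.targets.gene_ids),
            "specific": len(self.specific),
            "peat_shared": len(self.peat_shared),
            "prc2_shared": len(self.prc2_shared),
            "both_shared": len(self.both_shared),
        }


def partition_subclasses(
    targets: TargetSet,
    peat: Iterable[str],
    prc2: Iterable[str],
) -> SubclassPartition:
    """Split complex targets by their overlap with PEAT and PRC2 targets."""
    t = targets.gene_ids
    peat = frozenset(peat)
    prc2 = frozenset(prc2)
    return SubclassPartition(
        targets=targets,
        specific=frozenset(t - peat - prc2),
        peat_shared=frozenset(t & peat),
        prc2_shared=frozenset(t & prc2),
        both_shared=frozenset(t & peat & prc2),
    )


def dependence_ratio(
    subclass: Iterable[str],
    affected: Iterable[str],
) -> tuple[int, float]:
    """Count and percentage of a subclass found in the affected set.

    Used for "demethylation dependence": the affected set is typically the
    genes whose H3K4me3 increases in a mutant. Percentage is of the
    subclass size, rounded only at display time (two decimals).
    """
    sub = set(subclass)
    if not sub:
        raise ValueError("empty subclass")
    count = len(sub & set(affected))
    return count, 100.0 * count / len(sub)


# ---------------------------------------------------------------------------
# decile stratification

@dataclass(frozen=True)
class DecileAssignment:
    """gene_id -> decile 1..10 over the whole universe, ascending signal."""

    deciles: Mapping[str, int]

    def sizes(self) -> list[int]:
        out = [0] * 10
        for d in self.deciles.values():
            out[d - 1] += 1
        return out


def decile_assign(signal: Mapping[str, float]) -> DecileAssignment:
    """Assign every universe gene to a decile by ascending signal.

    Stable sort on (signal, gene_id) makes ties deterministic. With
    n = 10q + r genes, deciles 1..r take q+1 genes and deciles r+1..10
    take q; decile 1 holds the lowest signals.
    """
    if not signal:
        raise ValueError("empty signal")
    for g, v in signal.items():
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing/non-finite signal for gene {g!r}")
    order = sorted(signal, key=lambda g: (signal[g], g))
    n = len(order)
    q, r = divmod(n, 10)
    assignment: dict[str, int] = {}
    pos = 0
    for d in range(1, 11):
        size = q + 1 if d <= r else q
        for g in order[pos:pos + size]:
            assignment[g] = d
        pos += size
    return DecileAssignment(assignment)


def decile_distribution(
    assignment: DecileAssignment,
    affected: Iterable[str],
) -> list[int]:
    """Per-decile counts of the affected genes (universe members only)."""
    counts = [0] * 10
    for g in affected:
        d = assignment.deciles.get(g)
        if d is not None:
            counts[d - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# RNA x ChIP combination

def rna_chip_combination(
    up_degs: Iterable[str],
    targets: TargetSet,
    mark_calls: Sequence[DiffCall],
) -> dict[str, float]:
    """Mark status of target genes that are up-regulated DEGs.

    Returns counts of target up-DEGs whose mark call is up / down /
    unchanged (genes missing from the mark calls count as unchanged) plus
    the percentage with mark status 'up'. The three counts are disjoint and
    sum to |up_degs ∩ targets|.
    """
    status = {c.gene_id: c.status for c in mark_calls}
    pool = set(up_degs) & targets.gene_ids
    n_up = sum(status.get(g, "unchanged") == "up" for g in pool)
    n_down = sum(status.get(g, "unchanged") == "down" for g in pool)
    n_unchanged = len(pool) - n_up - n_down
    pct = 100.0 * n_up / len(pool) if pool else float("nan")
    return {
        "n_total": len(pool),
        "n_mark_up": n_up,
        "n_mark_down": n_down,
        "n_mark_unchanged": n_unchanged,
        "pct_mark_up": pct,
    }


def target_fraction_among_degs(
    deg_calls: Sequence[DiffCall],
    targets: TargetSet,
) -> dict[str, float | None]:
    """Fraction of complex targets among up- and among down-regulated DEGs.

    Sides with zero DEGs report None (undefined), not an error.
    """
    if not deg_calls:
        raise ValueError("no DEG calls")
    up = [c.gene_id for c in deg_calls if c.status == "up"]
    down = [c.gene_id for c in deg_calls if c.status == "down"]
    t = targets.gene_ids

    def frac(genes: list[str]) -> float | None:
        return len(set(genes) & t) / len(genes) if genes else None

    return {
        "n_up": len(up),
        "n_up_target": len(set(up) & t),
        "frac_up_target": frac(up),
        "n_down": len(down),
        "n_down_target": len(set(down) & t),
        "frac_down_target": frac(down),
    }


def subclass_table(partition: SubclassPartition, affected: Iterable[str]) -> pd.DataFrame:
    """Dependence ratios for the three subclasses in one frame."""
    affected = set(affected)
    rows = []
    for name in ("specific", "peat_shared", "prc2_shared"):
        sub = getattr(partition, name)
        count, pct = dependence_ratio(sub, affected) if sub else (0, float("nan"))
        rows.append({"subclass": name, "size": len(sub),
                     "n_affected": count, "pct_affected": pct})
    return pd.DataFrame(rows).set_index("subclass")
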