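"""Complex target-gene sets from per-factor binding calls.

A chromatin complex's target genes are defined operationally as the genes
bound by every one of a required list of component factors (intersection of
the factors' bound-gene sets). Membership combinations across several sets
are decomposed UpSet-style, and pairwise overlaps are scored with the
hypergeometric machinery in :mod:`chromtargets.stats_core`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .stats_core import OverlapResult, TailConvention, overlap_result


@dataclass(frozen=True)
class TargetSet:
    label: str
    gene_ids: frozenset[str]
    definition: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.gene_ids)


def define_complex_targets(
    bound_sets: Mapping[str, Iterable[str]],
    required: Sequence[str],
    label: str | None = None,
) -> TargetSet:
    """Genes bound by every required factor (order-independent)."""
    missing = [f for f in required if f not in bound_sets]
    if missing:
        raise KeyError(
            f"unknown factor(s) {missing}; available: {sorted(bound_sets)}"
        )
    if not required:
        raise ValueError("need at least one required factor")
    sets = [frozenset(bound_sets[f]) for f in required]
    genes = frozenset.intersection(*sets)
    return TargetSet(label or "+".join(sorted(required)), genes, tuple(required))


def upset_decomposition(sets: Sequence[TargetSet]) -> dict[frozenset[str], int]:
    """Exact-membership combination counts over the union of the sets.

    Every gene in the union is counted under exactly one combination (the
    frozenset of labels of the sets containing it), so the counts sum to
    the union size. Combinations with zero genes are included for every
    nonempty subset of labels, matching an UpSet plot's x-axis.
    """
    if not sets:
        raise ValueError("need at least one set")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")
    combos: Counter[frozenset[str]] = Counter()
    union = frozenset().union(*(s.gene_ids for s in sets))
    for g in union:
        combos[frozenset(s.label for s in sets if g in s.gene_ids)] += 1
    # make empty combinations explicit
    from itertools import combinations

    for r in range(1, len(sets) + 1):
        for combo in combinations(labels, r):
            combos.setdefault(frozenset(combo), 0)
    return dict(combos)


def overlap_enrichment(
    a: TargetSet,
    b: TargetSet,
    universe_size: int,
    universe: Iterable[str] | None = None,
    tail_convention: TailConvention = "min_likelihood",
) -> OverlapResult:
    """Hypergeometric enrichment of |a ∩ b| given the universe size."""
    if universe is not None:
        uni = set(universe)
        stray = (a.gene_ids | b.gene_ids) - uni
        if stray:
            raise ValueError(f"set members outside the universe: {sorted(stray)[:5]}")
    if universe_size < len(a.gene_ids | b.gene_ids):
        raise ValueError("universe smaller than the union of the sets")
    k = len(a.gene_ids & b.gene_ids)
    return overlap_result(k, len(a), len(b), universe_size, tail_convention)
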