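"""Multi-dataset DEG overlap: UpSet-style exclusive memberships and plain
intersections.

A DEG-set collection maps a dataset label to its (up, down) gene-id sets.
Gene identity is matched by exact string equality — stable ids where
available, otherwise case-sensitive symbols; cross-species comparisons need
an explicit homology mapping applied beforehand.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = ["deg_sets_from_de_tables", "deg_intersections", "shared_degs"]

DEGSetCollection = Mapping[str, tuple[set, set]]  # label -> (up, down)


def deg_sets_from_de_tables(tables: Mapping[str, pd.DataFrame]) -> dict[str, tuple[set, set]]:
    """Extract per-dataset (up, down) DEG id sets from classified DE tables."""
    out = {}
    for label, det in tables.items():
        up = set(det.index[det["deg_class"] == "up"])
        down = set(det.index[det["deg_class"] == "down"])
        out[label] = (up, down)
    return out


def _direction_sets(collection: DEGSetCollection, direction: str) -> dict[str, set]:
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    idx = 0 if direction == "up" else 1
    return {label: set(sets[idx]) for label, sets in collection.items()}


def deg_intersections(
    collection: DEGSetCollection, direction: str
) -> tuple[pd.DataFrame, list[str]]:
    """Exclusive (UpSet) membership counts plus the full-intersection list.

    Every gene in the union is assigned to exactly one membership
    combination — the exact set of datasets containing it — so the counts
    sum to the union size.  Returns (membership table sorted by descending
    count, sorted list of genes present in every dataset).
    """
    sets = _direction_sets(collection, direction)
    if len(sets) < 2:
        raise ValueError("need at least two datasets for intersections")
    labels = list(sets)
    membership: dict[frozenset, set] = {}
    for gene in set().union(*sets.values()):
        key = frozenset(l for l in labels if gene in sets[l])
        membership.setdefault(key, set()).add(gene)
    rows = [
        {
            "datasets": ",".join(l for l in labels if l in key),
            "degree": len(key),
            "count": len(genes),
            "genes": ";".join(str(g) for g in sorted(genes)),
        }
        for key, genes in membership.items()
    ]
    table = pd.DataFrame(rows, columns=["datasets", "degree", "count", "genes"])
    table = table.sort_values(["count", "degree"], ascending=[False, False]).reset_index(drop=True)
    full = sorted(set.intersection(*sets.values())) if sets else []
    return table, full


def shared_degs(
    collection: DEGSetCollection, datasets: Sequence[str], direction: str
) -> list[str]:
    """Plain (non-exclusive) intersection of DEGs across the named datasets."""
    sets = _direction_sets(collection, direction)
    unknown = [d for d in datasets if d not in sets]
    if unknown:
        raise KeyError(f"unknown dataset labels: {unknown}")
    if not datasets:
        raise ValueError("dataset subset must be non-empty")
    return sorted(set.intersection(*(sets[d] for d in datasets)))
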