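"""Fold-change "burst" detection of domain expansions between adjacent LCAs.

For each node on the root-to-focal backbone, a domain's mean merged-span
count per species inside the clade is divided by the same mean over the
sister lineage.  Means include zero-count species — otherwise emergence
would be invisible.  A sister mean of zero with a positive clade mean is
reported as the categorical status EMERGENT rather than an infinite ratio,
and never competes in the top-k ranking; a fold change at or above the
burst threshold (default 10) flags an expansion on the branch leading to
that node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from lgptrace.domain_architecture import DomainCountMatrix
from lgptrace.species_tree import SpeciesTree, TreeNode

__all__ = [
    "FoldChangeRecord",
    "BurstReport",
    "lineage_mean",
    "fold_changes",
    "top_k_report",
]

DEFAULT_BURST_THRESHOLD = 10.0


@dataclass(frozen=True)
class FoldChangeRecord:
    """Fold change of one domain at one backbone node.

    ``status`` is ``"ok"`` (finite ratio), ``"emergent"`` (absent from the
    sister lineage, present in the clade) or ``"absent"`` (absent from
    both); ``fold_change`` is defined only for ``"ok"``.
    """

    domain_acc: str
    node: str
    mean_in: float
    mean_sister: float
    fold_change: float | None
    status: str

    def __post_init__(self) -> None:
        if self.status == "ok" and (self.fold_change is None or self.fold_change < 0):
            raise ValueError("finite fold change must be a non-negative number")


def lineage_mean(counts: DomainCountMatrix, species_set: Iterable[str]) -> pd.Series:
    """Per-domain arithmetic mean of span counts over a species set.

    Species without the domain contribute zero; an empty set is an error
    (it has no mean).
    """
    species = sorted(set(species_set))
    if not species:
        raise ValueError("lineage mean over an empty species set is undefined")
    missing = set(species) - set(counts.by_species.columns)
    if missing:
        raise KeyError(f"species not in count matrix: {', '.join(sorted(missing))}")
    return counts.by_species[species].mean(axis=1)


def fold_changes(
    counts: DomainCountMatrix,
    tree: SpeciesTree,
    path: list[TreeNode] | None = None,
) -> list[FoldChangeRecord]:
    """One record per (domain, non-root path node).

    The root has no sister and is skipped.  Records are sorted by
    (node path position, accession).
    """
    if path is None:
        path = tree.path_to_focal()
    records: list[FoldChangeRecord] = []
    for node in path:
        if node.parent is None:
            continue  # root: no sister lineage to compare against
        clade = tree.clade_species(node)
        sister = tree.sister_species(node)
        mean_in = lineage_mean(counts, clade)
        mean_sister = lineage_mean(counts, sister)
        for acc in counts.by_species.index:
            mi = float(mean_in[acc])
            ms = float(mean_sister[acc])
            if ms > 0:
                records.append(
                    FoldChangeRecord(acc, node.name, mi, ms, mi / ms, "ok")
                )
            elif mi > 0:
                records.append(FoldChangeRecord(acc, node.name, mi, ms, None, "emergent"))
            else:
                records.append(FoldChangeRecord(acc, node.name, mi, ms, None, "absent"))
    return records


@dataclass
class BurstReport:
    """Per-node ranking of domain expansions.

    ``top_k``: the k largest finite fold changes per node (ties broken by
    higher clade mean, then accession).  ``bursts``: all finite records at
    or above the threshold.  ``emergent``: domains present in the clade but
    absent from the sister, listed separately.
    """

    top_k: dict[str, list[FoldChangeRecord]]
    bursts: dict[str, list[FoldChangeRecord]]
    emergent: dict[str, list[FoldChangeRecord]]
    k: int
    threshold: float


def top_k_report(
    records: Iterable[FoldChangeRecord],
    k: int = 10,
    threshold: float = DEFAULT_BURST_THRESHOLD,
) -> BurstReport:
    by_node: dict[str, list[FoldChangeRecord]] = {}
    for rec in records:
        by_node.setdefault(rec.node, []).append(rec)
    top_k: dict[str, list[FoldChangeRecord]] = {}
    bursts: dict[str, list[FoldChangeRecord]] = {}
    emergent: dict[str, list[FoldChangeRecord]] = {}
    for node, recs in sorted(by_node.items()):
        finite = [r for r in recs if r.status == "ok"]
        # descending fold change; ties: larger clade mean first, then accession
        finite.sort(key=lambda r: (-r.fold_change, -r.mean_in, r.domain_acc))
        top_k[node] = finite[:k]
        bursts[node] = [r for r in finite if r.fold_change >= threshold]
        emergent[node] = sorted(
            (r for r in recs if r.status == "emergent"),
            key=lambda r: (-r.mean_in, r.domain_acc),
        )
    return BurstReport(top_k=top_k, bursts=bursts, emergent=emergent, k=k, threshold=threshold)
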