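"""Domain interval merging, per-protein architectures and count matrices.

Domain predictors report the same domain repeatedly on overlapping
coordinate windows (several member databases, fragmented models).  Counting
raw hits would inflate repeat numbers, so per (protein, domain) the
occurrence intervals are union-merged: the merged spans are the minimal set
of intervals whose residue union equals the union of the inputs.  Counts and
left-to-right domain order ("architecture") are then taken over merged
spans, so a tandem repeat (e.g. a pentatricopeptide-repeat protein) counts
once per genuinely distinct occurrence.

The default merge rule joins intervals only when they actually share a
residue ("overlap" mode); "book_ended" mode additionally joins abutting
intervals (end + 1 == next start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import pandas as pd

from lgptrace.io_formats import DomainHit, OrthogroupTable

__all__ = [
    "MergedDomainSpan",
    "ProteinArchitecture",
    "DomainCountMatrix",
    "merge_intervals",
    "merge_all_hits",
    "build_architecture",
    "build_architectures",
    "count_matrix",
]

MergeMode = Literal["overlap", "book_ended"]


class MergedDomainSpan(NamedTuple):
    """A post-merge domain occurrence (1-based inclusive coordinates)."""

    protein_id: str
    domain_acc: str
    start: int
    end: int


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered domain content of one protein.

    ``order`` lists domain accessions of all merged spans sorted by
    (start, end, accession); a domain recurring at disjoint positions
    contributes one token per occurrence.  ``spans`` retains the
    coordinates in the same order.
    """

    protein_id: str
    order: tuple[str, ...]
    spans: tuple[MergedDomainSpan, ...]

    def project(self, domain_set: frozenset[str]) -> tuple[str, ...]:
        """Architecture restricted to a domain set, order preserved."""
        return tuple(d for d in self.order if d in domain_set)


def merge_intervals(
    hits: Iterable[DomainHit], mode: MergeMode = "overlap"
) -> list[MergedDomainSpan]:
    """Union-merge the hit intervals of one (protein, domain) pair.

    Output spans are pairwise non-overlapping and sorted by start; their
    residue union equals the union of the inputs.  Empty input yields an
    empty list.
    """
    hits = list(hits)
    if not hits:
        return []
    proteins = {h.protein_id for h in hits}
    domains = {h.domain_acc for h in hits}
    if len(proteins) > 1 or len(domains) > 1:
        raise ValueError(
            "merge_intervals expects hits of a single (protein, domain) pair; "
            f"got proteins {sorted(proteins)} and domains {sorted(domains)}"
        )
    gap = 1 if mode == "book_ended" else 0
    ordered = sorted((h.start, h.end) for h in hits)
    merged: list[list[int]] = [list(ordered[0])]
    for start, end in ordered[1:]:
        last = merged[-1]
        if start <= last[1] + gap:
            last[1] = max(last[1], end)
        else:
            merged.append([start, end])
    protein = next(iter(proteins))
    domain = next(iter(domains))
    return [MergedDomainSpan(protein, domain, s, e) for s, e in merged]


def merge_all_hits(
    hits: Iterable[DomainHit], mode: MergeMode = "overlap"
) -> list[MergedDomainSpan]:
    """Merge a full hit list, grouping by (protein, domain).

    Returns all merged spans sorted by (protein, start, end, accession).
    """
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        groups.setdefault((h.protein_id, h.domain_acc), []).append(h)
    spans: list[MergedDomainSpan] = []
    for key in sorted(groups):
        spans.extend(merge_intervals(groups[key], mode=mode))
    spans.sort(key=lambda s: (s.protein_id, s.start, s.end, s.domain_acc))
    return spans


def build_architecture(spans: Iterable[MergedDomainSpan]) -> ProteinArchitecture:
    """Order all merged spans of one protein into its architecture.

    Ties on start are broken by end, then accession, so the order is a
    deterministic function of the span set.  Nested spans (one domain inside
    another) keep both tokens.
    """
    spans = list(spans)
    if not spans:
        raise ValueError("cannot build an architecture from zero spans")
    proteins = {s.protein_id for s in spans}
    if len(proteins) > 1:
        raise ValueError(f"spans from multiple proteins: {sorted(proteins)}")
    ordered = tuple(sorted(spans, key=lambda s: (s.start, s.end, s.domain_acc)))
    return ProteinArchitecture(
        protein_id=next(iter(proteins)),
        order=tuple(s.domain_acc for s in ordered),
        spans=ordered,
    )


def build_architectures(
    spans: Iterable[MergedDomainSpan],
) -> dict[str, ProteinArchitecture]:
    """Architectures for every protein appearing in ``spans``."""
    by_protein: dict[str, list[MergedDomainSpan]] = {}
    for s in spans:
        by_protein.setdefault(s.protein_id, []).append(s)
    return {p: build_architecture(v) for p, v in by_protein.items()}


@dataclass
class DomainCountMatrix:
    """Merged-span counts of domains at species and orthogroup granularity.

    ``by_species``: DataFrame, rows = domain accessions, columns = species,
    values = number of merged spans across all proteins of that species in
    scope.  ``by_orthogroup``: same, columns = orthogroups.
    ``n_orthogroups`` / ``n_proteins``: per-domain number of distinct
    orthogroups / proteins carrying the domain (the two dimensions of a
    domain-frequency bubble plot).
    """

    by_species: pd.DataFrame
    by_orthogroup: pd.DataFrame
    n_orthogroups: pd.Series
    n_proteins: pd.Series

    @property
    def domains(self) -> list[str]:
        return list(self.by_species.index)


def count_matrix(
    spans: Iterable[MergedDomainSpan],
    ogs: OrthogroupTable,
    scope_orthogroups: frozenset[str] | None = None,
) -> DomainCountMatrix:
    """Count merged spans per (domain, species) and (domain, orthogroup).

    ``scope_orthogroups`` restricts counting to proteins of those
    orthogroups (e.g. the stress-annotated subset); ``None`` counts over
    the whole table.  Spans of proteins absent from the table are an error,
    as is any violation of the one-orthogroup-per-protein partition (already
    enforced by the table itself).
    """
    protein_sp = ogs.protein_species_map()
    species = list(ogs.species)
    rows: list[tuple[str, str, str, str]] = []
    for s in spans:
        og = ogs.orthogroup_of(s.protein_id)
        if og is None:
            raise ValueError(
                f"protein {s.protein_id!r} has domain spans but is in no orthogroup"
            )
        if scope_orthogroups is not None and og not in scope_orthogroups:
            continue
        rows.append((s.domain_acc, protein_sp[s.protein_id], og, s.protein_id))
    if rows:
        df = pd.DataFrame(rows, columns=["domain", "species", "orthogroup", "protein"])
        by_species = (
            df.groupby(["domain", "species"]).size().unstack(fill_value=0)
        )
        by_species = by_species.reindex(columns=species, fill_value=0).sort_index()
        by_orthogroup = (
            df.groupby(["domain", "orthogroup"]).size().unstack(fill_value=0).sort_index()
        )
        n_orthogroups = df.groupby("domain")["orthogroup"].nunique().sort_index()
        n_proteins = df.groupby("domain")["protein"].nunique().sort_index()
    else:
        by_species = pd.DataFrame(columns=species, dtype=int)
        by_orthogroup = pd.DataFrame(dtype=int)
        n_orthogroups = pd.Series(dtype=int)
        n_proteins = pd.Series(dtype=int)
    return DomainCountMatrix(
        by_species=by_species,
        by_orthogroup=by_orthogroup,
        n_orthogroups=n_orthogroups,
        n_proteins=n_proteins,
    )
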