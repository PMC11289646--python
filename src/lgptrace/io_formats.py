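"""Readers and writers for the external formats the pipeline consumes.

Supported formats:

* orthogroup membership tables in the OrthoFinder ``Orthogroups.tsv``
  dialect (rows = orthogroups, columns = species, cells = comma-separated
  protein IDs),
* protein domain predictions in the InterProScan TSV dialect,
* GO ontologies in OBO (``is_a`` and ``relationship: part_of`` edges),
* rooted Newick species trees with internal-node labels,
* two-column TSV GO-annotation tables and species→lineage maps.

Coordinates in domain hits are 1-based inclusive residue positions, the
convention InterProScan itself documents; all downstream interval math keeps
that convention.  Every writer sorts rows by primary ID so output files are
byte-stable across runs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import networkx as nx
import obonet

from lgptrace.species_tree import SpeciesTree

__all__ = [
    "LINEAGE_VOCABULARY",
    "EMBRYOPHYTE_LINEAGES",
    "OrthogroupTable",
    "DomainHit",
    "GoDag",
    "GoAnnotationTable",
    "LineageMap",
    "read_orthogroups",
    "write_orthogroups",
    "read_interproscan_tsv",
    "write_interproscan_tsv",
    "read_obo",
    "read_newick_tree",
    "read_go_table",
    "write_go_table",
    "read_lineage_map",
    "write_lineage_map",
]

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Controlled vocabulary of lineage labels, ordered root-ward to crown-ward.
LINEAGE_VOCABULARY = (
    "cyanobacteria",
    "chlorophyte",
    "mesostigmatophyceae",
    "chlorokybophyceae",
    "klebsormidiophyceae",
    "charophyceae",
    "coleochaetophyceae",
    "zygnematophyceae",
    "bryophyte",
    "tracheophyte",
)

#: Lineages whose union constitutes the embryophytes (land plants).
EMBRYOPHYTE_LINEAGES = frozenset({"bryophyte", "tracheophyte"})


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup → species → protein IDs.

    Orthogroup IDs are unique and protein IDs are globally unique across the
    whole table (each protein belongs to exactly one orthogroup — the
    partition property that origin assignment and domain counting rely on).
    Every species column is present for every row; empty memberships are
    empty tuples.
    """

    species: tuple[str, ...]
    members: dict[str, dict[str, tuple[str, ...]]]
    _protein_to_og: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._protein_to_og:
            for og_id, row in self.members.items():
                for sp_proteins in row.values():
                    for protein in sp_proteins:
                        prev = self._protein_to_og.get(protein)
                        if prev is not None:
                            raise ValueError(
                                f"protein {protein!r} appears in orthogroups "
                                f"{prev!r} and {og_id!r}; protein IDs must be "
                                "globally unique"
                            )
                        self._protein_to_og[protein] = og_id

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.members)

    def proteins_of(self, og_id: str) -> list[str]:
        """All member proteins of an orthogroup, in species-column order."""
        row = self.members[og_id]
        return [p for sp in self.species for p in row[sp]]

    def orthogroup_of(self, protein: str) -> str | None:
        return self._protein_to_og.get(protein)

    def carrier_species(self, og_id: str) -> frozenset[str]:
        """Species with at least one member protein in the orthogroup."""
        row = self.members[og_id]
        return frozenset(sp for sp, prots in row.items() if prots)

    def species_of_protein(self, protein: str) -> str | None:
        og = self._protein_to_og.get(protein)
        if og is None:
            return None
        for sp, prots in self.members[og].items():
            if protein in prots:
                return sp
        return None

    def protein_species_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for row in self.members.values():
            for sp, prots in row.items():
                for p in prots:
                    out[p] = sp
        return out


def read_orthogroups(path) -> OrthogroupTable:
    """Read an OrthoFinder-dialect ``Orthogroups.tsv`` file.

    The first column is the orthogroup ID; the remaining headers are species
    IDs.  Cells are split on commas (``", "`` or ``","``) and whitespace-
    trimmed; empty cells denote absence.  Duplicate orthogroup IDs or a
    protein ID appearing in two rows are hard errors.
    """
    members: dict[str, dict[str, tuple[str, ...]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty orthogroup file")
        cols = header.split("\t")
        species = tuple(cols[1:])
        if len(set(species)) != len(species):
            raise ValueError(f"{path}: duplicate species columns in header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            og_id = parts[0]
            if og_id in members:
                raise ValueError(f"{path}:{lineno}: duplicate orthogroup ID {og_id!r}")
            row = {}
            for sp, cell in zip(species, parts[1:]):
                cell = cell.strip()
                row[sp] = tuple(p.strip() for p in cell.split(",") if p.strip()) if cell else ()
            members[og_id] = row
    return OrthogroupTable(species=species, members=members)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    """Write an orthogroup table in the OrthoFinder dialect (``", "`` separator)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og_id in sorted(table.members):
            row = table.members[og_id]
            cells = [", ".join(row[sp]) for sp in table.species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------


class DomainHit(NamedTuple):
    """One predicted domain occurrence on a protein (1-based inclusive)."""

    protein_id: str
    domain_acc: str
    start: int
    end: int
    source_db: str | None = None


AccessionPolicy = Literal["interpro_only", "fallback_signature"]

# InterProScan TSV column indices (0-based).
_IPR_COL_PROTEIN = 0
_IPR_COL_ANALYSIS = 3
_IPR_COL_SIGNATURE = 4
_IPR_COL_START = 6
_IPR_COL_STOP = 7
_IPR_COL_INTERPRO = 11


def read_interproscan_tsv(
    path, accession_policy: AccessionPolicy = "interpro_only"
) -> list[DomainHit]:
    """Read an InterProScan TSV file into a list of :class:`DomainHit`.

    The domain accession is taken from the InterPro accession column when
    present and not ``"-"``.  Under ``"interpro_only"`` (the default, since
    downstream counting is over integrated IPR accessions) rows without an
    InterPro accession are skipped and the skip count logged; under
    ``"fallback_signature"`` the member-database signature accession is used
    instead.  Rows with non-integer coordinates or start > end are errors.
    """
    if accession_policy not in ("interpro_only", "fallback_signature"):
        raise ValueError(f"unknown accession policy {accession_policy!r}")
    hits: list[DomainHit] = []
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected ≥8 tab-separated columns, got {len(parts)}"
                )
            protein = parts[_IPR_COL_PROTEIN]
            try:
                start = int(parts[_IPR_COL_START])
                end = int(parts[_IPR_COL_STOP])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer domain coordinates "
                    f"{parts[_IPR_COL_START]!r}..{parts[_IPR_COL_STOP]!r}"
                ) from None
            if not (1 <= start <= end):
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}..{end} "
                    "(need 1 <= start <= end)"
                )
            interpro = parts[_IPR_COL_INTERPRO] if len(parts) > _IPR_COL_INTERPRO else "-"
            source_db = parts[_IPR_COL_ANALYSIS] if len(parts) > _IPR_COL_ANALYSIS else None
            if interpro and interpro != "-":
                acc = interpro
            elif accession_policy == "fallback_signature":
                acc = parts[_IPR_COL_SIGNATURE]
            else:
                n_skipped += 1
                continue
            if not acc:
                raise ValueError(f"{path}:{lineno}: empty domain accession")
            hits.append(DomainHit(protein, acc, start, end, source_db))
    if n_skipped:
        logger.info(
            "%s: skipped %d rows without an InterPro accession (policy interpro_only)",
            path,
            n_skipped,
        )
    return hits


def write_interproscan_tsv(hits: Iterable[DomainHit], path) -> None:
    """Write domain hits as a minimal 12-column InterProScan-dialect TSV.

    Only the columns the reader consumes carry data; the rest are ``-``
    placeholders.  Rows are sorted by (protein, start, end, accession).
    """
    rows = sorted(hits, key=lambda h: (h.protein_id, h.start, h.end, h.domain_acc))
    with open(path, "wt", encoding="utf-8") as fh:
        for h in rows:
            cols = ["-"] * 12
            cols[_IPR_COL_PROTEIN] = h.protein_id
            cols[_IPR_COL_ANALYSIS] = h.source_db or "-"
            cols[_IPR_COL_SIGNATURE] = h.domain_acc
            cols[_IPR_COL_START] = str(h.start)
            cols[_IPR_COL_STOP] = str(h.end)
            cols[_IPR_COL_INTERPRO] = h.domain_acc
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GO ontology (OBO)
# ---------------------------------------------------------------------------


@dataclass
class GoDag:
    """A GO DAG: term set plus child→parent edges tagged ``is_a``/``part_of``.

    ``graph`` is a :class:`networkx.MultiDiGraph` with edges pointing from
    child to parent, keyed by the relation name (the orientation obonet
    uses).  The graph is validated acyclic on construction.
    """

    graph: nx.MultiDiGraph

    def __post_init__(self) -> None:
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            return
        desc = " -> ".join(str(edge[0]) for edge in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"GO graph contains a cycle: {desc}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def children(self, term: str, relations: frozenset[str]) -> list[str]:
        """Direct children of ``term`` via the given relations."""
        out = []
        for child, _, key in self.graph.in_edges(term, keys=True):
            if key in relations:
                out.append(child)
        return out


def read_obo(path) -> GoDag:
    """Read an OBO ontology (``is_a`` and ``relationship: part_of`` edges)."""
    graph = obonet.read_obo(path)
    multi = nx.MultiDiGraph()
    multi.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        multi.add_edge(child, parent, key=key)
    return GoDag(graph=multi)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick_tree(path, focal_label: str = SpeciesTree.DEFAULT_FOCAL_LABEL) -> SpeciesTree:
    """Read a rooted, internally labeled Newick tree (delegates to SpeciesTree)."""
    return SpeciesTree.from_newick_file(path, focal_label=focal_label)


# ---------------------------------------------------------------------------
# GO annotation tables
# ---------------------------------------------------------------------------


@dataclass
class GoAnnotationTable:
    """Subject (protein or orthogroup) → set of GO IDs."""

    subject_kind: Literal["protein", "orthogroup"]
    annotations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for subject, terms in self.annotations.items():
            for term in terms:
                if not GO_ID_RE.match(term):
                    raise ValueError(
                        f"invalid GO ID {term!r} for subject {subject!r} "
                        "(expected GO: followed by 7 digits)"
                    )


def read_go_table(path, subject_kind: Literal["protein", "orthogroup"]) -> GoAnnotationTable:
    """Read a two-column TSV ``subject<TAB>GO:NNNNNNN`` (one pair per row).

    Multiple rows per subject accumulate; a comma-separated second column is
    also accepted.
    """
    annotations: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            subject, cell = parts
            terms = [t.strip() for t in cell.split(",") if t.strip()]
            annotations.setdefault(subject, set()).update(terms)
    return GoAnnotationTable(
        subject_kind=subject_kind,
        annotations={s: frozenset(t) for s, t in annotations.items()},
    )


def write_go_table(table: GoAnnotationTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for subject in sorted(table.annotations):
            for term in sorted(table.annotations[subject]):
                fh.write(f"{subject}\t{term}\n")


# ---------------------------------------------------------------------------
# Lineage map
# ---------------------------------------------------------------------------


@dataclass
class LineageMap:
    """Species → lineage label from the controlled vocabulary."""

    lineages: dict[str, str]

    def __post_init__(self) -> None:
        for sp, lineage in self.lineages.items():
            if lineage not in LINEAGE_VOCABULARY:
                raise ValueError(
                    f"species {sp!r} has unknown lineage {lineage!r}; "
                    f"expected one of {', '.join(LINEAGE_VOCABULARY)}"
                )

    def lineage_of(self, species: str) -> str:
        try:
            return self.lineages[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no lineage assignment") from None

    def species_of(self, lineage: str) -> frozenset[str]:
        return frozenset(sp for sp, lin in self.lineages.items() if lin == lineage)

    def embryophytes(self) -> frozenset[str]:
        """Land-plant species: bryophytes ∪ tracheophytes."""
        return frozenset(
            sp for sp, lin in self.lineages.items() if lin in EMBRYOPHYTE_LINEAGES
        )

    def is_embryophyte(self, species: str) -> bool:
        return self.lineage_of(species) in EMBRYOPHYTE_LINEAGES

    def validate_covers(self, species: Iterable[str]) -> None:
        missing = sorted(set(species) - set(self.lineages))
        if missing:
            raise ValueError(f"species without lineage assignment: {', '.join(missing)}")


def read_lineage_map(path) -> LineageMap:
    lineages: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sp, lineage = parts
            if sp in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate species {sp!r}")
            lineages[sp] = lineage
    return LineageMap(lineages=lineages)


def write_lineage_map(lmap: LineageMap, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sp in sorted(lmap.lineages):
            fh.write(f"{sp}\t{lmap.lineages[sp]}\n")
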