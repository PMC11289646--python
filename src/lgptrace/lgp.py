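"""Latent genetic potential: novelty by recombination of old domains.

An orthogroup born at node N shows *latent genetic potential* (LGP) when it
is built from protein domains that each existed before N — so the raw
material predates the gene family — while the ordered domain combination
itself does not occur in any single protein outside the clade of N.  The
gene family is then a new arrangement of old parts (domain shuffling /
co-option) rather than a de novo domain birth.

The domain set evaluated is the orthogroup's *embryophytic domain set*:
domains predicted on its proteins in at least one bryophyte AND at least
one tracheophyte, i.e. the domain configuration attributable to the
land-plant LCA rather than to a single land-plant subclade.  Orthogroups
with an empty set are ineligible (counted in origin denominators, never
LGP).

Two readings of "the domains existed before N" are implemented:

* ``any_outgroup`` — every set domain occurs in ≥1 species outside
  clade(N) (collective evidence of prior existence);
* ``all_previous_lineages`` (default, the stricter reading) — every set
  domain occurs in ≥1 species of *each* sister lineage branching along the
  root path above N.  The sister of the root itself (the outgroup clade on
  the far side of the root, e.g. cyanobacteria) is not required.

``all_previous_lineages`` implies ``any_outgroup``, so its LGP set is a
subset of the laxer mode's on every input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from lgptrace.domain_architecture import ProteinArchitecture
from lgptrace.io_formats import GoAnnotationTable, LineageMap, OrthogroupTable
from lgptrace.phylostratigraphy import OriginAssignment
from lgptrace.species_tree import SpeciesTree, TreeNode

__all__ = [
    "AgeMode",
    "EmbryophyticDomainSet",
    "LgpRecord",
    "NodeTally",
    "embryophytic_domain_set",
    "domain_completion",
    "classify_lgp",
    "classify_all",
    "node_tallies",
    "go_term_counts",
]

AgeMode = Literal["any_outgroup", "all_previous_lineages"]
DEFAULT_AGE_MODE: AgeMode = "all_previous_lineages"


@dataclass(frozen=True)
class EmbryophyticDomainSet:
    """Domains of an orthogroup attributable to the land-plant LCA.

    ``domains``: accessions predicted on the orthogroup's proteins in ≥1
    bryophyte and ≥1 tracheophyte species.  ``representative_architectures``:
    the distinct non-empty projections of embryophyte member architectures
    onto that domain set — the ordered combinations whose novelty LGP asks
    about.
    """

    orthogroup_id: str
    domains: frozenset[str]
    representative_architectures: frozenset[tuple[str, ...]]


@dataclass(frozen=True)
class LgpRecord:
    """LGP verdict of one orthogroup, evaluated at node N.

    ``lgp`` is true iff the orthogroup originated exactly at N, every set
    domain passes the age rule, and no outgroup protein shows any
    representative ordered combination.  ``eligible`` is false when the
    embryophytic domain set is empty (verdict then forced false).
    """

    orthogroup_id: str
    node: str
    og_origin: str
    eligible: bool
    domain_age_ok: bool
    architecture_novel: bool
    lgp: bool
    stress: bool


@dataclass(frozen=True)
class NodeTally:
    """Per-node x/y counts: x = stress LGP orthogroups, y = all LGP.

    ``n_origin_stress`` / ``n_origin_total`` are the matching origin
    denominators (stress-annotated and all orthogroups assigned to the
    node), exported alongside so either ratio can be formed.
    """

    node: str
    x: int
    y: int
    n_origin_stress: int
    n_origin_total: int


def embryophytic_domain_set(
    og_id: str,
    ogs: OrthogroupTable,
    architectures: dict[str, ProteinArchitecture],
    lineage_map: LineageMap,
) -> EmbryophyticDomainSet:
    """Compute the embryophytic domain set and its representative architectures."""
    bry = lineage_map.species_of("bryophyte")
    tra = lineage_map.species_of("tracheophyte")
    row = ogs.members[og_id]
    domains_bry: set[str] = set()
    domains_tra: set[str] = set()
    for sp, proteins in row.items():
        if sp in bry or sp in tra:
            bucket = domains_bry if sp in bry else domains_tra
            for p in proteins:
                arch = architectures.get(p)
                if arch is not None:
                    bucket.update(arch.order)
    domains = frozenset(domains_bry & domains_tra)
    reps: set[tuple[str, ...]] = set()
    if domains:
        for sp, proteins in row.items():
            if sp in bry or sp in tra:
                for p in proteins:
                    arch = architectures.get(p)
                    if arch is not None:
                        proj = arch.project(domains)
                        if proj:
                            reps.add(proj)
    return EmbryophyticDomainSet(
        orthogroup_id=og_id,
        domains=domains,
        representative_architectures=frozenset(reps),
    )


def domain_completion(
    eset: EmbryophyticDomainSet,
    domain_carriers: dict[str, frozenset[str]],
    species: Iterable[str],
) -> dict[str, bool]:
    """Per species: does it carry every domain of the embryophytic set?

    ``domain_carriers`` maps each domain to the species carrying it in the
    configured background scope (any protein of the species, not only
    members of this orthogroup).  An empty set has no completion to assess.
    """
    if not eset.domains:
        raise ValueError(
            f"orthogroup {eset.orthogroup_id!r} has an empty embryophytic "
            "domain set; completion is undefined"
        )
    empty: frozenset[str] = frozenset()
    return {
        sp: all(sp in domain_carriers.get(d, empty) for d in eset.domains)
        for sp in species
    }


def _sister_lineages_above(tree: SpeciesTree, node: TreeNode) -> list[frozenset[str]]:
    """Sister leaf sets at each ancestor of ``node`` strictly below the root.

    Walking root-ward from ``node``, each ancestor contributes the leaves of
    its other children (the lineage that branched off at that point).  The
    root is excluded: the clade on the far side of the root is an outgroup
    to the whole ingroup radiation, not one of its "previous lineages".
    """
    sisters: list[frozenset[str]] = []
    child = node
    ancestor = node.parent
    while ancestor is not None and ancestor.parent is not None:
        acc: set[str] = set()
        for c in ancestor.children:
            if c is not child:
                acc |= c.leafset
        sisters.append(frozenset(acc))
        child = ancestor
        ancestor = ancestor.parent
    return sisters


def classify_lgp(
    eset: EmbryophyticDomainSet,
    og_origin: OriginAssignment,
    domain_carriers: dict[str, frozenset[str]],
    architectures: dict[str, ProteinArchitecture],
    protein_species: dict[str, str],
    tree: SpeciesTree,
    node: TreeNode | str | None = None,
    age_mode: AgeMode = DEFAULT_AGE_MODE,
    stress: bool = False,
    domain_protein_index: dict[str, frozenset[str]] | None = None,
) -> LgpRecord:
    """Classify one orthogroup at node N (default: its own origin node).

    ``domain_carriers`` gives background-scope species presence per domain;
    ``architectures``/``protein_species`` cover the full background proteome
    (the outgroup scan needs every protein, not just this orthogroup's).
    ``domain_protein_index`` (domain → proteins carrying it) is an optional
    precomputed index that keeps the outgroup architecture scan from
    touching unrelated proteins.
    """
    n_node = tree._resolve(node) if node is not None else og_origin.origin_node
    clade = tree.clade_species(n_node)
    empty: frozenset[str] = frozenset()

    eligible = bool(eset.domains)
    origin_matches = og_origin.origin_node is n_node

    domain_age_ok = False
    architecture_novel = False
    if eligible:
        if age_mode == "any_outgroup":
            outgroup = tree.leaf_set - clade
            domain_age_ok = all(
                domain_carriers.get(d, empty) & outgroup for d in eset.domains
            )
        elif age_mode == "all_previous_lineages":
            sisters = _sister_lineages_above(tree, n_node)
            domain_age_ok = bool(sisters) and all(
                all(domain_carriers.get(d, empty) & sis for sis in sisters)
                for d in eset.domains
            )
        else:
            raise ValueError(f"unknown age mode {age_mode!r}")

        # outgroup architecture scan: only proteins carrying a set domain matter
        if domain_protein_index is not None:
            candidates: set[str] = set()
            for d in eset.domains:
                candidates |= domain_protein_index.get(d, empty)
        else:
            candidates = set(architectures)
        reps = eset.representative_architectures
        architecture_novel = True
        for p in candidates:
            sp = protein_species.get(p)
            if sp is None or sp in clade:
                continue
            proj = architectures[p].project(eset.domains)
            if proj and proj in reps:
                architecture_novel = False
                break

    return LgpRecord(
        orthogroup_id=eset.orthogroup_id,
        node=n_node.name,
        og_origin=og_origin.origin_node.name,
        eligible=eligible,
        domain_age_ok=domain_age_ok,
        architecture_novel=architecture_novel,
        lgp=eligible and origin_matches and domain_age_ok and architecture_novel,
        stress=stress,
    )


def classify_all(
    ogs: OrthogroupTable,
    og_origins: dict[str, OriginAssignment],
    domain_carriers: dict[str, frozenset[str]],
    architectures: dict[str, ProteinArchitecture],
    lineage_map: LineageMap,
    tree: SpeciesTree,
    stress_ogs: frozenset[str] = frozenset(),
    age_mode: AgeMode = DEFAULT_AGE_MODE,
) -> list[LgpRecord]:
    """LGP records for every orthogroup with an origin, each at its own origin."""
    protein_species = ogs.protein_species_map()
    index: dict[str, set[str]] = {}
    for p, arch in architectures.items():
        for d in set(arch.order):
            index.setdefault(d, set()).add(p)
    frozen_index = {d: frozenset(ps) for d, ps in index.items()}
    records = []
    for og_id in sorted(ogs.members):
        origin = og_origins.get(og_id)
        if origin is None:
            continue
        eset = embryophytic_domain_set(og_id, ogs, architectures, lineage_map)
        records.append(
            classify_lgp(
                eset,
                origin,
                domain_carriers,
                architectures,
                protein_species,
                tree,
                age_mode=age_mode,
                stress=og_id in stress_ogs,
                domain_protein_index=frozen_index,
            )
        )
    return records


def node_tallies(
    records: Iterable[LgpRecord],
    path: list[TreeNode],
) -> list[NodeTally]:
    """Per backbone node: x/y LGP counts plus origin denominators."""
    records = list(records)
    tallies = []
    for node in path:
        at_node = [r for r in records if r.og_origin == node.name]
        lgp_here = [r for r in at_node if r.lgp]
        tallies.append(
            NodeTally(
                node=node.name,
                x=sum(1 for r in lgp_here if r.stress),
                y=len(lgp_here),
                n_origin_stress=sum(1 for r in at_node if r.stress),
                n_origin_total=len(at_node),
            )
        )
    return tallies


def go_term_counts(
    og_ids: Iterable[str], og_go: GoAnnotationTable
) -> list[tuple[str, int]]:
    """GO-term frequency among a set of orthogroups (word-cloud data).

    Returns (term, count) pairs sorted by descending count then term.
    """
    counter: Counter[str] = Counter()
    empty: frozenset[str] = frozenset()
    for og_id in og_ids:
        counter.update(og_go.annotations.get(og_id, empty))
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
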