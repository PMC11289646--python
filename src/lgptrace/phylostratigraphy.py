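"""Origin assignment of orthogroups and domains by Dollo-style parsimony.

Each entity (an orthogroup, or a protein domain) is assumed to have arisen
once; its origin node is therefore the most recent common ancestor of all
species that still carry it, and absences inside that clade are losses.
Under lineage loss this estimate can only be too young (a descendant of the
true birth node), never too old — the direction the monotonicity tests
assert.

Domain origins are computed by default over proteins of *all* orthogroups,
not just the stress-annotated scope: the latent-genetic-potential question
is when a domain existed anywhere in the genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from lgptrace.domain_architecture import MergedDomainSpan
from lgptrace.io_formats import LineageMap, OrthogroupTable
from lgptrace.species_tree import SpeciesTree, TreeNode

__all__ = [
    "PresenceProfile",
    "OriginAssignment",
    "presence_profile",
    "orthogroup_profiles",
    "domain_profiles",
    "assign_origin",
    "assign_origins",
    "land_plant_specific",
]


@dataclass(frozen=True)
class PresenceProfile:
    """Which species carry an entity (orthogroup or domain)."""

    entity_id: str
    entity_kind: Literal["orthogroup", "domain"]
    carrier_species: frozenset[str]


@dataclass(frozen=True)
class OriginAssignment:
    """Parsimony origin: the MRCA of carrier species."""

    entity_id: str
    entity_kind: Literal["orthogroup", "domain"]
    origin_node: TreeNode
    n_carriers: int


def presence_profile(
    entity_id: str,
    entity_kind: Literal["orthogroup", "domain"],
    carriers: Iterable[str],
    tree: SpeciesTree,
) -> PresenceProfile:
    carriers = frozenset(carriers)
    unknown = carriers - tree.leaf_set
    if unknown:
        raise KeyError(
            f"{entity_kind} {entity_id!r} has carriers not on the tree: "
            f"{', '.join(sorted(unknown))}"
        )
    return PresenceProfile(entity_id, entity_kind, carriers)


def orthogroup_profiles(ogs: OrthogroupTable, tree: SpeciesTree) -> list[PresenceProfile]:
    """Per-orthogroup carrier sets (species with ≥1 member protein)."""
    return [
        presence_profile(og_id, "orthogroup", ogs.carrier_species(og_id), tree)
        for og_id in sorted(ogs.members)
    ]


def domain_profiles(
    spans: Iterable[MergedDomainSpan],
    ogs: OrthogroupTable,
    tree: SpeciesTree,
    scope_orthogroups: frozenset[str] | None = None,
) -> list[PresenceProfile]:
    """Per-domain carrier sets (species with ≥1 merged span in scope)."""
    protein_sp = ogs.protein_species_map()
    carriers: dict[str, set[str]] = {}
    for s in spans:
        if scope_orthogroups is not None:
            og = ogs.orthogroup_of(s.protein_id)
            if og not in scope_orthogroups:
                continue
        sp = protein_sp.get(s.protein_id)
        if sp is None:
            raise ValueError(f"protein {s.protein_id!r} is in no orthogroup")
        carriers.setdefault(s.domain_acc, set()).add(sp)
    return [
        presence_profile(acc, "domain", spp, tree) for acc, spp in sorted(carriers.items())
    ]


def assign_origin(profile: PresenceProfile, tree: SpeciesTree) -> OriginAssignment:
    """Origin node of one entity; empty profiles are rejected upstream."""
    if not profile.carrier_species:
        raise ValueError(
            f"{profile.entity_kind} {profile.entity_id!r} has no carriers; "
            "cannot assign an origin"
        )
    node = tree.mrca(profile.carrier_species)
    return OriginAssignment(
        entity_id=profile.entity_id,
        entity_kind=profile.entity_kind,
        origin_node=node,
        n_carriers=len(profile.carrier_species),
    )


def assign_origins(
    profiles: Iterable[PresenceProfile], tree: SpeciesTree
) -> dict[str, OriginAssignment]:
    """Origins for all profiles with ≥1 carrier; empty ones are skipped."""
    out: dict[str, OriginAssignment] = {}
    for profile in profiles:
        if not profile.carrier_species:
            continue
        out[profile.entity_id] = assign_origin(profile, tree)
    return out


def land_plant_specific(
    ogs: OrthogroupTable,
    lineage_map: LineageMap,
    require_sublineages: tuple[str, str] = ("bryophyte", "tracheophyte"),
) -> frozenset[str]:
    """Orthogroups restricted to land plants but spanning both its crown clades.

    An orthogroup qualifies when every carrier species is an embryophyte and
    it has at least one carrier in each of the two required sub-lineages
    (default: a bryophyte and a tracheophyte), i.e. the orthogroup plausibly
    dates to the land-plant LCA rather than to one of its subclades.
    """
    lineage_map.validate_covers(ogs.species)
    emb = lineage_map.embryophytes()
    sub_a = lineage_map.species_of(require_sublineages[0])
    sub_b = lineage_map.species_of(require_sublineages[1])
    out = set()
    for og_id in ogs.members:
        carriers = ogs.carrier_species(og_id)
        if not carriers or not carriers <= emb:
            continue
        if carriers & sub_a and carriers & sub_b:
            out.add(og_id)
    return frozenset(out)
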