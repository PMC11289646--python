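"""Dual-evidence stress annotation of orthogroups.

An orthogroup is called stress-relevant when two independent lines of GO
evidence agree:

* **approach 1** — reference-species evidence: the orthogroup contains at
  least one stress-annotated protein from *every* configured reference
  species (in the motivating study: one angiosperm and one moss reference
  proteome with curated GO annotation);
* **approach 2** — de novo evidence: the orthogroup's own GO assignment
  (e.g. from an orthology-based functional annotator) contains at least one
  term from the stress closure.

"Stress" is operationalized as a fixed set of seed GO terms plus all their
descendants in the ontology.  The final call is the intersection
``approach1 AND approach2``, which trades recall for precision: each
approach alone over-calls in a different way (reference bias vs transfer
noise), and their conjunction keeps only doubly supported orthogroups.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from lgptrace.io_formats import GoAnnotationTable, GoDag, OrthogroupTable

__all__ = [
    "DEFAULT_CLOSURE_RELATIONS",
    "StressCall",
    "load_default_seed_terms",
    "go_descendant_closure",
    "reference_stress_proteins",
    "approach1_calls",
    "approach2_calls",
    "intersect_calls",
]

DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class StressCall:
    """Per-orthogroup stress verdict with its two evidence lines.

    ``stress`` is the conjunction of the two approaches; ``evidence1`` holds
    the supporting reference proteins (per reference species), ``evidence2``
    the closure terms found in the orthogroup's de novo annotation.
    """

    orthogroup_id: str
    approach1: bool
    approach2: bool
    evidence1: tuple[tuple[str, tuple[str, ...]], ...] = ()
    evidence2: tuple[str, ...] = ()

    @property
    def stress(self) -> bool:
        return self.approach1 and self.approach2


def load_default_seed_terms() -> frozenset[str]:
    """The packaged 31 seed GO terms for stress-response processes."""
    text = resources.files("lgptrace.data").joinpath("stress_seed_go_terms.txt").read_text()
    terms = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return frozenset(terms)


def go_descendant_closure(
    dag: GoDag,
    seeds: frozenset[str] | set[str],
    relations: frozenset[str] = DEFAULT_CLOSURE_RELATIONS,
) -> frozenset[str]:
    """Seeds plus every term from which a seed is reachable via child edges.

    Traverses the child relation (the reverse of the stored child→parent
    edges) restricted to ``relations``; annotating a protein with a
    descendant term implies the seed process, so the closure is the full
    stress vocabulary.
    """
    seeds = frozenset(seeds)
    missing = seeds - dag.terms
    if missing:
        raise KeyError(f"seed terms absent from ontology: {', '.join(sorted(missing))}")
    closure: set[str] = set(seeds)
    frontier = list(seeds)
    while frontier:
        term = frontier.pop()
        for child in dag.children(term, relations):
            if child not in closure:
                closure.add(child)
                frontier.append(child)
    return frozenset(closure)


def reference_stress_proteins(
    annotations: GoAnnotationTable, closure: frozenset[str]
) -> frozenset[str]:
    """Proteins of a reference species annotated with ≥1 closure term."""
    if annotations.subject_kind != "protein":
        raise ValueError("reference annotations must be protein-level")
    return frozenset(
        protein
        for protein, terms in annotations.annotations.items()
        if terms & closure
    )


def approach1_calls(
    ogs: OrthogroupTable, ref_sets: dict[str, frozenset[str]]
) -> dict[str, bool]:
    """Reference-species conjunction rule.

    An orthogroup passes iff it contains at least one stress protein from
    *every* reference species in ``ref_sets`` (keys are species column
    names, values the species' stress-protein sets).
    """
    if len(ref_sets) < 2:
        raise ValueError("approach 1 needs at least two reference species")
    missing = sorted(set(ref_sets) - set(ogs.species))
    if missing:
        raise ValueError(
            f"reference species not in orthogroup table columns: {', '.join(missing)}"
        )
    calls: dict[str, bool] = {}
    for og_id, row in ogs.members.items():
        ok = True
        for ref_sp, stress_set in ref_sets.items():
            if not any(p in stress_set for p in row[ref_sp]):
                ok = False
                break
        calls[og_id] = ok
    return calls


def approach1_evidence(
    ogs: OrthogroupTable, ref_sets: dict[str, frozenset[str]], og_id: str
) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """Supporting reference proteins of one orthogroup, per reference species."""
    row = ogs.members[og_id]
    return tuple(
        (ref_sp, tuple(p for p in row[ref_sp] if p in stress_set))
        for ref_sp, stress_set in sorted(ref_sets.items())
    )


def approach2_calls(
    og_go: GoAnnotationTable,
    closure: frozenset[str],
    universe: list[str] | None = None,
) -> dict[str, bool]:
    """De novo rule: the orthogroup's GO set intersects the stress closure.

    ``universe`` lists all orthogroup IDs to report (unannotated ones are
    False); defaults to the annotated subjects only.
    """
    if og_go.subject_kind != "orthogroup":
        raise ValueError("approach 2 annotations must be orthogroup-level")
    ids = universe if universe is not None else list(og_go.annotations)
    empty: frozenset[str] = frozenset()
    return {
        og_id: bool(og_go.annotations.get(og_id, empty) & closure) for og_id in ids
    }


def aggregate_protein_go(
    protein_go: GoAnnotationTable, ogs: OrthogroupTable
) -> GoAnnotationTable:
    """Union protein-level de novo GO annotations up to the orthogroup."""
    if protein_go.subject_kind != "protein":
        raise ValueError("expected protein-level annotations")
    agg: dict[str, set[str]] = {}
    for protein, terms in protein_go.annotations.items():
        og = ogs.orthogroup_of(protein)
        if og is not None:
            agg.setdefault(og, set()).update(terms)
    return GoAnnotationTable(
        subject_kind="orthogroup",
        annotations={og: frozenset(t) for og, t in agg.items()},
    )


def intersect_calls(
    a1: dict[str, bool],
    a2: dict[str, bool],
    og_go: GoAnnotationTable | None = None,
    closure: frozenset[str] | None = None,
) -> list[StressCall]:
    """Combine the two approaches into per-orthogroup stress calls.

    Both call maps must cover the same orthogroup universe.  The returned
    list is sorted by orthogroup ID; ``evidence2`` is filled when the de
    novo annotation table and closure are provided.
    """
    if set(a1) != set(a2):
        only1 = sorted(set(a1) - set(a2))[:3]
        only2 = sorted(set(a2) - set(a1))[:3]
        raise ValueError(
            "approach 1 and approach 2 cover different orthogroup universes "
            f"(e.g. only in a1: {only1}, only in a2: {only2})"
        )
    calls = []
    empty: frozenset[str] = frozenset()
    for og_id in sorted(a1):
        ev2: tuple[str, ...] = ()
        if og_go is not None and closure is not None:
            ev2 = tuple(sorted(og_go.annotations.get(og_id, empty) & closure))
        calls.append(
            StressCall(
                orthogroup_id=og_id,
                approach1=a1[og_id],
                approach2=a2[og_id],
                evidence2=ev2,
            )
        )
    return calls


def call_summary(calls: list[StressCall]) -> dict[str, int]:
    """Counts of a1-only / a2-only / both / neither over the universe."""
    both = sum(1 for c in calls if c.approach1 and c.approach2)
    a1_only = sum(1 for c in calls if c.approach1 and not c.approach2)
    a2_only = sum(1 for c in calls if c.approach2 and not c.approach1)
    return {
        "n_orthogroups": len(calls),
        "approach1": both + a1_only,
        "approach2": both + a2_only,
        "a1_only": a1_only,
        "a2_only": a2_only,
        "stress": both,
        "neither": len(calls) - both - a1_only - a2_only,
    }
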