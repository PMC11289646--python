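"""Deterministic synthetic input bundles with planted ground truth.

The generator emulates the statistical structure of a comparative-genomics
dataset over the green lineage: a rooted 37-species phylogeny (five
cyanobacteria, six chlorophytes, seven streptophyte algae, four bryophytes
and fifteen tracheophytes), protein domains born on internal branches,
orthogroups born later and assembled from domains already present in their
lineage, per-species gene duplications and losses, redundant overlapping
domain predictions, and two partially disagreeing lines of GO stress
evidence.

Every entity's birth branch, architecture and label is recorded in a
:class:`SimTruth`; truth labels (origins, stress calls, LGP verdicts) are
re-derived from the *materialized* tables by plain brute-force loops, so
they remain correct even when sampling accidents (losses, architecture
collisions, noise flips) change an entity's intended fate.

Biological constraints honoured by construction: a protein can only contain
domains that already existed on its branch (every architecture domain is
born at an ancestor-or-equal node of the orthogroup's birth node), and every
domain is anchored by a single-domain "background" orthogroup spanning its
full birth clade, so that under zero loss the carrier MRCA equals the birth
node exactly, and under loss it can only be a descendant of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from lgptrace.io_formats import (
    DomainHit,
    LineageMap,
    OrthogroupTable,
    write_go_table,
    write_interproscan_tsv,
    write_lineage_map,
    write_orthogroups,
    GoAnnotationTable,
)
from lgptrace.species_tree import SpeciesTree

__all__ = ["SimConfig", "SimTruth", "SimBundle", "paper37_newick", "simulate", "make_worked_micro_case"]

# ---------------------------------------------------------------------------
# The 37-species preset phylogeny
# ---------------------------------------------------------------------------

_PAPER37_LINEAGES: dict[str, str] = {
    **{f"cya{i}": "cyanobacteria" for i in range(1, 6)},
    **{f"chl{i}": "chlorophyte" for i in range(1, 7)},
    "mes1": "mesostigmatophyceae",
    "cko1": "chlorokybophyceae",
    "kle1": "klebsormidiophyceae",
    "cha1": "charophyceae",
    "col1": "coleochaetophyceae",
    "zyg1": "zygnematophyceae",
    "zyg2": "zygnematophyceae",
    **{f"bry{i}": "bryophyte" for i in range(1, 5)},
    **{f"tra{i}": "tracheophyte" for i in range(1, 16)},
}


def _ladder(leaves: list[str], label: str) -> str:
    """Pectinate subtree over the leaves, crown node labeled."""
    out = leaves[0]
    for leaf in leaves[1:-1]:
        out = f"({out},{leaf})"
    return f"({out},{leaves[-1]}){label}"


def paper37_newick() -> str:
    """Rooted Newick of the 37-species backbone with labeled LCA nodes.

    Backbone, root-ward to crown-ward: root (cyanobacteria vs green
    lineage), chloroplastida, streptophytes, Klebsormidiophyceae +
    Phragmoplastophyta, Phragmoplastophyta, Coleochaetophyceae + crown,
    Zygnematophyceae + land plants, land plants.
    """
    cya = _ladder([f"cya{i}" for i in range(1, 6)], "cyanobacteria")
    chl = _ladder([f"chl{i}" for i in range(1, 7)], "chlorophytes")
    bry = _ladder([f"bry{i}" for i in range(1, 5)], "bryophytes")
    tra = _ladder([f"tra{i}" for i in range(1, 16)], "tracheophytes")
    land_plants = f"({bry},{tra})land_plants"
    zyg = "(zyg1,zyg2)zygnematophyceae"
    zyg_lp = f"({zyg},{land_plants})zygnematophyceae_land_plants"
    coleo_plus = f"(col1,{zyg_lp})coleochaetophyceae_plus"
    phragmo = f"(cha1,{coleo_plus})phragmoplastophyta"
    phragmo_klebs = f"(kle1,{phragmo})phragmoplastophyta_klebsormidiophyceae"
    strepto = f"((mes1,cko1)mesostigmatophyceae_chlorokybophyceae,{phragmo_klebs})streptophytes"
    chloroplastida = f"({chl},{strepto})chloroplastida"
    return f"({cya},{chloroplastida})root;"


#: Default birth-node weights for domains (deep-skewed: most domains predate
#: streptophytes) and for orthogroups (crown-skewed: gene families keep
#: arising throughout, with a land-plant pulse).
_DOMAIN_NODE_WEIGHTS = {
    "root": 0.25,
    "chloroplastida": 0.25,
    "streptophytes": 0.10,
    "phragmoplastophyta_klebsormidiophyceae": 0.05,
    "phragmoplastophyta": 0.05,
    "coleochaetophyceae_plus": 0.03,
    "zygnematophyceae_land_plants": 0.07,
    "land_plants": 0.10,
    "bryophytes": 0.03,
    "tracheophytes": 0.07,
}

_OG_NODE_WEIGHTS = {
    "root": 0.04,
    "chloroplastida": 0.10,
    "streptophytes": 0.04,
    "phragmoplastophyta_klebsormidiophyceae": 0.03,
    "phragmoplastophyta": 0.03,
    "coleochaetophyceae_plus": 0.02,
    "zygnematophyceae_land_plants": 0.08,
    "land_plants": 0.22,
    "bryophytes": 0.04,
    "tracheophytes": 0.25,
    "zygnematophyceae": 0.03,
    "chlorophytes": 0.04,
    "cyanobacteria": 0.04,
    "mesostigmatophyceae_chlorokybophyceae": 0.04,
}


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Generator parameters (defaults are the study-like conditions).

    ``p_lgp`` is the probability that an orthogroup born on a focal-path
    branch is assembled only from domains born on strictly ancestral
    branches with a combination unused before; ``p_collision`` plants
    counter-examples whose ordered combination already exists on a single
    older protein.  ``dup_mean`` is the mean number of proteins per
    (species, orthogroup); ``p_loss`` is per-(orthogroup, species) lineage
    loss.  ``redundant_hit_rate`` duplicates a domain prediction on jittered
    overlapping coordinates to exercise interval merging.
    """

    seed: int = 0
    tree: str = "paper37"
    n_orthogroups: int = 2000
    n_domains: int = 300
    p_lgp: float = 0.15
    p_collision: float = 0.05
    p_loss: float = 0.0
    dup_mean: float = 1.5
    redundant_hit_rate: float = 0.1
    stress_fraction: float = 0.25
    a1_only_fraction: float = 0.05
    a2_only_fraction: float = 0.10
    noise_a1: float = 0.0
    noise_a2: float = 0.0
    expansion_node: str | None = None
    expansion_factor: float = 15.0
    ref_species: tuple[str, str] = ("tra1", "bry1")

    def __post_init__(self) -> None:
        for name in (
            "p_lgp",
            "p_collision",
            "p_loss",
            "redundant_hit_rate",
            "stress_fraction",
            "a1_only_fraction",
            "a2_only_fraction",
            "noise_a1",
            "noise_a2",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimTruth:
    """Planted and derived ground truth of one simulated bundle."""

    focal_label: str
    species_lineages: dict[str, str]
    domain_birth: dict[str, str]
    orthogroups: dict[str, dict]
    span_counts: dict[str, dict[str, int]]
    n_raw_hits: int
    noise: dict[str, float]
    expansion: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimBundle:
    """Paths of an emitted input bundle plus its truth."""

    directory: Path
    orthogroups: Path
    domains: Path
    obo: Path
    tree: Path
    lineages: Path
    og_go: Path
    ref_go: dict[str, Path]
    truth_json: Path
    truth: SimTruth = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Internal generation state
# ---------------------------------------------------------------------------


class _Sim:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        newick = paper37_newick() if config.tree == "paper37" else config.tree
        self.tree = SpeciesTree.from_newick(newick)
        self.lineages = dict(_PAPER37_LINEAGES) if config.tree == "paper37" else None
        self.path = self.tree.path_to_focal()
        self.path_labels = [n.name for n in self.path]
        # orthogroup structures
        self.og_arch: dict[str, tuple[str, ...]] = {}
        self.og_birth: dict[str, str] = {}
        self.og_kind: dict[str, str] = {}
        self.og_members: dict[str, dict[str, list[str]]] = {}
        self.protein_arch: dict[str, tuple[str, ...]] = {}
        self.protein_species: dict[str, str] = {}
        self.domain_birth: dict[str, str] = {}
        self._og_counter = 0

    # -- helpers -------------------------------------------------------

    def new_og_id(self) -> str:
        self._og_counter += 1
        return f"OG{self._og_counter:07d}"

    def ancestors_or_equal(self, label: str) -> list[str]:
        node = self.tree.node(label)
        out = [label]
        out.extend(n.name for n in self.tree.ancestors(node) if n.name)
        return out

    def strict_ancestors(self, label: str) -> list[str]:
        return self.ancestors_or_equal(label)[1:]

    def sample_node(self, weights: dict[str, float]) -> str:
        labels = sorted(weights)
        probs = np.array([weights[l] for l in labels], dtype=float)
        probs /= probs.sum()
        return labels[self.rng.choice(len(labels), p=probs)]

    # -- domains -------------------------------------------------------

    def make_domains(self) -> None:
        for i in range(self.cfg.n_domains):
            acc = f"IPR9{i + 1:05d}"
            self.domain_birth[acc] = self.sample_node(_DOMAIN_NODE_WEIGHTS)

    def domains_born_at(self, labels: list[str]) -> list[str]:
        wanted = set(labels)
        return sorted(a for a, b in self.domain_birth.items() if b in wanted)

    # -- orthogroup membership -----------------------------------------

    def add_orthogroup(
        self,
        birth: str,
        arch: tuple[str, ...],
        kind: str,
        dup_mean: float | None = None,
        no_loss: bool = False,
    ) -> str:
        og = self.new_og_id()
        self.og_birth[og] = birth
        self.og_arch[og] = arch
        self.og_kind[og] = kind
        clade = sorted(self.tree.clade_species(birth))
        dup = self.cfg.dup_mean if dup_mean is None else dup_mean
        members: dict[str, list[str]] = {}
        survivors = []
        for sp in clade:
            if no_loss or self.cfg.p_loss == 0 or self.rng.random() >= self.cfg.p_loss:
                survivors.append(sp)
        if not survivors:
            survivors = [clade[int(self.rng.integers(len(clade)))]]
        for sp in survivors:
            n = 1 + (int(self.rng.poisson(dup - 1.0)) if dup > 1.0 else 0)
            prots = []
            for k in range(n):
                pid = f"{sp}_{og}_{k}"
                prots.append(pid)
                self.protein_arch[pid] = arch
                self.protein_species[pid] = sp
            members[sp] = prots
        self.og_members[og] = members
        return og

    def add_collision_protein(self, og: str, species: str, arch: tuple[str, ...]) -> str:
        existing = self.og_members[og].get(species, [])
        k = sum(1 for p in existing if f"_{og}_c" in p)
        pid = f"{species}_{og}_c{k}"
        self.og_members[og].setdefault(species, []).append(pid)
        self.protein_arch[pid] = arch
        self.protein_species[pid] = species
        return pid

    # -- main generation ----------------------------------------------

    def make_orthogroups(self) -> None:
        # background anchors: one single-domain orthogroup per domain
        for acc in sorted(self.domain_birth):
            self.add_orthogroup(self.domain_birth[acc], (acc,), "background")
        on_path = set(self.path_labels[1:])  # every path node except the root
        for _ in range(self.cfg.n_orthogroups):
            birth = self.sample_node(_OG_NODE_WEIGHTS)
            u = self.rng.random()
            intent = "normal"
            if birth in on_path:
                if u < self.cfg.p_lgp:
                    intent = "lgp"
                elif u < self.cfg.p_lgp + self.cfg.p_collision:
                    intent = "collision"
            arch = self._draw_architecture(birth, intent)
            og = self.add_orthogroup(birth, arch, "main")
            if intent == "collision" and all(
                self.domain_birth[d] != birth for d in arch
            ):
                self._plant_collision(og, birth, arch)

    def _draw_architecture(self, birth: str, intent: str) -> tuple[str, ...]:
        ancestral = self.domains_born_at(self.strict_ancestors(birth))
        at_node = self.domains_born_at([birth])
        allowed = self.domains_born_at(self.ancestors_or_equal(birth))
        if intent in ("lgp", "collision") and ancestral:
            size = int(self.rng.integers(1, 4))
            size = min(size, len(ancestral))
            idx = self.rng.choice(len(ancestral), size=size, replace=False)
            return tuple(ancestral[i] for i in sorted(idx))
        # normal: usually include a domain born on this very branch
        pool = allowed or self.domains_born_at(["root"])
        size = int(self.rng.integers(1, 4))
        size = min(size, len(pool))
        idx = self.rng.choice(len(pool), size=size, replace=False)
        arch = [pool[i] for i in sorted(idx)]
        if at_node and self.rng.random() < 0.6:
            arch[int(self.rng.integers(len(arch)))] = at_node[
                int(self.rng.integers(len(at_node)))
            ]
        return tuple(arch)

    def _plant_collision(self, og: str, birth: str, arch: tuple[str, ...]) -> None:
        """Give one older protein the same ordered combination.

        The carrier species sits inside the clade of the youngest
        architecture domain but outside the orthogroup's clade, so domain
        carrier sets stay within their birth clades.
        """
        births = [self.domain_birth[d] for d in arch]
        # youngest birth node = the one whose clade is smallest
        youngest = min(births, key=lambda b: len(self.tree.clade_species(b)))
        pool = sorted(
            self.tree.clade_species(youngest) - self.tree.clade_species(birth)
        )
        if not pool:
            return
        species = pool[int(self.rng.integers(len(pool)))]
        # host: the background orthogroup of the youngest-born first domain
        host = None
        for cand_og, kind in self.og_kind.items():
            if kind == "background" and self.og_arch[cand_og][0] in arch:
                if self.og_birth[cand_og] == youngest:
                    host = cand_og
                    break
        if host is None:
            return
        self.add_collision_protein(host, species, arch)

    def plant_expansion(self) -> dict | None:
        if self.cfg.expansion_node is None:
            return None
        node = self.cfg.expansion_node
        factor = self.cfg.expansion_factor
        acc = "IPR999999"
        # baseline: exactly one span per species of the whole ingroup
        base_birth = self.path_labels[1] if len(self.path_labels) > 1 else "root"
        self.domain_birth[acc] = base_birth
        base_og = self.add_orthogroup(base_birth, (acc,), "expansion", dup_mean=1.0, no_loss=True)
        # expansion: factor-1 extra single-span proteins per clade species
        exp_og = self.new_og_id()
        self.og_birth[exp_og] = node
        self.og_arch[exp_og] = (acc,)
        self.og_kind[exp_og] = "expansion"
        members: dict[str, list[str]] = {}
        extra = int(round(factor)) - 1
        for sp in sorted(self.tree.clade_species(node)):
            prots = []
            for k in range(extra):
                pid = f"{sp}_{exp_og}_{k}"
                prots.append(pid)
                self.protein_arch[pid] = (acc,)
                self.protein_species[pid] = sp
            members[sp] = prots
        self.og_members[exp_og] = members
        return {"domain": acc, "node": node, "factor": factor, "baseline_og": base_og, "og": exp_og}

    # -- domain hits ----------------------------------------------------

    def make_hits(self) -> list[DomainHit]:
        hits: list[DomainHit] = []
        for pid in sorted(self.protein_arch):
            arch = self.protein_arch[pid]
            pos = 1 + int(self.rng.integers(0, 20))
            for acc in arch:
                length = int(self.rng.integers(40, 121))
                start, end = pos, pos + length - 1
                hits.append(DomainHit(pid, acc, start, end, "SIM"))
                if self.rng.random() < self.cfg.redundant_hit_rate:
                    # jittered duplicate strictly inside the true span
                    a = int(self.rng.integers(0, 4))
                    b = int(self.rng.integers(0, 4))
                    if start + a <= end - b:
                        hits.append(DomainHit(pid, acc, start + a, end - b, "SIM2"))
                pos = end + 1 + int(self.rng.integers(8, 31))
        return hits

    # -- GO evidence ----------------------------------------------------

    def make_go(self) -> tuple[dict, dict, dict, dict, str]:
        """Plant approach-1/approach-2 labels, apply flip noise, emit tables.

        Returns (og_flags, ref_tables, og_go_annotations, ontology_terms,
        obo_text); og_flags records planted and realized labels per
        orthogroup.
        """
        cfg = self.cfg
        seeds = _load_seed_terms()
        seed_children = {s: [f"GO:71{i:02d}{j:03d}" for j in range(3)] for i, s in enumerate(sorted(seeds))}
        nonstress = [f"GO:60000{j:02d}" for j in range(1, 41)]
        closure_terms = sorted(set(seeds) | {c for cs in seed_children.values() for c in cs})

        ref_a, ref_b = cfg.ref_species
        main_ogs = sorted(og for og, k in self.og_kind.items() if k == "main")
        eligible = [
            og
            for og in main_ogs
            if self.og_members[og].get(ref_a) and self.og_members[og].get(ref_b)
        ]
        n_stress = min(int(round(cfg.stress_fraction * len(main_ogs))), len(eligible))
        stress = set(
            np.array(eligible)[
                self.rng.choice(len(eligible), size=n_stress, replace=False)
            ].tolist()
            if n_stress
            else []
        )
        remaining_eligible = [og for og in eligible if og not in stress]
        n_a1_only = min(
            int(round(cfg.a1_only_fraction * len(main_ogs))), len(remaining_eligible)
        )
        a1_only = set(
            np.array(remaining_eligible)[
                self.rng.choice(len(remaining_eligible), size=n_a1_only, replace=False)
            ].tolist()
            if n_a1_only
            else []
        )
        rest = [og for og in main_ogs if og not in stress and og not in a1_only]
        n_a2_only = min(int(round(cfg.a2_only_fraction * len(main_ogs))), len(rest))
        a2_only = set(
            np.array(rest)[
                self.rng.choice(len(rest), size=n_a2_only, replace=False)
            ].tolist()
            if n_a2_only
            else []
        )

        all_ogs = sorted(self.og_members)
        og_flags: dict[str, dict] = {}
        ref_tables: dict[str, dict[str, set[str]]] = {ref_a: {}, ref_b: {}}
        og_go: dict[str, set[str]] = {}
        for og in all_ogs:
            a1_planted = og in stress or og in a1_only
            a2_planted = og in stress or og in a2_only
            flippable = bool(
                self.og_members[og].get(ref_a) and self.og_members[og].get(ref_b)
            )
            a1 = a1_planted
            if cfg.noise_a1 > 0 and self.rng.random() < cfg.noise_a1:
                a1 = not a1
            if a1 and not flippable:
                a1 = False
            a2 = a2_planted
            if cfg.noise_a2 > 0 and self.rng.random() < cfg.noise_a2:
                a2 = not a2
            og_flags[og] = {
                "a1_planted": a1_planted,
                "a2_planted": a2_planted,
                "a1_flippable": flippable,
                "a1": a1,
                "a2": a2,
                "stress": a1 and a2,
            }
            # approach 1 realization: one stress-term protein per reference
            term_pool = closure_terms
            if a1:
                for ref in (ref_a, ref_b):
                    pid = self.og_members[og][ref][0]
                    term = term_pool[int(self.rng.integers(len(term_pool)))]
                    ref_tables[ref].setdefault(pid, set()).add(term)
            elif flippable:
                # annotate with non-stress terms; occasionally one reference
                # (never both) gets a stress term, exercising the conjunction
                lucky = (
                    (ref_a,)
                    if self.rng.random() < 0.3
                    else ()
                )
                for ref in (ref_a, ref_b):
                    pid = self.og_members[og][ref][0]
                    if ref in lucky:
                        term = term_pool[int(self.rng.integers(len(term_pool)))]
                    else:
                        term = nonstress[int(self.rng.integers(len(nonstress)))]
                    ref_tables[ref].setdefault(pid, set()).add(term)
            # approach 2 realization: orthogroup-level de novo annotation
            terms: set[str] = set()
            if a2:
                terms.add(term_pool[int(self.rng.integers(len(term_pool)))])
            terms.add(nonstress[int(self.rng.integers(len(nonstress)))])
            og_go[og] = terms

        obo = _build_obo(seeds, seed_children, nonstress)
        return og_flags, ref_tables, og_go, {"closure": closure_terms}, obo


def _load_seed_terms() -> list[str]:
    from lgptrace.stress_annotation import load_default_seed_terms

    return sorted(load_default_seed_terms())


def _build_obo(
    seeds: list[str], seed_children: dict[str, list[str]], nonstress: list[str]
) -> str:
    """Minimal OBO: one root, the seed terms, their children, a non-stress arm."""
    lines = ["format-version: 1.2", "ontology: go", ""]

    def stanza(term: str, name: str, parents: list[str], part_of: list[str] = ()):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {name}")
        for p in parents:
            lines.append(f"is_a: {p}")
        for p in part_of:
            lines.append(f"relationship: part_of {p}")
        lines.append("")

    stanza("GO:0008150", "biological_process", [])
    for i, s in enumerate(sorted(seeds)):
        stanza(s, f"stress process {i}", ["GO:0008150"])
        children = seed_children[s]
        for j, c in enumerate(children):
            if j == len(children) - 1:
                # last child attached by part_of to exercise both relations
                stanza(c, f"stress child {i}.{j}", [], part_of=[s])
            else:
                stanza(c, f"stress child {i}.{j}", [s])
    for j, t in enumerate(nonstress):
        stanza(t, f"housekeeping process {j}", ["GO:0008150"])
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Truth derivation (independent brute-force loops over the materialized data)
# ---------------------------------------------------------------------------


def _derive_truth(sim: _Sim, og_flags: dict, expansion: dict | None, n_raw_hits: int) -> SimTruth:
    tree = sim.tree
    lineages = sim.lineages
    bry = {sp for sp, l in lineages.items() if l == "bryophyte"}
    tra = {sp for sp, l in lineages.items() if l == "tracheophyte"}

    # carrier sets per domain, from protein architectures
    domain_carriers: dict[str, set[str]] = {}
    domain_proteins: dict[str, set[str]] = {}
    for pid, arch in sim.protein_arch.items():
        sp = sim.protein_species[pid]
        for acc in arch:
            domain_carriers.setdefault(acc, set()).add(sp)
            domain_proteins.setdefault(acc, set()).add(pid)

    # merged span counts per (domain, species): redundant duplicates lie
    # inside the true span, so merged counts equal architecture token counts
    span_counts: dict[str, dict[str, int]] = {}
    for pid, arch in sim.protein_arch.items():
        sp = sim.protein_species[pid]
        for acc in arch:
            span_counts.setdefault(acc, {}).setdefault(sp, 0)
            span_counts[acc][sp] += 1

    orthogroups: dict[str, dict] = {}
    for og in sorted(sim.og_members):
        members = sim.og_members[og]
        carriers = {sp for sp, prots in members.items() if prots}
        origin = tree.mrca(carriers).name if carriers else None
        n_value = tree.node(origin) if origin else None

        # embryophytic domain set
        dom_bry: set[str] = set()
        dom_tra: set[str] = set()
        for sp, prots in members.items():
            for pid in prots:
                if sp in bry:
                    dom_bry.update(sim.protein_arch[pid])
                elif sp in tra:
                    dom_tra.update(sim.protein_arch[pid])
        eset = dom_bry & dom_tra
        reps: set[tuple[str, ...]] = set()
        for sp, prots in members.items():
            if sp in bry or sp in tra:
                for pid in prots:
                    proj = tuple(d for d in sim.protein_arch[pid] if d in eset)
                    if proj:
                        reps.add(proj)

        lgp_any = False
        lgp_all = False
        if eset and origin is not None:
            clade = tree.clade_species(n_value)
            outgroup = tree.leaf_set - clade
            age_any = all(domain_carriers.get(d, set()) & outgroup for d in eset)
            sisters = []
            child, anc = n_value, n_value.parent
            while anc is not None and anc.parent is not None:
                sis: set[str] = set()
                for c in anc.children:
                    if c is not child:
                        sis |= set(c.leafset)
                sisters.append(sis)
                child, anc = anc, anc.parent
            age_all = bool(sisters) and all(
                all(domain_carriers.get(d, set()) & s for s in sisters) for d in eset
            )
            cand = set()
            for d in eset:
                cand |= domain_proteins.get(d, set())
            novel = True
            for pid in cand:
                if sim.protein_species[pid] in clade:
                    continue
                proj = tuple(d for d in sim.protein_arch[pid] if d in eset)
                if proj and proj in reps:
                    novel = False
                    break
            lgp_any = age_any and novel
            lgp_all = age_all and novel

        flags = og_flags.get(og, {})
        orthogroups[og] = {
            "birth": sim.og_birth[og],
            "origin": origin,
            "kind": sim.og_kind[og],
            "architecture": list(sim.og_arch[og]),
            "members": {sp: sorted(p) for sp, p in members.items() if p},
            "embryophytic_set": sorted(eset),
            "lgp_any_outgroup": lgp_any,
            "lgp_all_previous": lgp_all,
            **flags,
        }

    return SimTruth(
        focal_label=tree.focal_label,
        species_lineages=dict(sorted(lineages.items())),
        domain_birth=dict(sorted(sim.domain_birth.items())),
        orthogroups=orthogroups,
        span_counts={a: dict(sorted(c.items())) for a, c in sorted(span_counts.items())},
        n_raw_hits=n_raw_hits,
        noise={"a1": sim.cfg.noise_a1, "a2": sim.cfg.noise_a2},
        expansion=expansion,
    )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _write_bundle(
    out_dir: Path,
    tree: SpeciesTree,
    lineages: dict[str, str],
    og_members: dict[str, dict[str, list[str]]],
    hits: list[DomainHit],
    ref_tables: dict[str, dict[str, set[str]]],
    og_go: dict[str, set[str]],
    obo_text: str,
    truth: SimTruth,
) -> SimBundle:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = sorted(lineages)
    table = OrthogroupTable(
        species=tuple(species),
        members={
            og: {sp: tuple(sorted(row.get(sp, ()))) for sp in species}
            for og, row in og_members.items()
        },
    )
    paths = SimBundle(
        directory=out_dir,
        orthogroups=out_dir / "Orthogroups.tsv",
        domains=out_dir / "domains.tsv",
        obo=out_dir / "ontology.obo",
        tree=out_dir / "tree.nwk",
        lineages=out_dir / "lineages.tsv",
        og_go=out_dir / "og_go.tsv",
        ref_go={sp: out_dir / f"ref_go_{sp}.tsv" for sp in sorted(ref_tables)},
        truth_json=out_dir / "truth.json",
        truth=truth,
    )
    write_orthogroups(table, paths.orthogroups)
    write_interproscan_tsv(hits, paths.domains)
    with open(paths.obo, "wt", encoding="utf-8") as fh:
        fh.write(obo_text)
    with open(paths.tree, "wt", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
    write_lineage_map(LineageMap(lineages=lineages), paths.lineages)
    write_go_table(
        GoAnnotationTable(
            subject_kind="orthogroup",
            annotations={og: frozenset(t) for og, t in og_go.items()},
        ),
        paths.og_go,
    )
    for sp, table_path in paths.ref_go.items():
        write_go_table(
            GoAnnotationTable(
                subject_kind="protein",
                annotations={p: frozenset(t) for p, t in ref_tables[sp].items()},
            ),
            table_path,
        )
    truth.to_json(paths.truth_json)
    return paths


def simulate(config: SimConfig, out_dir) -> SimBundle:
    """Generate a complete input bundle with planted truth under ``out_dir``.

    Files: ``Orthogroups.tsv``, ``domains.tsv`` (InterProScan dialect),
    ``ontology.obo``, ``tree.nwk``, ``lineages.tsv``, ``og_go.tsv``,
    ``ref_go_<species>.tsv`` per reference species, ``truth.json``.
    A fixed seed yields byte-identical bundles.
    """
    sim = _Sim(config)
    if sim.lineages is None:
        raise ValueError("custom trees need a lineage map; use tree='paper37'")
    sim.make_domains()
    sim.make_orthogroups()
    expansion = sim.plant_expansion()
    hits = sim.make_hits()
    og_flags, ref_tables, og_go, _, obo_text = sim.make_go()
    truth = _derive_truth(sim, og_flags, expansion, n_raw_hits=len(hits))
    return _write_bundle(
        Path(out_dir),
        sim.tree,
        sim.lineages,
        sim.og_members,
        hits,
        ref_tables,
        og_go,
        obo_text,
        truth,
    )


# ---------------------------------------------------------------------------
# Hand-sized worked case
# ---------------------------------------------------------------------------

_MICRO_NEWICK = (
    "(chl1,(cha1,(zyg1,(bry1,(tra1,tra2)tracheophytes)land_plants)"
    "zygnematophyceae_land_plants)streptophytes)root;"
)

_MICRO_LINEAGES = {
    "chl1": "chlorophyte",
    "cha1": "charophyceae",
    "zyg1": "zygnematophyceae",
    "bry1": "bryophyte",
    "tra1": "tracheophyte",
    "tra2": "tracheophyte",
}


def make_worked_micro_case(out_dir) -> SimBundle:
    """A fixed six-species bundle with three decisive orthogroups.

    * ``OG0000001`` — a Remorin-like case: embryophyte-only orthogroup whose
      two domains each occur separately in the algae (charophyte and
      zygnematophyte) but never together on one algal protein → LGP true.
    * ``OG0000002`` — a genuinely new domain: one of its domains occurs
      nowhere outside land plants → LGP false (de novo novelty, not
      recombination).
    * ``OG0000003`` — an architecture collision: both domains are old *and*
      one charophyte protein already carries them in the same order → LGP
      false (the combination is not new).

    Single-domain background orthogroups anchor the old domains in the
    algae.  Only ``OG0000001`` is stress-annotated, so the focal-node tally
    is x/y = 1/1.
    """
    tree = SpeciesTree.from_newick(_MICRO_NEWICK)
    d1, d2, d3, d4, d5, d6 = (f"IPR90000{i}" for i in range(1, 7))

    og_members: dict[str, dict[str, list[str]]] = {}
    protein_arch: dict[str, tuple[str, ...]] = {}
    protein_species: dict[str, str] = {}

    def add(og: str, sp: str, arch: tuple[str, ...], idx: int = 0) -> str:
        pid = f"{sp}_{og}_{idx}"
        og_members.setdefault(og, {}).setdefault(sp, []).append(pid)
        protein_arch[pid] = arch
        protein_species[pid] = sp
        return pid

    # main cases
    rem_b = add("OG0000001", "bry1", (d1, d2))
    rem_t = add("OG0000001", "tra1", (d1, d2))
    add("OG0000002", "bry1", (d3, d4))
    add("OG0000002", "tra2", (d3, d4))
    add("OG0000003", "bry1", (d5, d6))
    add("OG0000003", "tra1", (d5, d6))
    # background anchors in the algae (one domain per protein)
    for og, dom in (
        ("OG0000004", d1),
        ("OG0000005", d2),
        ("OG0000006", d3),
        ("OG0000007", d5),
        ("OG0000008", d6),
    ):
        add(og, "cha1", (dom,))
        add(og, "zyg1", (dom,))
    # the collision: one charophyte protein with both OG0000003 domains in order
    add("OG0000007", "cha1", (d5, d6), idx=1)

    # lay out hits; one redundant overlapping duplicate exercises merging
    hits: list[DomainHit] = []
    for pid in sorted(protein_arch):
        pos = 10
        for acc in protein_arch[pid]:
            hits.append(DomainHit(pid, acc, pos, pos + 70, "MICRO"))
            pos += 90
    hits.append(DomainHit(rem_b, d1, 15, 70, "MICRO2"))  # inside the d1 span

    seed = "GO:0006952"
    child = "GO:7100001"
    nonstress = "GO:6000001"
    seeds = _load_seed_terms()
    seed_children = {s: [] for s in seeds}
    seed_children[seed] = [child, "GO:7100002"]
    obo_text = _build_obo(seeds, seed_children, [nonstress])
    ref_tables = {
        "tra1": {rem_t: {child}, f"tra1_OG0000003_0": {nonstress}},
        "bry1": {rem_b: {seed}, f"bry1_OG0000002_0": {nonstress}},
    }
    og_go = {
        "OG0000001": {child, nonstress},
        "OG0000002": {nonstress},
        "OG0000003": {nonstress},
    }
    og_flags = {
        og: {
            "a1_planted": og == "OG0000001",
            "a2_planted": og == "OG0000001",
            "a1_flippable": og == "OG0000001",
            "a1": og == "OG0000001",
            "a2": og == "OG0000001",
            "stress": og == "OG0000001",
        }
        for og in og_members
    }

    class _Shim:
        pass

    shim = _Shim()
    shim.tree = tree
    shim.lineages = _MICRO_LINEAGES
    shim.protein_arch = protein_arch
    shim.protein_species = protein_species
    shim.og_members = og_members
    shim.og_birth = {og: tree.mrca({sp for sp, p in row.items() if p}).name for og, row in og_members.items()}
    shim.og_kind = {
        og: ("main" if og in ("OG0000001", "OG0000002", "OG0000003") else "background")
        for og in og_members
    }
    shim.og_arch = {
        "OG0000001": (d1, d2),
        "OG0000002": (d3, d4),
        "OG0000003": (d5, d6),
        "OG0000004": (d1,),
        "OG0000005": (d2,),
        "OG0000006": (d3,),
        "OG0000007": (d5,),
        "OG0000008": (d6,),
    }
    shim.cfg = SimConfig(seed=0)
    shim.domain_birth = {
        d1: "streptophytes",
        d2: "streptophytes",
        d3: "streptophytes",
        d4: "land_plants",
        d5: "streptophytes",
        d6: "streptophytes",
    }
    truth = _derive_truth(shim, og_flags, None, n_raw_hits=len(hits))
    return _write_bundle(
        Path(out_dir),
        tree,
        _MICRO_LINEAGES,
        og_members,
        hits,
        ref_tables,
        og_go,
        obo_text,
        truth,
    )
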