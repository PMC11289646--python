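"""End-to-end orchestration: stress calls → architectures → origins → bursts → LGP.

Each stage reads validated inputs (and the persisted TSV intermediates of
earlier stages), computes, and writes its own sorted TSV outputs plus a
machine-readable JSON report, so any stage can be re-run in isolation and a
full run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from lgptrace import __version__
from lgptrace.bursts import DEFAULT_BURST_THRESHOLD, fold_changes, top_k_report
from lgptrace.domain_architecture import (
    MergedDomainSpan,
    build_architectures,
    count_matrix,
    merge_all_hits,
)
from lgptrace.io_formats import (
    read_go_table,
    read_interproscan_tsv,
    read_lineage_map,
    read_newick_tree,
    read_obo,
    read_orthogroups,
)
from lgptrace.lgp import (
    DEFAULT_AGE_MODE,
    classify_all,
    domain_completion,
    embryophytic_domain_set,
    go_term_counts,
    node_tallies,
)
from lgptrace.phylostratigraphy import (
    assign_origins,
    domain_profiles,
    orthogroup_profiles,
)
from lgptrace.stress_annotation import (
    approach1_calls,
    approach2_calls,
    call_summary,
    go_descendant_closure,
    intersect_calls,
    load_default_seed_terms,
    reference_stress_proteins,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and knobs of one pipeline run."""

    orthogroups: Path
    domains: Path
    obo: Path
    tree: Path
    lineages: Path
    og_go: Path
    ref_go: dict[str, Path]
    out_dir: Path
    focal_node: str = "land_plants"
    seed_terms: Path | None = None
    closure_relations: tuple[str, ...] = ("is_a", "part_of")
    accession_policy: str = "interpro_only"
    merge_mode: str = "overlap"
    age_mode: str = DEFAULT_AGE_MODE
    burst_scope: str = "stress"
    burst_threshold: float = DEFAULT_BURST_THRESHOLD
    top_k: int = 10

    def __post_init__(self) -> None:
        for name in ("orthogroups", "domains", "obo", "tree", "lineages", "og_go"):
            setattr(self, name, Path(getattr(self, name)))
        self.ref_go = {sp: Path(p) for sp, p in self.ref_go.items()}
        self.out_dir = Path(self.out_dir)
        for name in ("orthogroups", "domains", "obo", "tree", "lineages", "og_go"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        for sp, p in self.ref_go.items():
            if not p.exists():
                raise FileNotFoundError(f"reference GO table for {sp} not found: {p}")

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir, **kwargs) -> "PipelineConfig":
        """Configure from a directory using the generator's file names."""
        bundle_dir = Path(bundle_dir)
        ref_go = {
            p.stem.removeprefix("ref_go_"): p
            for p in sorted(bundle_dir.glob("ref_go_*.tsv"))
        }
        return cls(
            orthogroups=bundle_dir / "Orthogroups.tsv",
            domains=bundle_dir / "domains.tsv",
            obo=bundle_dir / "ontology.obo",
            tree=bundle_dir / "tree.nwk",
            lineages=bundle_dir / "lineages.tsv",
            og_go=bundle_dir / "og_go.tsv",
            ref_go=ref_go,
            out_dir=out_dir,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if "closure_relations" in raw:
            raw["closure_relations"] = tuple(raw["closure_relations"])
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        payload = {k: str(v) for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _b(flag: bool) -> str:
    return "1" if flag else "0"


@dataclass
class _State:
    """Loaded inputs shared by the stages of one run."""

    config: PipelineConfig
    ogs: object = None
    tree: object = None
    lineage_map: object = None
    dag: object = None
    og_go: object = None

    def load(self) -> "_State":
        cfg = self.config
        self.ogs = read_orthogroups(cfg.orthogroups)
        self.tree = read_newick_tree(cfg.tree, focal_label=cfg.focal_node)
        self.lineage_map = read_lineage_map(cfg.lineages)
        self.lineage_map.validate_covers(self.ogs.species)
        self.dag = read_obo(cfg.obo)
        self.og_go = read_go_table(cfg.og_go, subject_kind="orthogroup")
        return self


def _load_seeds(config: PipelineConfig) -> frozenset[str]:
    if config.seed_terms is None:
        return load_default_seed_terms()
    with open(config.seed_terms, "rt", encoding="utf-8") as fh:
        return frozenset(
            ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_annotate(state: _State) -> dict:
    """Dual-evidence stress calls; writes ``stress_calls.tsv``."""
    cfg = state.config
    seeds = _load_seeds(cfg)
    closure = go_descendant_closure(
        state.dag, seeds, relations=frozenset(cfg.closure_relations)
    )
    ref_sets = {}
    for sp, path in cfg.ref_go.items():
        table = read_go_table(path, subject_kind="protein")
        ref_sets[sp] = reference_stress_proteins(table, closure)
    a1 = approach1_calls(state.ogs, ref_sets)
    a2 = approach2_calls(state.og_go, closure, universe=list(state.ogs.members))
    calls = intersect_calls(a1, a2, og_go=state.og_go, closure=closure)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    with open(cfg.out_dir / "stress_calls.tsv", "wt", encoding="utf-8") as fh:
        fh.write("orthogroup\tapproach1\tapproach2\tstress\n")
        for c in calls:
            fh.write(
                f"{c.orthogroup_id}\t{_b(c.approach1)}\t{_b(c.approach2)}\t{_b(c.stress)}\n"
            )
    return call_summary(calls)


def read_stress_calls(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "stress_calls.tsv", sep="\t", dtype={"orthogroup": str})


def stress_set(out_dir) -> frozenset[str]:
    df = read_stress_calls(out_dir)
    return frozenset(df.loc[df["stress"] == 1, "orthogroup"])


def stage_architectures(state: _State) -> dict:
    """Merge hits, derive architectures and count matrices.

    Writes ``spans.tsv``, ``architectures.tsv`` and the all-scope and
    stress-scope domain × species count matrices.
    """
    cfg = state.config
    hits = read_interproscan_tsv(cfg.domains, accession_policy=cfg.accession_policy)
    spans = merge_all_hits(hits, mode=cfg.merge_mode)
    archs = build_architectures(spans)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    with open(cfg.out_dir / "spans.tsv", "wt", encoding="utf-8") as fh:
        fh.write("protein\tdomain\tstart\tend\n")
        for s in spans:
            fh.write(f"{s.protein_id}\t{s.domain_acc}\t{s.start}\t{s.end}\n")
    with open(cfg.out_dir / "architectures.tsv", "wt", encoding="utf-8") as fh:
        fh.write("protein\tarchitecture\n")
        for pid in sorted(archs):
            fh.write(f"{pid}\t{';'.join(archs[pid].order)}\n")
    counts_all = count_matrix(spans, state.ogs)
    counts_all.by_species.to_csv(
        cfg.out_dir / "counts_domain_species.tsv", sep="\t", index_label="domain"
    )
    stress = stress_set(cfg.out_dir)
    counts_stress = count_matrix(spans, state.ogs, scope_orthogroups=stress)
    counts_stress.by_species.to_csv(
        cfg.out_dir / "counts_domain_species_stress.tsv", sep="\t", index_label="domain"
    )
    return {
        "n_raw_hits": len(hits),
        "n_merged_spans": len(spans),
        "n_proteins_with_domains": len(archs),
        "n_domains_all": int(counts_all.by_species.shape[0]),
        "n_domains_stress": int(counts_stress.by_species.shape[0]),
    }


def read_spans(out_dir) -> list[MergedDomainSpan]:
    df = pd.read_csv(Path(out_dir) / "spans.tsv", sep="\t", dtype={"protein": str, "domain": str})
    return [
        MergedDomainSpan(r.protein, r.domain, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def stage_origins(state: _State) -> dict:
    """Parsimony origins of orthogroups and domains; writes origins/profiles."""
    cfg = state.config
    spans = read_spans(cfg.out_dir)
    og_profiles = orthogroup_profiles(state.ogs, state.tree)
    dom_profiles = domain_profiles(spans, state.ogs, state.tree)
    og_origins = assign_origins(og_profiles, state.tree)
    dom_origins = assign_origins(dom_profiles, state.tree)
    with open(cfg.out_dir / "origins.tsv", "wt", encoding="utf-8") as fh:
        fh.write("entity\tkind\torigin\tn_carriers\n")
        for oid in sorted(og_origins):
            o = og_origins[oid]
            fh.write(f"{oid}\torthogroup\t{o.origin_node.name}\t{o.n_carriers}\n")
        for acc in sorted(dom_origins):
            o = dom_origins[acc]
            fh.write(f"{acc}\tdomain\t{o.origin_node.name}\t{o.n_carriers}\n")
    species = list(state.ogs.species)
    with open(cfg.out_dir / "profiles.tsv", "wt", encoding="utf-8") as fh:
        fh.write("entity\tkind\t" + "\t".join(species) + "\n")
        for p in og_profiles:
            row = "\t".join(_b(sp in p.carrier_species) for sp in species)
            fh.write(f"{p.entity_id}\torthogroup\t{row}\n")
        for p in dom_profiles:
            row = "\t".join(_b(sp in p.carrier_species) for sp in species)
            fh.write(f"{p.entity_id}\tdomain\t{row}\n")
    per_node: dict[str, int] = {}
    for o in og_origins.values():
        per_node[o.origin_node.name] = per_node.get(o.origin_node.name, 0) + 1
    return {
        "n_orthogroups_with_origin": len(og_origins),
        "n_domains_with_origin": len(dom_origins),
        "orthogroup_origins_per_node": dict(sorted(per_node.items())),
    }


def stage_bursts(state: _State) -> dict:
    """Adjacent-LCA fold changes along the backbone; writes fold_changes/bursts."""
    cfg = state.config
    spans = read_spans(cfg.out_dir)
    scope = stress_set(cfg.out_dir) if cfg.burst_scope == "stress" else None
    counts = count_matrix(spans, state.ogs, scope_orthogroups=scope)
    records = fold_changes(counts, state.tree)
    report = top_k_report(records, k=cfg.top_k, threshold=cfg.burst_threshold)
    with open(cfg.out_dir / "fold_changes.tsv", "wt", encoding="utf-8") as fh:
        fh.write("domain\tnode\tmean_in\tmean_sister\tfold_change\tstatus\n")
        for r in sorted(records, key=lambda r: (r.node, r.domain_acc)):
            fc = _fmt(r.fold_change) if r.fold_change is not None else ""
            fh.write(
                f"{r.domain_acc}\t{r.node}\t{_fmt(r.mean_in)}\t{_fmt(r.mean_sister)}\t{fc}\t{r.status}\n"
            )
    with open(cfg.out_dir / "bursts.tsv", "wt", encoding="utf-8") as fh:
        fh.write("node\trank\tdomain\tfold_change\n")
        for node in sorted(report.top_k):
            for rank, r in enumerate(report.top_k[node], start=1):
                fh.write(f"{node}\t{rank}\t{r.domain_acc}\t{_fmt(r.fold_change)}\n")
    return {
        "n_fold_change_records": len(records),
        "bursts_per_node": {n: len(v) for n, v in sorted(report.bursts.items())},
    }


def stage_lgp(state: _State) -> dict:
    """Embryophytic domain sets, LGP classification and per-node tallies."""
    cfg = state.config
    spans = read_spans(cfg.out_dir)
    archs = build_architectures(spans)
    stress = stress_set(cfg.out_dir)
    og_origins = assign_origins(orthogroup_profiles(state.ogs, state.tree), state.tree)
    dom_profiles = domain_profiles(spans, state.ogs, state.tree)
    domain_carriers = {p.entity_id: p.carrier_species for p in dom_profiles}
    records = classify_all(
        state.ogs,
        og_origins,
        domain_carriers,
        archs,
        state.lineage_map,
        state.tree,
        stress_ogs=stress,
        age_mode=cfg.age_mode,
    )
    with open(cfg.out_dir / "lgp.tsv", "wt", encoding="utf-8") as fh:
        fh.write(
            "orthogroup\tnode\torigin\teligible\tdomain_age_ok\tarchitecture_novel\tlgp\tstress\n"
        )
        for r in records:
            fh.write(
                f"{r.orthogroup_id}\t{r.node}\t{r.og_origin}\t{_b(r.eligible)}\t"
                f"{_b(r.domain_age_ok)}\t{_b(r.architecture_novel)}\t{_b(r.lgp)}\t{_b(r.stress)}\n"
            )
    path = state.tree.path_to_focal()
    tallies = node_tallies(records, path)
    with open(cfg.out_dir / "node_tallies.tsv", "wt", encoding="utf-8") as fh:
        fh.write("node\tx\ty\tn_origin_stress\tn_origin_total\n")
        for t in tallies:
            fh.write(f"{t.node}\t{t.x}\t{t.y}\t{t.n_origin_stress}\t{t.n_origin_total}\n")

    focal = state.tree.focal.name
    focal_lgp = sorted(r.orthogroup_id for r in records if r.lgp and r.node == focal)
    species = list(state.ogs.species)
    with open(cfg.out_dir / "fig3a_matrix.tsv", "wt", encoding="utf-8") as fh:
        fh.write("orthogroup\tspecies\tn_proteins\tcomplete\n")
        for og_id in focal_lgp:
            eset = embryophytic_domain_set(og_id, state.ogs, archs, state.lineage_map)
            completion = domain_completion(eset, domain_carriers, species)
            row = state.ogs.members[og_id]
            for sp in species:
                fh.write(f"{og_id}\t{sp}\t{len(row[sp])}\t{_b(completion[sp])}\n")
    with open(cfg.out_dir / "go_wordcounts.tsv", "wt", encoding="utf-8") as fh:
        fh.write("go_term\tcount\n")
        for term, count in go_term_counts(focal_lgp, state.og_go):
            fh.write(f"{term}\t{count}\n")

    x_focal = sum(1 for r in records if r.lgp and r.stress and r.node == focal)
    return {
        "n_lgp_records": len(records),
        "node_tallies": {
            t.node: {
                "x": t.x,
                "y": t.y,
                "n_origin_stress": t.n_origin_stress,
                "n_origin_total": t.n_origin_total,
            }
            for t in tallies
        },
        "focal_node": focal,
        "focal_lgp_total": len(focal_lgp),
        "focal_lgp_stress": x_focal,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write ``report.json``.

    Returns the report dict: per-stage record counts plus version and a
    configuration hash.  Idempotent for fixed inputs — outputs are fully
    sorted and contain no timestamps.
    """
    state = _State(config).load()
    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_orthogroups": len(state.ogs.members),
        "n_species": len(state.ogs.species),
        "stress": stage_annotate(state),
        "architectures": stage_architectures(state),
        "origins": stage_origins(state),
        "bursts": stage_bursts(state),
        "lgp": stage_lgp(state),
    }
    s = report["stress"]
    if s["stress"] > min(s["approach1"], s["approach2"]):
        raise AssertionError("intersection exceeds a single approach — internal error")
    with open(config.out_dir / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
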