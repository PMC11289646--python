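"""Generator contracts: determinism, cross-reference integrity, truth
self-consistency (re-derived by an independent brute-force checker)."""

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pytest

from lgptrace.synthetic_data import SimConfig, make_worked_micro_case, simulate


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


BUNDLE_FILES = ("orthogroups", "domains", "obo", "tree", "lineages", "og_go", "truth_json")


class TestDeterminismAndIntegrity:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = dict(seed=5, n_orthogroups=80, n_domains=25)
        b1 = simulate(SimConfig(**cfg), tmp_path / "a")
        b2 = simulate(SimConfig(**cfg), tmp_path / "b")
        for name in BUNDLE_FILES:
            assert _sha(getattr(b1, name)) == _sha(getattr(b2, name)), name
        for sp in b1.ref_go:
            assert _sha(b1.ref_go[sp]) == _sha(b2.ref_go[sp])

    def test_different_seeds_differ(self, tmp_path):
        b1 = simulate(SimConfig(seed=5, n_orthogroups=80, n_domains=25), tmp_path / "a")
        b2 = simulate(SimConfig(seed=6, n_orthogroups=80, n_domains=25), tmp_path / "b")
        assert _sha(b1.orthogroups) != _sha(b2.orthogroups)

    def test_cross_references_resolve(self, sim_bundle):
        from lgptrace.io_formats import (
            read_go_table,
            read_interproscan_tsv,
            read_obo,
            read_orthogroups,
        )

        ogs = read_orthogroups(sim_bundle.orthogroups)
        hits = read_interproscan_tsv(sim_bundle.domains)
        dag = read_obo(sim_bundle.obo)
        # every protein with hits belongs to the table
        proteins = set(ogs.protein_species_map())
        assert {h.protein_id for h in hits} <= proteins
        # every annotated GO ID exists in the ontology
        og_go = read_go_table(sim_bundle.og_go, subject_kind="orthogroup")
        used = set().union(*og_go.annotations.values())
        for sp, path in sim_bundle.ref_go.items():
            table = read_go_table(path, subject_kind="protein")
            assert set(table.annotations) <= proteins
            used |= set().union(*table.annotations.values()) if table.annotations else set()
        assert used <= dag.terms

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p_lgp"):
            SimConfig(p_lgp=1.5)

    def test_mean_proteins_per_species_matches_config(self, tmp_path):
        cfg = SimConfig(seed=17, n_orthogroups=800, n_domains=50, dup_mean=1.5)
        bundle = simulate(cfg, tmp_path / "m")
        counts = []
        for info in bundle.truth.orthogroups.values():
            for prots in info["members"].values():
                counts.append(len(prots))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - cfg.dup_mean) <= 3 * max(se, 1e-9)

    def test_planted_stress_count_matches_fraction(self, tmp_path):
        cfg = SimConfig(seed=23, n_orthogroups=600, n_domains=40, stress_fraction=0.25)
        bundle = simulate(cfg, tmp_path / "s")
        main = [i for i in bundle.truth.orthogroups.values() if i["kind"] == "main"]
        planted = sum(1 for i in main if i["a1_planted"] and i["a2_planted"])
        assert planted == round(0.25 * len(main))


# ---------------------------------------------------------------------------
# Independent truth checker: plain loops over the emitted files only
# ---------------------------------------------------------------------------


def _check_truth_against_bundle(bundle):
    """Re-derive origins and LGP labels from the bundle files alone.

    Uses dendropy for the tree and naive per-residue interval handling, with
    no lgptrace analysis code, and compares with the truth JSON.
    """
    truth = json.loads(bundle.truth_json.read_text())
    dtree = dendropy.Tree.get(path=str(bundle.tree), schema="newick",
                              suppress_internal_node_taxa=True, preserve_underscores=True)
    name_of = {}
    parent = {}
    leaf_names = {}
    for nd in dtree.preorder_node_iter():
        name = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        name_of[id(nd)] = name
        for ch in nd.child_nodes():
            parent_name = name
            parent[ch] = nd
    def node_name(nd):
        return nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
    leaves_under = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            leaves_under[nd] = {node_name(nd)}
        else:
            acc = set()
            for ch in nd.child_nodes():
                acc |= leaves_under[ch]
            leaves_under[nd] = acc

    def mrca_name(species):
        nd = dtree.seed_node
        while True:
            nxt = [ch for ch in nd.child_nodes() if species <= leaves_under[ch]]
            if not nxt:
                return node_name(nd)
            nd = nxt[0]

    # membership from Orthogroups.tsv
    og_df = pd.read_csv(bundle.orthogroups, sep="\t", dtype=str).fillna("")
    species_cols = list(og_df.columns[1:])
    members = {}
    prot_species = {}
    for _, row in og_df.iterrows():
        og = row.iloc[0]
        members[og] = {}
        for sp in species_cols:
            prots = [p.strip() for p in row[sp].split(",") if p.strip()]
            members[og][sp] = prots
            for p in prots:
                prot_species[p] = sp

    # architectures from domains.tsv: merge per (protein, domain) by residues
    ipr = pd.read_csv(bundle.domains, sep="\t", header=None, dtype=str)
    raw = {}
    for _, r in ipr.iterrows():
        raw.setdefault((r[0], r[11]), []).append((int(r[6]), int(r[7])))
    spans_by_protein = {}
    for (pid, acc), ivs in raw.items():
        mask = set()
        for s, e in ivs:
            mask.update(range(s, e + 1))
        # contiguous runs of the residue set
        run = []
        start = None
        prev = None
        for pos in sorted(mask):
            if start is None:
                start = prev = pos
            elif pos == prev + 1:
                prev = pos
            else:
                run.append((start, prev))
                start = prev = pos
        run.append((start, prev))
        for s, e in run:
            spans_by_protein.setdefault(pid, []).append((s, e, acc))
    arch = {
        pid: tuple(a for _, _, a in sorted(sp))
        for pid, sp in spans_by_protein.items()
    }

    lineages = dict(
        ln.split("\t") for ln in bundle.lineages.read_text().splitlines() if ln
    )
    bry = {s for s, l in lineages.items() if l == "bryophyte"}
    tra = {s for s, l in lineages.items() if l == "tracheophyte"}

    domain_carriers = {}
    domain_proteins = {}
    for pid, a in arch.items():
        for acc in a:
            domain_carriers.setdefault(acc, set()).add(prot_species[pid])
            domain_proteins.setdefault(acc, set()).add(pid)

    mismatches = []
    for og, info in truth["orthogroups"].items():
        carriers = {sp for sp, ps in members[og].items() if ps}
        if mrca_name(carriers) != info["origin"]:
            mismatches.append((og, "origin"))
            continue
        dom_b = set().union(*(arch.get(p, ()) for sp in bry for p in members[og][sp])) if bry else set()
        dom_b = set()
        dom_t = set()
        for sp, ps in members[og].items():
            for p in ps:
                if sp in bry:
                    dom_b.update(arch.get(p, ()))
                elif sp in tra:
                    dom_t.update(arch.get(p, ()))
        eset = dom_b & dom_t
        if sorted(eset) != info["embryophytic_set"]:
            mismatches.append((og, "eset"))
            continue
        # LGP any-outgroup label
        lgp_any = False
        if eset:
            nd = dtree.seed_node
            while True:
                nxt = [ch for ch in nd.child_nodes() if carriers <= leaves_under[ch]]
                if not nxt:
                    break
                nd = nxt[0]
            clade = leaves_under[nd]
            outgroup = leaves_under[dtree.seed_node] - clade
            age = all(domain_carriers.get(d, set()) & outgroup for d in eset)
            reps = set()
            for sp, ps in members[og].items():
                if sp in bry or sp in tra:
                    for p in ps:
                        proj = tuple(d for d in arch.get(p, ()) if d in eset)
                        if proj:
                            reps.add(proj)
            novel = True
            for d in eset:
                for p in domain_proteins.get(d, ()):  # only carriers can match
                    if prot_species[p] in clade:
                        continue
                    proj = tuple(x for x in arch[p] if x in eset)
                    if proj and proj in reps:
                        novel = False
            lgp_any = age and novel
        if lgp_any != info["lgp_any_outgroup"]:
            mismatches.append((og, "lgp"))
    return mismatches


class TestTruthSelfConsistency:
    def test_independent_checker_agrees_with_truth(self, tmp_path):
        bundle = simulate(
            SimConfig(seed=13, n_orthogroups=120, n_domains=30), tmp_path / "b"
        )
        assert _check_truth_against_bundle(bundle) == []

    def test_micro_case_truth_agrees(self, micro_bundle):
        assert _check_truth_against_bundle(micro_bundle) == []


class TestMicroCase:
    def test_three_planted_verdicts(self, micro_bundle):
        truth = micro_bundle.truth.orthogroups
        assert truth["OG0000001"]["lgp_all_previous"] and truth["OG0000001"]["lgp_any_outgroup"]
        assert not truth["OG0000002"]["lgp_any_outgroup"]  # genuinely new domain
        assert not truth["OG0000003"]["lgp_any_outgroup"]  # architecture collision
        assert truth["OG0000001"]["stress"]
        assert not truth["OG0000002"]["stress"] and not truth["OG0000003"]["stress"]

    def test_micro_bundle_is_fixed(self, micro_bundle, tmp_path):
        again = make_worked_micro_case(tmp_path / "again")
        for name in BUNDLE_FILES:
            assert _sha(getattr(micro_bundle, name)) == _sha(getattr(again, name))
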