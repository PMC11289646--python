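"""GO closure and the dual-evidence stress-annotation rules."""

import networkx as nx
import numpy as np
import pytest

from lgptrace.io_formats import GoAnnotationTable, GoDag, OrthogroupTable
from lgptrace.stress_annotation import (
    approach1_calls,
    approach2_calls,
    call_summary,
    go_descendant_closure,
    intersect_calls,
    load_default_seed_terms,
    reference_stress_proteins,
)


def _dag(edges):
    g = nx.MultiDiGraph()
    for child, parent, rel in edges:
        g.add_edge(child, parent, key=rel)
    return GoDag(graph=g)


def _go(i: int) -> str:
    return f"GO:{i:07d}"


def _random_dag(rng, n_terms: int) -> GoDag:
    """Random DAG: each term gets 0–2 parents among lower-indexed terms."""
    g = nx.MultiDiGraph()
    g.add_node(_go(1))
    for i in range(2, n_terms + 1):
        g.add_node(_go(i))
        for _ in range(int(rng.integers(0, 3))):
            parent = int(rng.integers(1, i))
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            g.add_edge(_go(i), _go(parent), key=rel)
    return GoDag(graph=g)


def _oracle_closure(dag: GoDag, seeds, relations):
    """Independent brute force: DFS upward from every term, keep those
    reaching a seed (plus the seeds themselves)."""
    out = set(seeds)
    for term in dag.terms:
        stack, seen = [term], set()
        while stack:
            t = stack.pop()
            if t in seeds:
                out.add(term)
                break
            for _, parent, key in dag.graph.out_edges(t, keys=True):
                if key in relations and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
    return frozenset(out)


class TestClosure:
    def test_chain(self):
        dag = _dag([(_go(3), _go(2), "is_a"), (_go(2), _go(1), "is_a")])
        assert go_descendant_closure(dag, {_go(1)}) == {_go(1), _go(2), _go(3)}

    def test_leaf_seed_is_its_own_closure(self):
        dag = _dag([(_go(3), _go(2), "is_a"), (_go(2), _go(1), "is_a")])
        assert go_descendant_closure(dag, {_go(3)}) == {_go(3)}

    def test_part_of_respected_only_when_selected(self):
        dag = _dag([(_go(2), _go(1), "part_of")])
        assert go_descendant_closure(dag, {_go(1)}, frozenset({"is_a"})) == {_go(1)}
        assert go_descendant_closure(dag, {_go(1)}, frozenset({"is_a", "part_of"})) == {
            _go(1),
            _go(2),
        }

    def test_missing_seed_is_an_error(self):
        dag = _dag([(_go(2), _go(1), "is_a")])
        with pytest.raises(KeyError, match="GO:0000009"):
            go_descendant_closure(dag, {_go(9)})

    def test_matches_dfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            dag = _random_dag(rng, int(rng.integers(5, 120)))
            terms = sorted(dag.terms)
            seeds = frozenset(
                terms[i] for i in rng.choice(len(terms), size=min(3, len(terms)), replace=False)
            )
            for relations in (frozenset({"is_a"}), frozenset({"is_a", "part_of"})):
                got = go_descendant_closure(dag, seeds, relations)
                assert got == _oracle_closure(dag, seeds, relations)

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(5)
        dag = _random_dag(rng, 60)
        seeds = frozenset(sorted(dag.terms)[:3])
        closure = go_descendant_closure(dag, seeds)
        assert go_descendant_closure(dag, closure) == closure
        # adding an edge never shrinks the closure
        g2 = dag.graph.copy()
        g2.add_edge(_go(59), _go(1), key="is_a")
        closure2 = go_descendant_closure(GoDag(graph=g2), seeds)
        assert closure <= closure2

    def test_packaged_seed_list_has_31_terms(self):
        seeds = load_default_seed_terms()
        assert len(seeds) == 31
        assert all(s.startswith("GO:") and len(s) == 10 for s in seeds)


def _ogs(rows: dict[str, dict[str, tuple[str, ...]]], species) -> OrthogroupTable:
    full = {og: {sp: row.get(sp, ()) for sp in species} for og, row in rows.items()}
    return OrthogroupTable(species=tuple(species), members=full)


class TestApproaches:
    def test_reference_stress_proteins(self):
        table = GoAnnotationTable(
            subject_kind="protein",
            annotations={"p1": frozenset({_go(1)}), "p2": frozenset({_go(9)})},
        )
        assert reference_stress_proteins(table, frozenset({_go(1), _go(2)})) == {"p1"}
        empty = GoAnnotationTable(subject_kind="protein", annotations={})
        assert reference_stress_proteins(empty, frozenset({_go(1)})) == frozenset()

    def test_approach1_requires_every_reference(self):
        ogs = _ogs(
            {
                "OG1": {"ref1": ("r1a",), "ref2": ("r2a",)},
                "OG2": {"ref1": ("r1b",)},
                "OG3": {},
            },
            ["ref1", "ref2", "other"],
        )
        calls = approach1_calls(
            ogs, {"ref1": frozenset({"r1a", "r1b"}), "ref2": frozenset({"r2a"})}
        )
        assert calls == {"OG1": True, "OG2": False, "OG3": False}

    def test_approach1_missing_reference_column_errors(self):
        ogs = _ogs({"OG1": {}}, ["A"])
        with pytest.raises(ValueError, match="ref1"):
            approach1_calls(ogs, {"ref1": frozenset(), "A": frozenset()})

    def test_approach2_membership_in_closure(self):
        table = GoAnnotationTable(
            subject_kind="orthogroup",
            annotations={"OG1": frozenset({_go(2)}), "OG2": frozenset({_go(9)})},
        )
        calls = approach2_calls(table, frozenset({_go(1), _go(2)}), universe=["OG1", "OG2", "OG3"])
        assert calls == {"OG1": True, "OG2": False, "OG3": False}

    def test_intersection_and_summary(self):
        a1 = {"OG1": True, "OG2": True, "OG3": False}
        a2 = {"OG1": False, "OG2": True, "OG3": True}
        calls = intersect_calls(a1, a2)
        assert [c.orthogroup_id for c in calls if c.stress] == ["OG2"]
        summary = call_summary(calls)
        assert summary["stress"] == 1 and summary["a1_only"] == 1 and summary["a2_only"] == 1
        assert summary["stress"] <= min(summary["approach1"], summary["approach2"])

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            intersect_calls({"OG1": True}, {"OG2": True})

    def test_intersection_cardinality_bound_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            universe = [f"OG{i}" for i in range(int(rng.integers(1, 40)))]
            a1 = {og: bool(rng.random() < 0.4) for og in universe}
            a2 = {og: bool(rng.random() < 0.6) for og in universe}
            s = call_summary(intersect_calls(a1, a2))
            assert s["stress"] <= min(s["approach1"], s["approach2"])

    def test_adding_protein_never_flips_true_call_false(self):
        species = ["ref1", "ref2"]
        ogs = _ogs({"OG1": {"ref1": ("a",), "ref2": ("b",)}}, species)
        refs = {"ref1": frozenset({"a"}), "ref2": frozenset({"b"})}
        assert approach1_calls(ogs, refs)["OG1"]
        bigger = _ogs({"OG1": {"ref1": ("a", "x"), "ref2": ("b",)}}, species)
        assert approach1_calls(bigger, refs)["OG1"]
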