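"""Embryophytic domain sets, LGP classification and node tallies."""

import pandas as pd
import pytest

from lgptrace.domain_architecture import MergedDomainSpan, build_architectures
from lgptrace.io_formats import LineageMap, OrthogroupTable
from lgptrace.lgp import (
    classify_lgp,
    domain_completion,
    embryophytic_domain_set,
    node_tallies,
)
from lgptrace.phylostratigraphy import OriginAssignment
from lgptrace.species_tree import SpeciesTree


@pytest.fixture(scope="module")
def world():
    """Six-species world: one charophyte, one zygnematophyte, land plants."""
    tree = SpeciesTree.from_newick(
        "(chl1,(cha1,(zyg1,(bry1,(tra1,tra2)tracheophytes)land_plants)zlp)strep)root;"
    )
    lmap = LineageMap(
        lineages={
            "chl1": "chlorophyte",
            "cha1": "charophyceae",
            "zyg1": "zygnematophyceae",
            "bry1": "bryophyte",
            "tra1": "tracheophyte",
            "tra2": "tracheophyte",
        }
    )
    return tree, lmap


def _build(spans_by_protein, og_rows, species):
    spans = []
    for pid, archs in spans_by_protein.items():
        pos = 1
        for acc in archs:
            spans.append(MergedDomainSpan(pid, acc, pos, pos + 50))
            pos += 100
    archs = build_architectures(spans)
    table = OrthogroupTable(
        species=tuple(species),
        members={
            og: {sp: tuple(p for p in row.get(sp, ())) for sp in species}
            for og, row in og_rows.items()
        },
    )
    protein_species = table.protein_species_map()
    carriers: dict[str, frozenset[str]] = {}
    for pid, arch in archs.items():
        for acc in arch.order:
            carriers[acc] = carriers.get(acc, frozenset()) | {protein_species[pid]}
    return table, archs, protein_species, carriers


SPECIES = ("chl1", "cha1", "zyg1", "bry1", "tra1", "tra2")


class TestEmbryophyticDomainSet:
    def test_domain_on_moss_and_tracheophyte_included(self, world):
        tree, lmap = world
        table, archs, _, _ = _build(
            {"bry1_p": ("D1",), "tra1_p": ("D1",)},
            {"OG1": {"bry1": ("bry1_p",), "tra1": ("tra1_p",)}},
            SPECIES,
        )
        eset = embryophytic_domain_set("OG1", table, archs, lmap)
        assert eset.domains == {"D1"}
        assert eset.representative_architectures == {("D1",)}

    def test_tracheophyte_only_domain_excluded(self, world):
        tree, lmap = world
        table, archs, _, _ = _build(
            {"bry1_p": ("D1",), "tra1_p": ("D1", "D2")},
            {"OG1": {"bry1": ("bry1_p",), "tra1": ("tra1_p",)}},
            SPECIES,
        )
        eset = embryophytic_domain_set("OG1", table, archs, lmap)
        assert eset.domains == {"D1"}
        # representative architectures are projections onto the kept set
        assert eset.representative_architectures == {("D1",)}

    def test_recovers_planted_set_on_simulation(self, sim_bundle, sim_run):
        _, _, out = sim_run
        lgp = pd.read_csv(out / "lgp.tsv", sep="\t")
        eligible = set(lgp[lgp.eligible == 1].orthogroup)
        truth_eligible = {
            og for og, i in sim_bundle.truth.orthogroups.items() if i["embryophytic_set"]
        }
        assert eligible == truth_eligible


class TestDomainCompletion:
    def test_missing_domain_means_incomplete(self, world):
        _, lmap = world
        table, archs, _, carriers = _build(
            {"bry1_p": ("D1", "D2"), "tra1_p": ("D1", "D2"), "cha1_p": ("D1",)},
            {
                "OG1": {"bry1": ("bry1_p",), "tra1": ("tra1_p",)},
                "OG2": {"cha1": ("cha1_p",)},
            },
            SPECIES,
        )
        eset = embryophytic_domain_set("OG1", table, archs, lmap)
        completion = domain_completion(eset, carriers, SPECIES)
        assert completion["bry1"] and completion["tra1"]
        assert not completion["cha1"]  # has D1 but not D2
        assert not completion["chl1"]  # empty proteome


def _classify(world, spans_by_protein, og_rows, og="OG1", mode="all_previous_lineages"):
    tree, lmap = world
    table, archs, protein_species, carriers = _build(spans_by_protein, og_rows, SPECIES)
    eset = embryophytic_domain_set(og, table, archs, lmap)
    origin = OriginAssignment(
        og, "orthogroup", tree.mrca(table.carrier_species(og)), len(table.carrier_species(og))
    )
    return classify_lgp(
        eset, origin, carriers, archs, protein_species, tree, age_mode=mode
    )


BASE_ROWS = {
    "OG1": {"bry1": ("bry1_p",), "tra1": ("tra1_p",)},
    "BG1": {"cha1": ("cha1_a",), "zyg1": ("zyg1_a",)},
    "BG2": {"cha1": ("cha1_b",), "zyg1": ("zyg1_b",)},
}


class TestClassifyLgp:
    def test_old_domains_new_combination_is_lgp(self, world):
        rec = _classify(
            world,
            {
                "bry1_p": ("D1", "D2"),
                "tra1_p": ("D1", "D2"),
                "cha1_a": ("D1",),
                "zyg1_a": ("D1",),
                "cha1_b": ("D2",),
                "zyg1_b": ("D2",),
            },
            BASE_ROWS,
        )
        assert rec.domain_age_ok and rec.architecture_novel and rec.lgp

    def test_domain_absent_outside_clade_is_not_lgp(self, world):
        rec = _classify(
            world,
            {
                "bry1_p": ("D1", "D9"),
                "tra1_p": ("D1", "D9"),
                "cha1_a": ("D1",),
                "zyg1_a": ("D1",),
                "cha1_b": ("D2",),
                "zyg1_b": ("D2",),
            },
            BASE_ROWS,
        )
        assert not rec.domain_age_ok and not rec.lgp

    def test_outgroup_protein_with_same_order_kills_novelty(self, world):
        rec = _classify(
            world,
            {
                "bry1_p": ("D1", "D2"),
                "tra1_p": ("D1", "D2"),
                "cha1_a": ("D1", "D2"),  # the collision: both, in order
                "zyg1_a": ("D1",),
                "cha1_b": ("D2",),
                "zyg1_b": ("D2",),
            },
            BASE_ROWS,
        )
        assert rec.domain_age_ok and not rec.architecture_novel and not rec.lgp

    def test_outgroup_reversed_order_stays_novel(self, world):
        rec = _classify(
            world,
            {
                "bry1_p": ("D1", "D2"),
                "tra1_p": ("D1", "D2"),
                "cha1_a": ("D2", "D1"),  # same domains, other order
                "zyg1_a": ("D1",),
                "cha1_b": ("D2",),
                "zyg1_b": ("D2",),
            },
            BASE_ROWS,
        )
        assert rec.architecture_novel and rec.lgp

    def test_all_previous_mode_needs_every_sister_lineage(self, world):
        # D2 present in the charophyte but not the zygnematophyte sister
        spans = {
            "bry1_p": ("D1", "D2"),
            "tra1_p": ("D1", "D2"),
            "cha1_a": ("D1",),
            "zyg1_a": ("D1",),
            "cha1_b": ("D2",),
        }
        rows = {
            "OG1": BASE_ROWS["OG1"],
            "BG1": BASE_ROWS["BG1"],
            "BG2": {"cha1": ("cha1_b",)},
        }
        strict = _classify(world, spans, rows, mode="all_previous_lineages")
        lax = _classify(world, spans, rows, mode="any_outgroup")
        assert not strict.lgp and lax.lgp

    def test_strict_mode_is_subset_of_lax_on_simulation(self, sim_bundle, tmp_path):
        from lgptrace.pipeline import PipelineConfig, run_all

        run_all(
            PipelineConfig.from_bundle(sim_bundle.directory, tmp_path / "lax", age_mode="any_outgroup")
        )
        run_all(
            PipelineConfig.from_bundle(
                sim_bundle.directory, tmp_path / "strict", age_mode="all_previous_lineages"
            )
        )
        lax = pd.read_csv(tmp_path / "lax" / "lgp.tsv", sep="\t")
        strict = pd.read_csv(tmp_path / "strict" / "lgp.tsv", sep="\t")
        assert set(strict[strict.lgp == 1].orthogroup) <= set(lax[lax.lgp == 1].orthogroup)

    def test_empty_set_is_ineligible(self, world):
        rec = _classify(
            world,
            {"bry1_p": ("D1",), "tra1_p": ("D2",), "cha1_a": ("D1",), "zyg1_a": ("D1",),
             "cha1_b": ("D2",), "zyg1_b": ("D2",)},
            BASE_ROWS,
        )
        assert not rec.eligible and not rec.lgp


class TestRecoveryAndTallies:
    def test_planted_lgp_labels_recovered_exactly(self, sim_bundle, sim_run):
        _, _, out = sim_run
        lgp = pd.read_csv(out / "lgp.tsv", sep="\t")
        pred = set(lgp[lgp.lgp == 1].orthogroup)
        truth = {
            og for og, i in sim_bundle.truth.orthogroups.items() if i["lgp_all_previous"]
        }
        assert pred == truth  # precision = recall = 1.0

    def test_tally_counting(self, world):
        from lgptrace.lgp import LgpRecord

        tree, _ = world
        path = tree.path_to_focal()
        recs = [
            LgpRecord(f"OG{i}", "land_plants", "land_plants", True, True, True, i < 4, i < 2)
            for i in range(10)
        ]
        tallies = {t.node: t for t in node_tallies(recs, path)}
        lp = tallies["land_plants"]
        assert (lp.x, lp.y) == (2, 4)
        assert lp.n_origin_total == 10 and lp.n_origin_stress == 2
        assert tallies["strep"].x == 0 and tallies["strep"].y == 0

    def test_tallies_consistent_on_simulation(self, sim_run):
        _, report, out = sim_run
        tallies = pd.read_csv(out / "node_tallies.tsv", sep="\t")
        assert (tallies.x <= tallies.y).all()
        assert (tallies.y <= tallies.n_origin_total).all()
        assert (tallies.x <= tallies.n_origin_stress).all()
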