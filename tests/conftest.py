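"""Shared fixtures: generated bundles and pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from lgptrace.pipeline import PipelineConfig, run_all
from lgptrace.synthetic_data import SimConfig, make_worked_micro_case, simulate


@pytest.fixture(scope="session")
def micro_bundle(tmp_path_factory):
    return make_worked_micro_case(tmp_path_factory.mktemp("micro") / "bundle")


@pytest.fixture(scope="session")
def micro_run(micro_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("micro_out")
    report = run_all(PipelineConfig.from_bundle(micro_bundle.directory, out))
    return micro_bundle, report, out


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Small loss-free noise-free bundle with planted truth."""
    cfg = SimConfig(seed=11, n_orthogroups=300, n_domains=60)
    return simulate(cfg, tmp_path_factory.mktemp("sim") / "bundle")


@pytest.fixture(scope="session")
def sim_run(sim_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_out")
    report = run_all(PipelineConfig.from_bundle(sim_bundle.directory, out))
    return sim_bundle, report, out


def random_rooted_tree(rng: np.random.Generator, n_leaves: int):
    """A random rooted tree as (newick, parent-name map).

    Joins random groups of 2–3 subtrees until two remain, then roots them,
    so the root is always bifurcating while internal multifurcations occur.
    Returns the Newick string and an independently built child→parent map
    used by brute-force oracles.
    """
    items = [(f"L{i}", f"L{i}") for i in range(n_leaves)]  # (name, newick)
    parent: dict[str, str] = {}
    counter = 0
    while len(items) > 2:
        k = 3 if (rng.random() < 0.2 and len(items) > 3) else 2
        idx = sorted(rng.choice(len(items), size=k, replace=False), reverse=True)
        picked = [items.pop(i) for i in idx]
        counter += 1
        name = f"I{counter}"
        for child_name, _ in picked:
            parent[child_name] = name
        newick = "(" + ",".join(nwk for _, nwk in picked) + ")" + name
        items.append((name, newick))
    for child_name, _ in items:
        parent[child_name] = "root"
    newick = "(" + ",".join(nwk for _, nwk in items) + ")root;"
    return newick, parent


def oracle_mrca(parent: dict[str, str], leaves: list[str]) -> str:
    """Brute-force MRCA: intersect root paths."""
    paths = []
    for leaf in leaves:
        path = [leaf]
        while path[-1] != "root":
            path.append(parent[path[-1]])
        paths.append(path)
    candidate_sets = [set(p) for p in paths[1:]]
    for node in paths[0]:
        if all(node in s for s in candidate_sets):
            return node
    raise AssertionError("no common ancestor found")  # pragma: no cover
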