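import numpy as np
import pytest

from sna_qgen import network_traits as nt
from sna_qgen import pedigree_kinship as pk
from sna_qgen import synthetic_data as sd
from sna_qgen.io_formats import PenRoster


def make_graph(nodes, edges, pen_id="P1", sex="female", batch="B1"):
    """Pen graph from a node string/list and (a, b, weight) triples."""
    roster = PenRoster(pen_id, tuple(nodes), sex, batch)
    dyads = {frozenset((a, b)): float(w) for a, b, w in edges}
    return nt.build_graph(roster, dyads)


def random_graph(rng, max_nodes=7, p=0.45, integer_weights=False):
    """Random weighted pen graph on 2..max_nodes nodes (isolates allowed)."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [chr(65 + i) for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = (float(rng.integers(1, 11)) if integer_weights
                     else float(rng.uniform(0.5, 60.0)))
                edges.append((nodes[i], nodes[j], w))
    return make_graph(nodes, edges)


def random_pedigree(rng, n, n_founders=None):
    """Random sorted pedigree of n animals; parents drawn from predecessors."""
    n_founders = n_founders or max(4, n // 10)
    sires, dams = [], []
    for i in range(n):
        if i < n_founders:
            sires.append("0")
            dams.append("0")
        else:
            p = rng.choice(i, size=2, replace=False)
            sires.append(str(p[0] + 1))
            dams.append(str(p[1] + 1))
    return pk.PedigreeTable.from_records(
        [str(i + 1) for i in range(n)], sires, dams)


MINI_CONFIG = dict(n_sires=8, n_dams=24, n_offspring=96, pedigree_total=200,
                   pen_size=12, n_pens=8, n_batches=3, n_lines=3)


@pytest.fixture(scope="session")
def mini_study():
    """A small synthetic study shared by I/O and pipeline tests."""
    return sd.simulate_study(sd.SimulationConfig(seed=123, **MINI_CONFIG))


@pytest.fixture(scope="session")
def study_metadata():
    """Study-shaped animal metadata (9 lines, 2 sexes, 9 batches, 50 pens)."""
    cfg = sd.SimulationConfig(seed=7)
    ped = sd.simulate_pedigree(cfg, seed=7)
    animals, rosters = sd.assign_pens(ped, cfg, seed=8)
    return cfg, ped, animals, rosters
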