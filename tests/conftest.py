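import networkx as nx
import pytest

from lhpc.complex_catalog import ComplexCatalog
from lhpc.pipeline import PipelineConfig, run_pipeline
from lhpc.synthetic_data import WorldConfig, generate_universe
from lhpc.types import ProteinGroup


def make_catalog(members: dict[str, set[str]],
                 parents: dict[str, list[str]] | None = None) -> ComplexCatalog:
    """A ComplexCatalog assembled directly, bypassing ontology selection."""
    hier = nx.DiGraph()
    hier.add_nodes_from(members)
    for child, ps in (parents or {}).items():
        for p in ps:
            hier.add_edge(child, p)
    complexes = {
        tid: ProteinGroup(group_id=tid, role="complex", proteins=frozenset(prots))
        for tid, prots in members.items()
    }
    return ComplexCatalog(complexes=complexes, hierarchy=hier,
                          n_selected=len(members))


def make_group(gid: str, proteins: set[str], role: str = "ps") -> ProteinGroup:
    return ProteinGroup(group_id=gid, role=role, proteins=frozenset(proteins))


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """Default synthetic world: file bundle, truth manifest, input dir."""
    d = tmp_path_factory.mktemp("world")
    paths, truth = generate_universe(WorldConfig(seed=11), d)
    return {"dir": d, "paths": paths, "truth": truth}


@pytest.fixture(scope="session")
def world_report(world, tmp_path_factory):
    """Full pipeline report over the default world (light null replicates)."""
    out = tmp_path_factory.mktemp("world_out")
    report = run_pipeline(PipelineConfig(
        input_dir=str(world["dir"]), output_dir=str(out), mode="ps_based",
        reps=200, seed=5,
    ))
    return {"out": out, "report": report, "truth": world["truth"]}
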