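import itertools
import random

import dendropy
import pytest

from sagqc.records import Contig, GeneCall, SAGAssembly
from sagqc.simulate import SimulationConfig, simulate_sag


@pytest.fixture(scope="session")
def default_sim():
    """The reference synthetic contaminated SAG (seed 42, defaults:
    60 target + 15 contaminant contigs, GC 0.45 vs 0.60, 50% completeness)."""
    return simulate_sag(SimulationConfig(seed=42))


@pytest.fixture
def toy_assembly():
    """Hand-built 4-contig assembly with known GC and taxonomy."""
    contigs = [
        Contig(id="c1", sequence="ACGT" * 1000),          # 4 kb, GC 0.5
        Contig(id="c2", sequence="ATAT" * 600),           # 2.4 kb, GC 0.0
        Contig(id="c3", sequence="GCGC" * 500),           # 2 kb, GC 1.0
        Contig(id="c4", sequence="ACGTACGT" * 100),       # 800 bp, GC 0.5
    ]
    genes = [
        GeneCall("g1", "c1", 1, 300, "+", "Archaea", "Euryarchaeota"),
        GeneCall("g2", "c1", 400, 900, "-", "Archaea", "Euryarchaeota"),
        GeneCall("g3", "c2", 1, 300, "+", "Bacteria", "Proteobacteria"),
        GeneCall("g4", "c2", 400, 900, "+", "Bacteria", "Proteobacteria"),
    ]
    return SAGAssembly(sag_id="TOY", contigs=contigs, genes=genes)


def brute_force_fitch(tree: dendropy.Tree, col_by_taxon: dict[str, str],
                      missing: frozenset[str] = frozenset("-?XN")) -> int:
    """Exhaustive minimal-labeling parsimony length for one site: enumerate
    every assignment of observed states to internal nodes (and to missing
    leaves) and count edge mismatches.  Independent of the Fitch pass."""
    observed = sorted({s for s in col_by_taxon.values() if s not in missing})
    if len(observed) <= 1:
        return 0
    nodes = list(tree.postorder_node_iter())
    free = [n for n in nodes
            if not n.is_leaf() or col_by_taxon[n.taxon.label] in missing]
    best = float("inf")
    for assign in itertools.product(observed, repeat=len(free)):
        state = {id(n): s for n, s in zip(free, assign)}
        for n in nodes:
            if n.is_leaf() and col_by_taxon[n.taxon.label] not in missing:
                state[id(n)] = col_by_taxon[n.taxon.label]
        cost = sum(
            1
            for n in nodes
            for ch in n.child_nodes()
            if state[id(n)] != state[id(ch)]
        )
        best = min(best, cost)
    return int(best)


def random_tree(taxa: list[str], seed: int) -> dendropy.Tree:
    """Random binary topology over the given taxa (deterministic per seed)."""
    rng = random.Random(seed)
    tns = dendropy.TaxonNamespace(taxa)
    return dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.0, taxon_namespace=tns, num_extant_tips=len(taxa), rng=rng
    )
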