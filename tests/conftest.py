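import copy

import pytest

from karyograph import mdm, mgraph, simulate

INTEGRATION_SEED = 1


@pytest.fixture(scope="session")
def fx():
    """The standard end-to-end scenario: 6 chromosomes, 5 layers, 3 chimeras,
    20x error-free reads, truth-derived alignments."""
    return simulate.integration_fixture(seed=INTEGRATION_SEED)


@pytest.fixture(scope="session")
def _built_graph_cached(fx):
    return mgraph.build_graph(fx.assemblies, fx.reciprocal_alignments)


@pytest.fixture
def built_graph(_built_graph_cached):
    # graphs are mutable; each test gets its own copy of the cached build
    return copy.deepcopy(_built_graph_cached)


@pytest.fixture(scope="session")
def _mdm_cached(fx):
    g = mgraph.build_graph(fx.assemblies, fx.reciprocal_alignments)
    g, events = mdm.run_mdm(g)
    return g, events


@pytest.fixture
def mdm_result(_mdm_cached):
    g, events = _mdm_cached
    return copy.deepcopy(g), list(events)


def node_true_chromosome(truth, g, node):
    """Chromosome holding the majority of a node's interval, from truth."""
    layer_name = g.layers[node.layer].name
    best, best_ov = None, -1
    for seg in truth.layers[layer_name][node.name]:
        if seg.strand == "+":
            lo, hi = seg.offset, seg.offset + seg.length
        else:
            lo, hi = seg.offset, seg.offset + seg.length
        ov = min(hi, node.end) - max(lo, node.start)
        if ov > best_ov:
            best, best_ov = seg.chrom, ov
    return best
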