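import numpy as np
import pytest

from acst.pathway_io import PathwayGraph


def make_graph(edges, extra_nodes=(), pathway_id="toy"):
    """PathwayGraph from (src, tgt, sign) triples plus optional isolated nodes."""
    nodes = {n for s, t, _ in edges for n in (s, t)} | set(extra_nodes)
    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=set(edges))


@pytest.fixture
def chain_abc():
    """a→b→c, both activation."""
    return make_graph([("a", "b", 1), ("b", "c", 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


KGML_TOY = """<?xml version="1.0"?>
<pathway name="path:hsa99999" title="Toy pathway">
 <entry id="1" name="hsa:10" type="gene"/>
 <entry id="2" name="hsa:20" type="gene"/>
 <entry id="3" name="hsa:30 hsa:31" type="gene"/>
 <entry id="4" name="cpd:C00001" type="compound"/>
 <relation entry1="1" entry2="2" type="GErel">
  <subtype name="expression" value="--&gt;"/>
 </relation>
 <relation entry1="3" entry2="1" type="GErel">
  <subtype name="repression" value="--|"/>
 </relation>
 <relation entry1="2" entry2="3" type="PPrel">
  <subtype name="phosphorylation" value="+p"/>
 </relation>
</pathway>
"""


@pytest.fixture
def kgml_toy():
    return KGML_TOY
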