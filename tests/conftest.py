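import numpy as np
import pytest

from isochron.model_io import (
    CellClass,
    Compartment,
    Dataset,
    Skeleton,
    SkeletonNode,
    SynapseAnnotation,
    TargetClass,
)
from isochron.profiles import load_profile


@pytest.fixture(scope="session")
def mouse_p105():
    return load_profile("mouse_V1_L23_p105")


@pytest.fixture(scope="session")
def mouse_p14():
    return load_profile("mouse_V1_L23_p14")


@pytest.fixture(scope="session")
def mouse_p6():
    return load_profile("mouse_V1_L23_p6")


@pytest.fixture(scope="session")
def primate_p7():
    return load_profile("primate_V1_L23_p7")


@pytest.fixture(scope="session")
def primate_p75():
    return load_profile("primate_V1_L23_p75")


def chain_skeleton(points, radii=None, compartment=Compartment.DENDRITE_BASAL,
                   skeleton_id="sk0", cell_class=CellClass.EXCITATORY,
                   start_id=1):
    """Unbranched skeleton through the given 3D points."""
    pts = np.asarray(points, dtype=float)
    radii = np.full(len(pts), 0.4) if radii is None else np.asarray(radii, float)
    nodes = {}
    for k in range(len(pts)):
        nid = start_id + k
        nodes[nid] = SkeletonNode(nid, pts[k], float(radii[k]),
                                  None if k == 0 else start_id + k - 1, compartment)
    return Skeleton(skeleton_id=skeleton_id, nodes=nodes, cell_id=skeleton_id,
                    cell_class=cell_class)


def straight_dendrite(length_um=10.0, step=1.0, **kw):
    """Straight dendrite along +x with nodes every ``step`` µm."""
    n = int(round(length_um / step)) + 1
    pts = [(k * step, 0.0, 0.0) for k in range(n)]
    return chain_skeleton(pts, **kw)


def synapse_on(sk, node_id, target=TargetClass.SPINE, synapse_id=None,
               pre_axon_id="ax0", offset=(0.0, 0.0, 0.0), **kw):
    node = sk.nodes[node_id]
    return SynapseAnnotation(
        synapse_id=synapse_id or f"{sk.skeleton_id}-{node_id}-{target.value}",
        pre_axon_id=pre_axon_id,
        post_cell_id=sk.cell_id,
        post_node_id=node_id,
        target_class=target,
        position=node.position + np.asarray(offset, float),
        **kw,
    )


@pytest.fixture
def simple_dataset():
    """One 10 µm dendrite with 5 spine and 2 shaft synapses."""
    sk = straight_dendrite(10.0)
    ds = Dataset(skeletons=[sk])
    for k, nid in enumerate([2, 4, 6, 8, 10]):
        ds.synapses.append(synapse_on(sk, nid, TargetClass.SPINE,
                                      synapse_id=f"sp{k}", offset=(0, 1.0, 0)))
    for k, nid in enumerate([3, 7]):
        ds.synapses.append(synapse_on(sk, nid, TargetClass.SHAFT,
                                      synapse_id=f"sh{k}"))
    return ds
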