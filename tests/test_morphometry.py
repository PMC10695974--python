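"""Cable length, fragment sampling, densities, diameters, spine distances."""

import numpy as np
import pytest

from isochron.model_io import Compartment, Dataset, SkeletonNode, Skeleton, TargetClass
from isochron.morphometry import (
    DendriteFragment,
    bulk_2d_density,
    cable_length,
    fragment_density,
    fragment_diameter,
    filopodia_density,
    sample_fragments,
    spine_branch_distance,
    whole_dendrite_fragment,
)
from isochron.model_io import FilopodiumAnnotation
from isochron.synthetic import generate_dendrite, generate_fov_counts
import pandas as pd

from conftest import chain_skeleton, straight_dendrite, synapse_on


def y_tree():
    """Root → A (5 µm), A → B (12 µm), A → C (8 µm)."""
    nodes = {
        1: SkeletonNode(1, (0, 0, 0), 0.5, None, Compartment.DENDRITE_BASAL),
        2: SkeletonNode(2, (3, 4, 0), 0.4, 1, Compartment.DENDRITE_BASAL),
        3: SkeletonNode(3, (3, 4, 12), 0.3, 2, Compartment.DENDRITE_BASAL),
        4: SkeletonNode(4, (3, 12, 0), 0.2, 2, Compartment.DENDRITE_BASAL),
    }
    return Skeleton("y", nodes)


def test_cable_length_chain():
    sk = chain_skeleton([(0, 0, 0), (3, 4, 0)])
    assert cable_length(sk) == pytest.approx(5.0)


def test_cable_length_y_tree_additivity():
    assert cable_length(y_tree()) == pytest.approx(25.0)


def test_cable_length_single_node_zero():
    sk = chain_skeleton([(1, 2, 3)])
    assert cable_length(sk) == 0.0


def test_cable_length_disconnected_subset_rejected():
    with pytest.raises(ValueError, match="connected"):
        cable_length(y_tree(), {3, 4})  # siblings without their parent


def test_cable_length_subset_sums_over_components():
    sk = y_tree()
    total = cable_length(sk)
    assert (cable_length(sk, {1, 2}) + cable_length(sk, {2, 3})
            + cable_length(sk, {2, 4})) == pytest.approx(total)


def test_sample_fragments_unbranched_full_length():
    sk = straight_dendrite(100.0)
    frags = sample_fragments(sk, target_length=10.0, n=5, seed=1)
    non_trunc = [f for f in frags if not f.truncated]
    for f in non_trunc:
        assert f.path_length == pytest.approx(10.0)
    assert len(frags) == 5


def test_sample_fragment_truncated_at_tip():
    sk = straight_dendrite(10.0)
    # force the start 4 µm from the tip: node 7 (at x=6) → 4 µm remain
    frags = [f for s in range(50)
             for f in sample_fragments(sk, 10.0, n=1, seed=s)
             if f.node_path[0] == 7]
    assert frags, "start node 7 never drawn"
    f = frags[0]
    assert f.truncated and f.path_length == pytest.approx(4.0)


def test_sample_fragments_deterministic():
    sk = straight_dendrite(100.0)
    a = sample_fragments(sk, 10.0, n=5, seed=9)
    b = sample_fragments(sk, 10.0, n=5, seed=9)
    assert [f.node_path for f in a] == [f.node_path for f in b]


def test_sample_fragments_stop_at_branch():
    sk = y_tree()
    frags = sample_fragments(sk, 10.0, n=4, seed=0, rule="stop_at_branch")
    for f in frags:
        # a stopped fragment never contains both daughters of node 2
        assert not ({3, 4} <= set(f.node_path))


def test_sample_fragments_requires_dendritic_cable():
    sk = chain_skeleton([(0, 0, 0), (1, 0, 0)], compartment=Compartment.AXON)
    with pytest.raises(ValueError, match="dendritic"):
        sample_fragments(sk, 10.0, n=1)


def test_fragment_density_simple(simple_dataset):
    """10 µm with 5 spine synapses → 0.5/µm; 2 shaft → 0.2/µm."""
    sk = simple_dataset.skeletons[0]
    frag = whole_dendrite_fragment(sk)
    rec = fragment_density(frag, simple_dataset)
    assert rec.spine_density == pytest.approx(0.5)
    assert rec.shaft_density == pytest.approx(0.2)


def test_fragment_density_truncated_uses_actual_length(simple_dataset):
    sk = simple_dataset.skeletons[0]
    frag = DendriteFragment(sk.skeleton_id, [7, 8, 9, 10, 11], 4.0, 0.8,
                            Compartment.DENDRITE_BASAL, truncated=True)
    rec = fragment_density(frag, simple_dataset)
    assert rec.spine_count == 2  # spines on nodes 8 and 10
    assert rec.spine_density == pytest.approx(0.5)


def test_fragment_density_split_and_pool_is_exact(simple_dataset):
    """Splitting a fragment and pooling counts/lengths reproduces its density."""
    sk = simple_dataset.skeletons[0]
    whole = whole_dendrite_fragment(sk)
    path = whole.node_path
    cut = 5
    first = DendriteFragment(sk.skeleton_id, path[:cut],
                             cable_length(sk, set(path[:cut])), 0.8,
                             Compartment.DENDRITE_BASAL)
    second = DendriteFragment(sk.skeleton_id, path[cut:],
                              whole.path_length - first.path_length, 0.8,
                              Compartment.DENDRITE_BASAL)
    r1 = fragment_density(first, simple_dataset)
    r2 = fragment_density(second, simple_dataset)
    rw = fragment_density(whole, simple_dataset)
    assert r1.spine_count + r2.spine_count == rw.spine_count
    # the connecting edge is assigned to the second part, so lengths pool exactly
    pooled = (r1.spine_count + r2.spine_count) / (r1.path_length + r2.path_length)
    assert pooled == pytest.approx(rw.spine_density)


def test_fragment_density_generator_oracle(mouse_p14):
    """20 fragments at the p14 rate: mean spine density ≈ 0.87/µm within 3 SE."""
    dens = []
    for i in range(20):
        dd = generate_dendrite(mouse_p14, 10.0, seed=55, cell_index=i)
        dens.append(fragment_density(whole_dendrite_fragment(dd.skeletons[0]), dd, "spine"))
    sem = np.std(dens, ddof=1) / np.sqrt(len(dens))
    assert abs(np.mean(dens) - 0.87) < 3 * sem


def test_fragment_diameter_constant_radius():
    sk = straight_dendrite(5.0)  # all radii 0.4
    assert fragment_diameter(whole_dendrite_fragment(sk)) == pytest.approx(0.8)


def test_fragment_diameter_mean_of_radii():
    sk = chain_skeleton([(0, 0, 0), (1, 0, 0)], radii=[0.3, 0.5])
    assert fragment_diameter(whole_dendrite_fragment(sk)) == pytest.approx(0.8)


def test_fragment_diameter_taper_bounds():
    radii = np.linspace(0.2, 0.6, 11)
    sk = chain_skeleton([(k, 0, 0) for k in range(11)], radii=radii)
    d = fragment_diameter(whole_dendrite_fragment(sk))
    assert 2 * radii.min() <= d <= 2 * radii.max()


def test_spine_branch_distance_on_cable_is_zero():
    sk = straight_dendrite(10.0)
    syn = synapse_on(sk, 3, TargetClass.SPINE)
    assert spine_branch_distance(syn, sk) == pytest.approx(0.0)


def test_spine_branch_distance_constructed_1107nm():
    sk = straight_dendrite(10.0)
    syn = synapse_on(sk, 3, TargetClass.SPINE, offset=(0.0, 1.107, 0.0))
    assert spine_branch_distance(syn, sk) == pytest.approx(1107.0)


def test_spine_branch_distance_rotation_invariant():
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [31.0, -12.0, 77.0], degrees=True)
    pts = [(k, 0, 0) for k in range(11)]
    sk = straight_dendrite(10.0)
    syn = synapse_on(sk, 4, TargetClass.SPINE, offset=(0.3, 0.9, -0.2))
    d0 = spine_branch_distance(syn, sk)
    sk_r = chain_skeleton(rot.apply(np.asarray(pts, float)))
    syn_r = synapse_on(sk_r, 5, TargetClass.SPINE)
    syn_r.position = rot.apply(syn.position)
    d1 = spine_branch_distance(syn_r, sk_r)
    assert d0 >= 0 and d1 == pytest.approx(d0, rel=1e-9)


def test_spine_branch_distance_rejects_non_spine():
    sk = straight_dendrite(10.0)
    syn = synapse_on(sk, 3, TargetClass.SHAFT)
    with pytest.raises(ValueError, match="spine"):
        spine_branch_distance(syn, sk)


def test_bulk_density_counts_and_threshold():
    """9 qualifying + 2 sub-threshold detections in 20 µm² → 0.45/µm²."""
    rows = [{"fov_id": 0, "vesicle_count": 30}] * 9 + \
           [{"fov_id": 0, "vesicle_count": 3}] * 2
    res = bulk_2d_density(pd.DataFrame(rows), 20.0, min_vesicles=5, n_fov=1)
    assert res.per_fov[0] == pytest.approx(0.45)


def test_bulk_density_all_zero_fovs():
    df = pd.DataFrame(columns=["fov_id", "vesicle_count"])
    res = bulk_2d_density(df, 20.0, n_fov=4)
    assert res.mean == 0.0 and res.sem == 0.0


def test_bulk_density_invariant_to_distractors():
    rows = [{"fov_id": f, "vesicle_count": 40} for f in range(4) for _ in range(5)]
    base = bulk_2d_density(pd.DataFrame(rows), 20.0, n_fov=4)
    rows += [{"fov_id": f, "vesicle_count": 2} for f in range(4) for _ in range(7)]
    spiked = bulk_2d_density(pd.DataFrame(rows), 20.0, n_fov=4)
    assert spiked.mean == base.mean and list(spiked.per_fov) == list(base.per_fov)


def test_bulk_density_poisson_oracle():
    """Grand mean over 1000 replicates of 4×20 µm² FOVs recovers 0.465/µm²."""
    means = [bulk_2d_density(generate_fov_counts(0.465, 4, 20.0, seed=i), 20.0).mean
             for i in range(1000)]
    sem = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - 0.465) < 3 * sem


def test_bulk_density_zero_area_rejected():
    with pytest.raises(ValueError):
        bulk_2d_density(pd.DataFrame(columns=["fov_id", "vesicle_count"]), 0.0)


def test_filopodia_density_simple():
    sk = straight_dendrite(10.0)
    ds = Dataset(skeletons=[sk])
    ds.filopodia.append(FilopodiumAnnotation("f0", sk.cell_id, 5, 3.0))
    frag = whole_dendrite_fragment(sk)
    assert filopodia_density(frag, ds) == pytest.approx(0.1)
    ds.filopodia.clear()
    assert filopodia_density(frag, ds) == 0.0


def test_filopodia_density_p105_generator_oracle(mouse_p105):
    """Adult filopodia are nearly absent: mean ≈ 0.005/µm within 3 SE."""
    dens = []
    for i in range(200):
        dd = generate_dendrite(mouse_p105, 10.0, seed=66, cell_index=i)
        dens.append(filopodia_density(whole_dendrite_fragment(dd.skeletons[0]), dd))
    se = max(np.std(dens, ddof=1) / np.sqrt(len(dens)), 1e-4)
    assert abs(np.mean(dens) - 0.005) < 3 * se
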