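"""Generator contracts: determinism, parameter recovery, structural invariants."""

from dataclasses import replace

import numpy as np
import pytest

from isochron.axon_analysis import detect_retraction_bulbs
from isochron.model_io import TargetClass, validate_dataset, write_dataset
from isochron.morphometry import bulk_2d_density, whole_dendrite_fragment, fragment_density
from isochron.synthetic import (
    generate_axon,
    generate_boutons,
    generate_dendrite,
    generate_fov_counts,
    generate_mitochondria,
    generate_soma,
    simulate_dataset,
)


def _sem(x):
    return np.std(x, ddof=1) / np.sqrt(len(x))


# -- determinism -------------------------------------------------------------

def test_fixed_seed_gives_byte_identical_dataset(tmp_path, mouse_p14):
    a = simulate_dataset(mouse_p14, n_dendrites=3, n_somata=2, n_axons=3, seed=42)
    b = simulate_dataset(mouse_p14, n_dendrites=3, n_somata=2, n_axons=3, seed=42)
    write_dataset(a, tmp_path / "a")
    write_dataset(b, tmp_path / "b")
    for fn in ("skeletons.swc", "synapses.csv", "filopodia.csv",
               "mitochondria.csv", "metadata.json"):
        assert (tmp_path / "a" / fn).read_bytes() == (tmp_path / "b" / fn).read_bytes(), fn


def test_different_seed_changes_dataset(mouse_p14):
    a = simulate_dataset(mouse_p14, n_dendrites=2, n_somata=1, n_axons=1, seed=1)
    b = simulate_dataset(mouse_p14, n_dendrites=2, n_somata=1, n_axons=1, seed=2)
    assert len(a.synapses) != len(b.synapses) or any(
        not np.allclose(x.position, y.position)
        for x, y in zip(a.synapses, b.synapses))


# -- dendrites ---------------------------------------------------------------

def test_zero_spine_rate_never_places_spines(mouse_p105):
    p = replace(mouse_p105, spine_rate=0.0)
    for i in range(10):
        dd = generate_dendrite(p, 20.0, seed=i)
        assert not any(s.target_class == TargetClass.SPINE for s in dd.synapses)


def test_negative_length_rejected(mouse_p105):
    with pytest.raises(ValueError):
        generate_dendrite(mouse_p105, -1.0)


def test_spine_density_recovers_profile_rate(mouse_p105):
    """200 ten-µm fragments: Poisson thinning oracle, mean within 3 SE of 2.1/µm."""
    dens = []
    for i in range(200):
        dd = generate_dendrite(mouse_p105, 10.0, seed=101, cell_index=i)
        frag = whole_dendrite_fragment(dd.skeletons[0])
        dens.append(fragment_density(frag, dd, "spine"))
    assert abs(np.mean(dens) - mouse_p105.spine_rate) < 3 * _sem(dens)


def test_density_estimator_unbiased_for_all_bundled_profiles():
    """|mean − rate| < 3 SE over 200 fragments, for every bundled profile."""
    from isochron.profiles import bundled_profile_names, load_profile

    for k, name in enumerate(bundled_profile_names()):
        p = load_profile(name)
        dens = []
        for i in range(200):
            dd = generate_dendrite(p, 10.0, seed=500 + k, cell_index=i)
            frag = whole_dendrite_fragment(dd.skeletons[0])
            dens.append(fragment_density(frag, dd, "spine"))
        se = max(_sem(dens), np.sqrt(p.spine_rate / 10.0 / 200) if p.spine_rate else 1e-3)
        assert abs(np.mean(dens) - p.spine_rate) < 3 * se, name


# -- somata ------------------------------------------------------------------

def test_zero_axon_mean_gives_empty_soma(mouse_p105):
    p = replace(mouse_p105, axons_per_soma_mean=0.0, soma_synapse_mean=0.0)
    sd = generate_soma(p, seed=0)
    assert sd.synapses == []


def test_soma_counts_recover_profile_means(mouse_p105):
    totals, axons = [], []
    for i in range(500):
        sd = generate_soma(mouse_p105, seed=7, cell_index=i)
        per_axon = {}
        for s in sd.synapses:
            per_axon[s.pre_axon_id] = per_axon.get(s.pre_axon_id, 0) + 1
        assert sum(per_axon.values()) == len(sd.synapses)  # conservation, every draw
        totals.append(len(sd.synapses))
        axons.append(len(per_axon))
    assert abs(np.mean(totals) - mouse_p105.soma_synapse_mean) < 3 * _sem(totals)
    assert abs(np.mean(axons) - mouse_p105.axons_per_soma_mean) < 3 * _sem(axons)


# -- axons -------------------------------------------------------------------

def test_zero_branch_rate_gives_unbranched_polyline(primate_p7):
    p = replace(primate_p7, axon_branch_rate=0.0)
    ad = generate_axon(p, seed=3)
    axon = ad.skeletons[0]
    assert all(len(kids) <= 1 for kids in axon.children().values())


def test_axon_synapse_rate_recovered(primate_p7):
    freqs = []
    for i in range(300):
        ad = generate_axon(primate_p7, seed=8, axon_index=i)
        axon = ad.skeletons[0]
        n = sum(1 for s in ad.synapses if s.pre_axon_id == axon.cell_id)
        freqs.append(n / axon.cable_length())
    assert abs(np.mean(freqs) - primate_p7.axon_synapse_rate) < 3 * _sem(freqs)


def test_bulb_axon_detected_by_detector(primate_p75):
    """Generator/detector closure: the planted bulb terminal is the one flagged."""
    for i in range(5):
        ad = generate_axon(primate_p75, with_retraction_bulb=True, seed=21, axon_index=i)
        hits = detect_retraction_bulbs(ad.skeletons[0], ad)
        assert hits == [ad.metadata["bulb_terminal"]]


# -- boutons and FOV counts --------------------------------------------------

def test_boutons_recover_vesicle_mean(mouse_p6):
    df = generate_boutons(mouse_p6, 500, seed=4)
    v = df["vesicle_count"].to_numpy()
    assert abs(v.mean() - mouse_p6.vesicle_count_mean) < 3 * _sem(v)
    assert (v >= 1).all()


def test_fov_zero_density_all_zero():
    df = generate_fov_counts(0.0, 4, 20.0, seed=0)
    assert len(df) == 0
    res = bulk_2d_density(df, 20.0, n_fov=4)
    assert res.mean == 0.0 and res.sem == 0.0


def test_fov_qualifying_total_matches_poisson_mean():
    """0.465/µm² × 4 FOV × 20 µm² → 37.2 qualifying synapses on average."""
    totals = []
    for rep in range(1000):
        df = generate_fov_counts(0.465, 4, 20.0, seed=rep)
        totals.append((df["vesicle_count"] >= 5).sum())
    assert abs(np.mean(totals) - 37.2) < 3 * _sem(totals)


def test_fov_all_distractors_measure_zero():
    df = generate_fov_counts(0.465, 4, 20.0, seed=1, distractor_fraction=1.0)
    res = bulk_2d_density(df, 20.0, min_vesicles=5, n_fov=4)
    assert res.mean == 0.0


# -- mitochondria ------------------------------------------------------------

def _mito_records(profile, n, length, seed):
    dens_syn, dens_mito = [], []
    for i in range(n):
        dd = generate_dendrite(profile, length, seed=seed, cell_index=i)
        sk = dd.skeletons[0]
        mitos = generate_mitochondria(dd, profile, seed=seed, dendrite_index=i)
        n_spine = sum(1 for s in dd.synapses if s.target_class == TargetClass.SPINE)
        dens_syn.append(n_spine / length)
        dens_mito.append(sum(m.volume for m in mitos) / (length * 1000.0))
        assert all(m.volume > 0 for m in mitos)
    return np.asarray(dens_mito), np.asarray(dens_syn)


def test_mito_zero_correlation_profile(mouse_p105):
    p = replace(mouse_p105, mito_synapse_corr=0.0)
    m, s = _mito_records(p, 500, 30.0, seed=31)
    r = np.corrcoef(m, s)[0, 1]
    assert abs(r) < 0.1


def test_mito_target_correlation_recovered(mouse_p105):
    """Basal dendrites, target r = 0.54: sample r within the Fisher-z band."""
    m, s = _mito_records(mouse_p105, 500, 30.0, seed=32)
    r = np.corrcoef(m, s)[0, 1]
    assert 0.44 < r < 0.64


def test_mito_density_mean_recovered(mouse_p105):
    m, _ = _mito_records(mouse_p105, 200, 30.0, seed=33)
    assert abs(m.mean() - mouse_p105.mito_density_mean) < 3 * _sem(m)


# -- whole datasets ----------------------------------------------------------

@pytest.mark.parametrize("profile_name", ["mouse_V1_L23_p6", "mouse_V1_L23_p105",
                                          "primate_V1_L23_p75"])
def test_simulated_datasets_always_validate(profile_name):
    from isochron.profiles import load_profile

    ds = simulate_dataset(load_profile(profile_name), n_dendrites=3, n_somata=2,
                          n_axons=2, seed=77)
    rep = validate_dataset(ds)
    assert rep.ok, rep.findings[:5]
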