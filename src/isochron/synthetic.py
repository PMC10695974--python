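"""Synthetic annotation-data generators.

Each generator draws a piece of a :class:`~isochron.model_io.Dataset` whose
statistical structure matches what the measurement modules assume:

* synapses and filopodia are placed along dendritic cable as independent
  homogeneous Poisson processes at the profile rates;
* somatic innervation is a Poisson number of axons, each contributing
  ``1 + Poisson`` synapses, rescaled so the total matches the profile mean;
* axons carry Poisson branch points and output synapses per µm of cable;
* PSD areas are log-normal, bouton radii derive from a log-normal bouton
  volume, vesicle counts are shifted Poisson;
* per-dendrite mitochondrial coverage is a linear-plus-noise function of
  spine-synapse density solved to hit a target mean and Pearson correlation.

Determinism contract: a fixed ``(profile, seed)`` yields a byte-identical
dataset.  All sub-streams are derived from the dataset seed with
counter-based ``numpy.random.SeedSequence`` spawn keys, so generation order
cannot perturb any stream.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model_io import (
    CellClass,
    Compartment,
    Dataset,
    FilopodiumAnnotation,
    MitochondrionInstance,
    Skeleton,
    SkeletonNode,
    SynapseAnnotation,
    TargetClass,
)
from .profiles import AgeProfile

__all__ = [
    "generate_dendrite",
    "generate_soma",
    "generate_axon",
    "generate_boutons",
    "generate_fov_counts",
    "generate_mitochondria",
    "simulate_dataset",
]

#: Mean spine length used to offset spine-synapse positions from the shaft,
#: in µm.  Matches the measured spine-to-branch distance scale (~1.1 µm).
SPINE_OFFSET_MEAN = 1.107
SPINE_OFFSET_SD = 0.097

#: Fraction of excitatory-axon output synapses that target spines (the rest
#: target shafts); soma targets are not drawn for excitatory axons.
AXON_SPINE_TARGET_FRACTION = 0.76

#: Log-sd of the bouton volume distribution (volumes are log-normal with the
#: profile mean).
BOUTON_VOLUME_LOGSD = 0.4

#: Retraction-bulb construction: terminal radius factor over the axon base
#: radius, and number of clustered mitochondria placed in the bulb.
BULB_RADIUS_FACTOR = 3.0
BULB_N_MITOS = 4
BULB_MITO_VOLUME = 3.0e7  # nm³, per clustered mitochondrion

#: Coefficient of variation of per-dendrite mitochondria density around the
#: profile mean.
MITO_DENSITY_CV = 0.25


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream: same (seed, key) -> same stream, always."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _polyline_points(
    rng: np.random.Generator,
    start: np.ndarray,
    length_um: float,
    step: float = 1.0,
    jitter: float = 0.15,
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Random-walk polyline with exact total arc length ``length_um``."""
    d = _unit(rng.normal(size=3)) if direction is None else _unit(direction)
    pts = [np.asarray(start, dtype=float)]
    remaining = length_um
    while remaining > 1e-12:
        d = _unit(d + jitter * rng.normal(size=3))
        seg = min(step, remaining)
        pts.append(pts[-1] + d * seg)
        remaining -= seg
    return np.asarray(pts)


def _perpendicular(rng: np.random.Generator, direction: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= v.dot(direction) * direction
    n = np.linalg.norm(v)
    if n < 1e-12:  # pathological draw parallel to the cable
        v = np.cross(direction, [1.0, 0.0, 0.0])
        n = np.linalg.norm(v)
    return v / n


def _bouton_radius(rng: np.random.Generator, mean_volume: float) -> float:
    """Radius of a sphere whose volume is log-normal with the given mean."""
    mu = math.log(mean_volume) - BOUTON_VOLUME_LOGSD**2 / 2
    vol = rng.lognormal(mu, BOUTON_VOLUME_LOGSD)
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def _vesicle_count(rng: np.random.Generator, mean: float) -> int:
    """Shifted Poisson: every bouton holds at least one vesicle."""
    if mean <= 1:
        return 1
    return int(1 + rng.poisson(mean - 1.0))


def _psd_area(rng: np.random.Generator, profile: AgeProfile) -> float:
    return float(rng.lognormal(profile.psd_logmean, profile.psd_logsd))


# ---------------------------------------------------------------------------
# dendrites
# ---------------------------------------------------------------------------

def generate_dendrite(
    profile: AgeProfile,
    length_um: float,
    compartment: Compartment = Compartment.DENDRITE_BASAL,
    seed: int = 0,
    *,
    cell_index: int = 0,
    node_id_start: int = 1,
) -> Dataset:
    """One dendrite skeleton with Poisson-placed spine/shaft synapses and filopodia.

    Spine, shaft and filopodium events are three independent homogeneous
    Poisson processes along the cable at the profile rates.  Each spine
    synapse sits ~1.1 µm off the shaft; shaft synapses sit on the cable.
    """
    if not length_um > 0:
        raise ValueError(f"length_um must be > 0, got {length_um}")
    rng = _rng(seed, 0, cell_index)
    cell_id = f"d{cell_index:04d}"
    origin = rng.uniform(-200.0, 200.0, size=3)
    pts = _polyline_points(rng, origin, length_um)
    base_r = rng.uniform(0.35, 0.45)
    radii = np.clip(base_r + rng.normal(0.0, 0.02, size=len(pts)), 0.05, None)
    nodes: dict[int, SkeletonNode] = {}
    ids = list(range(node_id_start, node_id_start + len(pts)))
    for k, nid in enumerate(ids):
        nodes[nid] = SkeletonNode(
            node_id=nid,
            position=pts[k],
            radius=float(radii[k]),
            parent_id=None if k == 0 else ids[k - 1],
            compartment=compartment,
        )
    sk = Skeleton(skeleton_id=cell_id, nodes=nodes, cell_id=cell_id,
                  cell_class=CellClass.EXCITATORY)

    # cumulative arc length -> node lookup (node k covers [cum[k-1], cum[k]])
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    def node_at(dist: float) -> int:
        k = int(np.searchsorted(cum, dist, side="right")) - 1
        return ids[min(max(k, 0), len(ids) - 1)]

    ds = Dataset(skeletons=[sk])
    ds.metadata = {"profile": profile.name, "seed": seed}

    n_spine = rng.poisson(profile.spine_rate * length_um)
    n_shaft = rng.poisson(profile.shaft_rate * length_um)
    n_filo = rng.poisson(profile.filopodia_rate * length_um)

    for j in range(n_spine):
        dist = rng.uniform(0.0, length_um)
        nid = nodes[node_at(dist)]
        k = ids.index(nid.node_id)
        local_dir = _unit(pts[min(k + 1, len(pts) - 1)] - pts[max(k - 1, 0)])
        offset = abs(rng.normal(SPINE_OFFSET_MEAN, SPINE_OFFSET_SD))
        pos = nid.position + _perpendicular(rng, local_dir) * offset
        vc = _vesicle_count(rng, profile.vesicle_count_mean)
        ds.synapses.append(SynapseAnnotation(
            synapse_id=f"{cell_id}-sp{j:04d}",
            pre_axon_id=f"{cell_id}-preax{j:04d}",
            post_cell_id=cell_id, post_node_id=nid.node_id,
            target_class=TargetClass.SPINE, position=pos,
            psd_area=_psd_area(rng, profile), vesicle_count=vc,
            bouton_radius=_bouton_radius(rng, profile.bouton_volume_mean),
            vesicle_cloud_size=float(vc * 6.0e4 * rng.lognormal(0.0, 0.2)),
            pre_excitatory=True,
        ))
    for j in range(n_shaft):
        dist = rng.uniform(0.0, length_um)
        nid = nodes[node_at(dist)]
        excit = bool(rng.random() < profile.excitatory_shaft_fraction)
        vc = _vesicle_count(rng, profile.vesicle_count_mean)
        ds.synapses.append(SynapseAnnotation(
            synapse_id=f"{cell_id}-sh{j:04d}",
            pre_axon_id=f"{cell_id}-shax{j:04d}",
            post_cell_id=cell_id, post_node_id=nid.node_id,
            target_class=TargetClass.SHAFT,
            position=nid.position + rng.normal(0.0, 0.05, size=3),
            psd_area=_psd_area(rng, profile), vesicle_count=vc,
            bouton_radius=_bouton_radius(rng, profile.bouton_volume_mean),
            vesicle_cloud_size=float(vc * 6.0e4 * rng.lognormal(0.0, 0.2)),
            pre_excitatory=excit,
        ))
    for j in range(n_filo):
        dist = rng.uniform(0.0, length_um)
        ds.filopodia.append(FilopodiumAnnotation(
            filopodium_id=f"{cell_id}-fl{j:04d}",
            post_cell_id=cell_id,
            base_node_id=node_at(dist),
            length=float(rng.uniform(2.0, 6.0)),
        ))
    return ds


# ---------------------------------------------------------------------------
# somata
# ---------------------------------------------------------------------------

#: Default soma radius in µm (node radius of generated somata).
SOMA_RADIUS_UM = 7.0


def generate_soma(
    profile: AgeProfile,
    seed: int = 0,
    *,
    cell_index: int = 0,
    node_id_start: int = 1,
) -> Dataset:
    """One complete soma plus its somatic (perisomatic, PV-type) synapses.

    The number of innervating axons is Poisson(``axons_per_soma_mean``); each
    axon contributes ``1 + Poisson(lam)`` synapses with ``lam`` solved so the
    expected total equals ``soma_synapse_mean``.
    """
    rng = _rng(seed, 1, cell_index)
    cell_id = f"s{cell_index:04d}"
    center = rng.uniform(-200.0, 200.0, size=3)
    nid = node_id_start
    sk = Skeleton(
        skeleton_id=cell_id,
        nodes={nid: SkeletonNode(nid, center, SOMA_RADIUS_UM, None, Compartment.SOMA)},
        cell_id=cell_id, cell_class=CellClass.EXCITATORY, soma_complete=True,
    )
    ds = Dataset(skeletons=[sk])
    ds.metadata = {"profile": profile.name, "seed": seed}

    n_axons = int(rng.poisson(profile.axons_per_soma_mean))
    if profile.axons_per_soma_mean > 0:
        lam = max(0.0, profile.soma_synapse_mean / profile.axons_per_soma_mean - 1.0)
    else:
        lam = 0.0
    j = 0
    for a in range(n_axons):
        axon_id = f"{cell_id}-ax{a:03d}"
        for _ in range(1 + int(rng.poisson(lam))):
            u = _unit(rng.normal(size=3))
            vc = _vesicle_count(rng, profile.vesicle_count_mean)
            ds.synapses.append(SynapseAnnotation(
                synapse_id=f"{cell_id}-so{j:04d}",
                pre_axon_id=axon_id,
                post_cell_id=cell_id, post_node_id=nid,
                target_class=TargetClass.SOMA,
                position=center + u * SOMA_RADIUS_UM,
                psd_area=_psd_area(rng, profile), vesicle_count=vc,
                bouton_radius=_bouton_radius(rng, profile.bouton_volume_mean),
                vesicle_cloud_size=float(vc * 6.0e4 * rng.lognormal(0.0, 0.2)),
                pre_excitatory=False,
            ))
            j += 1
    return ds


# ---------------------------------------------------------------------------
# axons
# ---------------------------------------------------------------------------

def generate_axon(
    profile: AgeProfile,
    with_retraction_bulb: bool = False,
    seed: int = 0,
    *,
    length_um: float = 60.0,
    axon_index: int = 0,
    node_id_start: int = 1,
) -> Dataset:
    """One excitatory axon: branched skeleton, output synapses, optional bulb.

    The branch count is Poisson(``axon_branch_rate × length``) and the output
    synapse count Poisson(``axon_synapse_rate × length``), with total cable
    held at exactly ``length_um`` (a tree with ``b`` branch points is built
    from ``2b + 1`` equal-length segments).  With a retraction bulb, one
    terminal node is inflated to ``BULB_RADIUS_FACTOR ×`` the axon base
    radius and ``BULB_N_MITOS`` mitochondria are clustered on it.

    The postsynaptic partners of the output synapses lie outside the traced
    cells, so a small stub skeleton hosts their target nodes.
    """
    if not length_um > 0:
        raise ValueError(f"length_um must be > 0, got {length_um}")
    rng = _rng(seed, 2, axon_index)
    axon_id = f"a{axon_index:04d}"
    base_r = 0.3
    n_branch = int(rng.poisson(profile.axon_branch_rate * length_um))
    n_segments = 2 * n_branch + 1
    seg_length = length_um / n_segments

    nodes: dict[int, SkeletonNode] = {}
    next_id = node_id_start

    def add_node(pos: np.ndarray, parent: int | None, radius: float) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = SkeletonNode(nid, pos, radius, parent, Compartment.AXON)
        return nid

    origin = rng.uniform(-200.0, 200.0, size=3)
    root = add_node(origin, None, base_r)

    def grow_segment(parent: int, direction: np.ndarray) -> int:
        """Append one segment of seg_length starting after ``parent``."""
        pts = _polyline_points(rng, nodes[parent].position, seg_length,
                               direction=direction)
        last = parent
        for p in pts[1:]:
            r = float(np.clip(base_r + rng.normal(0.0, 0.03), 0.05, 0.5))
            last = add_node(p, last, r)
        return last

    leaves: list[int] = []

    def build(parent: int, direction: np.ndarray, branch_budget: int) -> None:
        tip = grow_segment(parent, direction)
        if branch_budget == 0:
            leaves.append(tip)
            return
        left = int(rng.integers(0, branch_budget))  # split remaining branches
        d1 = _unit(direction + 0.8 * rng.normal(size=3))
        d2 = _unit(direction + 0.8 * rng.normal(size=3))
        build(tip, d1, left)
        build(tip, d2, branch_budget - 1 - left)

    build(root, _unit(rng.normal(size=3)), n_branch)

    sk = Skeleton(skeleton_id=axon_id, nodes=nodes, cell_id=axon_id,
                  cell_class=CellClass.EXCITATORY)
    ds = Dataset(skeletons=[sk])
    ds.metadata = {"profile": profile.name, "seed": seed}

    # output synapses, uniform over cable (edge-length weighted node choice)
    nids = sorted(nodes)
    edge_w = np.array([sk.edge_length(nid) for nid in nids])
    n_syn = int(rng.poisson(profile.axon_synapse_rate * length_um))
    stub_nodes: dict[int, SkeletonNode] = {}
    stub_id = f"{axon_id}-post"
    prev_stub = None
    if edge_w.sum() > 0:
        probs = edge_w / edge_w.sum()
        for j in range(n_syn):
            nid = int(rng.choice(nids, p=probs))
            target = (TargetClass.SPINE
                      if rng.random() < AXON_SPINE_TARGET_FRACTION
                      else TargetClass.SHAFT)
            pos = nodes[nid].position + rng.normal(0.0, 0.3, size=3)
            post_nid = next_id
            next_id += 1
            stub_nodes[post_nid] = SkeletonNode(
                post_nid, pos + np.array([0.0, 0.0, 0.3]), 0.3, prev_stub,
                Compartment.DENDRITE_BASAL)
            prev_stub = post_nid
            vc = _vesicle_count(rng, profile.vesicle_count_mean)
            ds.synapses.append(SynapseAnnotation(
                synapse_id=f"{axon_id}-sy{j:04d}",
                pre_axon_id=axon_id,
                post_cell_id=stub_id, post_node_id=post_nid,
                target_class=target, position=pos,
                psd_area=_psd_area(rng, profile), vesicle_count=vc,
                bouton_radius=_bouton_radius(rng, profile.bouton_volume_mean),
                vesicle_cloud_size=float(vc * 6.0e4 * rng.lognormal(0.0, 0.2)),
                pre_excitatory=True,
            ))
    if stub_nodes:
        ds.skeletons.append(Skeleton(
            skeleton_id=stub_id, nodes=stub_nodes, cell_id=stub_id,
            cell_class=CellClass.UNCLASSIFIED))

    if with_retraction_bulb:
        bulb = leaves[int(rng.integers(0, len(leaves)))]
        nodes[bulb].radius = base_r * BULB_RADIUS_FACTOR
        for k in range(BULB_N_MITOS):
            ds.mitochondria.append(MitochondrionInstance(
                mito_id=f"{axon_id}-bm{k:02d}",
                host_skeleton_id=axon_id,
                volume=float(rng.lognormal(math.log(BULB_MITO_VOLUME), 0.3)),
                start_node_id=bulb, end_node_id=bulb,
            ))
        ds.metadata["bulb_terminal"] = bulb
    return ds


# ---------------------------------------------------------------------------
# boutons, FOV counts, mitochondria
# ---------------------------------------------------------------------------

def generate_boutons(profile: AgeProfile, n: int, seed: int = 0) -> pd.DataFrame:
    """n presynaptic boutons: vesicle counts, radii, PSD areas (one row each)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, 5)
    rows = [{
        "bouton_id": f"b{j:05d}",
        "vesicle_count": _vesicle_count(rng, profile.vesicle_count_mean),
        "bouton_radius": _bouton_radius(rng, profile.bouton_volume_mean),
        "psd_area": _psd_area(rng, profile),
    } for j in range(n)]
    return pd.DataFrame(rows)


def generate_fov_counts(
    density_2d: float,
    n_fov: int,
    fov_area_um2: float,
    seed: int = 0,
    distractor_fraction: float = 0.0,
) -> pd.DataFrame:
    """Per-FOV synapse detections for the single-section density estimate.

    Detections per FOV are Poisson(``density_2d × area``); each detection is
    independently a sub-threshold distractor (vesicle count below 5) with
    probability ``distractor_fraction``, otherwise a qualifying synapse with
    ≥ 5 vesicles.  Returns one row per detection (``fov_id, vesicle_count``);
    the FOV count travels in ``df.attrs['n_fov']`` so empty FOVs are kept.
    """
    if n_fov < 1:
        raise ValueError("n_fov must be >= 1")
    if not fov_area_um2 > 0:
        raise ValueError("fov_area_um2 must be > 0")
    rng = _rng(seed, 6)
    rows = []
    for f in range(n_fov):
        for _ in range(int(rng.poisson(density_2d * fov_area_um2))):
            if rng.random() < distractor_fraction:
                vc = int(rng.integers(0, 5))  # sub-threshold: 0..4 vesicles
            else:
                vc = int(5 + rng.poisson(25.0))
            rows.append({"fov_id": f, "vesicle_count": vc})
    df = pd.DataFrame(rows, columns=["fov_id", "vesicle_count"])
    df.attrs["n_fov"] = n_fov
    df.attrs["fov_area_um2"] = fov_area_um2
    return df


def generate_mitochondria(
    dendrite: Dataset,
    profile: AgeProfile,
    seed: int = 0,
    *,
    dendrite_index: int = 0,
) -> list[MitochondrionInstance]:
    """Mitochondria for one generated dendrite.

    The per-dendrite mitochondria density (nm³ volume per nm cable, i.e. nm²)
    is ``mean + slope × (spine density − rate) + noise`` with slope and noise
    solved so the across-dendrite mean is ``mito_density_mean`` and the
    Pearson correlation with spine-synapse density is ``mito_synapse_corr``
    for basal dendrites (apical dendrites are uncorrelated).  The total
    volume is split across a Poisson number of instances.
    """
    if not -1.0 <= profile.mito_synapse_corr <= 1.0:
        raise ValueError(f"infeasible correlation {profile.mito_synapse_corr}")
    sk = dendrite.skeletons[0]
    rng = _rng(seed, 3, dendrite_index)
    length = sk.cable_length()
    if length <= 0:
        raise ValueError("dendrite has zero cable length")
    mu = profile.mito_density_mean
    if mu <= 0:
        return []
    comp = next(iter(sk.nodes.values())).compartment
    r = profile.mito_synapse_corr if comp == Compartment.DENDRITE_BASAL else 0.0
    sigma_m = MITO_DENSITY_CV * mu
    n_spine = sum(1 for s in dendrite.synapses
                  if s.post_cell_id == sk.cell_id and s.target_class == TargetClass.SPINE)
    s_density = n_spine / length
    m = mu + sigma_m * math.sqrt(max(0.0, 1.0 - r * r)) * rng.normal()
    if r != 0.0 and profile.spine_rate > 0:
        sigma_s = math.sqrt(profile.spine_rate / length)  # Poisson count / length
        m += r * sigma_m * (s_density - profile.spine_rate) / sigma_s
    m = max(m, 0.05 * mu)  # coverage is strictly positive
    total_volume = m * length * 1000.0  # nm² × (length in nm)

    n_mito = 1 + int(rng.poisson(length / 8.0))
    shares = rng.dirichlet(np.ones(n_mito))
    nids = sorted(sk.nodes)
    out = []
    for k in range(n_mito):
        i, j = sorted(rng.integers(0, len(nids), size=2))
        out.append(MitochondrionInstance(
            mito_id=f"{sk.skeleton_id}-mt{k:04d}",
            host_skeleton_id=sk.skeleton_id,
            volume=float(total_volume * shares[k]),
            start_node_id=nids[i], end_node_id=nids[j],
        ))
    return out


# ---------------------------------------------------------------------------
# whole-dataset assembly
# ---------------------------------------------------------------------------

def simulate_dataset(
    profile: AgeProfile,
    n_dendrites: int = 20,
    n_somata: int = 8,
    n_axons: int = 50,
    seed: int = 0,
    *,
    dendrite_length_um: float = 100.0,
    axon_length_um: float = 60.0,
    n_bulb_axons: int = 0,
    apical_every: int = 3,
    with_shaft_axons: bool = True,
) -> Dataset:
    """Assemble a full dataset: dendrites (+ mitochondria), somata, axons.

    Every ``apical_every``-th dendrite is apical, the rest basal.  When
    ``with_shaft_axons`` is set, each shaft synapse on a dendrite gets a
    traceable presynaptic axon making three further synapses (onto a shared
    unclassified target pool), at least one of them a spine synapse iff the
    shaft input was drawn excitatory — this is what the axon-classification
    rule consumes.
    """
    ds = Dataset()
    ds.metadata = {
        "profile": profile.name, "species": profile.species,
        "region": profile.region, "layer": profile.layer,
        "age_days": profile.age_days, "seed": seed,
        "n_dendrites": n_dendrites, "n_somata": n_somata, "n_axons": n_axons,
    }
    next_node = 1
    for i in range(n_dendrites):
        comp = (Compartment.DENDRITE_APICAL
                if apical_every and i % apical_every == apical_every - 1
                else Compartment.DENDRITE_BASAL)
        dd = generate_dendrite(profile, dendrite_length_um, comp, seed,
                               cell_index=i, node_id_start=next_node)
        next_node += len(dd.skeletons[0].nodes)
        ds.skeletons += dd.skeletons
        ds.synapses += dd.synapses
        ds.filopodia += dd.filopodia
        ds.mitochondria += generate_mitochondria(dd, profile, seed, dendrite_index=i)
    for i in range(n_somata):
        sd = generate_soma(profile, seed, cell_index=i, node_id_start=next_node)
        next_node += 1
        ds.skeletons += sd.skeletons
        ds.synapses += sd.synapses
    for i in range(n_axons):
        ad = generate_axon(profile, with_retraction_bulb=i < n_bulb_axons,
                           seed=seed, length_um=axon_length_um,
                           axon_index=i, node_id_start=next_node)
        next_node = 1 + max((max(s.nodes) for s in ad.skeletons), default=next_node)
        ds.skeletons += ad.skeletons
        ds.synapses += ad.synapses
        ds.mitochondria += ad.mitochondria
        if "bulb_terminal" in ad.metadata:
            ds.metadata.setdefault("bulb_terminals", {})[ad.skeletons[0].skeleton_id] = \
                ad.metadata["bulb_terminal"]
    if with_shaft_axons:
        next_node = _attach_shaft_axons(ds, profile, seed, next_node)
    return ds


def _attach_shaft_axons(ds: Dataset, profile: AgeProfile, seed: int, next_node: int) -> int:
    """Give every dendritic shaft synapse a traceable presynaptic axon."""
    pool_nodes: dict[int, SkeletonNode] = {}
    pool_id = "shaftpool"
    prev_pool: int | None = None
    shaft_syns = [s for s in ds.synapses
                  if s.target_class == TargetClass.SHAFT and s.pre_axon_id.count("-shax")]
    for k, syn in enumerate(shaft_syns):
        rng = _rng(seed, 4, k)
        axon_id = f"shx{k:04d}"
        syn.pre_axon_id = axon_id
        # short polyline axon through the seed bouton
        pts = _polyline_points(rng, syn.position, 8.0)
        ids = list(range(next_node, next_node + len(pts)))
        next_node += len(pts)
        nodes = {
            nid: SkeletonNode(nid, pts[j], 0.3, None if j == 0 else ids[j - 1],
                              Compartment.AXON)
            for j, nid in enumerate(ids)
        }
        ds.skeletons.append(Skeleton(skeleton_id=axon_id, nodes=nodes,
                                     cell_id=axon_id,
                                     cell_class=CellClass.UNCLASSIFIED))
        # three additional synapses along the trace, in path order
        spine_slot = int(rng.integers(0, 3)) if syn.pre_excitatory else -1
        for a, node_k in enumerate((3, 5, 7)):
            target = TargetClass.SPINE if a == spine_slot else TargetClass.SHAFT
            pos = pts[node_k] + rng.normal(0.0, 0.2, size=3)
            pool_nid = next_node
            next_node += 1
            pool_nodes[pool_nid] = SkeletonNode(
                pool_nid, pos + np.array([0.0, 0.3, 0.0]), 0.3, prev_pool,
                Compartment.DENDRITE_BASAL)
            prev_pool = pool_nid
            ds.synapses.append(SynapseAnnotation(
                synapse_id=f"{axon_id}-extra{a}",
                pre_axon_id=axon_id,
                post_cell_id=pool_id, post_node_id=pool_nid,
                target_class=target, position=pos,
                psd_area=_psd_area(rng, profile),
                vesicle_count=_vesicle_count(rng, profile.vesicle_count_mean),
                bouton_radius=_bouton_radius(rng, profile.bouton_volume_mean),
                pre_excitatory=bool(syn.pre_excitatory),
            ))
    if pool_nodes:
        ds.skeletons.append(Skeleton(skeleton_id=pool_id, nodes=pool_nodes,
                                     cell_id=pool_id,
                                     cell_class=CellClass.UNCLASSIFIED))
    return next_node
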