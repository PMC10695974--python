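"""Soma-centric analysis: somatic synapse counts, innervating axons, boutons.

Somatic synapses on cortical excitatory neurons are perisomatic inhibitory
contacts (PV-interneuron type).  A :class:`SomaInnervationProfile` tallies
them per distinct presynaptic axon; bouton geometry converts fitted bouton
radii to surface areas and volumes; PSD occupancy asks what fraction of a
(spherical) soma surface the somatic PSDs cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model_io import Compartment, Dataset, TargetClass

__all__ = [
    "SomaInnervationProfile",
    "soma_profile",
    "perisomatic_tally",
    "bouton_geometry",
    "psd_occupancy",
]


@dataclass
class SomaInnervationProfile:
    cell_id: str
    total_soma_synapses: int
    innervating_axons: int
    per_axon_counts: dict[str, int] = field(default_factory=dict)
    mean_bouton_volume: float | None = None  # µm³
    psd_occupancy_fraction: float | None = None

    def __post_init__(self) -> None:
        assert sum(self.per_axon_counts.values()) == self.total_soma_synapses
        assert len(self.per_axon_counts) == self.innervating_axons


def soma_profile(cell_id: str, dataset: Dataset) -> SomaInnervationProfile:
    """Tally somatic synapses on one cell, grouped by presynaptic axon.

    Only cells whose soma is fully contained in the volume are admissible
    (the ``soma_complete`` flag on the soma skeleton); an incomplete soma
    raises, since a partial tally would understate innervation.
    """
    skels = dataset.skeletons_of_cell(cell_id)
    if not skels:
        raise KeyError(f"no skeletons for cell {cell_id!r}")
    has_soma_nodes = any(
        n.compartment == Compartment.SOMA for sk in skels for n in sk.nodes.values()
    )
    if has_soma_nodes and not all(sk.soma_complete for sk in skels):
        raise ValueError(f"cell {cell_id!r}: soma not fully contained in the volume")
    per_axon: dict[str, int] = {}
    radii = []
    for s in dataset.synapses:
        if s.post_cell_id == cell_id and s.target_class == TargetClass.SOMA:
            per_axon[s.pre_axon_id] = per_axon.get(s.pre_axon_id, 0) + 1
            if s.bouton_radius is not None:
                radii.append(s.bouton_radius)
    mean_vol = (
        sum(bouton_geometry(r)["volume"] for r in radii) / len(radii) if radii else None
    )
    return SomaInnervationProfile(
        cell_id=cell_id,
        total_soma_synapses=sum(per_axon.values()),
        innervating_axons=len(per_axon),
        per_axon_counts=dict(sorted(per_axon.items())),
        mean_bouton_volume=mean_vol,
    )


def perisomatic_tally(cell_id: str, dataset: Dataset, first_um: float = 10.0) -> int:
    """Synapses on the first ``first_um`` µm of dendrite leaving the soma.

    Kept separate from the per-soma counts: the headline somatic metric is
    strictly the soma surface.
    """
    count = 0
    for sk in dataset.skeletons_of_cell(cell_id):
        soma_ids = {n.node_id for n in sk.nodes.values()
                    if n.compartment == Compartment.SOMA}
        if not soma_ids:
            continue
        # path distance from the soma for every dendritic node
        dist: dict[int, float] = {nid: 0.0 for nid in soma_ids}
        children = sk.children()
        stack = list(soma_ids)
        near: set[int] = set()
        while stack:
            cur = stack.pop()
            for kid in children[cur]:
                d = dist[cur] + sk.edge_length(kid)
                dist[kid] = d
                if sk.nodes[kid].compartment != Compartment.SOMA and d <= first_um:
                    near.add(kid)
                if d <= first_um:
                    stack.append(kid)
        count += sum(
            1 for s in dataset.synapses
            if s.post_cell_id == cell_id and s.post_node_id in near
            and s.target_class != TargetClass.SOMA
        )
    return count


def bouton_geometry(radius_um: float) -> dict[str, float]:
    """Sphere surface area (µm²) and volume (µm³) from a fitted bouton radius."""
    if not radius_um > 0:
        raise ValueError(f"radius must be > 0, got {radius_um}")
    return {
        "surface_area": 4.0 * math.pi * radius_um**2,
        "volume": 4.0 / 3.0 * math.pi * radius_um**3,
    }


def psd_occupancy(cell_id: str, dataset: Dataset, soma_radius_um: float) -> float:
    """Fraction of a spherical soma surface covered by somatic PSDs.

    Σ psd_area / (4π r²), both in nm².  Values above 1 are reported as
    given (the caller decides how to flag them).  Any somatic synapse
    lacking a PSD area raises, listing the offending synapse ids.
    """
    if not soma_radius_um > 0:
        raise ValueError("soma_radius_um must be > 0")
    missing = []
    total = 0.0
    n = 0
    for s in dataset.synapses:
        if s.post_cell_id == cell_id and s.target_class == TargetClass.SOMA:
            n += 1
            if s.psd_area is None:
                missing.append(s.synapse_id)
            else:
                total += s.psd_area
    if missing:
        raise ValueError(f"somatic synapses without psd_area: {missing}")
    if n == 0:
        return 0.0
    surface_nm2 = 4.0 * math.pi * (soma_radius_um * 1000.0) ** 2
    return total / surface_nm2
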