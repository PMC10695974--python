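"""Mitochondria morphometry and its correlation with synapse density.

Coverage is expressed as the published density unit nm² — total
mitochondrial volume (nm³) per nm of dendritic cable — kept verbatim so
printed values compare directly.  Membership is by the mitochondrion's
``host_skeleton_id`` span; a partial span contributes its full volume
(no apportioning model is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Compartment, Dataset, Skeleton, TargetClass
from .stats import pearson

__all__ = ["MitoDendriteRecord", "mito_dendrite_record", "coverage_synapse_correlation"]


@dataclass
class MitoDendriteRecord:
    skeleton_id: str
    compartment: Compartment
    cable_length: float  # µm
    total_mito_volume: float  # nm³
    mito_count: int
    mean_mito_size: float  # µm³
    synapse_density: float  # spine synapses / µm

    @property
    def mito_density(self) -> float:
        """nm³ of mitochondrion per nm of cable, i.e. nm²."""
        return self.total_mito_volume / (self.cable_length * 1000.0)


def mito_dendrite_record(dendrite: Skeleton, dataset: Dataset) -> MitoDendriteRecord:
    """Pair one dendrite's mitochondria coverage with its spine-synapse density."""
    length = dendrite.cable_length()
    if length <= 0:
        raise ValueError(f"dendrite {dendrite.skeleton_id} has zero cable length")
    vols = [m.volume for m in dataset.mitochondria
            if m.host_skeleton_id == dendrite.skeleton_id]
    n_spine = sum(
        1 for s in dataset.synapses
        if s.post_cell_id == dendrite.cell_id and s.target_class == TargetClass.SPINE
    )
    comps = {n.compartment for n in dendrite.nodes.values()}
    comp = (Compartment.DENDRITE_APICAL if Compartment.DENDRITE_APICAL in comps
            else Compartment.DENDRITE_BASAL)
    return MitoDendriteRecord(
        skeleton_id=dendrite.skeleton_id,
        compartment=comp,
        cable_length=length,
        total_mito_volume=float(sum(vols)),
        mito_count=len(vols),
        mean_mito_size=float(np.mean(vols)) / 1e9 if vols else 0.0,  # nm³ -> µm³
        synapse_density=n_spine / length,
    )


def coverage_synapse_correlation(
    records: list[MitoDendriteRecord],
    compartment_filter: str = "combined",
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between mito density and synapse density.

    ``compartment_filter`` ∈ {"apical", "basal", "combined"}.
    """
    if compartment_filter == "apical":
        recs = [r for r in records if r.compartment == Compartment.DENDRITE_APICAL]
    elif compartment_filter == "basal":
        recs = [r for r in records if r.compartment == Compartment.DENDRITE_BASAL]
    elif compartment_filter == "combined":
        recs = list(records)
    else:
        raise ValueError(f"unknown compartment_filter {compartment_filter!r}")
    if len(recs) < 3:
        raise ValueError("need at least 3 records after filtering")
    return pearson([r.mito_density for r in recs], [r.synapse_density for r in recs])
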